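"""The CTCF binding-site classifier.

Architecture: the forward-strand and reverse-complement k-mer embedding
matrices of a window are passed through a shared three-layer convolutional
stack (conv -> ReLU -> max-pool, three times); the two resulting feature
sequences are concatenated along the sequence axis and read by a
bidirectional GRU; the concatenated final states of the two directions feed
two dense layers ending in a sigmoid that outputs P(bound). Sharing the
convolutional weights across strands forces motif detectors to be reusable on
either strand. Embedding rows are frozen inputs, not trained parameters.

Training minimizes binary cross-entropy with Adam, early-stopping on the
best validation AUROC. All randomness is seeded; inference is deterministic
(dropout disabled).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import roc_auc_score

from . import nn
from .embedding import KmerEmbedding, reverse_complement, sequence_to_indices
from .sampling import LabeledSample

FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are sized for desk-scale CPU training."""

    window: int = 100
    k: int = 4
    dim: int = 100
    conv_channels: tuple[int, int, int] = (64, 64, 32)
    kernel_sizes: tuple[int, int, int] = (8, 4, 4)
    pool_sizes: tuple[int, int, int] = (2, 2, 2)
    gru_hidden: int = 64
    dense_hidden: int = 64
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 12
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_channels = tuple(self.conv_channels)
        self.kernel_sizes = tuple(self.kernel_sizes)
        self.pool_sizes = tuple(self.pool_sizes)
        if not (len(self.conv_channels) == len(self.kernel_sizes) == len(self.pool_sizes) == 3):
            raise ValueError("exactly 3 conv layers required")
        if any(v <= 0 for v in self.conv_channels + self.kernel_sizes + self.pool_sizes):
            raise ValueError("conv sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        # fail at build time if the conv/pool stack eats the whole sequence
        t = self.window - self.k + 1
        for kern, pool in zip(self.kernel_sizes, self.pool_sizes):
            t = (t - kern + 1) // pool
            if t <= 0:
                raise ValueError(
                    f"window {self.window} too short for conv/pool stack (length {t})"
                )
        self.conv_out_len = t

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        d["kernel_sizes"] = list(self.kernel_sizes)
        d["pool_sizes"] = list(self.pool_sizes)
        d.pop("conv_out_len", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d.pop("conv_out_len", None)
        return cls(**d)


class CBSModel:
    """Binding classifier: parameter dict plus config and training log."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = self._init_params(config)
        self.training_log: list[dict] = []

    # ------------------------------------------------------------ build --
    @staticmethod
    def _init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(cfg.seed)
        params: dict[str, np.ndarray] = {}
        cin = cfg.dim
        for i, (cout, kern) in enumerate(zip(cfg.conv_channels, cfg.kernel_sizes), 1):
            params[f"conv{i}_w"] = nn.he_init(rng, (kern * cin, cout), kern * cin)
            params[f"conv{i}_b"] = np.zeros(cout, dtype=nn.DTYPE)
            cin = cout
        for prefix in ("gru_fw", "gru_bw"):
            for name, shape in nn.gru_param_shapes(cin, cfg.gru_hidden, prefix).items():
                params[name] = (
                    np.zeros(shape, dtype=nn.DTYPE)
                    if name.endswith(("bz", "br", "bc"))
                    else nn.glorot_init(rng, shape)
                )
        params["dense1_w"] = nn.he_init(
            rng, (2 * cfg.gru_hidden, cfg.dense_hidden), 2 * cfg.gru_hidden
        )
        params["dense1_b"] = np.zeros(cfg.dense_hidden, dtype=nn.DTYPE)
        params["dense2_w"] = nn.glorot_init(rng, (cfg.dense_hidden, 1))
        params["dense2_b"] = np.zeros(1, dtype=nn.DTYPE)
        return params

    # ---------------------------------------------------------- forward --
    def _conv_stack(self, x: np.ndarray):
        caches = []
        for i, pool in enumerate(self.config.pool_sizes, 1):
            x, c_conv = nn.conv1d_forward(x, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"])
            x, c_relu = nn.relu_forward(x)
            x, c_pool = nn.maxpool1d_forward(x, pool)
            caches.append((c_conv, c_relu, c_pool))
        return x, caches

    def _conv_stack_backward(self, dx: np.ndarray, caches, grads: dict) -> None:
        for i in range(3, 0, -1):
            c_conv, c_relu, c_pool = caches[i - 1]
            dx = nn.maxpool1d_backward(dx, c_pool)
            dx = nn.relu_backward(dx, c_relu)
            dx, dw, db = nn.conv1d_backward(dx, c_conv)
            grads[f"conv{i}_w"] = grads.get(f"conv{i}_w", 0) + dw
            grads[f"conv{i}_b"] = grads.get(f"conv{i}_b", 0) + db

    def forward(
        self,
        x_fwd: np.ndarray,
        x_rev: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Logits for a batch of (B, L-k+1, dim) strand matrices."""
        f_out, f_caches = self._conv_stack(x_fwd)
        r_out, r_caches = self._conv_stack(x_rev)
        seq = np.concatenate([f_out, r_out], axis=1)
        h_fw, c_gf = nn.gru_forward(seq, self.params, "gru_fw", reverse=False)
        h_bw, c_gb = nn.gru_forward(seq, self.params, "gru_bw", reverse=True)
        h = np.concatenate([h_fw, h_bw], axis=1)
        d1, c_d1 = nn.dense_forward(h, self.params["dense1_w"], self.params["dense1_b"])
        a1, c_r1 = nn.relu_forward(d1)
        a1d, c_drop = nn.dropout_forward(a1, self.config.dropout, dropout_rng)
        logits, c_d2 = nn.dense_forward(a1d, self.params["dense2_w"], self.params["dense2_b"])
        cache = (f_caches, r_caches, f_out.shape[1], c_gf, c_gb, c_d1, c_r1, c_drop, c_d2)
        return logits[:, 0], cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        f_caches, r_caches, split, c_gf, c_gb, c_d1, c_r1, c_drop, c_d2 = cache
        grads: dict[str, np.ndarray] = {}
        dl = dlogits[:, None]
        da1d, grads["dense2_w"], grads["dense2_b"] = nn.dense_backward(dl, c_d2)
        da1 = nn.dropout_backward(da1d, c_drop)
        dd1 = nn.relu_backward(da1, c_r1)
        dh, grads["dense1_w"], grads["dense1_b"] = nn.dense_backward(dd1, c_d1)
        H = self.config.gru_hidden
        dseq_f, g_f = nn.gru_backward(dh[:, :H], c_gf, self.params)
        dseq_b, g_b = nn.gru_backward(dh[:, H:], c_gb, self.params)
        grads.update(g_f)
        grads.update(g_b)
        dseq = dseq_f + dseq_b
        self._conv_stack_backward(dseq[:, :split, :], f_caches, grads)
        self._conv_stack_backward(dseq[:, split:, :], r_caches, grads)
        return grads

    # -------------------------------------------------------- inference --
    def predict_matrices(self, x_fwd: np.ndarray, x_rev: np.ndarray) -> np.ndarray:
        """Probabilities for pre-encoded strand matrices (dropout off)."""
        probs = []
        bs = self.config.batch_size
        for lo in range(0, len(x_fwd), bs):
            logits, _ = self.forward(x_fwd[lo : lo + bs], x_rev[lo : lo + bs])
            probs.append(1.0 / (1.0 + np.exp(-logits.astype(np.float64))))
        return np.concatenate(probs) if probs else np.empty(0)


def _padded_table(embedding: KmerEmbedding) -> np.ndarray:
    return np.vstack([embedding.vectors, np.zeros((1, embedding.dim), dtype=nn.DTYPE)])


def encode_batch(
    sequences: list[str], embedding: KmerEmbedding
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked forward/reverse strand matrices for equal-length sequences."""
    table = _padded_table(embedding)
    vocab = len(embedding.vectors)
    fwd_idx = np.stack([sequence_to_indices(s, embedding.k) for s in sequences])
    rev_idx = np.stack(
        [sequence_to_indices(reverse_complement(s), embedding.k) for s in sequences]
    )
    x_fwd = table[np.where(fwd_idx < 0, vocab, fwd_idx)].astype(nn.DTYPE)
    x_rev = table[np.where(rev_idx < 0, vocab, rev_idx)].astype(nn.DTYPE)
    return x_fwd, x_rev


def build_model(config: ModelConfig) -> CBSModel:
    """Seeded, untrained classifier for the given configuration."""
    return CBSModel(config)


def train_model(
    model: CBSModel,
    train: list[LabeledSample],
    val: list[LabeledSample],
    embedding: KmerEmbedding,
    config: ModelConfig | None = None,
) -> CBSModel:
    """Train in place; returns the model restored to its best-validation state.

    Early stopping: training ends once the validation AUROC has failed to
    improve for more than ``patience`` consecutive epochs, and the parameters
    of the best epoch are restored.
    """
    cfg = config or model.config
    for name, part in (("train", train), ("val", val)):
        labels = {s.label for s in part}
        if labels != {0, 1}:
            raise ValueError(f"{name} set must contain both classes, has labels {labels}")

    xt_f, xt_r = encode_batch([s.sequence for s in train], embedding)
    yt = np.array([s.label for s in train], dtype=np.float64)
    xv_f, xv_r = encode_batch([s.sequence for s in val], embedding)
    yv = np.array([s.label for s in val], dtype=np.float64)

    rng = np.random.default_rng(cfg.seed + 1)
    adam = nn.Adam(model.params, lr=cfg.learning_rate)
    best_auroc = -np.inf
    best_params: dict[str, np.ndarray] | None = None
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            logits, cache = model.forward(xt_f[sel], xt_r[sel], dropout_rng=rng)
            loss, _, dlogits = nn.sigmoid_bce(logits, yt[sel])
            grads = model.backward(dlogits, cache)
            adam.step(model.params, grads)
            losses.append(loss)
        val_probs = model.predict_matrices(xv_f, xv_r)
        val_auroc = float(roc_auc_score(yv, val_probs))
        model.training_log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auroc": val_auroc}
        )
        if val_auroc > best_auroc:
            best_auroc = val_auroc
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def predict_binding(model: CBSModel, sequence: str, embedding: KmerEmbedding) -> float:
    """P(CTCF bound) for one window-length sequence."""
    if len(sequence) != model.config.window:
        raise ValueError(
            f"sequence length {len(sequence)} != model window {model.config.window}"
        )
    x_fwd, x_rev = encode_batch([sequence], embedding)
    return float(model.predict_matrices(x_fwd, x_rev)[0])


def predict_batch(
    model: CBSModel, sequences: list[str], embedding: KmerEmbedding
) -> np.ndarray:
    """Vector of P(bound) for many window-length sequences."""
    for s in sequences:
        if len(s) != model.config.window:
            raise ValueError("all sequences must have the model window length")
    if not sequences:
        return np.empty(0)
    x_fwd, x_rev = encode_batch(sequences, embedding)
    return model.predict_matrices(x_fwd, x_rev)


def evaluate_auroc(
    model: CBSModel, samples: list[LabeledSample], embedding: KmerEmbedding
) -> float:
    """AUROC of the model on labeled samples (midrank tie handling)."""
    labels = np.array([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    probs = predict_batch(model, [s.sequence for s in samples], embedding)
    return float(roc_auc_score(labels, probs))


# -------------------------------------------------------------- bundle ----

def _probe_inputs(cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(12345)
    L = cfg.window - cfg.k + 1
    return (
        rng.standard_normal((4, L, cfg.dim)).astype(nn.DTYPE),
        rng.standard_normal((4, L, cfg.dim)).astype(nn.DTYPE),
    )


def save_model(model: CBSModel, path: str | Path) -> None:
    """Model bundle directory: weights.npz + config.yaml + probe checksum."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.params)
    probe = model.predict_matrices(*_probe_inputs(model.config))
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "format_version": FORMAT_VERSION,
                "config": model.config.to_dict(),
                "probe_probs": [float(p) for p in probe],
                "training_log": model.training_log,
            },
            fh,
        )


def load_model(path: str | Path) -> CBSModel:
    """Load a bundle; the probe predictions must reproduce to 1e-6."""
    path = Path(path)
    cfg_file = path / "config.yaml"
    if not cfg_file.exists():
        raise FileNotFoundError(f"model bundle missing config.yaml in {path}")
    with open(cfg_file) as fh:
        meta = yaml.safe_load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model bundle version {meta.get('format_version')}")
    cfg = ModelConfig.from_dict(meta["config"])
    model = CBSModel(cfg)
    with np.load(path / "weights.npz") as npz:
        weights = {k: npz[k] for k in npz.files}
    if set(weights) != set(model.params):
        raise ValueError("weights do not match the configured architecture")
    for k, v in model.params.items():
        if weights[k].shape != v.shape:
            raise ValueError(f"shape mismatch for parameter {k}")
    model.params = weights
    model.training_log = meta.get("training_log", [])
    probe = model.predict_matrices(*_probe_inputs(cfg))
    if not np.allclose(probe, meta["probe_probs"], atol=1e-6):
        raise ValueError("probe predictions do not reproduce; corrupt bundle")
    return model
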