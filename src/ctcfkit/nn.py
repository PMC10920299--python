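"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the binding classifier needs: 1-D convolution (via im2col), ReLU,
non-overlapping max pooling, a GRU run in either direction, dense layers,
inverted dropout, and Adam. Layers are stateless functions of a parameter
dict so that training, checkpointing and gradient checks stay simple and
deterministic. All math in float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------- init ----

def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


def glorot_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# ---------------------------------------------------------------- conv ----

def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid-mode 1-D convolution.

    x: (B, L, Cin); w: (K*Cin, Cout); b: (Cout,). Returns (out, cache) with
    out of shape (B, L-K+1, Cout).
    """
    B, L, Cin = x.shape
    K = w.shape[0] // Cin
    Lout = L - K + 1
    cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)  # (B, Lout, Cin, K)
    cols = cols.transpose(0, 1, 3, 2).reshape(B, Lout, K * Cin)
    out = cols @ w + b
    return out, (cols, x.shape, K, w)


def conv1d_backward(dout: np.ndarray, cache):
    cols, x_shape, K, w = cache
    B, L, Cin = x_shape
    Lout = L - K + 1
    dw = np.tensordot(cols, dout, axes=([0, 1], [0, 1]))  # (K*Cin, Cout)
    db = dout.sum(axis=(0, 1))
    dcols = dout @ w.T  # (B, Lout, K*Cin)
    dcols = dcols.reshape(B, Lout, K, Cin)
    dx = np.zeros(x_shape, dtype=DTYPE)
    for kk in range(K):
        dx[:, kk : kk + Lout, :] += dcols[:, :, kk, :]
    return dx, dw, db


# ---------------------------------------------------------------- relu ----

def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


# ---------------------------------------------------------------- pool ----

def maxpool1d_forward(x: np.ndarray, pool: int):
    """Non-overlapping max pool along axis 1; trailing remainder dropped."""
    B, L, C = x.shape
    Lout = L // pool
    xt = x[:, : Lout * pool, :].reshape(B, Lout, pool, C)
    argmax = xt.argmax(axis=2)  # (B, Lout, C)
    out = np.take_along_axis(xt, argmax[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (argmax, x.shape, pool)


def maxpool1d_backward(dout: np.ndarray, cache) -> np.ndarray:
    argmax, x_shape, pool = cache
    B, L, C = x_shape
    Lout = L // pool
    dxt = np.zeros((B, Lout, pool, C), dtype=DTYPE)
    np.put_along_axis(dxt, argmax[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = np.zeros(x_shape, dtype=DTYPE)
    dx[:, : Lout * pool, :] = dxt.reshape(B, Lout * pool, C)
    return dx


# ----------------------------------------------------------------- gru ----

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gru_forward(x: np.ndarray, params: dict, prefix: str, reverse: bool = False):
    """GRU over (B, T, I); returns final hidden state (B, H) and cache.

    params holds ``{prefix}_Wz/Wr/Wc`` (I,H), ``{prefix}_Uz/Ur/Uc`` (H,H) and
    ``{prefix}_bz/br/bc`` (H,). ``reverse=True`` consumes the sequence
    right-to-left.
    """
    B, T, _ = x.shape
    H = params[f"{prefix}_bz"].shape[0]
    h = np.zeros((B, H), dtype=DTYPE)
    order = range(T - 1, -1, -1) if reverse else range(T)
    steps = []
    Wz, Wr, Wc = params[f"{prefix}_Wz"], params[f"{prefix}_Wr"], params[f"{prefix}_Wc"]
    Uz, Ur, Uc = params[f"{prefix}_Uz"], params[f"{prefix}_Ur"], params[f"{prefix}_Uc"]
    bz, br, bc = params[f"{prefix}_bz"], params[f"{prefix}_br"], params[f"{prefix}_bc"]
    for t in order:
        xt = x[:, t, :]
        z = _sigmoid(xt @ Wz + h @ Uz + bz)
        r = _sigmoid(xt @ Wr + h @ Ur + br)
        c = np.tanh(xt @ Wc + (r * h) @ Uc + bc)
        h_new = (1.0 - z) * h + z * c
        steps.append((t, xt, h, z, r, c))
        h = h_new
    return h, (steps, x.shape, prefix)


def gru_backward(dh: np.ndarray, cache, params: dict):
    """Backprop the final-state gradient; returns (dx, grads dict)."""
    steps, x_shape, prefix = cache
    dx = np.zeros(x_shape, dtype=DTYPE)
    Wz, Wr, Wc = params[f"{prefix}_Wz"], params[f"{prefix}_Wr"], params[f"{prefix}_Wc"]
    Uz, Ur, Uc = params[f"{prefix}_Uz"], params[f"{prefix}_Ur"], params[f"{prefix}_Uc"]
    grads = {
        f"{prefix}_{name}": np.zeros_like(params[f"{prefix}_{name}"])
        for name in ("Wz", "Wr", "Wc", "Uz", "Ur", "Uc", "bz", "br", "bc")
    }
    dh = dh.astype(DTYPE)
    for t, xt, h_prev, z, r, c in reversed(steps):
        dc = dh * z * (1.0 - c * c)
        dz = dh * (c - h_prev) * z * (1.0 - z)
        dh_prev = dh * (1.0 - z)

        grads[f"{prefix}_Wc"] += xt.T @ dc
        grads[f"{prefix}_Uc"] += (r * h_prev).T @ dc
        grads[f"{prefix}_bc"] += dc.sum(axis=0)
        drh = dc @ Uc.T
        dr = drh * h_prev
        dh_prev += drh * r

        dpr = dr * r * (1.0 - r)
        grads[f"{prefix}_Wr"] += xt.T @ dpr
        grads[f"{prefix}_Ur"] += h_prev.T @ dpr
        grads[f"{prefix}_br"] += dpr.sum(axis=0)

        grads[f"{prefix}_Wz"] += xt.T @ dz
        grads[f"{prefix}_Uz"] += h_prev.T @ dz
        grads[f"{prefix}_bz"] += dz.sum(axis=0)

        dh_prev += dpr @ Ur.T + dz @ Uz.T
        dx[:, t, :] = dc @ Wc.T + dpr @ Wr.T + dz @ Wz.T
        dh = dh_prev
    return dx, grads


def gru_param_shapes(input_dim: int, hidden: int, prefix: str) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}
    for g in ("z", "r", "c"):
        shapes[f"{prefix}_W{g}"] = (input_dim, hidden)
        shapes[f"{prefix}_U{g}"] = (hidden, hidden)
        shapes[f"{prefix}_b{g}"] = (hidden,)
    return shapes


# --------------------------------------------------------------- dense ----

def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, (x, w)


def dense_backward(dout: np.ndarray, cache):
    x, w = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


# ------------------------------------------------------------- dropout ----

def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when rng is None (inference)."""
    if rng is None or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate).astype(DTYPE) / DTYPE(1.0 - rate)
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout if mask is None else dout * mask


# ---------------------------------------------------------------- loss ----

def sigmoid_bce(logits: np.ndarray, labels: np.ndarray):
    """Numerically stable sigmoid + binary cross-entropy.

    Returns (mean loss, probabilities, dlogits).
    """
    logits = logits.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-logits))
    loss = np.mean(
        np.maximum(logits, 0) - logits * labels + np.log1p(np.exp(-np.abs(logits)))
    )
    dlogits = ((p - labels) / len(labels)).astype(DTYPE)
    return float(loss), p, dlogits


# ---------------------------------------------------------------- adam ----

class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            m = self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            v = self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            params[key] -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                params[key].dtype
            )
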