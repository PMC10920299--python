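"""Shared fixtures: a mini synthetic dataset and a tiny fast classifier."""

from __future__ import annotations

import numpy as np
import pytest

from ctcfkit.embedding import KmerEmbedding
from ctcfkit.io import GenomicInterval
from ctcfkit.model import CBSModel, ModelConfig, build_model, train_model
from ctcfkit.sampling import LabeledSample, sequence_stats
from ctcfkit.synthetic import make_fixture


@pytest.fixture(scope="session")
def mini_fixture_dir(tmp_path_factory):
    """A complete mini fixture directory (toy genome, peaks, loops, ...)."""
    d = tmp_path_factory.mktemp("mini_fixture")
    make_fixture(d, preset="mini", seed=1)
    return d


TINY = dict(
    window=30, k=3, dim=16, conv_channels=(8, 8, 4), kernel_sizes=(5, 3, 3),
    pool_sizes=(2, 1, 2), gru_hidden=8, dense_hidden=8, batch_size=16,
)


@pytest.fixture(scope="session")
def tiny_embedding() -> KmerEmbedding:
    rng = np.random.default_rng(7)
    return KmerEmbedding(
        k=3, dim=16, vectors=rng.standard_normal((64, 16)).astype(np.float32)
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_separable_samples(
    n_per_class: int, seed: int = 0, window: int = 30, motif: str = "ACGTACGTAC"
) -> list[LabeledSample]:
    """Toy dataset: positives carry a fixed motif mid-window, negatives don't."""
    rng = np.random.default_rng(seed)
    samples = []
    at = (window - len(motif)) // 2
    for i in range(2 * n_per_class):
        label = i % 2
        seq = _random_seq(rng, window)
        if label:
            seq = seq[:at] + motif + seq[at + len(motif):]
        gc, rep = sequence_stats(seq)
        samples.append(
            LabeledSample(
                interval=GenomicInterval("chrT", 1000 * i, 1000 * i + window),
                sequence=seq, label=label, gc=gc, repeat_fraction=rep,
            )
        )
    return samples


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_embedding) -> CBSModel:
    """A tiny classifier trained to separate the toy motif dataset."""
    samples = make_separable_samples(120, seed=3)
    train, val = samples[:180], samples[180:]
    cfg = ModelConfig(
        seed=5, max_epochs=12, patience=4, dropout=0.1, learning_rate=3e-3, **TINY
    )
    m = build_model(cfg)
    return train_model(m, train, val, tiny_embedding)
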