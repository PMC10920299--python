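"""k-mer embeddings of DNA sequence.

A sequence is represented as the dense matrix whose row i is the embedding
vector of the k-mer starting at position i (stride 1), so an L-bp window maps
to an (L-k+1) x dim matrix. Vectors come from a small skip-gram model trained
on the genome corpus: k-mers that occur in similar sequence contexts end up
close in the vector space, giving the downstream convolutional network a
smoother input geometry than one-hot columns. k-mers containing N map to the
zero vector so the shape law is preserved over masked sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import FormatError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(sequence: str) -> str:
    """Uppercased reverse complement; N self-complements."""
    bad = set(sequence) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)!r}")
    return sequence.translate(_COMPLEMENT)[::-1].upper()


def kmerize(sequence: str, k: int) -> list[str]:
    """All stride-1 k-mers of ``sequence``, uppercased, order preserved."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} shorter than k={k}")
    upper = sequence.upper()
    return [upper[i : i + k] for i in range(len(upper) - k + 1)]


def _kmer_index(kmer: str) -> int:
    """Base-4 code of a k-mer, or -1 if it contains a non-ACGT character."""
    code = 0
    for c in kmer:
        b = _BASE_CODE.get(c)
        if b is None:
            return -1
        code = code * 4 + b
    return code


def sequence_to_indices(sequence: str, k: int) -> np.ndarray:
    """Vectorized base-4 k-mer codes for a sequence; N-containing k-mers -> -1."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} shorter than k={k}")
    codes = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for base, val in _BASE_CODE.items():
        lut[ord(base)] = val
    base_codes = lut[codes]
    n_kmers = len(sequence) - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(base_codes, k)[:n_kmers]
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = np.where(valid, (np.maximum(windows, 0) * powers).sum(axis=1), -1)
    return idx


@dataclass
class KmerEmbedding:
    """Embedding table for all 4^k k-mers plus a zero vector for N."""

    k: int
    dim: int
    vectors: np.ndarray  # (4^k, dim) float32; row order = base-4 k-mer code

    def __post_init__(self) -> None:
        expected = (4**self.k, self.dim)
        if self.vectors.shape != expected:
            raise ValueError(f"vectors must have shape {expected}, got {self.vectors.shape}")

    @property
    def unk_vector(self) -> np.ndarray:
        return np.zeros(self.dim, dtype=self.vectors.dtype)

    @property
    def table(self) -> dict[str, np.ndarray]:
        """k-mer string -> vector view (uppercase ACGT k-mers only)."""
        kmers = _all_kmers(self.k)
        return {km: self.vectors[i] for i, km in enumerate(kmers)}

    def lookup(self, kmer: str) -> np.ndarray:
        idx = _kmer_index(kmer.upper())
        return self.unk_vector if idx < 0 else self.vectors[idx]

    def encode_indices(self, indices: np.ndarray) -> np.ndarray:
        """Rows for an index array; -1 entries get the zero vector."""
        padded = np.vstack([self.vectors, self.unk_vector[None, :]])
        return padded[np.where(indices < 0, len(self.vectors), indices)]


@dataclass(frozen=True)
class EncodedSequence:
    """(L-k+1) x dim matrix for one strand of one sequence."""

    matrix: np.ndarray
    strand: str  # "forward" or "reverse"

    def __post_init__(self) -> None:
        if self.strand not in {"forward", "reverse"}:
            raise ValueError("strand must be 'forward' or 'reverse'")


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in "ACGT"]
    return kmers


def encode_sequence(
    sequence: str, embedding: KmerEmbedding
) -> tuple[EncodedSequence, EncodedSequence]:
    """Forward and reverse-complement encodings of one sequence."""
    fwd_idx = sequence_to_indices(sequence, embedding.k)
    rev_idx = sequence_to_indices(reverse_complement(sequence), embedding.k)
    return (
        EncodedSequence(embedding.encode_indices(fwd_idx), "forward"),
        EncodedSequence(embedding.encode_indices(rev_idx), "reverse"),
    )


def train_embedding(
    corpus: Iterable[str],
    k: int = 4,
    dim: int = 100,
    window: int = 5,
    epochs: int = 3,
    seed: int = 0,
    learning_rate: float = 0.05,
    batch_size: int = 1024,
    max_pairs: int = 400_000,
) -> KmerEmbedding:
    """Skip-gram k-mer embedding trained on a DNA corpus.

    The corpus is k-merized at stride 1; (center, context) pairs within
    ``window`` tokens are the training examples of a one-hidden-layer
    softmax-output skip-gram (full softmax — the vocabulary is only 4^k).
    When more than ``max_pairs`` pairs exist a seeded subsample is used per
    epoch. k-mers never seen in the corpus get the zero (unknown) vector and
    are counted in a warning. Deterministic for a fixed seed.
    """
    vocab = 4**k
    rng = np.random.default_rng(seed)

    token_runs: list[np.ndarray] = []
    for seq in corpus:
        if len(seq) >= k:
            idx = sequence_to_indices(seq, k)
            token_runs.append(idx[idx >= 0])
    if not token_runs:
        raise ValueError("corpus contains no sequence of length >= k")

    centers_list, contexts_list = [], []
    for run in token_runs:
        n = len(run)
        for off in range(1, window + 1):
            if n > off:
                centers_list.append(run[:-off])
                contexts_list.append(run[off:])
                centers_list.append(run[off:])
                contexts_list.append(run[:-off])
    centers = np.concatenate(centers_list)
    contexts = np.concatenate(contexts_list)

    seen = np.zeros(vocab, dtype=bool)
    seen[np.concatenate(token_runs)] = True
    n_missing = int(vocab - seen.sum())
    if n_missing:
        logger.warning("%d of %d possible %d-mers absent from corpus", n_missing, vocab, k)

    w_in = (rng.standard_normal((vocab, dim)) * 0.1).astype(np.float32)
    w_out = (rng.standard_normal((dim, vocab)) * 0.1).astype(np.float32)

    n_pairs = len(centers)
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        if n_pairs > max_pairs:
            order = order[:max_pairs]
        for lo in range(0, len(order), batch_size):
            sel = order[lo : lo + batch_size]
            c, t = centers[sel], contexts[sel]
            h = w_in[c]  # (B, dim)
            logits = h @ w_out  # (B, vocab)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(sel)), t] -= 1.0  # dsoftmax-CE
            p /= len(sel)
            dh = p @ w_out.T
            w_out -= learning_rate * (h.T @ p)
            np.add.at(w_in, c, -learning_rate * dh)
    w_in[~seen] = 0.0
    return KmerEmbedding(k=k, dim=dim, vectors=w_in)


def save_embedding(embedding: KmerEmbedding, path: str | Path) -> None:
    """Plain-text table: one line per k-mer, ``kmer v1 ... v_dim``; 9 significant digits round-trip float32 exactly."""
    kmers = _all_kmers(embedding.k)
    with open(path, "w") as fh:
        for i, km in enumerate(kmers):
            vals = " ".join(f"{v:.9g}" for v in embedding.vectors[i])
            fh.write(f"{km} {vals}\n")


def load_embedding(path: str | Path) -> KmerEmbedding:
    rows: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            km, vals = parts[0].upper(), parts[1:]
            if dim is None:
                dim = len(vals)
                if dim == 0:
                    raise FormatError(f"{path}:{lineno}: no vector values")
            elif len(vals) != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(vals)}"
                )
            rows[km] = np.array([float(v) for v in vals], dtype=np.float32)
    if not rows:
        raise FormatError(f"{path}: empty embedding file")
    k = len(next(iter(rows)))
    vectors = np.zeros((4**k, dim), dtype=np.float32)
    for km, vec in rows.items():
        idx = _kmer_index(km)
        if idx < 0 or len(km) != k:
            raise FormatError(f"bad k-mer {km!r} in {path}")
        vectors[idx] = vec
    return KmerEmbedding(k=k, dim=dim, vectors=vectors)
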