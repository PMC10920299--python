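"""Training-set construction: summit-centered positives and matched negatives.

Positives are fixed-width windows centered on ChIP-seq peak summits. Each
negative is drawn for one specific positive by rejection sampling until it
matches that positive's GC content and repeat (soft-masked) fraction within
tolerance, has the same length, contains < 10% N and overlaps no positive
window — the per-pair matching makes the null comparable base-composition-wise
so the classifier must learn sequence pattern, not composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Genome, GenomicInterval, Peak, RecordError, write_fasta

logger = logging.getLogger(__name__)

_VALID = set("ACGTNacgtn")
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class LabeledSample:
    """One training window: interval, sequence, binary label and stats."""

    interval: GenomicInterval
    sequence: str  # case as in the genome; uppercase for modeling
    label: int
    gc: float
    repeat_fraction: float

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not (0.0 <= self.gc <= 1.0 and 0.0 <= self.repeat_fraction <= 1.0):
            raise ValueError("gc and repeat_fraction must lie in [0,1]")


def sequence_stats(sequence: str) -> tuple[float, float]:
    """Return (gc, repeat_fraction) of a DNA string.

    GC is computed case-insensitively over non-N bases; the repeat fraction is
    the lowercase (soft-masked) fraction of all bases. An all-N sequence gets
    gc = 0.0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)!r}")
    upper = sequence.upper()
    n_n = upper.count("N")
    denom = len(sequence) - n_n
    gc = (upper.count("G") + upper.count("C")) / denom if denom else 0.0
    repeat = sum(1 for c in sequence if c.islower()) / len(sequence)
    return gc, repeat


def _n_fraction(sequence: str) -> float:
    return sequence.upper().count("N") / len(sequence)


def extract_positive_samples(
    peaks: list[Peak], genome: Genome, window: int = 100
) -> list[LabeledSample]:
    """Summit-centered windows of ``window`` bp, labeled 1.

    The window is [summit - window/2, summit + window/2); the summit falls
    back to the peak midpoint when absent. Windows running off a chromosome
    end, or with >= 10% N, are dropped with a logged count.
    """
    if window % 2:
        raise ValueError("window must be even")
    samples: list[LabeledSample] = []
    n_off_end = 0
    n_n_rich = 0
    for peak in peaks:
        chrom = peak.interval.chrom
        if chrom not in genome:
            raise RecordError(f"peak chromosome {chrom!r} absent from genome")
        start = peak.summit - window // 2
        end = peak.summit + window // 2
        if start < 0 or end > len(genome[chrom]):
            n_off_end += 1
            continue
        interval = GenomicInterval(chrom, start, end)
        seq = genome.fetch(interval)
        if _n_fraction(seq) >= MAX_N_FRACTION:
            n_n_rich += 1
            continue
        gc, repeat = sequence_stats(seq)
        samples.append(
            LabeledSample(interval=interval, sequence=seq, label=1, gc=gc, repeat_fraction=repeat)
        )
    if n_off_end or n_n_rich:
        logger.info("dropped %d off-end and %d N-rich peak windows", n_off_end, n_n_rich)
    return samples


def generate_matched_negatives(
    positives: list[LabeledSample],
    genome: Genome,
    gc_tol: float = 0.02,
    repeat_tol: float = 0.05,
    max_tries_per_positive: int = 1000,
    seed: int = 0,
) -> list[LabeledSample]:
    """One composition-matched, peak-free random window per positive.

    Every emitted negative satisfies |gc - gc_pos| <= gc_tol and
    |repeat - repeat_pos| <= repeat_tol against its own positive, has < 10% N
    and overlaps no positive window. Positives for which no match is found in
    ``max_tries_per_positive`` draws are skipped with a logged count.
    """
    return [neg for _, neg in matched_negative_pairs(
        positives, genome, gc_tol=gc_tol, repeat_tol=repeat_tol,
        max_tries_per_positive=max_tries_per_positive, seed=seed,
    )]


def matched_negative_pairs(
    positives: list[LabeledSample],
    genome: Genome,
    gc_tol: float = 0.02,
    repeat_tol: float = 0.05,
    max_tries_per_positive: int = 1000,
    seed: int = 0,
) -> list[tuple[LabeledSample, LabeledSample]]:
    """Like :func:`generate_matched_negatives` but keeps the pairing explicit."""
    if not positives:
        raise ValueError("positives must be non-empty")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.float64)
    chrom_p = lengths / lengths.sum()

    # positive windows indexed per chromosome for the overlap check
    pos_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in positives:
        pos_by_chrom.setdefault(s.interval.chrom, []).append(
            (s.interval.start, s.interval.end)
        )
    for ivs in pos_by_chrom.values():
        ivs.sort()
    starts_by_chrom = {c: np.array([iv[0] for iv in ivs]) for c, ivs in pos_by_chrom.items()}
    ends_by_chrom = {c: np.array([iv[1] for iv in ivs]) for c, ivs in pos_by_chrom.items()}

    def overlaps_positive(chrom: str, start: int, end: int) -> bool:
        if chrom not in starts_by_chrom:
            return False
        starts = starts_by_chrom[chrom]
        ends = ends_by_chrom[chrom]
        i = int(np.searchsorted(starts, end))
        # any positive with start < end and end > start
        return bool((ends[:i] > start).any())

    pairs: list[tuple[LabeledSample, LabeledSample]] = []
    n_skipped = 0
    for pos in positives:
        window = len(pos.interval)
        found = False
        for _ in range(max_tries_per_positive):
            ci = int(rng.choice(len(chroms), p=chrom_p))
            chrom = chroms[ci]
            limit = len(genome[chrom]) - window
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + window
            if overlaps_positive(chrom, start, end):
                continue
            seq = genome.fetch(GenomicInterval(chrom, start, end))
            if _n_fraction(seq) >= MAX_N_FRACTION:
                continue
            gc, repeat = sequence_stats(seq)
            if abs(gc - pos.gc) <= gc_tol and abs(repeat - pos.repeat_fraction) <= repeat_tol:
                pairs.append(
                    (pos, LabeledSample(
                        interval=GenomicInterval(chrom, start, end),
                        sequence=seq,
                        label=0,
                        gc=gc,
                        repeat_fraction=repeat,
                    ))
                )
                found = True
                break
        if not found:
            n_skipped += 1
    if n_skipped:
        logger.info("no matched negative found for %d positives", n_skipped)
    return pairs


def split_dataset(
    samples: list[LabeledSample],
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> tuple[list[LabeledSample], list[LabeledSample], list[LabeledSample]]:
    """Label-stratified disjoint train/val/test split with exact fractions."""
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    splits: tuple[list[LabeledSample], ...] = ([], [], [])
    for label in (0, 1):
        stratum = [s for s in samples if s.label == label]
        if not stratum:
            raise ValueError(f"no samples with label {label}")
        order = rng.permutation(len(stratum))
        n = len(stratum)
        counts = [int(np.floor(f * n)) for f in fractions]
        # hand remainders to the largest fractional parts, ties to earlier splits
        rem = n - sum(counts)
        fracs = [f * n - c for f, c in zip(fractions, counts)]
        for idx in sorted(range(3), key=lambda i: -fracs[i])[:rem]:
            counts[idx] += 1
        offset = 0
        for part, count in zip(splits, counts):
            part.extend(stratum[i] for i in order[offset : offset + count])
            offset += count
    return splits


def write_samples(samples: list[LabeledSample], out_prefix: str | Path) -> None:
    """Write a sample set as BED + FASTA + tab-separated manifest."""
    out_prefix = Path(out_prefix)
    ids = [f"s{i:06d}" for i in range(len(samples))]
    with open(f"{out_prefix}.bed", "w") as fh:
        for sid, s in zip(ids, samples):
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t{sid}\t"
                f"{s.label}\t.\n"
            )
    write_fasta({sid: s.sequence for sid, s in zip(ids, samples)}, f"{out_prefix}.fa")
    with open(f"{out_prefix}.tsv", "w") as fh:
        fh.write("id\tchrom\tstart\tend\tlabel\tgc\trepeat_fraction\n")
        for sid, s in zip(ids, samples):
            fh.write(
                f"{sid}\t{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"{s.label}\t{s.gc:.6f}\t{s.repeat_fraction:.6f}\n"
            )


def read_samples(out_prefix: str | Path) -> list[LabeledSample]:
    """Read back a sample set written by :func:`write_samples`."""
    from .io import read_fasta

    out_prefix = Path(out_prefix)
    seqs = read_fasta(f"{out_prefix}.fa")
    samples: list[LabeledSample] = []
    with open(f"{out_prefix}.tsv") as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise RecordError("bad manifest header")
        for line in fh:
            sid, chrom, start, end, label, gc, repeat = line.rstrip("\n").split("\t")
            samples.append(
                LabeledSample(
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    sequence=seqs[sid],
                    label=int(label),
                    gc=float(gc),
                    repeat_fraction=float(repeat),
                )
            )
    return samples
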