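"""Scoring somatic variants for disruption of CTCF binding.

A variant is scored at a binding site by predicting binding probability on
the reference summit window (p_ref) and on the same window carrying the
alternate allele (p_alt). A site is called disrupted when binding is
predicted on the reference (p_ref >= tau) but lost on the mutated sequence
(p_alt < tau); delta = p_alt - p_ref ranks variants by severity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .embedding import KmerEmbedding
from .io import Genome, GenomicInterval, Peak, Variant
from .model import CBSModel, predict_batch

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.5


@dataclass(frozen=True)
class VariantImpact:
    """Ref/alt binding probabilities and disruption call for one pair."""

    variant: Variant
    site: Peak
    window: GenomicInterval
    p_ref: float
    p_alt: float
    delta: float
    disrupted: bool
    applicable: bool = True  # False when the variant misses the summit window


def summit_window(site: Peak, window: int) -> GenomicInterval:
    """The model window centered on a site's summit."""
    return GenomicInterval(
        site.interval.chrom, site.summit - window // 2, site.summit + window // 2
    )


def apply_variant(
    sequence: str,
    window: GenomicInterval,
    variant: Variant,
    genome: Genome | None = None,
) -> str:
    """Apply a variant to a reference window; the result keeps the window length.

    SNVs substitute in place. For indels the edited sequence is restored to
    the window length deterministically: deletions are refilled from the
    right genomic flank (requires ``genome``; N-padded otherwise), and
    insertions are trimmed symmetrically — floor(extra/2) bases from the
    left, the rest from the right — keeping the edit near the window center.
    """
    if len(sequence) != len(window):
        raise ValueError("sequence does not match window length")
    if variant.chrom != window.chrom or not (
        window.start <= variant.pos and variant.pos + max(1, len(variant.ref)) <= window.end
    ):
        raise ValueError("variant outside window")
    off = variant.pos - window.start
    ref_here = sequence[off : off + len(variant.ref)].upper()
    if ref_here != variant.ref.upper():
        raise ValueError(
            f"ref allele mismatch at offset {off}: window has {ref_here!r}, "
            f"variant says {variant.ref!r}"
        )
    mutated = sequence[:off] + variant.alt + sequence[off + len(variant.ref) :]
    target = len(window)
    if len(mutated) < target:  # deletion: refill from the right flank
        need = target - len(mutated)
        if genome is not None:
            flank = genome.fetch(
                GenomicInterval(window.chrom, window.end, window.end + need)
            )
        else:
            flank = "N" * need
        mutated = mutated + flank
    elif len(mutated) > target:  # insertion: symmetric trim
        extra = len(mutated) - target
        left = extra // 2
        mutated = mutated[left : left + target]
    return mutated


def score_variant(
    model: CBSModel,
    embedding: KmerEmbedding,
    genome: Genome,
    site: Peak,
    variant: Variant,
    tau: float = DEFAULT_TAU,
) -> VariantImpact:
    """Score one variant against one binding site's summit window."""
    try:
        window = summit_window(site, model.config.window)
        if window.end > len(genome[window.chrom]):
            raise ValueError("window beyond chromosome end")
    except (ValueError, KeyError):
        # summit too close to a chromosome edge: nothing to score
        return VariantImpact(
            variant=variant, site=site, window=site.interval,
            p_ref=float("nan"), p_alt=float("nan"), delta=float("nan"),
            disrupted=False, applicable=False,
        )
    span = variant.ref_span
    inside = (
        span.chrom == window.chrom
        and window.start <= span.start
        and span.end <= window.end
    )
    if not inside:
        return VariantImpact(
            variant=variant, site=site, window=window,
            p_ref=float("nan"), p_alt=float("nan"), delta=float("nan"),
            disrupted=False, applicable=False,
        )
    ref_seq = genome.fetch(window).upper()
    alt_seq = apply_variant(ref_seq, window, variant, genome=genome)
    p_ref, p_alt = predict_batch(model, [ref_seq, alt_seq], embedding)
    p_ref, p_alt = float(p_ref), float(p_alt)
    return VariantImpact(
        variant=variant, site=site, window=window,
        p_ref=p_ref, p_alt=p_alt, delta=p_alt - p_ref,
        disrupted=(p_ref >= tau) and (p_alt < tau),
    )


def scan_variants(
    model: CBSModel,
    embedding: KmerEmbedding,
    genome: Genome,
    sites: list[Peak],
    variants: list[Variant],
    tau: float = DEFAULT_TAU,
) -> list[VariantImpact]:
    """All (variant, site) scores where the variant lies in a summit window.

    Output sorted by delta ascending (most disruptive first); summary counts
    are logged.
    """
    w = model.config.window
    trees: dict[str, IntervalTree] = {}
    n_edge = 0
    for i, site in enumerate(sites):
        try:
            win = summit_window(site, w)
        except ValueError:
            n_edge += 1
            continue
        trees.setdefault(win.chrom, IntervalTree()).addi(win.start, win.end, i)
    if n_edge:
        logger.info("%d sites too close to a chromosome edge to window", n_edge)

    impacts: list[VariantImpact] = []
    for variant in variants:
        tree = trees.get(variant.chrom)
        if tree is None:
            continue
        span = variant.ref_span
        for hit in sorted(tree.overlap(span.start, span.end), key=lambda h: h.data):
            impact = score_variant(model, embedding, genome, sites[hit.data], variant, tau)
            if impact.applicable:
                impacts.append(impact)
    impacts.sort(key=lambda im: im.delta)
    n_disrupted = sum(im.disrupted for im in impacts)
    logger.info("scored %d variant-site pairs, %d disrupted", len(impacts), n_disrupted)
    return impacts


def write_impacts(impacts: list[VariantImpact], path) -> None:
    """Tab-separated impact table (one row per scored variant-site pair)."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tsample\tsite\twindow_start\twindow_end\t"
            "p_ref\tp_alt\tdelta\tdisrupted\n"
        )
        for im in impacts:
            v = im.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.sample_id}\t{im.site.name}\t"
                f"{im.window.start}\t{im.window.end}\t{im.p_ref:.6f}\t{im.p_alt:.6f}\t"
                f"{im.delta:.6f}\t{int(im.disrupted)}\n"
            )
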