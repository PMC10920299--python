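"""Insulated-neighborhood calling and downstream gene-level statistics.

An insulated neighborhood is a CTCF-CTCF chromatin loop whose two anchors
each overlap both a CTCF and a RAD21 (cohesin) ChIP-seq peak and whose span
fully contains at least one gene. Somatic variants falling inside an
anchor's CTCF peak make the neighborhood "mutated"; if the binding
classifier predicts loss of CTCF binding for any such variant the
neighborhood is "disrupted". Proto-oncogene over-representation among
neighborhood genes is assessed with the one-sided hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .embedding import KmerEmbedding
from .io import Gene, Genome, GenomicInterval, Loop, Peak, Variant
from .model import CBSModel
from .variants import DEFAULT_TAU, VariantImpact, score_variant

logger = logging.getLogger(__name__)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class InsulatedNeighborhood:
    loop: Loop
    ctcf_left: Peak
    ctcf_right: Peak
    rad21_left: Peak
    rad21_right: Peak
    genes: tuple[Gene, ...]
    id: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("an insulated neighborhood must contain >= 1 gene")


@dataclass(frozen=True)
class AnchorHit:
    variant: Variant
    anchor: str  # "left" or "right"
    ctcf_peak: Peak


@dataclass(frozen=True)
class MutatedNeighborhood:
    neighborhood: InsulatedNeighborhood
    anchor_hits: tuple[AnchorHit, ...]
    disrupted: bool = False
    evidence: tuple[VariantImpact, ...] = ()


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int
    successes_in_universe: int
    sample_size: int
    successes_in_sample: int
    p_value: float


def _best_peak(anchor: GenomicInterval, peaks: list[Peak]) -> Peak | None:
    """Evidence peak: largest overlap, ties to higher signal, then leftmost."""
    best: Peak | None = None
    best_key = None
    for p in peaks:
        bp = _overlap_bp(anchor, p.interval)
        if bp <= 0:
            continue
        key = (-bp, -p.signal, p.interval.start)
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


def _peak_tree(peaks: list[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    return trees


def identify_neighborhoods(
    loops: list[Loop],
    ctcf_peaks: list[Peak],
    rad21_peaks: list[Peak],
    genes: list[Gene],
    containment: str = "body",
) -> list[InsulatedNeighborhood]:
    """Loops qualifying as insulated neighborhoods, in genomic order.

    A loop qualifies iff both anchors overlap at least one CTCF peak and at
    least one RAD21 peak, and at least one gene lies in the loop span —
    entire gene body with ``containment="body"`` (default), or 5' end (TSS)
    only with ``containment="tss"``.
    """
    if containment not in {"body", "tss"}:
        raise ValueError("containment must be 'body' or 'tss'")
    ctcf_trees = _peak_tree(ctcf_peaks)
    rad21_trees = _peak_tree(rad21_peaks)
    gene_trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        gene_trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, i
        )

    def anchor_evidence(anchor: GenomicInterval, peaks: list[Peak], trees) -> Peak | None:
        tree = trees.get(anchor.chrom)
        if tree is None:
            return None
        hits = [peaks[h.data] for h in tree.overlap(anchor.start, anchor.end)]
        return _best_peak(anchor, hits)

    result: list[InsulatedNeighborhood] = []
    for loop in loops:
        cl = anchor_evidence(loop.anchor_left, ctcf_peaks, ctcf_trees)
        cr = anchor_evidence(loop.anchor_right, ctcf_peaks, ctcf_trees)
        rl = anchor_evidence(loop.anchor_left, rad21_peaks, rad21_trees)
        rr = anchor_evidence(loop.anchor_right, rad21_peaks, rad21_trees)
        if cl is None or cr is None or rl is None or rr is None:
            continue
        span = loop.span
        tree = gene_trees.get(span.chrom)
        contained: list[Gene] = []
        if tree is not None:
            for hit in tree.overlap(span.start, span.end):
                g = genes[hit.data]
                if containment == "body":
                    ok = span.start <= g.interval.start and g.interval.end <= span.end
                else:
                    tss = g.interval.start if g.strand == "+" else g.interval.end - 1
                    ok = span.start <= tss < span.end
                if ok:
                    contained.append(g)
        if not contained:
            continue
        contained.sort(key=lambda g: (g.interval.start, g.gene_id))
        result.append(
            InsulatedNeighborhood(
                loop=loop, ctcf_left=cl, ctcf_right=cr, rad21_left=rl, rad21_right=rr,
                genes=tuple(contained),
                id=f"{span.chrom}:{span.start}-{span.end}",
            )
        )
    result.sort(key=lambda n: (n.loop.span.chrom, n.loop.span.start, n.loop.span.end))
    return result


def find_mutated_neighborhoods(
    neighborhoods: list[InsulatedNeighborhood], variants: list[Variant]
) -> list[MutatedNeighborhood]:
    """Neighborhoods with >= 1 variant inside an anchor's CTCF evidence peak.

    Only the CTCF peaks recorded as anchor evidence count; a variant inside
    the anchor interval but outside the peak does not make the neighborhood
    mutated.
    """
    var_trees: dict[str, IntervalTree] = {}
    for i, v in enumerate(variants):
        span = v.ref_span
        var_trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, i)

    result: list[MutatedNeighborhood] = []
    for nb in neighborhoods:
        hits: list[AnchorHit] = []
        for which, peak in (("left", nb.ctcf_left), ("right", nb.ctcf_right)):
            tree = var_trees.get(peak.interval.chrom)
            if tree is None:
                continue
            for hit in sorted(
                tree.overlap(peak.interval.start, peak.interval.end), key=lambda h: h.data
            ):
                hits.append(AnchorHit(variants[hit.data], which, peak))
        if hits:
            result.append(MutatedNeighborhood(neighborhood=nb, anchor_hits=tuple(hits)))
    return result


def call_disrupted(
    mutated: list[MutatedNeighborhood],
    model: CBSModel,
    embedding: KmerEmbedding,
    genome: Genome,
    tau: float = DEFAULT_TAU,
) -> list[MutatedNeighborhood]:
    """Score every anchor hit; a neighborhood is disrupted if any hit is.

    Hits outside the evidence peak's summit window come back flagged
    not-applicable and cannot make the call.
    """
    out: list[MutatedNeighborhood] = []
    n_disrupted = 0
    n_genes = 0
    for mn in mutated:
        evidence = tuple(
            score_variant(model, embedding, genome, hit.ctcf_peak, hit.variant, tau)
            for hit in mn.anchor_hits
        )
        disrupted = any(im.disrupted for im in evidence if im.applicable)
        if disrupted:
            n_disrupted += 1
            n_genes += len(mn.neighborhood.genes)
        out.append(replace(mn, evidence=evidence, disrupted=disrupted))
    logger.info(
        "%d mutated neighborhoods, %d disrupted covering %d genes",
        len(out), n_disrupted, n_genes,
    )
    return out


def hypergeometric_enrichment(
    universe_genes: set[str], neighborhood_genes: set[str], oncogenes: set[str]
) -> EnrichmentResult:
    """Upper-tail P(X >= x) for oncogene count among neighborhood genes.

    X ~ Hypergeometric(N, K, n) with N the universe size, K the oncogenes in
    the universe, n the neighborhood genes, x the observed overlap.
    """
    if not neighborhood_genes <= universe_genes:
        raise ValueError("neighborhood genes must be a subset of the universe")
    N = len(universe_genes)
    K = len(oncogenes & universe_genes)
    n = len(neighborhood_genes)
    x = len(neighborhood_genes & oncogenes)
    if n > N or K > N:
        raise ValueError("inconsistent counts")
    # sf(x-1) = P(X >= x); exact and stable in scipy's log-space implementation
    p = float(hypergeom.sf(x - 1, N, K, n))
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentResult(
        universe_size=N, successes_in_universe=K, sample_size=n,
        successes_in_sample=x, p_value=p,
    )


def intersect_de_genes(
    disrupted_gene_set: set[str], de_lists: tuple[set[str], set[str], set[str]]
) -> set[str]:
    """Genes of disrupted neighborhoods found in all three DE gene lists.

    Symbols are matched case-insensitively (uppercased). An empty DE list
    yields a warning, not an error.
    """
    result = {g.upper() for g in disrupted_gene_set}
    for i, de in enumerate(de_lists, 1):
        if not de:
            logger.warning("DE list %d is empty", i)
        result &= {g.upper() for g in de}
    logger.info(
        "intersection sizes: disrupted=%d, DE=%s -> %d survivors",
        len(disrupted_gene_set), [len(d) for d in de_lists], len(result),
    )
    return result


def write_neighborhoods(neighborhoods: list[InsulatedNeighborhood], path) -> None:
    """BEDPE-with-metadata table of called neighborhoods."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tid\tn_genes\tgenes\n"
        )
        for nb in neighborhoods:
            lo = nb.loop
            genes = ",".join(g.name for g in nb.genes)
            fh.write(
                f"{lo.anchor_left.chrom}\t{lo.anchor_left.start}\t{lo.anchor_left.end}\t"
                f"{lo.anchor_right.chrom}\t{lo.anchor_right.start}\t{lo.anchor_right.end}\t"
                f"{nb.id}\t{len(nb.genes)}\t{genes}\n"
            )
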