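"""Synthetic fixture generator with known ground truth.

Emits a toy genome with a planted CTCF-like motif, matching ChIP-seq peaks,
chromatin loops covering every neighborhood-qualification scenario, gene
models, somatic variants (motif-ablating and background), and gene lists for
the expression-intersection step — everything the pipeline consumes, with a
machine-checkable truth record, so the full method is testable offline.

Layout: binding sites are planted on a regular grid (one site per ``stride``
bp cell, jittered within the cell) so that site windows never overlap and
loop scenarios can address consecutive sites. Loops live on the first
chromosome; "anchor without CTCF peak" loops live in a reserved site-free
tail of that chromosome; universe/decoy genes live on the second chromosome
so that no-gene loop spans stay empty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .io import (
    Gene,
    Genome,
    GenomicInterval,
    Loop,
    Peak,
    Variant,
    write_bedpe,
    write_fasta,
    write_gene_list,
    write_gtf_genes,
    write_narrowpeak,
    write_vcf,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

MOTIF_LENGTH = 19
PEAK_HALF_WIDTH = 100
SITE_STRIDE = 300
WINDOW = 100


@dataclass
class MotifModel:
    """Position-probability matrix of the planted motif."""

    pwm: np.ndarray  # (length, 4), rows sum to 1, column order ACGT

    def __post_init__(self) -> None:
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if (self.pwm < 0).any():
            raise ValueError("PWM probabilities must be non-negative")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    def log_odds(self, sequence: str, background: float = 0.25) -> float:
        """PWM log-odds of a motif-length sequence (natural log)."""
        if len(sequence) != self.length:
            raise ValueError("sequence length must equal motif length")
        score = 0.0
        for i, base in enumerate(sequence.upper()):
            p = self.pwm[i, BASES.index(base)] if base in BASES else 0.25
            score += np.log(max(p, 1e-9) / background)
        return float(score)

    def information_bits(self) -> np.ndarray:
        """Per-position information content in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(self.pwm > 0, self.pwm * np.log2(self.pwm), 0.0), axis=1)
        return 2.0 - h


def make_motif(seed: int = 0, length: int = MOTIF_LENGTH) -> MotifModel:
    """A CTCF-like PWM: sharp core flanked by weakly informative positions.

    The core (positions 5..13 of the default 19) mixes near-deterministic
    columns (consensus probability 0.97) with strong but degenerate ones
    (0.85); flanks carry little information (max 0.40). Deterministic per
    seed: the seed permutes consensus bases, not the information profile.
    """
    rng = np.random.default_rng(seed)
    pwm = np.zeros((length, 4))
    core = range(5, length - 5) if length >= 15 else range(length)
    sharp = {length // 2 - 1, length // 2, length // 2 + 1}
    for i in range(length):
        consensus = int(rng.integers(0, 4))
        others = [b for b in range(4) if b != consensus]
        if i in sharp:
            p_max = 0.97
            rest = [0.015, 0.01, 0.005]
        elif i in core:
            p_max = 0.85
            rest = [0.08, 0.05, 0.02]
        else:
            p_max = 0.40
            rest = [0.25, 0.20, 0.15]
        pwm[i, consensus] = p_max
        order = rng.permutation(3)
        for j, b in enumerate(others):
            pwm[i, b] = rest[order[j]]
    return MotifModel(pwm=pwm)


def make_genome(
    n_chroms: int = 2,
    chrom_length: int = 100_000,
    gc: float = 0.41,
    repeat_density: float = 0.1,
    seed: int = 0,
) -> Genome:
    """I.i.d. background genome at the stated GC with soft-masked repeats.

    Repeats are lowercase stretches (mean length 300 bp) covering roughly
    ``repeat_density`` of each chromosome. Deterministic per seed.
    """
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, str] = {}
    for ci in range(n_chroms):
        codes = rng.choice(4, size=chrom_length, p=p)
        arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)[codes].copy()
        if repeat_density > 0:
            masked = np.zeros(chrom_length, dtype=bool)
            target = repeat_density * chrom_length
            while masked.sum() < target:
                start = int(rng.integers(0, chrom_length))
                length = int(rng.geometric(1 / 300))
                masked[start : start + length] = True
            arr[masked] += 32  # uppercase -> lowercase in ASCII
        chroms[f"chr{ci + 1}"] = arr.tobytes().decode()
    return Genome(chroms)


@dataclass
class PlantedSite:
    chrom: str
    motif_start: int  # 0-based first base of the planted motif
    center: int  # summit position = central motif base
    strand: str
    sequence: str  # the motif-length bases written into the genome


def plant_sites(
    genome: Genome,
    motif: MotifModel,
    n_sites: int,
    seed: int = 0,
    reserve: dict[str, int] | None = None,
) -> tuple[Genome, list[Peak], list[PlantedSite]]:
    """Write PWM-sampled motif instances into the genome; emit peaks + truth.

    Sites occupy consecutive grid cells of ``SITE_STRIDE`` bp (filled in
    chromosome order, jittered within each cell) so site windows never
    overlap and are at least the model window apart. ``reserve`` excludes a
    tail region per chromosome from planting. The emitted narrowPeak summit
    points at the motif center. Raises if the genome cannot host ``n_sites``.
    """
    reserve = reserve or {}
    rng = np.random.default_rng(seed)
    margin = PEAK_HALF_WIDTH
    jitter_max = SITE_STRIDE - 2 * WINDOW - motif.length
    cells: list[tuple[str, int]] = []
    for chrom in sorted(genome):
        usable = len(genome[chrom]) - reserve.get(chrom, 0) - 2 * margin
        for k in range(max(0, usable // SITE_STRIDE)):
            cells.append((chrom, margin + k * SITE_STRIDE))
    if n_sites > len(cells):
        raise ValueError(f"cannot place {n_sites} sites; capacity is {len(cells)}")

    seqs = {c: list(genome[c]) for c in genome}
    peaks: list[Peak] = []
    sites: list[PlantedSite] = []
    half = motif.length // 2
    for i, (chrom, cell_start) in enumerate(cells[:n_sites]):
        jit = int(rng.integers(0, jitter_max + 1))
        center = cell_start + WINDOW + jit
        sampled = "".join(
            BASES[int(rng.choice(4, p=motif.pwm[pos]))] for pos in range(motif.length)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = (
            sampled
            if strand == "+"
            else "".join(_COMP[b] for b in reversed(sampled))
        )
        motif_start = center - half
        seqs[chrom][motif_start : motif_start + motif.length] = list(inserted)
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, center - PEAK_HALF_WIDTH, center + PEAK_HALF_WIDTH),
                summit_offset=PEAK_HALF_WIDTH,
                signal=float(np.round(rng.uniform(2.0, 10.0), 3)),
                name=f"site{i:05d}",
            )
        )
        sites.append(
            PlantedSite(
                chrom=chrom, motif_start=motif_start, center=center,
                strand=strand, sequence=inserted,
            )
        )
    new_genome = Genome({c: "".join(s) for c, s in seqs.items()})
    return new_genome, peaks, sites


# ------------------------------------------------------------- variants ----

def _ablation_variant(
    genome: Genome,
    motif: MotifModel,
    site: PlantedSite,
    sample_id: str,
    col: int | None = None,
) -> Variant:
    """Core ablation: least-favored base at a maximal-information column."""
    if col is None:
        col = int(motif.information_bits().argmax())
    if site.strand == "+":
        pos = site.motif_start + col
    else:
        pos = site.motif_start + (motif.length - 1 - col)
    ref = genome.fetch(GenomicInterval(site.chrom, pos, pos + 1)).upper()
    worst = BASES[int(motif.pwm[col].argmin())]
    alt = worst if site.strand == "+" else _COMP[worst]
    if alt == ref:  # planted base was itself non-consensus; use next-worst
        order = motif.pwm[col].argsort()
        for b in order:
            cand = BASES[int(b)] if site.strand == "+" else _COMP[BASES[int(b)]]
            if cand != ref:
                alt = cand
                break
    return Variant(chrom=site.chrom, pos=pos, ref=ref, alt=alt, sample_id=sample_id)


def _motif_deletion_variant(
    genome: Genome, motif: MotifModel, site: PlantedSite, sample_id: str
) -> Variant:
    """Deletion of the whole planted motif; removes binding outright."""
    start = site.motif_start
    ref = genome.fetch(GenomicInterval(site.chrom, start, start + motif.length)).upper()
    return Variant(chrom=site.chrom, pos=start, ref=ref, alt="", sample_id=sample_id)


def _background_variant(
    genome: Genome, site: PlantedSite, rng: np.random.Generator, sample_id: str
) -> Variant:
    """SNV in background sequence >= 20 bp from the motif center, in-window."""
    offset = int(rng.integers(20, WINDOW // 2 - 4))
    if rng.random() < 0.5:
        offset = -offset - 1
    pos = site.center + offset
    ref = genome.fetch(GenomicInterval(site.chrom, pos, pos + 1)).upper()
    alt = BASES[int(rng.choice([b for b in range(4) if BASES[b] != ref]))]
    return Variant(chrom=site.chrom, pos=pos, ref=ref, alt=alt, sample_id=sample_id)


def make_variants(
    genome: Genome,
    motif: MotifModel,
    sites: list[PlantedSite],
    site_indices: list[int],
    n_core: int,
    n_background: int,
    seed: int = 0,
) -> tuple[list[Variant], list[dict]]:
    """Core-ablating and background SNVs on disjoint sites from the pool.

    Returns the variants plus truth records ``{site, kind}``; every ref
    allele is read from the genome, so it verifies by construction.
    """
    if n_core + n_background > len(site_indices):
        raise ValueError("not enough sites in the pool for the requested variants")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(np.array(site_indices))
    variants: list[Variant] = []
    truth: list[dict] = []
    for j in range(n_core):
        si = int(chosen[j])
        v = _ablation_variant(genome, motif, sites[si], f"P{j:04d}")
        variants.append(v)
        truth.append({"site": si, "kind": "core"})
    for j in range(n_background):
        si = int(chosen[n_core + j])
        v = _background_variant(genome, sites[si], rng, f"P{n_core + j:04d}")
        variants.append(v)
        truth.append({"site": si, "kind": "background"})
    return variants, truth


# ------------------------------------------------------ loops and genes ----

SCENARIOS = ("qualifying", "no_rad21", "no_ctcf", "no_gene")


def make_loops_and_genes(
    peaks: list[Peak],
    sites: list[PlantedSite],
    genome: Genome,
    scenario_counts: dict[str, int],
    seed: int = 0,
    loop_chrom: str = "chr1",
    gene_chrom: str = "chr2",
    n_extra_genes: int = 20,
    reserve: int = 0,
) -> tuple[list[Loop], list[Gene], list[Peak], dict]:
    """Loops, genes and RAD21 peaks instantiating each qualification scenario.

    Scenario semantics (each loop violates exactly the named condition):
    ``qualifying`` satisfies all three; ``no_rad21`` lacks RAD21 at the right
    anchor; ``no_ctcf`` has anchors in a site-free reserved region (no CTCF
    peak); ``no_gene`` contains no gene. Extra universe genes are placed on
    ``gene_chrom``, which hosts no loops. Truth records which loops qualify.
    """
    missing = [s for s in scenario_counts if s not in SCENARIOS]
    if missing:
        raise ValueError(f"unknown scenarios {missing}")
    rng = np.random.default_rng(seed)
    chrom_sites = [i for i, s in enumerate(sites) if s.chrom == loop_chrom]
    chrom_sites.sort(key=lambda i: sites[i].center)

    loops: list[Loop] = []
    genes: list[Gene] = []
    rad21: list[Peak] = []
    truth_loops: list[dict] = []
    gene_counter = 0
    anchor_gap = 4  # anchors 4 grid sites apart; spans ~1.2 kb
    block_stride = 6
    cursor = 0

    def new_gene(chrom: str, start: int, end: int) -> Gene:
        nonlocal gene_counter
        gene_counter += 1
        name = f"SGENE{gene_counter:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        return Gene(gene_id=f"G{gene_counter:04d}", name=name,
                    interval=GenomicInterval(chrom, start, end), strand=strand)

    def rad21_peak(anchor: GenomicInterval, tag: str) -> Peak:
        return Peak(
            interval=GenomicInterval(anchor.chrom, anchor.start - 20, anchor.end + 20),
            summit_offset=None,
            signal=float(np.round(rng.uniform(2.0, 8.0), 3)),
            name=tag,
        )

    grid_scenarios = [
        s for s in ("qualifying", "no_rad21", "no_gene") if scenario_counts.get(s, 0)
    ]
    for scenario in grid_scenarios:
        for rep in range(scenario_counts[scenario]):
            if cursor + anchor_gap >= len(chrom_sites):
                raise ValueError("not enough planted sites on the loop chromosome")
            left_site = chrom_sites[cursor]
            right_site = chrom_sites[cursor + anchor_gap]
            cursor += block_stride
            la, ra = peaks[left_site].interval, peaks[right_site].interval
            loop = Loop(anchor_left=la, anchor_right=ra, support=int(rng.integers(3, 30)))
            loops.append(loop)
            rad21.append(rad21_peak(la, f"rad_{scenario}_{rep}_L"))
            if scenario != "no_rad21":
                rad21.append(rad21_peak(ra, f"rad_{scenario}_{rep}_R"))
            loop_genes: list[str] = []
            if scenario != "no_gene":
                g_start = la.end + 60 + int(rng.integers(0, 80))
                g_end = g_start + 300 + int(rng.integers(0, 200))
                g = new_gene(loop_chrom, g_start, min(g_end, ra.start - 20))
                genes.append(g)
                loop_genes.append(g.gene_id)
            truth_loops.append(
                {
                    "scenario": scenario,
                    "qualifies": scenario == "qualifying",
                    "left_site": left_site,
                    "right_site": right_site,
                    "span": [la.start, ra.end],
                    "genes": loop_genes,
                }
            )

    # anchors with no CTCF peak live in the reserved site-free tail
    n_no_ctcf = scenario_counts.get("no_ctcf", 0)
    if n_no_ctcf:
        chrom_len = len(genome[loop_chrom])
        base = chrom_len - reserve + 200
        need = n_no_ctcf * 2 * SITE_STRIDE + 400
        if reserve < need - 200:
            raise ValueError(f"reserve of {reserve} bp too small for {n_no_ctcf} loops")
        for rep in range(n_no_ctcf):
            a_start = base + rep * 2 * SITE_STRIDE
            la = GenomicInterval(loop_chrom, a_start, a_start + 200)
            ra = GenomicInterval(loop_chrom, a_start + SITE_STRIDE, a_start + SITE_STRIDE + 200)
            loop = Loop(anchor_left=la, anchor_right=ra, support=int(rng.integers(3, 30)))
            loops.append(loop)
            rad21.append(rad21_peak(la, f"rad_no_ctcf_{rep}_L"))
            rad21.append(rad21_peak(ra, f"rad_no_ctcf_{rep}_R"))
            g = new_gene(loop_chrom, la.end + 10, ra.start - 10)
            genes.append(g)
            truth_loops.append(
                {
                    "scenario": "no_ctcf",
                    "qualifies": False,
                    "left_site": None,
                    "right_site": None,
                    "span": [la.start, ra.end],
                    "genes": [g.gene_id],
                }
            )

    # universe/decoy genes on the loop-free chromosome
    glen = len(genome[gene_chrom])
    for _ in range(n_extra_genes):
        start = int(rng.integers(500, glen - 1500))
        genes.append(new_gene(gene_chrom, start, start + 300 + int(rng.integers(0, 400))))

    truth = {"loops": truth_loops, "n_extra_genes": n_extra_genes}
    return loops, genes, rad21, truth


# ------------------------------------------------------------ DE fixture ----

def make_de_fixture(
    disrupted_genes: list[str],
    mutated_genes: list[str],
    all_gene_names: list[str],
    n_survivors: int = 3,
    n_decoys_per_list: int = 12,
    n_extra_oncogenes: int = 3,
    seed: int = 0,
) -> dict:
    """Three DE gene lists and an oncogene list with known intersections.

    Exactly ``n_survivors`` genes appear in all three DE lists and in
    disrupted neighborhoods; decoys are drawn from genes outside disrupted
    neighborhoods. The oncogene list overlaps the mutated-neighborhood gene
    set strongly enough that the hypergeometric test is significant; the
    achieved p-value is recomputed here, not assumed.
    """
    if len(disrupted_genes) < n_survivors:
        raise ValueError("not enough disrupted-neighborhood genes for the survivors")
    rng = np.random.default_rng(seed)
    survivors = sorted(
        str(g) for g in rng.choice(disrupted_genes, size=n_survivors, replace=False)
    )
    outside = sorted(set(all_gene_names) - set(mutated_genes) - set(disrupted_genes))
    de_lists = []
    for _ in range(3):
        decoys = rng.choice(outside, size=min(n_decoys_per_list, len(outside)), replace=False)
        de_lists.append(sorted(set(survivors) | {str(d) for d in decoys}))

    onco = sorted(set(mutated_genes)) + list(
        rng.choice(outside, size=min(n_extra_oncogenes, len(outside)), replace=False)
    )
    onco = sorted({str(g) for g in onco})
    N = len(set(all_gene_names))
    K = len(set(onco))
    n = len(set(mutated_genes))
    x = len(set(mutated_genes) & set(onco))
    p = float(hypergeom.sf(x - 1, N, K, n))
    return {
        "survivors": survivors,
        "de_lists": de_lists,
        "oncogenes": onco,
        "enrichment": {"N": N, "K": K, "n": n, "x": x, "p_value": p},
    }


# ---------------------------------------------------------- orchestration ----

PRESETS: dict[str, dict] = {
    "small": dict(
        n_chroms=2, chrom_length=600_000, gc=0.41, repeat_density=0.10,
        n_sites=2000, n_core=200, n_background=200,
        scenarios=dict(qualifying=10, no_rad21=10, no_ctcf=10, no_gene=10),
        n_extra_genes=60, reserve=15_000,
        n_disrupted=3, n_bg_mutated=3, n_survivors=3,
    ),
    "mini": dict(
        n_chroms=2, chrom_length=60_000, gc=0.41, repeat_density=0.10,
        n_sites=150, n_core=15, n_background=15,
        scenarios=dict(qualifying=4, no_rad21=3, no_ctcf=3, no_gene=3),
        n_extra_genes=20, reserve=8_000,
        n_disrupted=2, n_bg_mutated=1, n_survivors=2,
    ),
    "domain-b": dict(
        n_chroms=2, chrom_length=200_000, gc=0.52, repeat_density=0.10,
        n_sites=500, n_core=0, n_background=0,
        scenarios={}, n_extra_genes=0, reserve=0,
        n_disrupted=0, n_bg_mutated=0, n_survivors=0,
    ),
}


@dataclass
class FixtureTruth:
    """Ground truth for one emitted fixture; JSON round-trips."""

    preset: str
    seed: int
    gc: float
    motif_pwm: list[list[float]]
    sites: list[dict]
    variants: list[dict]
    loops: list[dict]
    anchor_variants: list[dict]
    expected_neighborhood_spans: list[list]
    expected_mutated_spans: list[list]
    expected_disrupted_spans: list[list]
    survivors: list[str]
    enrichment: dict
    files: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "FixtureTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_fixture(
    out_dir: str | Path,
    preset: str = "small",
    seed: int = 0,
    motif_seed: int | None = None,
    **overrides,
) -> FixtureTruth:
    """Generate a complete fixture directory; returns (and writes) the truth.

    Files: genome.fa, ctcf_peaks.narrowPeak, rad21_peaks.narrowPeak,
    loops.bedpe, genes.gtf, variants.vcf, de_list_{1,2,3}.txt,
    oncogenes.txt, truth.json. Byte-identical for a fixed (preset, seed).

    ``motif_seed`` (default: ``seed``) controls the planted PWM separately
    from genome/placement randomness, so two "cell-line" domains can share
    the motif while differing in background composition.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = dict(PRESETS[preset])
    cfg.update(overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    motif = make_motif(seed=seed if motif_seed is None else motif_seed)
    genome = make_genome(
        n_chroms=cfg["n_chroms"], chrom_length=cfg["chrom_length"],
        gc=cfg["gc"], repeat_density=cfg["repeat_density"], seed=seed + 1,
    )
    reserve = {"chr1": cfg["reserve"]} if cfg["reserve"] else {}
    genome, peaks, sites = plant_sites(
        genome, motif, cfg["n_sites"], seed=seed + 2, reserve=reserve
    )

    loops: list[Loop] = []
    genes: list[Gene] = []
    rad21: list[Peak] = []
    loops_truth: dict = {"loops": []}
    if cfg["scenarios"]:
        loops, genes, rad21, loops_truth = make_loops_and_genes(
            peaks, sites, genome, cfg["scenarios"], seed=seed + 3,
            n_extra_genes=cfg["n_extra_genes"], reserve=cfg["reserve"],
        )

    # anchor sites used by loops are excluded from the free variant pool
    anchor_site_ids = {
        t[side]
        for t in loops_truth["loops"]
        for side in ("left_site", "right_site")
        if t[side] is not None
    }
    pool = [i for i in range(len(sites)) if i not in anchor_site_ids]

    # loop anchors carry consensus-strength motif instances, like the strong
    # constitutive motifs at real CTCF anchors, so their reference windows
    # are confidently bound
    if anchor_site_ids:
        cons = motif.consensus
        seqs = {c: list(genome[c]) for c in genome}
        for si in sorted(anchor_site_ids):
            s = sites[si]
            inserted = cons if s.strand == "+" else "".join(
                _COMP[b] for b in reversed(cons)
            )
            seqs[s.chrom][s.motif_start : s.motif_start + motif.length] = list(inserted)
            s.sequence = inserted
        genome = Genome({c: "".join(v) for c, v in seqs.items()})
    variants, var_truth = ([], [])
    if cfg["n_core"] or cfg["n_background"]:
        variants, var_truth = make_variants(
            genome, motif, sites, pool, cfg["n_core"], cfg["n_background"], seed=seed + 4
        )

    # targeted variants at qualifying-loop anchors drive the disruption calls
    qualifying = [t for t in loops_truth["loops"] if t["qualifies"]]
    n_dis, n_bg = cfg["n_disrupted"], cfg["n_bg_mutated"]
    if n_dis + n_bg > len(qualifying):
        raise ValueError("not enough qualifying loops for the mutation scenarios")
    anchor_variants: list[dict] = []
    rng = np.random.default_rng(seed + 5)
    # disruption-designated anchors carry a deletion of the full motif — the
    # anchor-hotspot lesion that reliably abolishes binding — so the expected
    # disrupted set does not hinge on single-SNV calibration
    for j, t in enumerate(qualifying[:n_dis]):
        v = _motif_deletion_variant(genome, motif, sites[t["left_site"]], f"A{j:03d}")
        variants.append(v)
        anchor_variants.append({"span": t["span"], "kind": "motif_deletion", "pos": v.pos})
        t["mutation"] = "motif_deletion"
    for j, t in enumerate(qualifying[n_dis : n_dis + n_bg]):
        v = _background_variant(genome, sites[t["left_site"]], rng, f"B{j:03d}")
        variants.append(v)
        anchor_variants.append({"span": t["span"], "kind": "background", "pos": v.pos})
        t["mutation"] = "background"

    expected_neigh = [t["span"] for t in loops_truth["loops"] if t["qualifies"]]
    expected_mutated = [t["span"] for t in qualifying[: n_dis + n_bg]]
    expected_disrupted = [t["span"] for t in qualifying[:n_dis]]

    # gene bookkeeping for the DE/enrichment fixture
    gene_by_id = {g.gene_id: g for g in genes}
    disrupted_genes = sorted(
        {gene_by_id[gid].name for t in qualifying[:n_dis] for gid in t["genes"]}
    )
    mutated_genes = sorted(
        {gene_by_id[gid].name for t in qualifying[: n_dis + n_bg] for gid in t["genes"]}
    )
    all_gene_names = sorted(g.name for g in genes)
    de = {"survivors": [], "de_lists": [[], [], []], "oncogenes": [],
          "enrichment": {}}
    if cfg["n_survivors"] and disrupted_genes:
        de = make_de_fixture(
            disrupted_genes, mutated_genes, all_gene_names,
            n_survivors=cfg["n_survivors"], seed=seed + 6,
        )

    files = {
        "genome": "genome.fa",
        "ctcf_peaks": "ctcf_peaks.narrowPeak",
        "rad21_peaks": "rad21_peaks.narrowPeak",
        "loops": "loops.bedpe",
        "genes": "genes.gtf",
        "variants": "variants.vcf",
        "de_lists": ["de_list_1.txt", "de_list_2.txt", "de_list_3.txt"],
        "oncogenes": "oncogenes.txt",
    }
    write_fasta(genome, out / files["genome"])
    write_narrowpeak(peaks, out / files["ctcf_peaks"])
    write_narrowpeak(rad21, out / files["rad21_peaks"])
    write_bedpe(loops, out / files["loops"])
    write_gtf_genes(genes, out / files["genes"])
    write_vcf(variants, out / files["variants"], genome=genome)
    for i, lst in enumerate(de["de_lists"], 1):
        write_gene_list(lst, out / f"de_list_{i}.txt")
    write_gene_list(de["oncogenes"], out / files["oncogenes"])

    truth = FixtureTruth(
        preset=preset,
        seed=seed,
        gc=cfg["gc"],
        motif_pwm=[[float(v) for v in row] for row in motif.pwm],
        sites=[asdict(s) for s in sites],
        variants=var_truth,
        loops=loops_truth["loops"],
        anchor_variants=anchor_variants,
        expected_neighborhood_spans=expected_neigh,
        expected_mutated_spans=expected_mutated,
        expected_disrupted_spans=expected_disrupted,
        survivors=de["survivors"],
        enrichment=de["enrichment"],
        files=files,
    )
    truth.save(out / "truth.json")
    return truth


def audit_fixture(fixture_dir: str | Path) -> None:
    """Re-parse the emitted files and check them against the truth record.

    Verifies: planted motif sequences present in the FASTA at the recorded
    positions; every variant's ref allele matches the genome; qualifying
    loops recomputed by an independent triple scan over the emitted files
    equal the truth's expected set; DE survivors present in all three lists.
    Raises AssertionError on any inconsistency.
    """
    from .io import read_bedpe, read_fasta, read_gene_list, read_gtf_genes
    from .io import read_narrowpeak, read_vcf

    d = Path(fixture_dir)
    truth = FixtureTruth.load(d / "truth.json")
    genome = read_fasta(d / truth.files["genome"])
    motif = MotifModel(pwm=np.array(truth.motif_pwm))

    for s in truth.sites:
        observed = genome.fetch(
            GenomicInterval(s["chrom"], s["motif_start"], s["motif_start"] + motif.length)
        ).upper()
        assert observed == s["sequence"].upper(), f"motif mismatch at {s}"

    read_vcf(d / truth.files["variants"], genome=genome)  # raises on ref mismatch

    loops = read_bedpe(d / truth.files["loops"])
    ctcf = read_narrowpeak(d / truth.files["ctcf_peaks"])
    rad21 = read_narrowpeak(d / truth.files["rad21_peaks"])
    genes = read_gtf_genes(d / truth.files["genes"])

    def hits(iv: GenomicInterval, ps: list[Peak]) -> bool:
        return any(
            p.interval.chrom == iv.chrom
            and p.interval.start < iv.end
            and iv.start < p.interval.end
            for p in ps
        )

    qualifying = []
    for lo in loops:
        ok = (
            hits(lo.anchor_left, ctcf)
            and hits(lo.anchor_right, ctcf)
            and hits(lo.anchor_left, rad21)
            and hits(lo.anchor_right, rad21)
            and any(
                g.interval.chrom == lo.span.chrom
                and lo.span.start <= g.interval.start
                and g.interval.end <= lo.span.end
                for g in genes
            )
        )
        if ok:
            qualifying.append([lo.span.start, lo.span.end])
    expected = sorted([s[0], s[1]] for s in truth.expected_neighborhood_spans)
    assert sorted(qualifying) == expected, "qualifying loops disagree with truth"

    if truth.survivors:
        for i in (1, 2, 3):
            lst = read_gene_list(d / f"de_list_{i}.txt")
            assert set(g.upper() for g in truth.survivors) <= lst
        assert truth.enrichment["p_value"] < 0.05
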