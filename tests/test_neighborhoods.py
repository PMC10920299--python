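"""Neighborhood calling vs brute-force oracles; exact hypergeometric test."""

import math

import numpy as np
import pytest

from ctcfkit.io import Gene, GenomicInterval, Loop, Peak, Variant
from ctcfkit.neighborhoods import (
    find_mutated_neighborhoods,
    hypergeometric_enrichment,
    identify_neighborhoods,
    intersect_de_genes,
    overlaps,
)


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 10), ("chr1", 9, 20), True),
            (("chr1", 0, 10), ("chr1", 10, 20), False),  # half-open abutment
            (("chr1", 0, 10), ("chr2", 0, 10), False),
            (("chr1", 5, 6), ("chr1", 0, 100), True),
        ],
    )
    def test_cases(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected


def _peak(chrom, start, end, signal=1.0, name="p"):
    return Peak(GenomicInterval(chrom, start, end), None, signal, name)


def qualifying_scene():
    loop = Loop(GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 5000, 5200))
    ctcf = [_peak("chr1", 150, 250), _peak("chr1", 5050, 5150)]
    rad21 = [_peak("chr1", 120, 280), _peak("chr1", 5020, 5180)]
    genes = [Gene("G1", "A", GenomicInterval("chr1", 1000, 2000), "+")]
    return loop, ctcf, rad21, genes


class TestIdentify:
    def test_qualifying_loop(self):
        loop, ctcf, rad21, genes = qualifying_scene()
        (nb,) = identify_neighborhoods([loop], ctcf, rad21, genes)
        assert nb.genes[0].gene_id == "G1"
        assert nb.ctcf_left.interval.start == 150

    def test_each_condition_necessary(self):
        loop, ctcf, rad21, genes = qualifying_scene()
        assert identify_neighborhoods([loop], ctcf, rad21[:1], genes) == []  # no right RAD21
        assert identify_neighborhoods([loop], ctcf[:1], rad21, genes) == []  # no right CTCF
        assert identify_neighborhoods([loop], ctcf, rad21, []) == []  # no gene
        outside = [Gene("G2", "B", GenomicInterval("chr1", 5100, 6000), "+")]
        assert identify_neighborhoods([loop], ctcf, rad21, outside) == []  # gene not contained

    def test_evidence_peak_tie_breaking(self):
        loop, _, rad21, genes = qualifying_scene()
        ctcf = [
            _peak("chr1", 150, 250, signal=1.0, name="big"),     # 100 bp overlap
            _peak("chr1", 180, 260, signal=9.0, name="small"),   # 70 bp overlap
            _peak("chr1", 5050, 5150, name="right"),
        ]
        (nb,) = identify_neighborhoods([loop], ctcf, rad21, genes)
        assert nb.ctcf_left.name == "big"  # overlap beats signal


def random_instance(seed, n=200, chroms=("chr1", "chr2")):
    rng = np.random.default_rng(seed)
    span = 100_000

    def rand_iv():
        c = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, span))
        return GenomicInterval(c, s, s + int(rng.integers(50, 400)))

    ctcf = [_peak(*(lambda iv: (iv.chrom, iv.start, iv.end))(rand_iv()),
                  signal=float(rng.random()), name=f"c{i}") for i in range(n)]
    rad21 = [_peak(*(lambda iv: (iv.chrom, iv.start, iv.end))(rand_iv()),
                   signal=float(rng.random()), name=f"r{i}") for i in range(n)]
    genes = [Gene(f"G{i}", f"G{i}", rand_iv(), "+") for i in range(n)]
    loops = []
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        s1 = int(rng.integers(0, span))
        s2 = int(rng.integers(0, span))
        a = GenomicInterval(c, min(s1, s2), min(s1, s2) + 200)
        b = GenomicInterval(c, max(s1, s2) + 300, max(s1, s2) + 500)
        loops.append(Loop(a, b))
    variants = []
    for i in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        variants.append(Variant(c, int(rng.integers(0, span)), "A", "C", f"S{i}"))
    return loops, ctcf, rad21, genes, variants


def oracle_identify(loops, ctcf, rad21, genes):
    """Plain triple-loop re-derivation of the qualification rule."""
    def any_overlap(iv, peaks):
        return any(
            p.interval.chrom == iv.chrom and iv.start < p.interval.end
            and p.interval.start < iv.end
            for p in peaks
        )

    out = []
    for i, lo in enumerate(loops):
        if not (any_overlap(lo.anchor_left, ctcf) and any_overlap(lo.anchor_right, ctcf)):
            continue
        if not (any_overlap(lo.anchor_left, rad21) and any_overlap(lo.anchor_right, rad21)):
            continue
        contained = sorted(
            g.gene_id for g in genes
            if g.interval.chrom == lo.anchor_left.chrom
            and lo.anchor_left.start <= g.interval.start
            and g.interval.end <= lo.anchor_right.end
        )
        if contained:
            out.append((lo.anchor_left.chrom, lo.anchor_left.start, lo.anchor_right.end,
                        tuple(contained)))
    return sorted(out)


def oracle_mutated(neighborhoods, variants):
    out = []
    for nb in neighborhoods:
        hit = False
        for v in variants:
            for peak in (nb.ctcf_left, nb.ctcf_right):
                iv = peak.interval
                if v.chrom == iv.chrom and v.pos < iv.end and v.pos + max(1, len(v.ref)) > iv.start:
                    hit = True
        if hit:
            out.append(nb.id)
    return sorted(out)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identify_matches_brute_force(self, seed):
        loops, ctcf, rad21, genes, _ = random_instance(seed)
        got = identify_neighborhoods(loops, ctcf, rad21, genes)
        got_key = sorted(
            (nb.loop.anchor_left.chrom, nb.loop.anchor_left.start, nb.loop.anchor_right.end,
             tuple(sorted(g.gene_id for g in nb.genes)))
            for nb in got
        )
        assert got_key == oracle_identify(loops, ctcf, rad21, genes)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_find_mutated_matches_brute_force(self, seed):
        loops, ctcf, rad21, genes, variants = random_instance(seed)
        nbs = identify_neighborhoods(loops, ctcf, rad21, genes)
        got = sorted(mn.neighborhood.id for mn in find_mutated_neighborhoods(nbs, variants))
        assert got == oracle_mutated(nbs, variants)

    def test_variant_in_anchor_but_outside_peak_ignored(self):
        loop, ctcf, rad21, genes = qualifying_scene()
        (nb,) = identify_neighborhoods([loop], ctcf, rad21, genes)
        inside_peak = Variant("chr1", 200, "A", "C")
        in_anchor_only = Variant("chr1", 110, "A", "C")  # anchor [100,300), peak [150,250)
        assert len(find_mutated_neighborhoods([nb], [inside_peak])) == 1
        assert find_mutated_neighborhoods([nb], [in_anchor_only]) == []


def enumeration_tail(N, K, n, x):
    """Exact upper-tail probability from integer combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for j in range(x, min(n, K) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def _enrichment_p(N, K, n, x):
    universe = set(range(N))
    onco = set(range(K))
    sample = set(range(x)) | set(range(K, K + (n - x)))
    return hypergeometric_enrichment(universe, sample, onco).p_value


class TestHypergeometric:
    def test_worked_case_small(self):
        # N=20, K=5, n=4, x=4: only C(5,4) favorable draws of C(20,4)
        p = _enrichment_p(20, 5, 4, 4)
        assert p == pytest.approx(5 / 4845, rel=1e-9)

    def test_worked_case_complement(self):
        p = _enrichment_p(4, 2, 2, 1)
        assert p == pytest.approx(5 / 6, rel=1e-9)

    def test_zero_overlap_gives_one(self):
        assert _enrichment_p(20, 5, 4, 0) == 1.0

    @pytest.mark.parametrize("N", [7, 12, 19])
    def test_matches_enumeration(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for x in range(max(0, n - (N - K)), min(n, K) + 1):
                    assert _enrichment_p(N, K, n, x) == pytest.approx(
                        enumeration_tail(N, K, n, x), abs=1e-9
                    )

    def test_complement_identity_and_monotonicity(self):
        from scipy.stats import hypergeom

        N, K, n = 30, 8, 10
        for x in range(1, min(n, K) + 1):
            upper = _enrichment_p(N, K, n, x)
            lower = float(hypergeom.cdf(x - 1, N, K, n))
            assert upper + lower == pytest.approx(1.0, abs=1e-12)
            assert _enrichment_p(N, K, n, x) <= _enrichment_p(N, K, n, x - 1) + 1e-15

    def test_subset_precondition(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"A"}, {"A", "B"}, {"A"})


class TestIntersectDe:
    def test_worked_example(self):
        out = intersect_de_genes({"A", "B", "C"}, ({"A", "B"}, {"A", "B", "D"}, {"B"}))
        assert out == {"B"}

    def test_disjoint_sets(self):
        assert intersect_de_genes({"A"}, ({"B"}, {"C"}, {"D"})) == set()

    def test_case_insensitive(self):
        assert intersect_de_genes({"GeneX"}, ({"GENEX"}, {"genex"}, {"GeneX"})) == {"GENEX"}
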