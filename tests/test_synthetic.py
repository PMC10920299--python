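"""Fixture generator: motif, genome, planted sites, variants, truth audit."""

import numpy as np
import pytest

from ctcfkit.io import GenomicInterval, read_fasta, read_gene_list, read_vcf
from ctcfkit.synthetic import (
    FixtureTruth,
    MotifModel,
    audit_fixture,
    make_de_fixture,
    make_genome,
    make_motif,
    make_variants,
    plant_sites,
)


class TestMotif:
    def test_rows_sum_to_one(self):
        m = make_motif(seed=0)
        assert np.allclose(m.pwm.sum(axis=1), 1.0, atol=1e-9)
        assert (m.pwm >= 0).all()

    def test_deterministic_and_length(self):
        assert np.array_equal(make_motif(seed=5).pwm, make_motif(seed=5).pwm)
        assert len(make_motif(seed=5).consensus) == 19

    def test_sharp_core_exists(self):
        m = make_motif(seed=3)
        assert (m.pwm.max(axis=1) >= 0.95).sum() >= 2

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError):
            MotifModel(pwm=np.full((4, 4), 0.3))


class TestGenome:
    def test_gc_concentration(self):
        g = make_genome(n_chroms=1, chrom_length=100_000, gc=0.5, repeat_density=0, seed=0)
        seq = g["chr1"].upper()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_no_repeats_when_density_zero(self):
        g = make_genome(n_chroms=1, chrom_length=20_000, gc=0.4, repeat_density=0, seed=1)
        assert g["chr1"].isupper()

    def test_repeats_roughly_at_density(self):
        g = make_genome(n_chroms=1, chrom_length=100_000, gc=0.4, repeat_density=0.2, seed=2)
        frac = sum(1 for c in g["chr1"] if c.islower()) / len(g["chr1"])
        assert 0.15 <= frac <= 0.30

    def test_deterministic(self):
        a = make_genome(n_chroms=2, chrom_length=10_000, seed=9)
        b = make_genome(n_chroms=2, chrom_length=10_000, seed=9)
        assert dict(a) == dict(b)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            make_genome(chrom_length=5000)


class TestPlantSites:
    def test_planted_sites_score_above_background(self):
        motif = make_motif(seed=0)
        genome = make_genome(n_chroms=1, chrom_length=80_000, seed=1)
        planted, peaks, sites = plant_sites(genome, motif, 200, seed=2)
        assert len(peaks) == len(sites) == 200
        # background distribution of best log-odds over random motif-length windows
        rng = np.random.default_rng(3)
        bg = []
        for _ in range(500):
            start = int(rng.integers(0, 80_000 - motif.length))
            s = genome["chr1"][start : start + motif.length].upper()
            bg.append(motif.log_odds(s))
        threshold = np.quantile(bg, 0.99)
        n_above = sum(
            motif.log_odds(site.sequence if site.strand == "+" else _revcomp(site.sequence))
            > threshold
            for site in sites
        )
        assert n_above >= 195  # PWM samples may rarely be weak; nearly all must clear

    def test_windows_disjoint_and_summit_on_motif_center(self):
        motif = make_motif(seed=0)
        genome = make_genome(n_chroms=1, chrom_length=50_000, seed=4)
        _, peaks, sites = plant_sites(genome, motif, 100, seed=5)
        for p, s in zip(peaks, sites):
            assert p.summit == s.center
            assert s.motif_start == s.center - motif.length // 2
        ivs = sorted((p.interval.start, p.interval.end) for p in peaks)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_capacity_error(self):
        motif = make_motif(seed=0)
        genome = make_genome(n_chroms=1, chrom_length=12_000, seed=0)
        with pytest.raises(ValueError):
            plant_sites(genome, motif, 1000, seed=0)

    def test_deterministic(self):
        motif = make_motif(seed=0)
        genome = make_genome(n_chroms=1, chrom_length=30_000, seed=6)
        a = plant_sites(genome, motif, 30, seed=7)
        b = plant_sites(genome, motif, 30, seed=7)
        assert dict(a[0]) == dict(b[0]) and a[2] == b[2]


def _revcomp(s):
    return "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(s))


class TestVariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        motif = make_motif(seed=0)
        genome = make_genome(n_chroms=1, chrom_length=40_000, seed=1)
        genome, peaks, sites = plant_sites(genome, motif, 80, seed=2)
        return motif, genome, sites

    def test_core_variants_hit_planted_base(self, planted):
        motif, genome, sites = planted
        variants, truth = make_variants(genome, motif, sites, list(range(80)), 20, 20, seed=3)
        for v, t in zip(variants[:20], truth[:20]):
            site = sites[t["site"]]
            assert t["kind"] == "core"
            # the ref allele is the base actually planted at that position
            assert genome.fetch(GenomicInterval(v.chrom, v.pos, v.pos + 1)).upper() == v.ref
            assert site.motif_start <= v.pos < site.motif_start + motif.length

    def test_background_variants_far_from_motif_center(self, planted):
        motif, genome, sites = planted
        variants, truth = make_variants(genome, motif, sites, list(range(80)), 10, 30, seed=4)
        for v, t in zip(variants[10:], truth[10:]):
            site = sites[t["site"]]
            assert abs(v.pos - site.center) >= 20
            assert abs(v.pos - site.center) < 50  # still inside the summit window

    def test_deterministic_and_pool_limit(self, planted):
        motif, genome, sites = planted
        a = make_variants(genome, motif, sites, list(range(80)), 5, 5, seed=9)
        b = make_variants(genome, motif, sites, list(range(80)), 5, 5, seed=9)
        assert a == b
        with pytest.raises(ValueError):
            make_variants(genome, motif, sites, list(range(10)), 8, 8, seed=0)


class TestDeFixture:
    def test_survivors_and_significance(self):
        disrupted = [f"D{i}" for i in range(6)]
        mutated = disrupted + ["M1", "M2"]
        universe = mutated + [f"U{i}" for i in range(60)]
        out = make_de_fixture(disrupted, mutated, universe, n_survivors=3, seed=0)
        assert len(out["survivors"]) == 3
        for lst in out["de_lists"]:
            assert set(out["survivors"]) <= set(lst)
        # decoys never come from the disrupted set, so the intersection is exact
        for lst in out["de_lists"]:
            assert set(lst) & set(disrupted) == set(out["survivors"])
        assert out["enrichment"]["p_value"] < 0.05

    def test_insufficient_genes(self):
        with pytest.raises(ValueError):
            make_de_fixture(["A"], ["A"], ["A", "B"], n_survivors=3)


class TestFixtureDirectory:
    def test_audit_passes(self, mini_fixture_dir):
        audit_fixture(mini_fixture_dir)

    def test_truth_consistent_with_files(self, mini_fixture_dir):
        truth = FixtureTruth.load(mini_fixture_dir / "truth.json")
        genome = read_fasta(mini_fixture_dir / "genome.fa")
        variants = read_vcf(mini_fixture_dir / "variants.vcf", genome=genome)
        assert len(variants) == len(truth.variants) + len(truth.anchor_variants)
        for i in (1, 2, 3):
            lst = read_gene_list(mini_fixture_dir / f"de_list_{i}.txt")
            assert set(g.upper() for g in truth.survivors) <= lst
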