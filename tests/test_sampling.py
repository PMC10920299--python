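"""Sample construction: summit windows, composition matching, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcfkit.io import Genome, GenomicInterval, Peak
from ctcfkit.sampling import (
    LabeledSample,
    extract_positive_samples,
    generate_matched_negatives,
    matched_negative_pairs,
    read_samples,
    sequence_stats,
    split_dataset,
    write_samples,
)


def _uniform_genome(length: int = 50_000, seed: int = 0) -> Genome:
    rng = np.random.default_rng(seed)
    return Genome({"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, length))})


class TestSequenceStats:
    @pytest.mark.parametrize(
        "seq,gc,rep",
        [("ACGT", 0.5, 0.0), ("acgtACGT", 0.5, 0.5), ("GGCC", 1.0, 0.0), ("NNAT", 0.0, 0.0)],
    )
    def test_known_values(self, seq, gc, rep):
        assert sequence_stats(seq) == (gc, rep)

    def test_all_n_defined(self):
        assert sequence_stats("NNNN") == (0.0, 0.0)

    def test_illegal_character(self):
        with pytest.raises(ValueError):
            sequence_stats("ACGX")

    @given(st.text(alphabet="ACGTNacgtn", min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_ranges(self, seq):
        gc, rep = sequence_stats(seq)
        assert 0.0 <= gc <= 1.0 and 0.0 <= rep <= 1.0


class TestExtractPositives:
    def test_summit_centered_window(self):
        genome = _uniform_genome()
        peaks = [Peak(GenomicInterval("chr1", 100, 300), summit_offset=80)]
        (s,) = extract_positive_samples(peaks, genome, window=100)
        assert s.interval == GenomicInterval("chr1", 130, 230)
        assert len(s.sequence) == 100 and s.label == 1

    def test_off_end_dropped(self):
        genome = _uniform_genome()
        peaks = [Peak(GenomicInterval("chr1", 0, 40), summit_offset=None)]
        assert extract_positive_samples(peaks, genome, window=100) == []

    def test_count_conservation(self):
        genome = _uniform_genome()
        peaks = [
            Peak(GenomicInterval("chr1", s, s + 200), summit_offset=100)
            for s in (1000, 2000, 3000)
        ]
        out = extract_positive_samples(peaks, genome, window=100)
        assert len(out) == 3 and all(len(s.sequence) == 100 for s in out)

    def test_unknown_chromosome(self):
        with pytest.raises(Exception):
            extract_positive_samples(
                [Peak(GenomicInterval("chrZ", 100, 300), 80)], _uniform_genome()
            )


class TestMatchedNegatives:
    def test_every_negative_within_tolerance(self):
        genome = _uniform_genome(seed=1)
        peaks = [
            Peak(GenomicInterval("chr1", 500 + 600 * i, 700 + 600 * i), summit_offset=100)
            for i in range(50)
        ]
        pos = extract_positive_samples(peaks, genome)
        pairs = matched_negative_pairs(pos, genome, seed=11)
        assert len(pairs) >= 45
        pos_windows = [(p.interval.start, p.interval.end) for p in pos]
        for p, n in pairs:
            gc, rep = sequence_stats(n.sequence)  # recompute from sequence
            assert abs(gc - p.gc) <= 0.02
            assert abs(rep - p.repeat_fraction) <= 0.05
            assert len(n.sequence) == len(p.sequence)
            assert n.label == 0
            for ws, we in pos_windows:
                assert n.interval.end <= ws or n.interval.start >= we

    def test_impossible_match_skipped(self):
        at_genome = Genome({"chr1": "AT" * 10_000})
        impossible = LabeledSample(
            interval=GenomicInterval("chr1", 0, 8),
            sequence="GGCCGGCC", label=1, gc=1.0, repeat_fraction=0.0,
        )
        assert generate_matched_negatives(
            [impossible], at_genome, max_tries_per_positive=50, seed=0
        ) == []

    def test_determinism(self):
        genome = _uniform_genome(seed=2)
        peaks = [Peak(GenomicInterval("chr1", 1000 * i + 500, 1000 * i + 700), 100)
                 for i in range(10)]
        pos = extract_positive_samples(peaks, genome)
        a = generate_matched_negatives(pos, genome, seed=42)
        b = generate_matched_negatives(pos, genome, seed=42)
        assert a == b


class TestSplit:
    def _samples(self, n_per_class=50):
        out = []
        for i in range(2 * n_per_class):
            out.append(
                LabeledSample(
                    interval=GenomicInterval("chr1", 10 * i, 10 * i + 4),
                    sequence="ACGT", label=i % 2, gc=0.5, repeat_fraction=0.0,
                )
            )
        return out

    def test_exact_stratified_sizes(self):
        tr, va, te = split_dataset(self._samples(), (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        assert sum(s.label for s in tr) == 40
        assert sum(s.label for s in va) == 5 and sum(s.label for s in te) == 5

    def test_disjoint_union(self):
        samples = self._samples(20)
        tr, va, te = split_dataset(samples, (0.6, 0.2, 0.2), seed=1)
        ids = [id(s) for part in (tr, va, te) for s in part]
        assert len(ids) == len(set(ids)) == len(samples)

    def test_determinism_and_bad_fractions(self):
        samples = self._samples(10)
        assert split_dataset(samples, (0.5, 0.25, 0.25), seed=3) == split_dataset(
            samples, (0.5, 0.25, 0.25), seed=3
        )
        with pytest.raises(ValueError):
            split_dataset(samples, (0.5, 0.5, 0.5), seed=0)

    def test_empty_stratum(self):
        all_pos = [s for s in self._samples(10) if s.label == 1]
        with pytest.raises(ValueError):
            split_dataset(all_pos, (0.8, 0.1, 0.1), seed=0)


class TestSampleFiles:
    def test_write_read_round_trip(self, tmp_path):
        genome = _uniform_genome(seed=3)
        peaks = [Peak(GenomicInterval("chr1", 1000 * i + 500, 1000 * i + 700), 100)
                 for i in range(5)]
        pos = extract_positive_samples(peaks, genome)
        prefix = tmp_path / "samples"
        write_samples(pos, prefix)
        assert read_samples(prefix) == pos
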