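"""Unit and property tests for e-locus enumeration and disorder statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylhet import epiallele as ep


class TestEnumerateEloci:
    def test_window_respects_max_span(self):
        loci = ep.enumerate_eloci({"chr1": [10, 20, 30, 40, 200]}, max_span=100)
        assert [l.id for l in loci] == ["chr1:10-40"]

    def test_exactly_four_cpgs_one_locus(self):
        loci = ep.enumerate_eloci({"chr1": [5, 10, 15, 20]}, max_span=100)
        assert len(loci) == 1
        assert loci[0].positions == (5, 10, 15, 20)

    def test_six_cpgs_three_sliding_windows(self):
        loci = ep.enumerate_eloci({"chr1": [0, 10, 20, 30, 40, 50]}, max_span=100)
        assert [l.positions for l in loci] == [
            (0, 10, 20, 30), (10, 20, 30, 40), (20, 30, 40, 50),
        ]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ep.enumerate_eloci({"chr1": [30, 10, 20, 40]})

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            ep.enumerate_eloci({"chr1": [10, 10, 20, 30]})


class TestRemoveSnpCpgs:
    def test_empty_snp_set_identity(self):
        out = ep.remove_snp_cpgs({"chr1": [100, 200]}, {})
        assert out["chr1"].tolist() == [100, 200]

    def test_cpg_at_snp_removed_neighbour_kept(self):
        out = ep.remove_snp_cpgs({"chr1": [100, 200]}, {"chr1": [100]})
        assert out["chr1"].tolist() == [200]
        out2 = ep.remove_snp_cpgs({"chr1": [100]}, {"chr1": [101]})
        assert out2["chr1"].tolist() == [100]

    def test_bed_intervals_half_open(self):
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [102]})
        out = ep.remove_snp_cpgs({"chr1": [99, 100, 101, 102]}, bed)
        assert out["chr1"].tolist() == [99, 102]


class TestCountPatterns:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "call"])

    def test_fully_methylated_reads(self):
        loci = ep.enumerate_eloci({"chr1": [0, 10, 20, 30]})
        rows = [(f"r{i}", "chr1", p, 1) for i in range(5) for p in (0, 10, 20, 30)]
        counts = ep.count_patterns(self._calls(rows), loci)
        vec = counts.iloc[0]
        assert vec[15] == 5 and vec.sum() == 5

    def test_mixed_patterns(self):
        loci = ep.enumerate_eloci({"chr1": [0, 10, 20, 30]})
        rows = [("r1", "chr1", p, 1) for p in (0, 10, 20, 30)]
        rows += [(r, "chr1", p, 0) for r in ("r2", "r3") for p in (0, 10, 20, 30)]
        counts = ep.count_patterns(self._calls(rows), loci)
        vec = counts.iloc[0]
        assert vec[15] == 1 and vec[0] == 2

    def test_partial_read_excluded(self):
        loci = ep.enumerate_eloci({"chr1": [0, 10, 20, 30]})
        rows = [("r1", "chr1", p, 1) for p in (0, 10, 20)]  # covers 3 of 4
        counts = ep.count_patterns(self._calls(rows), loci)
        assert counts.empty or counts.to_numpy().sum() == 0

    def test_read_contributes_to_overlapping_windows(self):
        loci = ep.enumerate_eloci({"chr1": [0, 10, 20, 30, 40]})
        rows = [("r1", "chr1", p, 1) for p in (0, 10, 20, 30, 40)]
        counts = ep.count_patterns(self._calls(rows), loci)
        assert len(counts) == 2 and (counts[15] == 1).all()


class TestEpipolymorphism:
    def test_single_pattern_zero(self):
        c = np.zeros(16); c[7] = 12
        assert ep.epipolymorphism(c) == 0.0

    def test_uniform_maximum(self):
        assert ep.epipolymorphism(np.ones(16)) == pytest.approx(0.9375, abs=1e-15)

    def test_worked_example(self):
        # patterns 0000:8, 1000:4, 1100:2, 1110:2 -> 1 - (64+16+4+4)/256
        c = np.zeros(16); c[0] = 8; c[8] = 4; c[12] = 2; c[14] = 2
        assert ep.epipolymorphism(c) == pytest.approx(0.65625, abs=1e-15)

    def test_zero_depth_is_missing(self):
        assert np.isnan(ep.epipolymorphism(np.zeros(16)))

    def test_negative_counts_rejected(self):
        c = np.zeros(16); c[0] = -1
        with pytest.raises(ValueError):
            ep.epipolymorphism(c)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 50), min_size=16, max_size=16).filter(lambda c: sum(c) > 0),
           st.randoms(use_true_random=False))
    def test_relabeling_invariance(self, counts, rnd):
        perm = list(range(16))
        rnd.shuffle(perm)
        c = np.array(counts, dtype=float)
        assert ep.epipolymorphism(c[perm]) == pytest.approx(ep.epipolymorphism(c), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 50), min_size=16, max_size=16).filter(lambda c: sum(c) > 0))
    def test_duplicating_majority_pattern_never_increases(self, counts):
        c = np.array(counts, dtype=float)
        j = int(np.argmax(c))
        c2 = c.copy(); c2[j] += 1
        assert ep.epipolymorphism(c2) <= ep.epipolymorphism(c) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 50), min_size=16, max_size=16).filter(lambda c: sum(c) > 0))
    def test_cpg_order_reversal_invariance(self, counts):
        c = np.array(counts, dtype=float)
        rev = np.zeros(16)
        for code in range(16):
            bits = ep.decode_pattern(code)
            rcode = ep.pattern_code(bits[::-1])
            rev[rcode] = c[code]
        assert ep.epipolymorphism(rev) == pytest.approx(ep.epipolymorphism(c), abs=1e-12)
        assert ep.avg_methylation(rev) == pytest.approx(ep.avg_methylation(c), abs=1e-12)


class TestAvgMethylation:
    def test_all_methylated(self):
        c = np.zeros(16); c[15] = 7
        assert ep.avg_methylation(c) == 1.0

    def test_half_and_half(self):
        c = np.zeros(16); c[15] = 5; c[0] = 5
        assert ep.avg_methylation(c) == 0.5

    def test_worked_example(self):
        # 1000 x4 (1 CpG methylated), 1100 x4 (2 methylated) -> 12/(8*4)
        c = np.zeros(16); c[8] = 4; c[12] = 4
        assert ep.avg_methylation(c) == pytest.approx(0.375, abs=1e-15)

    def test_zero_depth_is_missing(self):
        assert np.isnan(ep.avg_methylation(np.zeros(16)))


class TestFilterEloci:
    @staticmethod
    def _profiles(depths_by_locus, samples):
        rows = []
        for locus, depths in depths_by_locus.items():
            for s, d in zip(samples, depths):
                rows.append((locus, s, 0.1, 0.5, d))
        return pd.DataFrame(
            rows, columns=["elocus_id", "sample_id", "epipolymorphism",
                           "avg_methylation", "depth"]
        )

    def test_boundary_75_percent_inclusive(self):
        samples = [f"s{i}" for i in range(8)]
        prof = self._profiles({"L1": [10, 10, 10, 10, 10, 10, 9, 0]}, samples)
        assert ep.filter_eloci(prof, samples=samples) == ["L1"]  # 6/8 = 0.75

    def test_below_boundary_dropped(self):
        samples = [f"s{i}" for i in range(8)]
        prof = self._profiles({"L1": [10, 10, 10, 10, 10, 9, 9, 0]}, samples)
        assert ep.filter_eloci(prof, samples=samples) == []  # 5/8

    def test_all_at_min_depth_retained(self):
        samples = [f"s{i}" for i in range(4)]
        prof = self._profiles({"L1": [10, 10, 10, 10]}, samples)
        assert ep.filter_eloci(prof, samples=samples) == ["L1"]

    def test_missing_samples_count_as_zero_depth(self):
        samples = [f"s{i}" for i in range(8)]
        prof = self._profiles({"L1": [30, 30, 30, 30, 30]}, samples[:5])
        assert ep.filter_eloci(prof, samples=samples) == []  # 5/8 < 0.75

    def test_empty_sample_set_rejected(self):
        prof = self._profiles({}, [])
        with pytest.raises(ValueError):
            ep.filter_eloci(prof, samples=[])


def test_profiles_match_direct_computation(small_sim):
    counts = small_sim.counts_table()
    prof = ep.profiles_from_counts(counts)
    i = 37
    row = prof.iloc[i]
    c = counts.iloc[i].to_numpy(dtype=float)
    if c.sum() > 0:
        assert row["epipolymorphism"] == pytest.approx(ep.epipolymorphism(c))
        assert row["depth"] == c.sum()
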