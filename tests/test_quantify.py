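"""Counting, RLE normalization, log2-CPM filtering and the exact NB test."""

import numpy as np
import pandas as pd
import pytest

import cagecraft as cg
from cagecraft.intervals import GenomicInterval, RegionSet
from cagecraft.tss import TagTrack


def make_cm(array, libs=None, lib_sizes=None, factors=None):
    arr = np.asarray(array)
    libs = libs or [f"L{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=libs, index=[f"f{i}" for i in range(arr.shape[0])])
    sizes = pd.Series(
        lib_sizes if lib_sizes is not None else df.sum(axis=0).astype(float), index=libs
    )
    cm = cg.CountMatrix(df, sizes)
    if factors is not None:
        cm = cm.with_factors(pd.Series(factors, index=libs, dtype=float))
    return cm


def track(rows, library_id="lib1"):
    return TagTrack(library_id, pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"]))


class TestCountTags:
    regions = RegionSet([GenomicInterval("chr1", 100, 200, "+", "r1")])

    def test_stranded_counts_matching_strand(self):
        t = track([("chr1", 120, "+", 1), ("chr1", 150, "+", 1), ("chr1", 199, "+", 1)])
        cm = cg.count_tags(self.regions, [t], "stranded")
        assert cm.counts.iloc[0, 0] == 3

    def test_stranded_ignores_opposite_strand(self):
        t = track([("chr1", 120, "-", 1), ("chr1", 150, "-", 1), ("chr1", 199, "-", 1)])
        cm = cg.count_tags(self.regions, [t], "stranded")
        assert cm.counts.iloc[0, 0] == 0

    def test_sum_strands_adds_both(self):
        enh = RegionSet([GenomicInterval("chr1", 100, 200, ".", "e1")])
        t = track([("chr1", 120, "+", 4), ("chr1", 150, "-", 6)])
        cm = cg.count_tags(enh, [t], "sum_strands")
        assert cm.counts.iloc[0, 0] == 10

    def test_half_open_span(self):
        t = track([("chr1", 99, "+", 1), ("chr1", 100, "+", 1), ("chr1", 200, "+", 1)])
        cm = cg.count_tags(self.regions, [t], "stranded")
        assert cm.counts.iloc[0, 0] == 1

    def test_unstranded_region_rejected_in_stranded_mode(self):
        bad = RegionSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="unstranded region"):
            cg.count_tags(bad, [track([("chr1", 5, "+", 1)])], "stranded")

    def test_library_size_is_track_total(self):
        t = track([("chr1", 120, "+", 2), ("chr2", 5, "-", 7)])
        cm = cg.count_tags(self.regions, [t], "stranded")
        assert cm.library_sizes.iloc[0] == 9


class TestRLENormFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_cm(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(cg.rle_norm_factors(cm), 1.0)

    def test_doubled_column_recovers_depth(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, size=500)
        cm = make_cm(
            np.column_stack([col, 2 * col]), lib_sizes=[1e6, 1e6]
        )
        f = cg.rle_norm_factors(cm)
        eff = (cm.with_factors(f)).effective_sizes()
        assert eff.iloc[1] / eff.iloc[0] == pytest.approx(2.0, rel=0.01)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        cm = make_cm(rng.poisson(50, size=(200, 5)))
        f = cg.rle_norm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_requires_a_feature_positive_everywhere(self):
        with pytest.raises(ValueError, match="positive in all libraries"):
            cg.rle_norm_factors(make_cm([[0, 5], [5, 0]], lib_sizes=[10.0, 10.0]))


class TestLog2CPM:
    def test_zero_count_with_prior_at_unit_effective_size(self):
        cm = make_cm([[0]], lib_sizes=[1e6], factors=[1.0])
        assert cg.log2_cpm(cm, prior=0.25).iloc[0, 0] == -2.0

    def test_unit_value_case(self):
        cm = make_cm([[1]], lib_sizes=[1.25e6], factors=[1.0])
        assert cg.log2_cpm(cm, prior=0.25).iloc[0, 0] == 0.0

    def test_monotone_in_count(self):
        cm = make_cm([[0], [1], [5], [50]], lib_sizes=[1e6], factors=[1.0])
        vals = cg.log2_cpm(cm).iloc[:, 0].to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_column_shift_equals_minus_log2_factor_ratio(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(40, size=(100, 2))
        base = make_cm(counts, lib_sizes=[1e6, 1e6], factors=[1.0, 1.0])
        scaled = make_cm(counts, lib_sizes=[1e6, 1e6], factors=[1.0, 4.0])
        delta = cg.log2_cpm(scaled) - cg.log2_cpm(base)
        assert np.allclose(delta.iloc[:, 0], 0.0)
        assert np.allclose(delta.iloc[:, 1], -2.0)


class TestExpressionFilter:
    def test_promoter_below_floor_dropped(self):
        lc = pd.DataFrame([[-2.5, -2.6]], index=["p1"])
        assert not cg.expression_filter(lc, floor=-2.0).loc["p1"]

    def test_enhancer_above_floor_in_one_library_kept(self):
        lc = pd.DataFrame([[-3.0, -4.0]], index=["e1"])
        assert cg.expression_filter(lc, floor=-3.5).loc["e1"]

    def test_one_of_eight_libraries_suffices(self):
        row = [[-5.0] * 7 + [-1.0]]
        assert cg.expression_filter(pd.DataFrame(row), floor=-2.0, min_libs=1).iloc[0]

    def test_strictly_above_floor_required(self):
        lc = pd.DataFrame([[-2.0, -2.0]])
        assert not cg.expression_filter(lc, floor=-2.0).iloc[0]


class TestSharedFactors:
    def test_enhancer_cpm_uses_promoter_factors(self):
        rng = np.random.default_rng(3)
        pc = make_cm(rng.poisson(100, size=(300, 4)), lib_sizes=[1e5] * 4)
        ec = make_cm(rng.poisson(5, size=(50, 4)), lib_sizes=[1e5] * 4)
        lp, le, factors = cg.promoter_enhancer_log2_cpm(pc, ec)
        expected = cg.log2_cpm(ec.with_factors(factors))
        pd.testing.assert_frame_equal(le, expected)
        pd.testing.assert_series_equal(factors, cg.rle_norm_factors(pc))


def bh_oracle(p):
    """Brute-force BH: q_(i) = min_{j>=i} m * p_(j) / (j+1), clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q[order[rank]] = running
    return q


class TestExactNBTestAndBH:
    def test_bh_worked_example(self):
        assert np.allclose(cg.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bh_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(cg.bh_adjust(p), bh_oracle(p))

    def test_identical_groups_give_p_one(self):
        counts = np.tile([[50], [10], [200]], (1, 8))
        cm = make_cm(counts, lib_sizes=[1e4] * 8, factors=[1.0] * 8)
        de = cg.nb_exact_test_bh(cm, ["a"] * 4 + ["b"] * 4)
        assert np.allclose(de["p"], 1.0)
        assert (de["label"] == "ns").all()

    def test_all_zero_feature_is_ns_with_p_one(self):
        counts = np.vstack([np.zeros(8, dtype=int), np.full(8, 50)])
        cm = make_cm(counts, lib_sizes=[1e4] * 8, factors=[1.0] * 8)
        de = cg.nb_exact_test_bh(cm, ["a"] * 4 + ["b"] * 4)
        assert de.iloc[0]["p"] == 1.0 and de.iloc[0]["logFC"] == 0.0

    def test_null_rejection_rate_single_seed(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.poisson(500, size=(2000, 8)))
        cm = cm.with_factors(cg.rle_norm_factors(cm))
        de = cg.nb_exact_test_bh(cm, ["a"] * 4 + ["b"] * 4)
        rate = (de["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 4 * se
        assert (de["q"] < 0.05).sum() <= 0.05 * 2000

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(7)
        r = 1 / 0.1
        mean = np.full((1000, 8), 100.0)
        mean[:50, 4:] *= 4
        counts = rng.negative_binomial(r, r / (r + mean))
        cm = make_cm(counts)
        cm = cm.with_factors(cg.rle_norm_factors(cm))
        de = cg.nb_exact_test_bh(cm, ["a"] * 4 + ["b"] * 4, levels=("a", "b"))
        assert (de["label"].iloc[:50] == "up").mean() >= 0.8

    def test_direction_labels_follow_fold_change(self):
        counts = np.tile([[20] * 4 + [200] * 4, [200] * 4 + [20] * 4], (30, 1))
        cm = make_cm(counts, lib_sizes=[1e4] * 8, factors=[1.0] * 8)
        de = cg.nb_exact_test_bh(cm, ["a"] * 4 + ["b"] * 4, levels=("a", "b"))
        assert (de["label"].iloc[0::2] == "up").all()
        assert (de["label"].iloc[1::2] == "down").all()

    def test_requires_two_libraries_per_group(self):
        cm = make_cm([[1, 2, 3]], lib_sizes=[10.0] * 3, factors=[1.0] * 3)
        with pytest.raises(ValueError, match=">= 2 libraries"):
            cg.nb_exact_test_bh(cm, ["a", "a", "b"])
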