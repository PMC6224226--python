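import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betainc

from epiclock import preprocess
from epiclock.preprocess import (
    BuildConfig,
    build_matrix,
    exclude_low_coverage_samples,
    filter_sites,
    jeffreys_bounds,
    jeffreys_interval,
    knn_impute,
    merge_replicates,
    methylation_frequency,
    pool_strands,
    reduce_missingness,
)

from conftest import make_counts, make_table


def beta_quantile_bisect(q, a, b, tol=1e-12):
    """Independent Beta quantile: bisection on the regularized incomplete
    beta function (never calls scipy's ppf)."""
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if betainc(a, b, mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestPoolStrands:
    def test_forward_and_reverse_counts_sum(self):
        rec = make_counts([("chr1", 100, "+", 3, 10), ("chr1", 101, "-", 2, 5)])
        pooled = pool_strands(rec)
        assert pooled.loc[("chr1", 100)].tolist() == [5, 15]
        assert len(pooled) == 1

    def test_forward_only_site_retained(self):
        pooled = pool_strands(make_counts([("chr1", 100, "+", 3, 10)]))
        assert pooled.loc[("chr1", 100)].tolist() == [3, 10]

    def test_reverse_only_site_maps_to_forward_position(self):
        pooled = pool_strands(make_counts([("chr1", 201, "-", 1, 4)]))
        assert pooled.loc[("chr1", 200)].tolist() == [1, 4]

    def test_reverse_at_position_one_rejected(self):
        with pytest.raises(ValueError, match="position 1"):
            pool_strands(make_counts([("chr1", 1, "-", 1, 4)]))


class TestMergeReplicates:
    def test_counts_sum_on_shared_keys(self):
        a = make_table({("s", 100): (3, 10)})
        b = make_table({("s", 100): (1, 2)})
        assert merge_replicates([a, b]).loc[("s", 100)].tolist() == [4, 12]

    def test_union_of_keys(self):
        a = make_table({("s", 100): (3, 10)})
        b = make_table({("s", 200): (0, 5)})
        m = merge_replicates([a, b])
        assert len(m) == 2 and m.loc[("s", 200)].tolist() == [0, 5]

    def test_single_table_is_identity(self):
        a = make_table({("s", 100): (3, 10)})
        pd.testing.assert_frame_equal(merge_replicates([a]), a)


class TestJeffreys:
    def test_no_reads_means_no_confidence(self):
        call = jeffreys_interval(0, 0)
        assert not call.confident and np.isnan(call.lower)

    def test_mid_frequency_shallow_coverage_not_confident(self):
        # Beta(5.5, 5.5) equal-tailed 95% interval is wider than 0.50
        call = jeffreys_interval(5, 10)
        assert call.upper - call.lower > 0.50 and not call.confident

    def test_extreme_frequency_shallow_coverage_confident(self):
        call = jeffreys_interval(0, 10)
        assert call.upper - call.lower < 0.50 and call.confident

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            jeffreys_interval(11, 10)

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (5, 10), (17, 40), (64, 64)])
    def test_matches_independent_bisection_oracle(self, k, n):
        call = jeffreys_interval(k, n)
        lo = beta_quantile_bisect(0.025, k + 0.5, n - k + 0.5)
        hi = beta_quantile_bisect(0.975, k + 0.5, n - k + 0.5)
        assert call.lower == pytest.approx(lo, abs=1e-6)
        assert call.upper == pytest.approx(hi, abs=1e-6)

    @given(n=st.integers(1, 200), frac=st.integers(0, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_posterior_symmetry(self, n, frac):
        # lower(k, n) == 1 - upper(n - k, n): Beta posterior mirror identity
        k = (n * frac) // 100
        a = jeffreys_interval(k, n)
        b = jeffreys_interval(n - k, n)
        assert a.lower == pytest.approx(1.0 - b.upper, abs=1e-12)

    @pytest.mark.parametrize("frac", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_width_shrinks_with_coverage(self, frac):
        ns = [5, 10, 20, 40, 80, 160, 320, 640]
        widths = []
        for n in ns:
            k = round(frac * n)
            lo, hi = jeffreys_bounds(float(k), float(n))
            widths.append(float(hi - lo))
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] < 0.50


class TestFrequency:
    @pytest.mark.parametrize("k,n,f", [(3, 10, 0.3), (0, 7, 0.0), (7, 7, 1.0)])
    def test_raw_frequency(self, k, n, f):
        assert methylation_frequency(k, n) == f

    def test_zero_coverage_is_missing(self):
        assert np.isnan(methylation_frequency(0, 0))


class TestSampleExclusion:
    @staticmethod
    def table_with_measured(n):
        return make_table({("chr1", 100 + 2 * i): (1, 2) for i in range(n)})

    def test_strictly_below_threshold_dropped(self):
        tables = {"a": self.table_with_measured(9), "b": self.table_with_measured(10)}
        kept, dropped = exclude_low_coverage_samples(tables, min_sites=10)
        assert dropped == ["a"] and list(kept) == ["b"]

    def test_exactly_at_threshold_retained(self):
        tables = {"a": self.table_with_measured(10)}
        kept, dropped = exclude_low_coverage_samples(tables, min_sites=10)
        assert not dropped

    def test_all_dropped_is_an_error(self):
        with pytest.raises(ValueError, match="floor"):
            exclude_low_coverage_samples({"a": self.table_with_measured(3)},
                                         min_sites=10)

    def test_zero_total_rows_do_not_count_as_measured(self):
        shallow = make_table({("chr1", 100): (0, 0), ("chr1", 102): (1, 2)})
        deep = self.table_with_measured(2)
        kept, dropped = exclude_low_coverage_samples(
            {"a": shallow, "b": deep}, min_sites=2
        )
        assert dropped == ["a"] and list(kept) == ["b"]


class TestFilterSites:
    def test_threshold_is_inclusive(self):
        conf = pd.DataFrame(True, index=range(20), columns=["s1", "s2"])
        conf.loc[0, "s1"] = False                     # 19/20 = 0.95 -> kept
        conf.loc[[0, 1], "s2"] = False                # 18/20 = 0.90 -> dropped
        assert filter_sites(conf, 0.95) == ["s1"]

    def test_matches_brute_force_on_random_calls(self):
        rng = np.random.default_rng(5)
        conf = pd.DataFrame(rng.random((50, 40)) < 0.9,
                            columns=[f"c{j}" for j in range(40)])
        expected = [c for c in conf.columns
                    if sum(conf[c]) / 50 >= 0.95]
        assert filter_sites(conf, 0.95) == expected


class TestReduceMissingness:
    def test_already_below_target_is_unchanged(self):
        vals = pd.DataFrame(np.ones((5, 20)), index=list("abcde"))
        vals.iloc[0, 0] = np.nan  # 1%
        out, removed = reduce_missingness(vals, target=0.02)
        assert removed == [] and out.shape == (5, 20)

    def test_removal_sequence_matches_hand_simulation(self):
        # A: 3 missing, B: 1, C: 0 over 4 sites; target 10%
        vals = pd.DataFrame(
            [[np.nan, np.nan, np.nan, 1.0],
             [np.nan, 1.0, 1.0, 1.0],
             [1.0, 1.0, 1.0, 1.0]],
            index=["A", "B", "C"],
        )
        out, removed = reduce_missingness(vals, target=0.10)
        assert removed == ["A", "B"]
        assert list(out.index) == ["C"]

    def test_tie_breaks_to_first_sample(self):
        vals = pd.DataFrame(
            [[np.nan, 1.0, 1.0], [np.nan, 1.0, 1.0], [1.0, 1.0, 1.0]],
            index=["x", "y", "z"],
        )
        _, removed = reduce_missingness(vals, target=0.05)
        assert removed[0] == "x"

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.random((30, 30)),
                            index=[f"s{i:02d}" for i in range(30)])
        vals = vals.mask(rng.random((30, 30)) < 0.15)
        out, removed = reduce_missingness(vals, target=0.05)

        ref = vals.copy()
        ref_removed = []
        while len(ref) > 1 and ref.isna().to_numpy().mean() > 0.05:
            counts = ref.isna().sum(axis=1)
            worst = counts.index[np.argmax(counts.to_numpy())]
            ref_removed.append(worst)
            ref = ref.drop(index=worst)
        assert removed == ref_removed
        assert list(out.index) == list(ref.index)


class TestKnnImpute:
    def test_uniform_donors_give_their_value(self):
        vals = pd.DataFrame(np.full((6, 3), 0.4))
        vals.iloc[0, 0] = np.nan
        out = knn_impute(vals, k=5)
        assert out.iloc[0, 0] == pytest.approx(0.4)

    def test_hand_computed_two_neighbor_mean(self):
        # distances from s0 over shared observed sites (cols 1,2):
        #   to s1: ((.2-.2)^2 + (.3-.3)^2)/2 = 0      -> nearest
        #   to s2: ((.2-.9)^2 + (.3-.9)^2)/2 = 0.425
        #   to s3: ((.2-.3)^2 + (.3-.4)^2)/2 = 0.01   -> second
        vals = pd.DataFrame(
            [[np.nan, 0.2, 0.3],
             [0.5, 0.2, 0.3],
             [0.9, 0.9, 0.9],
             [0.7, 0.3, 0.4]]
        )
        out = knn_impute(vals, k=2)
        assert out.iloc[0, 0] == pytest.approx((0.5 + 0.7) / 2)

    def test_no_missing_is_identity(self):
        vals = pd.DataFrame(np.random.default_rng(0).random((4, 4)))
        pd.testing.assert_frame_equal(knn_impute(vals, k=2), vals)

    def test_all_missing_site_rejected(self):
        vals = pd.DataFrame([[np.nan, 0.5], [np.nan, 0.6], [np.nan, 0.7]])
        with pytest.raises(ValueError, match="zero observed"):
            knn_impute(vals)

    def test_observed_cells_unchanged_and_values_in_range(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.random((20, 15)))
        mask = rng.random((20, 15)) < 0.1
        mask[:, 0] = False  # keep one fully observed site
        masked = vals.mask(mask)
        out = knn_impute(masked, k=5)
        observed = ~mask
        assert np.allclose(out.to_numpy()[observed], vals.to_numpy()[observed])
        assert ((out.to_numpy() >= 0) & (out.to_numpy() <= 1)).all()


class TestBuildMatrix:
    def test_pipeline_is_deterministic(self, small_sim):
        _, tables, metadata, _, _ = small_sim
        pooled = {s: pool_strands(t) for s, t in tables.items()}
        cfg = BuildConfig(min_sites=100)
        m1, man1 = build_matrix(pooled, metadata, cfg)
        m2, man2 = build_matrix(pooled, metadata, cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert man1 == man2

    def test_replicates_are_merged_by_summing(self):
        meta = pd.DataFrame(
            {"sample_id": ["a"], "tissue": ["liver"], "study": ["s"],
             "age": [3.0], "strain": ["B6"], "group": ["control"]}
        ).set_index("sample_id", drop=False)
        rep1 = make_table({("chr1", 100 + 2 * i): (10, 20) for i in range(5)})
        rep2 = make_table({("chr1", 100 + 2 * i): (5, 20) for i in range(5)})
        matrix, _ = build_matrix({"a": [rep1, rep2]}, meta, BuildConfig(min_sites=1))
        assert matrix.values.iloc[0, 0] == pytest.approx(15 / 40)

    def test_no_confident_sites_is_a_hard_error(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b"], "tissue": ["l", "l"], "study": ["s", "s"],
             "age": [1.0, 2.0], "strain": ["B6", "B6"], "group": ["c", "c"]}
        ).set_index("sample_id", drop=False)
        shallow = make_table({("chr1", 100): (1, 2), ("chr1", 102): (1, 2)})
        with pytest.raises(ValueError, match="no site"):
            build_matrix({"a": shallow, "b": shallow}, meta, BuildConfig(min_sites=1))
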