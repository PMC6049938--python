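"""Size factors, dispersion estimation, NB Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xutclass.differential import (
    CountMatrix,
    bh_adjust,
    estimate_dispersions,
    nb_wald_test,
    run_differential,
    size_factors_median_of_ratios,
)
from conftest import nb_counts

COND = {"WT_1": "WT", "WT_2": "WT", "mut_1": "mut", "mut_2": "mut"}


def _cm(arr, cond=None, columns=None):
    cond = cond or COND
    columns = columns or list(cond)
    return CountMatrix(pd.DataFrame(np.asarray(arr), columns=columns), cond)


class TestCountMatrix:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            _cm([[1, -1, 2, 3]])

    def test_rejects_single_condition(self):
        with pytest.raises(ValueError, match="two conditions"):
            _cm([[1, 2]], cond={"a": "WT", "b": "WT"})


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm(np.tile([[10], [50], [200]], (1, 4)))
        np.testing.assert_allclose(size_factors_median_of_ratios(cm), 1.0)

    def test_two_gene_hand_example(self):
        # g1=(100,200), g2=(400,800): geometric means 141.42 and 565.69,
        # per-sample ratio medians 1/sqrt(2) and sqrt(2)
        cm = _cm([[100, 200], [400, 800]], cond={"a": "WT", "b": "mut"})
        f = size_factors_median_of_ratios(cm)
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_scaling_one_column_scales_its_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=(100, 4))
        scaled = base.copy()
        scaled[:, 2] *= 3
        f0 = size_factors_median_of_ratios(_cm(base))
        f1 = size_factors_median_of_ratios(_cm(scaled))
        # ratios between factors of untouched samples are preserved;
        # the scaled sample's factor grows by 3 relative to them
        np.testing.assert_allclose(
            (f1 / f0).to_numpy() / (f1 / f0).iloc[0], [1, 1, 3, 1], rtol=1e-9
        )

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(1, 1000, size=(50, 4))
        perm = rng.permutation(50)
        np.testing.assert_allclose(
            size_factors_median_of_ratios(_cm(arr)),
            size_factors_median_of_ratios(_cm(arr[perm])),
        )

    def test_error_when_no_all_positive_feature(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_of_ratios(_cm([[0, 1, 2, 3], [4, 0, 5, 6]]))

    def test_agrees_with_pydeseq2(self):
        # independent reference implementation of the same estimator
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(2)
        arr = nb_counts(rng, 300.0, 0.1, size=(200, 4)) + 1
        cm = _cm(arr)
        meta = pd.DataFrame(
            {"condition": [COND[c] for c in cm.counts.columns]},
            index=cm.counts.columns,
        )
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        np.testing.assert_allclose(
            size_factors_median_of_ratios(cm),
            dds.obs["size_factors"].to_numpy(),
            rtol=1e-6,
        )


class TestDispersions:
    def test_equal_counts_give_zero_raw_dispersion(self):
        cm = _cm(np.full((1, 4), 50))
        d = estimate_dispersions(cm, size_factors_median_of_ratios(cm), fit_trend=False)
        assert d["disp_raw"].iloc[0] == 0.0

    def test_poisson_counts_recover_near_zero_dispersion(self):
        rng = np.random.default_rng(3)
        cm = _cm(rng.poisson(500.0, size=(1000, 4)))
        d = estimate_dispersions(cm, size_factors_median_of_ratios(cm))
        assert d["disp_raw"].median() <= 0.02

    def test_nb_counts_recover_known_dispersion(self):
        rng = np.random.default_rng(4)
        cm = _cm(nb_counts(rng, 500.0, 0.1, size=(2000, 4)))
        d = estimate_dispersions(cm, size_factors_median_of_ratios(cm))
        assert 0.05 <= d["disp_raw"].median() <= 0.2

    def test_all_zero_feature_flagged(self):
        arr = np.vstack([np.zeros(4, dtype=int), np.full(4, 100)])
        cm = _cm(arr)
        d = estimate_dispersions(cm, pd.Series(1.0, index=cm.counts.columns))
        assert bool(d["all_zero"].iloc[0]) and np.isnan(d["dispersion"].iloc[0])


class TestWald:
    def test_identical_large_counts_give_null_result(self):
        lfc, p = nb_wald_test([1000, 1000, 1000, 1000], [1, 1, 1, 1], 0.01,
                              [False, False, True, True])
        assert abs(lfc) < 1e-9 and p > 0.99

    def test_both_conditions_zero_untestable(self):
        lfc, p = nb_wald_test([0, 0, 0, 0], [1, 1, 1, 1], 0.05,
                              [False, False, True, True])
        assert (lfc, p) == (0.0, 1.0)

    def test_power_at_fourfold_reduction(self):
        # 4-fold reduction from mean 800, alpha=0.05, 2v2: near-complete power
        rng = np.random.default_rng(5)
        wt = nb_counts(rng, 800.0, 0.05, size=(500, 2))
        mut = nb_counts(rng, 200.0, 0.05, size=(500, 2))
        counts = np.hstack([wt, mut]).astype(float)
        is_mut = np.array([False, False, True, True])
        factors = np.ones(4)
        hits = sum(
            nb_wald_test(row, factors, 0.05, is_mut)[1] < 0.05 for row in counts
        )
        assert hits / 500 >= 0.9

    def test_power_monotone_in_fold_change_and_mean(self):
        rng = np.random.default_rng(6)
        is_mut = np.array([False, False, True, True])

        def power(mean, fold, n=300):
            wt = nb_counts(rng, mean, 0.05, size=(n, 2))
            mut = nb_counts(rng, mean / fold, 0.05, size=(n, 2))
            rows = np.hstack([wt, mut]).astype(float)
            return np.mean([nb_wald_test(r, np.ones(4), 0.05, is_mut)[1] < 0.05 for r in rows])

        by_fold = [power(500, f) for f in (1.5, 3, 6)]
        assert by_fold[0] <= by_fold[1] <= by_fold[2]
        by_mean = [power(m, 2) for m in (20, 200, 2000)]
        assert by_mean[0] <= by_mean[1] <= by_mean[2]


def bh_oracle(p):
    """Literal step-up rule: adjusted p at rank i is the smallest
    p_(k) * m / k over all ranks k >= i, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = [
        min(1.0, min(sorted_p[k] * m / (k + 1) for k in range(i, m)))
        for i in range(m)
    ]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_hand_example_all_collapse_to_largest(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.randoms())
    def test_permutation_equivariant_and_monotone(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p[perm]), bh_adjust(p)[perm])
        adj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestRunDifferential:
    def test_null_type_one_error_calibrated(self, null_count_matrix):
        res = run_differential(null_count_matrix)
        fpr = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= fpr <= 0.08
        assert (res["padj"] < 0.05).sum() <= 2  # BH controls FDR under the null

    def test_adjusted_p_dominates_raw_and_preserves_order(self, null_count_matrix):
        res = run_differential(null_count_matrix)
        ok = res.dropna(subset=["padj"])
        assert (ok["padj"] >= ok["pvalue"] - 1e-12).all()
        by_p = ok.sort_values("pvalue")["padj"].to_numpy()
        assert (np.diff(by_p) >= -1e-12).all()

    def test_untestable_rows_flagged(self):
        arr = np.vstack([np.zeros(4, dtype=int), np.full((20, 4), 100)])
        res = run_differential(_cm(arr))
        assert bool(res["untestable"].iloc[0])
        assert np.isnan(res["padj"].iloc[0]) and res["pvalue"].iloc[0] == 1.0

    def test_test_features_restricts_rows_but_uses_all_for_factors(self):
        rng = np.random.default_rng(8)
        arr = nb_counts(rng, 300.0, 0.05, size=(100, 4))
        cm = _cm(arr)
        ids = list(cm.counts.index[:40])
        res = run_differential(cm, test_features=ids)
        assert list(res.index) == ids
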