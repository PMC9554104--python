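"""Confusion measures, impairment strata, correlations, report layout."""

import numpy as np
import pandas as pd
import pytest

from armuse.evaluate import (ConfusionTable, confusion, descriptives_by_label,
                             method_comparison_report, performance,
                             stratify_by_impairment,
                             threshold_fma_correlation)
from armuse.thresholds import classify_threshold, conventional_models

from _oracles import tally_oracle


class TestConfusion:
    def test_perfect_predictions(self):
        t = np.array([1] * 6 + [0] * 4)
        tab = confusion(t.astype(bool), t)
        assert (tab.tp, tab.tn, tab.fp, tab.fn) == (6, 4, 0, 0)

    def test_all_positive_predictions(self):
        truth = np.array([1] * 3 + [0] * 7)
        tab = confusion(np.ones(10, bool), truth)
        assert (tab.tp, tab.fp, tab.tn, tab.fn) == (3, 7, 0, 0)

    def test_hand_tally(self):
        tab = confusion([True, True, False, False], [1, 0, 1, 0])
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="aligned"):
            confusion([True], [1, 0])

    def test_matches_tally_oracle_on_random_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 200))
            pred = rng.random(n) < 0.5
            truth = (rng.random(n) < 0.4).astype(int)
            tab = confusion(pred, truth)
            rep = performance(tab)
            want = tally_oracle(list(pred), list(truth))
            assert (tab.tp, tab.fp, tab.tn, tab.fn) == (
                want["tp"], want["fp"], want["tn"], want["fn"])
            for m in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
                got = getattr(rep, m)
                if np.isnan(want[m]):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want[m], abs=1e-15)


class TestPerformance:
    def test_direct_substitution(self):
        rep = performance(ConfusionTable(tp=30, fp=20, tn=40, fn=10))
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(0.70)
        assert rep.ppv == pytest.approx(0.60)
        assert rep.npv == pytest.approx(0.80)

    def test_single_class_truth_undefined_measures(self):
        with pytest.warns(UserWarning, match="specificity undefined"):
            rep = performance(ConfusionTable(tp=10, fp=0, tn=0, fn=0))
        assert rep.sensitivity == 1.0 and rep.accuracy == 1.0
        assert np.isnan(rep.specificity)

    def test_scale_invariance(self):
        r1 = performance(ConfusionTable(3, 2, 4, 1))
        r2 = performance(ConfusionTable(30, 20, 40, 10))
        for m in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert getattr(r1, m) == pytest.approx(getattr(r2, m))

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            performance(ConfusionTable(0, 0, 0, 0))

    def test_accuracy_is_prevalence_weighted_mean(self, rng):
        """acc = pi * sens + (1 - pi) * spec with pi the truth prevalence."""
        for _ in range(20):
            n = int(rng.integers(10, 500))
            pred = rng.random(n) < 0.5
            truth = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(int)
            if truth.min() == truth.max():
                continue
            rep = performance(confusion(pred, truth))
            pi = truth.mean()
            assert rep.accuracy == pytest.approx(
                pi * rep.sensitivity + (1 - pi) * rep.specificity, abs=1e-12)


class TestImpairmentStrata:
    @pytest.mark.parametrize("fma,cat", [
        (65, "mild"), (43, "mild"), (42, "moderate"), (38, "moderate"),
        (29, "moderate"), (28, "severe"), (19, "severe"), (16, "severe"),
        (0, "severe"), (66, "mild")])
    def test_bands(self, fma, cat):
        assert stratify_by_impairment(fma) == cat

    def test_bands_partition_full_range(self):
        assert all(stratify_by_impairment(f) in {"mild", "moderate", "severe"}
                   for f in range(0, 67))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            stratify_by_impairment(70)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = threshold_fma_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = threshold_fma_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = threshold_fma_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = threshold_fma_correlation([1.0] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 4"):
            threshold_fma_correlation([1, 2, 3], [1, 2, 3])


class TestDescriptives:
    def _table(self, counts, labels, wbm=None, side="affected"):
        n = len(counts)
        wbm = [False] * n if wbm is None else wbm
        return pd.DataFrame({
            "subject_id": "S0", "side": side, "epoch_index": range(n),
            "counts": counts,
            "label": pd.array([pd.NA if w else l for l, w in zip(labels, wbm)],
                              dtype="Int64"),
            "excluded_wbm": wbm})

    def test_interpolated_quartiles(self):
        df = descriptives_by_label(self._table([0, 0, 0, 10], [1, 1, 1, 1]))
        row = df.iloc[0]
        assert row["median"] == 0.0
        assert row["q3"] == pytest.approx(2.5)

    def test_single_value_degenerate(self):
        df = descriptives_by_label(self._table([7.0], [0]))
        row = df.iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 7.0

    def test_cohort_reproduces_published_functional_median(self, small_cohort):
        _, _, table = small_cohort
        df = descriptives_by_label(table)
        row = df[(df["side"] == "affected") & (df["class"] == "functional")]
        assert abs(row["median"].iloc[0] - 78.9) / 78.9 < 0.15

    def test_wbm_reported_separately(self):
        df = descriptives_by_label(self._table([1, 2, 3], [1, 0, 0],
                                               wbm=[False, False, True]))
        assert set(df["class"]) == {"functional", "non_functional", "wbm"}


class TestMethodComparison:
    def test_identical_predictors_identical_rows(self, small_cohort):
        _, _, table = small_cohort
        uni, _ = conventional_models()
        f = lambda c: classify_threshold(c, uni)
        grid, per_subject = method_comparison_report(
            table, {"a": {"affected": f, "unaffected": f},
                    "b": {"affected": f, "unaffected": f}})
        a = grid[grid["method"] == "a"].drop(columns="method").reset_index(drop=True)
        b = grid[grid["method"] == "b"].drop(columns="method").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert set(grid["laterality"]) == {"affected", "unaffected", "bilateral"}

    def test_conventional_vs_optimal_tradeoff(self, small_cohort):
        from armuse.roc import OptimalThresholdModel
        _, _, table = small_cohort
        uni, _ = conventional_models()
        fitted = {s: OptimalThresholdModel.from_epochs(table, s).fit()
                  for s in ("affected", "unaffected")}
        grid, _ = method_comparison_report(table, {
            "conventional": {s: (lambda c: classify_threshold(c, uni))
                             for s in ("affected", "unaffected")},
            "optimal": {s: fitted[s].predict for s in ("affected", "unaffected")},
        })
        g = grid.set_index(["method", "laterality"])
        for side in ("affected", "unaffected"):
            assert (g.loc[("conventional", side), "sensitivity"]
                    > g.loc[("optimal", side), "sensitivity"])
            assert (g.loc[("conventional", side), "specificity"]
                    < g.loc[("optimal", side), "specificity"])

    def test_prediction_length_mismatch_errors(self, small_cohort):
        _, _, table = small_cohort
        with pytest.raises(ValueError, match="denominator"):
            method_comparison_report(
                table, {"bad": {"affected": np.array([True]),
                                "unaffected": np.array([True])}})


def test_ppv_declines_with_prevalence_at_fixed_operating_point(rng):
    """Severity pattern: fewer functional epochs -> lower PPV at the same
    sensitivity and specificity."""
    sens, spec = 0.85, 0.78
    ppvs = []
    for prev in (0.45, 0.35, 0.25, 0.15, 0.05):
        n = 20000
        truth = (rng.random(n) < prev).astype(int)
        pred = np.where(truth == 1, rng.random(n) < sens, rng.random(n) > spec)
        ppvs.append(performance(confusion(pred, truth)).ppv)
    assert all(a > b for a, b in zip(ppvs, ppvs[1:]))
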