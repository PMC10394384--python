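"""Correlation, IRLS robust regression, chi-square, and ROI ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurofactor.crossval import PredictionTable
from neurofactor.evaluation import (
    DegenerateInputError,
    IRLSConfig,
    IRLSRegression,
    chi_square_p,
    evaluate_factor,
    irls_fit,
    median_mse_by_roi,
    pearson_with_p,
    rank_rois_top5,
)


def ols_slope_intercept(x, y):
    """Closed-form least-squares oracle."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(20)
        r, p = pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_vectors(self):
        r, _ = pearson_with_p([1, -1, 1, -1], [1, 1, -1, -1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # x=(1,2,3), y=(1,2,4): cov=1.5, sx=1, sy=sqrt(7/3) -> r=3/sqrt(28/3)
        r, p = pearson_with_p([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_p([1.0, 1.0, 1.0], [1, 2, 3])


class TestIrlsFit:
    @pytest.mark.parametrize("p", [1.0, 1.5, 2.0])
    def test_exact_line_recovered(self, p, rng):
        x = rng.standard_normal(30)
        y = 2.0 * x + 1.0
        fit = irls_fit(x, y, IRLSConfig(p=p))
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.converged

    def test_p2_equals_ols_closed_form(self):
        """With p=2 the weights stay constant and IRLS is exactly OLS."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.standard_normal(25)
            y = r.standard_normal(25) + 0.5 * x
            fit = irls_fit(x, y, IRLSConfig(p=2.0))
            slope, intercept = ols_slope_intercept(x, y)
            assert abs(fit.slope - slope) <= 1e-8
            assert abs(fit.intercept - intercept) <= 1e-8

    def test_robust_to_gross_outliers(self):
        """p=1 IRLS beats OLS for slope recovery under 10% contamination."""
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.standard_normal(50)
            y = 2.0 * x + r.normal(0, 0.1, 50)
            y[:5] += 10.0  # gross outliers
            fit = irls_fit(x, y, IRLSConfig(p=1.0))
            slope_ols, _ = ols_slope_intercept(x, y)
            if abs(fit.slope - 2.0) < abs(slope_ols - 2.0):
                wins += 1
        assert wins >= 90

    def test_t_statistic_matches_ols_inference_at_p2(self, rng):
        x = rng.standard_normal(40)
        y = 1.2 * x + rng.standard_normal(40)
        fit = irls_fit(x, y, IRLSConfig(p=2.0))
        lr = stats.linregress(x, y)
        assert fit.t_statistic == pytest.approx(lr.slope / lr.stderr, rel=1e-6)
        assert fit.p_value == pytest.approx(lr.pvalue, rel=1e-6)

    def test_weights_nonnegative_and_convergence_flagged(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        fit = irls_fit(x, y, IRLSConfig(p=1.0))
        assert np.all(fit.final_weights >= 0)
        assert fit.iterations_used <= 50

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            irls_fit([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


class TestIRLSRegressionEstimator:
    def test_fit_predict_and_fitted_attributes(self, rng):
        x = rng.standard_normal(50)
        y = 3.0 * x - 0.5 + rng.normal(0, 0.01, 50)
        est = IRLSRegression(p=1.0).fit(x[:, None], y)
        assert est.slope_ == pytest.approx(3.0, abs=0.01)
        assert est.intercept_ == pytest.approx(-0.5, abs=0.01)
        pred = est.predict(np.array([[0.0], [1.0]]))
        assert pred[1] - pred[0] == pytest.approx(est.slope_)

    def test_get_set_params(self):
        est = IRLSRegression(p=2.0)
        assert est.get_params()["p"] == 2.0
        est.set_params(p=1.0, max_iterations=10)
        assert est.p == 1.0


class TestChiSquare:
    def test_equal_observed_expected(self):
        stat, p = chi_square_p([5.0, 5.0], [5.0, 5.0], dof=1)
        assert stat == 0.0
        assert p == 1.0

    def test_textbook_example_matches_survival_function(self):
        stat, p = chi_square_p([10, 20], [15, 15], dof=1)
        assert stat == pytest.approx(10 / 3)
        assert p == pytest.approx(stats.chi2.sf(10 / 3, 1))
        assert p == pytest.approx(0.0679, abs=2e-4)

    def test_doubling_scales_statistic(self, rng):
        O = rng.uniform(1, 10, 5)
        E = rng.uniform(1, 10, 5)
        s1, _ = chi_square_p(O, E, 4)
        s2, _ = chi_square_p(2 * O, 2 * E, 4)
        assert s2 == pytest.approx(2 * s1)

    def test_p_monotone_decreasing_in_statistic(self):
        # O=(15+x, 15) vs E=(15, 15): statistic x^2/15 grows with x
        ps = [chi_square_p([15 + x, 15], [15, 15], 1)[1] for x in (0, 3, 6, 9)]
        assert ps == sorted(ps, reverse=True)
        assert len(set(ps)) == len(ps)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_p([1.0], [0.0], 1)


def _table_from_roi(roi_df, factor="Anxiety"):
    patch = roi_df.rename(columns={"estimate": "estimate"}).copy()
    patch["patch_id"] = 0
    return PredictionTable.from_patch_records(patch, factor)


class TestMedianMse:
    def _truths(self, subjects, values):
        return pd.DataFrame({"Anxiety": values},
                            index=pd.Index(subjects, name="subject_id"))

    def test_perfect_predictions_give_zero_medians(self):
        subjects = [f"S{i}" for i in range(6)]
        truths = self._truths(subjects, np.linspace(-1, 1, 6))
        rows = [{"subject_id": s, "roi": r, "patch_id": 0, "fold": 0,
                 "estimate": truths.loc[s, "Anxiety"]}
                for s in subjects for r in ("R1", "R2")]
        table = PredictionTable.from_patch_records(pd.DataFrame(rows), "Anxiety")
        m = median_mse_by_roi(table, truths)
        assert np.allclose(m["median_mse"], 0.0)

    def test_constant_offset_gives_unit_median(self):
        subjects = [f"S{i}" for i in range(5)]
        truths = self._truths(subjects, np.zeros(5))
        rows = [{"subject_id": s, "roi": "R1", "patch_id": 0, "fold": 0,
                 "estimate": 1.0} for s in subjects]
        table = PredictionTable.from_patch_records(pd.DataFrame(rows), "Anxiety")
        m = median_mse_by_roi(table, truths)
        assert m["median_mse"].iloc[0] == pytest.approx(1.0)

    def test_matches_sorting_oracle_with_groups(self, rng):
        subjects = [f"S{i}" for i in range(8)]
        truths = self._truths(subjects, rng.standard_normal(8))
        rows = [{"subject_id": s, "roi": r, "patch_id": 0, "fold": 0,
                 "estimate": float(rng.standard_normal())}
                for s in subjects for r in ("R1", "R2", "R3")]
        table = PredictionTable.from_patch_records(pd.DataFrame(rows), "Anxiety")
        groups = {"gA": ["R1", "R2"], "gB": ["R3"]}
        m = median_mse_by_roi(table, truths, roi_groups=groups)
        # sort-based oracle per ROI
        df = pd.DataFrame(rows)
        df["sq"] = (df["estimate"] - truths.loc[df["subject_id"], "Anxiety"].to_numpy())**2
        for roi, grp in df.groupby("roi"):
            vals = sorted(grp["sq"])
            oracle = (vals[len(vals)//2] if len(vals) % 2 else
                      0.5 * (vals[len(vals)//2 - 1] + vals[len(vals)//2]))
            got = m.loc[m["roi"] == roi, "median_mse"].iloc[0]
            assert got == pytest.approx(oracle, abs=1e-12)
        pooled = sorted(df[df["roi"].isin(["R1", "R2"])]["sq"])
        oracle_g = 0.5 * (pooled[len(pooled)//2 - 1] + pooled[len(pooled)//2])
        got_g = m.loc[m["group"] == "gA", "median_mse"].iloc[0]
        assert got_g == pytest.approx(oracle_g, abs=1e-12)

    def test_missing_truths_rejected(self):
        truths = self._truths(["S0"], [0.0])
        rows = [{"subject_id": "S1", "roi": "R1", "patch_id": 0, "fold": 0,
                 "estimate": 0.0}]
        table = PredictionTable.from_patch_records(pd.DataFrame(rows), "Anxiety")
        with pytest.raises(KeyError):
            median_mse_by_roi(table, truths)


class TestRankRois:
    def _table(self, medians):
        return pd.DataFrame([{"roi": k, "group": "", "n": 5, "median_mse": v}
                             for k, v in medians.items()])

    def test_five_smallest_in_order(self):
        m = self._table({"A": 0.5, "B": 0.1, "C": 0.9, "D": 0.3, "E": 0.2, "F": 0.7})
        assert rank_rois_top5(m) == ["B", "E", "D", "A", "F"]

    def test_ties_break_lexicographically(self):
        m = self._table({"Z": 0.5, "A": 0.5, "M": 0.5})
        assert rank_rois_top5(m) == ["A", "M", "Z"]

    def test_invariant_to_row_order(self, rng):
        medians = {f"R{i}": float(rng.uniform()) for i in range(8)}
        m = self._table(medians)
        shuffled = m.sample(frac=1.0, random_state=3)
        assert rank_rois_top5(m) == rank_rois_top5(shuffled)

    def test_fewer_than_five_rois(self):
        assert len(rank_rois_top5(self._table({"A": 1.0, "B": 2.0}))) == 2


class TestEvaluateFactor:
    def _make(self, estimates, truths_vals, rng, n_rois=4):
        subjects = [f"S{i}" for i in range(len(truths_vals))]
        truths = pd.DataFrame({"Anxiety": truths_vals},
                              index=pd.Index(subjects, name="subject_id"))
        rows = []
        for si, s in enumerate(subjects):
            for r in range(n_rois):
                rows.append({"subject_id": s, "roi": f"R{r}", "patch_id": 0,
                             "fold": 0, "estimate": float(estimates[si, r])})
        return PredictionTable.from_patch_records(pd.DataFrame(rows), "Anxiety"), truths

    def test_perfect_predictions(self, rng):
        t = rng.standard_normal(20)
        est = np.repeat(t[:, None], 4, axis=1)
        table, truths = self._make(est, t, rng)
        report = evaluate_factor(table, truths)
        assert report.pooled_pearson_r == pytest.approx(1.0)
        assert report.robust_fit.slope == pytest.approx(1.0, abs=1e-6)
        assert abs(report.robust_fit.intercept) < 1e-6
        assert np.allclose(report.median_mse["median_mse"], 0.0)

    def test_noisy_predictions_show_attenuation(self, rng):
        t = rng.standard_normal(200)
        noise = rng.standard_normal((200, 4))
        table, truths = self._make(t[:, None] + noise, t, rng)
        report = evaluate_factor(table, truths)
        assert 0.0 < report.pooled_pearson_r < 1.0
        assert report.robust_fit.slope == pytest.approx(1.0, abs=0.25)
        assert report.n_pairs == 800

    def test_constant_predictions_surface_degeneracy(self, rng):
        t = rng.standard_normal(10)
        table, truths = self._make(np.zeros((10, 4)), t, rng)
        with pytest.raises(DegenerateInputError):
            evaluate_factor(table, truths)
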