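"""Evaluation: pooled correlation, IRLS robust regression, ROI ranking.

ROI-level performance is summarized over pooled (subject, ROI) pairs — each
subject contributes one ROI-level estimate per ROI, all folds pooled — which
is the reading under which the degrees of freedom match p-values reported
for cohorts of this size.  Alongside the standard Pearson r with its
t-transform p-value, a robust straight-line fit by iteratively reweighted
least squares (IRLS) de-emphasizes outlying pairs: each iteration solves a
weighted least-squares problem with weights ``w_i^2 = max(|e_i|, eps)^(p-2)``
recomputed from the previous residuals, so the p-norm objective
``sum |e_i|^p`` is minimized by repeated 2-norm solves.  With p = 2 the
weights are constant and IRLS reduces exactly to ordinary least squares.

ROI informativeness is the median across subjects of the squared error of
the ROI-level estimate; lower medians mean more predictive regions, and the
five smallest-median ROIs form the per-factor ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IRLSConfig",
    "RobustFit",
    "IRLSRegression",
    "EvaluationReport",
    "pearson_with_p",
    "irls_fit",
    "chi_square_p",
    "median_mse_by_roi",
    "rank_rois_top5",
    "evaluate_factor",
]


class DegenerateInputError(ValueError):
    """Raised for zero-variance inputs where a statistic is undefined."""


@dataclass(frozen=True)
class IRLSConfig:
    """IRLS settings: norm power p (default 1, robust), iteration limits,
    and the residual floor eps guarding the weight formula at exact fits."""

    p: float = 1.0
    max_iterations: int = 50
    tolerance: float = 1e-8
    residual_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 2.0):
            raise ValueError("norm power p must be in (0, 2]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.residual_floor <= 0:
            raise ValueError("residual_floor must be positive")


@dataclass(frozen=True)
class RobustFit:
    """Result of a robust straight-line fit."""

    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    iterations_used: int
    converged: bool
    final_weights: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def pearson_with_p(estimates, truths) -> tuple[float, float]:
    """Product-moment correlation with its t-transform p (n - 2 dof)."""
    x = np.asarray(estimates, dtype=np.float64)
    y = np.asarray(truths, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _wls(x: np.ndarray, y: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Weighted least squares for y ~ slope*x + intercept; returns (slope, intercept)."""
    A = np.column_stack([x, np.ones_like(x)])
    Aw = A * w2[:, None]
    G = A.T @ Aw
    if np.linalg.matrix_rank(G) < 2:
        raise DegenerateInputError("degenerate design: constant predictor")
    return np.linalg.solve(G, Aw.T @ y)


def irls_fit(x, y, config: IRLSConfig | None = None) -> RobustFit:
    """Robust line fit by iteratively reweighted least squares.

    Starts from ordinary least squares, then alternates residual-derived
    weights ``w_i^2 = max(|e_i|, eps)^(p-2)`` with weighted 2-norm solves
    until the coefficient change drops below the tolerance or the iteration
    limit is reached.  The t statistic is slope / SE with the standard error
    taken from the weighted least-squares covariance at the final weights
    (weighted residual variance, n - 2 dof).
    """
    config = config or IRLSConfig()
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("degenerate design: constant predictor")

    w2 = np.ones(n)
    coef = _wls(x, y, w2)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        resid = y - (coef[0] * x + coef[1])
        w2 = np.maximum(np.abs(resid), config.residual_floor) ** (config.p - 2.0)
        new_coef = _wls(x, y, w2)
        delta = float(np.max(np.abs(new_coef - coef)))
        coef = new_coef
        if delta < config.tolerance:
            converged = True
            break

    resid = y - (coef[0] * x + coef[1])
    A = np.column_stack([x, np.ones_like(x)])
    G = A.T @ (A * w2[:, None])
    sigma2 = float((w2 * resid**2).sum() / (n - 2))
    cov = sigma2 * np.linalg.inv(G)
    se = float(np.sqrt(cov[0, 0]))
    if se == 0.0:
        t_stat = 0.0 if coef[0] == 0 else float(np.sign(coef[0]) * np.inf)
        p_val = 1.0 if coef[0] == 0 else 0.0
    else:
        t_stat = float(coef[0] / se)
        p_val = float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))
    return RobustFit(
        slope=float(coef[0]),
        intercept=float(coef[1]),
        t_statistic=t_stat,
        p_value=p_val,
        iterations_used=iterations,
        converged=converged,
        final_weights=np.sqrt(w2),
    )


class IRLSRegression(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator form of the IRLS robust line fit.

    Parameters mirror :class:`IRLSConfig`.  Fitted attributes: ``slope_``,
    ``intercept_``, ``t_statistic_``, ``p_value_``, ``converged_``,
    ``n_iter_``, ``weights_``.
    """

    def __init__(self, p: float = 1.0, max_iterations: int = 50,
                 tolerance: float = 1e-8, residual_floor: float = 1e-6):
        self.p = p
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.residual_floor = residual_floor

    def fit(self, X, y):
        x = np.asarray(X, dtype=np.float64)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("IRLSRegression fits a single predictor")
            x = x[:, 0]
        fit = irls_fit(x, y, IRLSConfig(
            p=self.p, max_iterations=self.max_iterations,
            tolerance=self.tolerance, residual_floor=self.residual_floor,
        ))
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.t_statistic_ = fit.t_statistic
        self.p_value_ = fit.p_value
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations_used
        self.weights_ = fit.final_weights
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, 0]
        return self.slope_ * x + self.intercept_


def chi_square_p(observed, expected, dof: int) -> tuple[float, float]:
    """Chi-square statistic ``sum (O - E)^2 / E`` and its upper-tail p.

    The observed/expected mapping is the caller's: the function applies the
    printed formula to whatever O, E, dof are supplied.  Expected values
    must be strictly positive.
    """
    O = np.asarray(observed, dtype=np.float64)
    E = np.asarray(expected, dtype=np.float64)
    if O.shape != E.shape:
        raise ValueError("length mismatch")
    if np.any(E <= 0):
        raise ValueError("expected values must be strictly positive")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    statistic = float(((O - E) ** 2 / E).sum())
    return statistic, float(stats.chi2.sf(statistic, df=dof))


def median_mse_by_roi(predictions, truths: pd.DataFrame,
                      roi_groups: dict[str, list[str]] | None = None,
                      group_method: str = "pool") -> pd.DataFrame:
    """Median across subjects of the squared ROI-level estimation error.

    One squared error per (ROI, subject): ``(roi_estimate - true_score)^2``;
    the per-ROI value is the median over subjects.  If ``roi_groups`` maps
    testing-set names to member ROI abbreviations, a per-group value is
    appended: the median over the pooled member records (``group_method
    "pool"``) or the mean of member medians (``"mean_of_medians"``).

    Returns a frame with columns roi, group, n, median_mse (group rows have
    roi = "").
    """
    factor = predictions.factor_name
    if factor not in truths.columns:
        raise KeyError(f"factor {factor!r} missing from truth table")
    roi_df = predictions.roi.copy()
    roi_df["subject_id"] = roi_df["subject_id"].astype(str)
    truth_col = truths[factor].copy()
    truth_col.index = truth_col.index.astype(str)
    missing = sorted(set(roi_df["subject_id"]) - set(truth_col.index))
    if missing:
        raise KeyError(f"subjects without truth scores: {missing}")
    roi_df["sq_error"] = (roi_df["estimate"] - truth_col.loc[
        roi_df["subject_id"]].to_numpy()) ** 2

    rows = []
    for roi, grp in roi_df.groupby("roi"):
        rows.append({"roi": str(roi), "group": "", "n": len(grp),
                     "median_mse": float(grp["sq_error"].median())})
    per_roi = pd.DataFrame(rows)

    if roi_groups:
        roi_to_median = dict(zip(per_roi["roi"], per_roi["median_mse"]))
        for gname, members in roi_groups.items():
            sub = roi_df[roi_df["roi"].isin(members)]
            if sub.empty:
                continue
            if group_method == "pool":
                val = float(sub["sq_error"].median())
            elif group_method == "mean_of_medians":
                val = float(np.mean([roi_to_median[m] for m in members
                                     if m in roi_to_median]))
            else:
                raise ValueError(f"unknown group_method {group_method!r}")
            per_roi = pd.concat([per_roi, pd.DataFrame([{
                "roi": "", "group": gname, "n": len(sub), "median_mse": val,
            }])], ignore_index=True)
    return per_roi


def rank_rois_top5(median_table: pd.DataFrame, k: int = 5) -> list[str]:
    """The k ROIs with the smallest median MSE, ascending; ties broken
    lexicographically by abbreviation."""
    rois = median_table[median_table["roi"] != ""]
    if rois.empty:
        raise ValueError("median table holds no ROI rows")
    ordered = rois.sort_values(["median_mse", "roi"], kind="mergesort")
    return [str(r) for r in ordered["roi"].head(min(k, len(ordered)))]


@dataclass
class EvaluationReport:
    """Per-factor evaluation summary."""

    factor_name: str
    pooled_pearson_r: float
    pooled_pearson_p: float
    robust_fit: RobustFit
    chi_square_statistic: float
    chi_square_p: float
    chi_square_dof: int
    median_mse: pd.DataFrame
    top5: list[str]
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "factor_name": self.factor_name,
            "pooled_pearson_r": self.pooled_pearson_r,
            "pooled_pearson_p": self.pooled_pearson_p,
            "robust_slope": self.robust_fit.slope,
            "robust_intercept": self.robust_fit.intercept,
            "robust_t": self.robust_fit.t_statistic,
            "robust_p": self.robust_fit.p_value,
            "robust_converged": bool(self.robust_fit.converged),
            "chi_square_statistic": self.chi_square_statistic,
            "chi_square_p": self.chi_square_p,
            "chi_square_dof": self.chi_square_dof,
            "median_mse": self.median_mse.to_dict(orient="records"),
            "top5": list(self.top5),
            "n_pairs": self.n_pairs,
        }


def _chi_square_on_bins(estimates: np.ndarray, truths: np.ndarray,
                        n_bins: int = 10) -> tuple[float, float, int]:
    """Distributional agreement check: counts of estimates (O) vs truths (E)
    over truth-decile bins, so expected counts are positive by construction."""
    qs = np.quantile(truths, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    # merge duplicate edges from ties
    edges = np.unique(qs)
    if len(edges) < 3:
        return 0.0, 1.0, 1
    E, _ = np.histogram(truths, bins=edges)
    O, _ = np.histogram(estimates, bins=edges)
    keep = E > 0
    dof = max(1, int(keep.sum()) - 1)
    stat, p = chi_square_p(O[keep], E[keep], dof)
    return stat, p, dof


def evaluate_factor(predictions, truths: pd.DataFrame,
                    config: IRLSConfig | None = None,
                    roi_groups: dict[str, list[str]] | None = None) -> EvaluationReport:
    """Full per-factor evaluation over pooled (subject, ROI) ROI-level pairs.

    Pools every ROI-level estimate with its subject's true score across all
    folds, computes Pearson r/p and the IRLS robust fit of estimates on
    truths, a chi-square distributional p (truth-decile bins), the per-ROI
    median-MSE table, and the top-5 ROI ranking.
    """
    config = config or IRLSConfig()
    factor = predictions.factor_name
    if factor not in truths.columns:
        raise KeyError(f"factor {factor!r} missing from truth table")
    roi_df = predictions.roi.copy()
    roi_df["subject_id"] = roi_df["subject_id"].astype(str)
    truth_col = truths[factor].copy()
    truth_col.index = truth_col.index.astype(str)
    est = roi_df["estimate"].to_numpy(dtype=np.float64)
    tru = truth_col.loc[roi_df["subject_id"]].to_numpy(dtype=np.float64)

    r, p = pearson_with_p(est, tru)
    fit = irls_fit(tru, est, config)
    chi_stat, chi_p, chi_dof = _chi_square_on_bins(est, tru)
    mtable = median_mse_by_roi(predictions, truths, roi_groups=roi_groups)
    top5 = rank_rois_top5(mtable)
    return EvaluationReport(
        factor_name=factor,
        pooled_pearson_r=r,
        pooled_pearson_p=p,
        robust_fit=fit,
        chi_square_statistic=chi_stat,
        chi_square_p=chi_p,
        chi_square_dof=chi_dof,
        median_mse=mtable,
        top5=top5,
        n_pairs=int(est.size),
    )
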