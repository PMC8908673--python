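"""Robust four-parameter-logistic (4PL) dose-response analysis.

The response model on the log10-dose axis is

    r(d) = bottom + (top - bottom) / (1 + 10**((log10_ec50 - log10 d) * hill))

with ``hill`` free in sign: positive for curves that rise with dose (e.g.
growth-factor potency assays), negative for viability curves that fall with
dose. Fitting minimizes a robust soft-L1 loss of the residuals
(``scipy.optimize.least_squares``) from multiple starts spanning both Hill
signs and several EC50 initializations.

Drug sensitivity is summarized as EC50 (dose units) and the area under the
fitted curve over log10 dose (AUC, % x log10-dose units); a larger AUC means
a more resistant sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DoseResponseDataset",
    "FourPLFit",
    "DrugSensitivity",
    "SubtypeComparison",
    "FourPLRegressor",
    "four_pl",
    "normalize_to_reference",
    "fit_4pl_robust",
    "ec50",
    "auc_log_dose",
    "soft_l1_loss",
    "compare_subtypes",
    "spearman_niche_vs_auc",
]


def four_pl(dose, bottom: float, top: float, log10_ec50: float, hill: float):
    """Evaluate the 4PL response at ``dose`` (> 0)."""
    logd = np.log10(np.asarray(dose, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ec50 - logd) * hill))


def soft_l1_loss(residuals: np.ndarray, f_scale: float) -> float:
    """Total soft-L1 cost: sum of f^2 * 2*(sqrt(1 + (r/f)^2) - 1).

    Matches 2x the ``least_squares`` cost with ``loss='soft_l1'``; quadratic
    for small residuals, linear for outliers.
    """
    z = (np.asarray(residuals, dtype=float) / f_scale) ** 2
    return float(f_scale**2 * np.sum(2.0 * (np.sqrt(1.0 + z) - 1.0)))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseDataset:
    drug: str
    sample_id: str
    dose: np.ndarray        # > 0, dose units
    response: np.ndarray    # %, normalized so reference-dose mean = 100
    dose_unit: str = ""
    reference_dose: float | None = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must have equal length")
        if (self.dose <= 0).any():
            raise ValueError("doses must be strictly positive (dose 0 disallowed)")


@dataclass
class FourPLFit:
    bottom: float
    top: float
    log10_ec50: float
    hill_slope: float
    loss_value: float
    converged: bool
    n_points: int
    hill_unidentifiable: bool = False

    @property
    def ec50(self) -> float:
        return float(10.0**self.log10_ec50)

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.log10_ec50, self.hill_slope)


@dataclass
class DrugSensitivity:
    sample_id: str
    drug: str
    ec50: float
    auc: float
    dose_range: tuple[float, float]


@dataclass
class SubtypeComparison:
    drug: str
    group_means: dict[str, float]
    group_n: dict[str, int]
    t_statistic: float
    p_value: float
    groups: tuple[str, str] = ("Low", "High")
    members: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_reference(
    points: pd.DataFrame, reference_dose: float, by=("drug", "sample_id")
) -> pd.DataFrame:
    """Scale responses so the mean response at ``reference_dose`` is 100%.

    ``points`` is a long table with at least (dose, response) plus the ``by``
    grouping columns. Raises if any group lacks the reference dose.
    """
    by = [c for c in by if c in points.columns]
    out = points.copy()

    def _scale(g: pd.DataFrame) -> pd.DataFrame:
        at_ref = g[np.isclose(g["dose"], reference_dose)]
        if at_ref.empty:
            raise ValueError(
                f"reference dose {reference_dose} absent in group "
                f"{tuple(g.iloc[0][by]) if by else '(all)'}"
            )
        ref_mean = at_ref["response"].mean()
        if ref_mean == 0:
            raise ValueError("zero mean response at reference dose")
        g = g.copy()
        g["response"] = g["response"] * (100.0 / ref_mean)
        return g

    if by:
        out = (
            out.groupby(by, group_keys=False, sort=False)[out.columns]
            .apply(_scale)
            .reset_index(drop=True)
        )
    else:
        out = _scale(out)
    return out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class FourPLRegressor(RegressorMixin, BaseEstimator):
    """Robust 4PL fit as a scikit-learn regressor.

    Parameters
    ----------
    loss : str, default "soft_l1"
        Residual loss passed to ``scipy.optimize.least_squares``.
    f_scale : float, default 5.0
        Soft-L1 scale, in response units (%): residuals beyond this magnitude
        are downweighted.
    bottom_min, top_max : float
        Box constraints stabilizing small-n fits on normalized % responses
        (bottom >= 0, top <= 150 by default); set to +/-inf to disable.

    Fitted attributes: ``bottom_``, ``top_`` (>= bottom_), ``log10_ec50_``,
    ``hill_``, ``ec50_``, ``loss_value_``, ``converged_``,
    ``hill_unidentifiable_``, ``n_points_``.
    """

    def __init__(
        self,
        loss: str = "soft_l1",
        f_scale: float = 5.0,
        bottom_min: float = 0.0,
        top_max: float = 150.0,
        max_nfev: int = 2000,
        tol: float = 1e-12,
    ):
        self.loss = loss
        self.f_scale = f_scale
        self.bottom_min = bottom_min
        self.top_max = top_max
        self.max_nfev = max_nfev
        self.tol = tol

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _as_dose(X) -> np.ndarray:
        d = np.asarray(X, dtype=float)
        if d.ndim == 2 and d.shape[1] == 1:
            d = d.ravel()
        if d.ndim != 1:
            raise ValueError("X must be a 1-D dose vector or (n, 1) column")
        if (d <= 0).any():
            raise ValueError("doses must be strictly positive")
        return d

    def _starts(self, logd: np.ndarray, y: np.ndarray):
        lo = max(float(np.min(y)), self.bottom_min)
        hi = min(float(np.max(y)), self.top_max)
        if hi <= lo:
            hi = lo + 1.0
        qs = np.quantile(logd, [0.25, 0.5, 0.75])
        for le in qs:
            for hill in (1.0, -1.0):
                yield np.array([lo, hi, le, hill])

    def fit(self, X, y):
        d = self._as_dose(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape != d.shape:
            raise ValueError("X and y must have equal length")
        n_distinct = np.unique(d).size
        if n_distinct < 4:
            raise ValueError(
                f"need >= 4 distinct doses to fit a 4PL (got {n_distinct})"
            )
        logd = np.log10(d)
        span = float(np.ptp(y))
        self.hill_unidentifiable_ = bool(span < 1e-9)

        lb = np.array([self.bottom_min, self.bottom_min, logd.min() - 2.0, -10.0])
        ub = np.array([self.top_max, self.top_max, logd.max() + 2.0, 10.0])

        def resid(theta):
            return four_pl(d, *theta) - y

        best = None
        any_success = False
        for x0 in self._starts(logd, y):
            x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
            try:
                res = optimize.least_squares(
                    resid, x0, bounds=(lb, ub), loss=self.loss,
                    f_scale=self.f_scale, max_nfev=self.max_nfev,
                    xtol=self.tol, ftol=self.tol, gtol=self.tol,
                )
            except Exception:  # pragma: no cover - scipy failure path
                continue
            any_success = any_success or bool(res.success)
            if best is None or res.cost < best.cost:
                best = res
        if best is None:  # pragma: no cover
            raise RuntimeError("4PL optimization failed from every start")

        bottom, top, log_ec50, hill = best.x
        if bottom > top:  # canonical form: top >= bottom, hill sign flipped
            bottom, top, hill = top, bottom, -hill
        self.bottom_ = float(bottom)
        self.top_ = float(top)
        self.log10_ec50_ = float(log_ec50)
        self.hill_ = float(hill)
        self.converged_ = any_success
        if self.loss == "soft_l1":
            self.loss_value_ = soft_l1_loss(resid(best.x), self.f_scale)
        else:
            self.loss_value_ = float(np.sum(resid(best.x) ** 2))
        self.n_points_ = int(d.size)
        self.dose_range_ = (float(d.min()), float(d.max()))
        self.n_features_in_ = 1
        return self

    @property
    def ec50_(self) -> float:
        check_is_fitted(self, "log10_ec50_")
        return float(10.0**self.log10_ec50_)

    def predict(self, X):
        check_is_fitted(self, "log10_ec50_")
        d = self._as_dose(X)
        return four_pl(d, self.bottom_, self.top_, self.log10_ec50_, self.hill_)

    def auc(self, dose_range: tuple[float, float] | None = None, n_grid: int = 513) -> float:
        """Integral of the fitted curve over log10 dose (trapezoid, fine grid)."""
        check_is_fitted(self, "log10_ec50_")
        lo, hi = dose_range if dose_range is not None else self.dose_range_
        if not (0 < lo < hi):
            raise ValueError("dose_range must satisfy 0 < lo < hi")
        grid = np.linspace(np.log10(lo), np.log10(hi), n_grid)
        resp = four_pl(10.0**grid, self.bottom_, self.top_,
                       self.log10_ec50_, self.hill_)
        return float(np.trapezoid(resp, grid))

    def to_fit(self) -> FourPLFit:
        check_is_fitted(self, "log10_ec50_")
        return FourPLFit(
            bottom=self.bottom_, top=self.top_, log10_ec50=self.log10_ec50_,
            hill_slope=self.hill_, loss_value=self.loss_value_,
            converged=self.converged_, n_points=self.n_points_,
            hill_unidentifiable=self.hill_unidentifiable_,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_4pl_robust(ds: DoseResponseDataset, **params) -> FourPLFit:
    return FourPLRegressor(**params).fit(ds.dose, ds.response).to_fit()


def ec50(fit: FourPLFit) -> float:
    return fit.ec50


def auc_log_dose(
    fit: FourPLFit, dose_range: tuple[float, float], n_grid: int = 513
) -> float:
    lo, hi = dose_range
    if not (0 < lo < hi):
        raise ValueError("dose_range must satisfy 0 < lo < hi")
    grid = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    return float(np.trapezoid(fit.predict(10.0**grid), grid))


def drug_sensitivity(ds: DoseResponseDataset, **params) -> DrugSensitivity:
    """Fit one (drug, sample) dataset and summarize EC50 + AUC."""
    fit = fit_4pl_robust(ds, **params)
    rng = (float(ds.dose.min()), float(ds.dose.max()))
    return DrugSensitivity(
        sample_id=ds.sample_id, drug=ds.drug, ec50=fit.ec50,
        auc=auc_log_dose(fit, rng), dose_range=rng,
    )


def compare_subtypes(
    sens: list[DrugSensitivity], labels: dict[str, str],
    groups: tuple[str, str] = ("Low", "High"),
) -> SubtypeComparison:
    """Unpaired two-tailed Student's t-test of AUC between two subtype groups."""
    by_group: dict[str, list[float]] = {g: [] for g in groups}
    members: dict[str, list[str]] = {g: [] for g in groups}
    drugs = {s.drug for s in sens}
    if len(drugs) != 1:
        raise ValueError(f"sensitivities span multiple drugs: {sorted(drugs)}")
    for s in sens:
        g = labels.get(s.sample_id)
        if g in by_group:
            by_group[g].append(s.auc)
            members[g].append(s.sample_id)
    a, b = (np.array(by_group[g], dtype=float) for g in groups)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variance
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return SubtypeComparison(
        drug=drugs.pop(),
        group_means={g: float(np.mean(by_group[g])) for g in groups},
        group_n={g: len(by_group[g]) for g in groups},
        t_statistic=float(t), p_value=float(p),
        groups=groups, members=members,
    )


def spearman_niche_vs_auc(
    scores: dict[str, float], sens: list[DrugSensitivity]
) -> tuple[float, float]:
    """Spearman rank correlation of niche-dependency score vs drug AUC."""
    pairs = [(scores[s.sample_id], s.auc) for s in sens if s.sample_id in scores]
    if len(pairs) < 3:
        raise ValueError("need >= 3 samples with both score and AUC")
    x, y = zip(*pairs)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
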