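"""Hierarchical polynomial (linear/quadratic/cubic) models of symptom change
on adversity factor scores, with cluster-robust inference and nested
likelihood-ratio comparison.

Each outcome x timepoint is fitted as its own regression of the change score
(later timepoint minus baseline) on powers of the mean-centered predictor
plus covariates, with the sandwich covariance clustered on family.  The
likelihood-ratio ladder (degree 1 -> 2 -> 3) mirrors standard practice for
deciding whether curvature and cubicity are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import DesignError, cluster_robust_cov, gaussian_loglik

__all__ = [
    "PolyModelSpec",
    "PolyFit",
    "NestedComparison",
    "fit_poly",
    "compare_nested",
    "standardize",
]


class ComparisonError(ValueError):
    """Model comparison requested for non-nested or misaligned fits."""


class DegenerateOutcomeError(ValueError):
    """Outcome has zero variance; standardized coefficients undefined."""


@dataclass(frozen=True)
class PolyModelSpec:
    """Specification of one polynomial outcome model.

    ``outcome`` is a change-score column, ``predictor`` a mean-centered
    factor-score column, ``degree`` in {1, 2, 3}.  ``cluster`` names the
    family identifier used for the robust covariance; scanner can optionally
    enter as fixed-effect dummies.
    """

    outcome: str
    predictor: str
    degree: int = 3
    covariates: Sequence[str] = ("sex", "age", "income")
    cluster: str = "family_id"
    scanner_col: str | None = None

    def __post_init__(self):
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2, or 3")


@dataclass
class PolyFit:
    """A fitted polynomial model: raw coefficients, standardized
    counterparts, cluster-robust covariance, and likelihood."""

    spec: PolyModelSpec
    terms: list[str]
    coef: pd.Series
    std_beta: pd.Series
    cov: pd.DataFrame  # cluster-robust
    loglik: float
    n_used: int
    n_clusters: int
    r_squared: float
    row_index: pd.Index = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.terms, name="se")

    def zvalues(self) -> pd.Series:
        return self.coef / self.se

    def pvalues(self) -> pd.Series:
        z = self.zvalues()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.terms, name="p")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zc = stats.norm.ppf(1 - alpha / 2)
        se = self.se
        return pd.DataFrame(
            {"lower": self.coef - zc * se, "upper": self.coef + zc * se}, index=self.terms
        )

    def poly_coefficients(self) -> np.ndarray:
        """(b0, b1, ..., b_degree) on the raw scale, for curve probing."""
        names = ["const"] + [self._power_name(p) for p in range(1, self.spec.degree + 1)]
        return self.coef[names].to_numpy()

    def _power_name(self, p: int) -> str:
        return self.spec.predictor if p == 1 else f"{self.spec.predictor}^{p}"


def _build_design(table: pd.DataFrame, spec: PolyModelSpec):
    cols = [spec.outcome, spec.predictor, *spec.covariates, spec.cluster]
    if spec.scanner_col:
        cols.append(spec.scanner_col)
    data = table[list(dict.fromkeys(cols))].dropna()

    x_full = table[spec.predictor].astype(float)
    if abs(x_full.mean()) > 1e-6:
        raise ValueError(
            f"predictor {spec.predictor!r} must be mean-centered (|mean| < 1e-6)"
        )

    x = data[spec.predictor].to_numpy(dtype=float)
    design = {"const": np.ones(len(data))}
    names = ["const"]
    for p in range(1, spec.degree + 1):
        name = spec.predictor if p == 1 else f"{spec.predictor}^{p}"
        design[name] = x**p
        names.append(name)
    for c in spec.covariates:
        design[c] = data[c].to_numpy(dtype=float)
        names.append(c)
    if spec.scanner_col:
        dummies = pd.get_dummies(data[spec.scanner_col], prefix="scanner", drop_first=True)
        for c in dummies.columns:
            design[c] = dummies[c].to_numpy(dtype=float)
            names.append(c)
    X = pd.DataFrame(design, index=data.index)[names]
    y = data[spec.outcome].to_numpy(dtype=float)
    return X, y, data[spec.cluster].to_numpy()


def fit_poly(table: pd.DataFrame, spec: PolyModelSpec) -> PolyFit:
    """Least-squares fit with family-clustered sandwich covariance.

    Powers are taken of the centered predictor (no re-orthogonalization), so
    the closed-form vertex/inflection formulas of the curve-probing module
    apply to the returned coefficients directly.  Standardized coefficients
    are beta_p = b_p * SD(x^p) / SD(y).
    """
    X, y, clusters = _build_design(table, spec)
    n, k = X.shape
    if n < 10 * k:
        raise ValueError(f"need >= {10 * k} complete rows for {k} parameters, have {n}")
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < k:
        # name the offending columns for the error message
        _, R = np.linalg.qr(Xv)
        bad = [X.columns[i] for i in range(k) if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise DesignError(f"design matrix rank deficient; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    robust = cluster_robust_cov(Xv, resid, clusters)
    if robust.n_clusters < 30:
        raise ValueError(f"need >= 30 clusters for robust covariance, have {robust.n_clusters}")
    ll = gaussian_loglik(resid, n, k)

    sd_y = float(np.std(y, ddof=1))
    if sd_y <= 0:
        raise DegenerateOutcomeError(f"outcome {spec.outcome!r} has zero variance")
    sd_x = np.array([float(np.std(Xv[:, j], ddof=1)) for j in range(k)])
    sd_x[0] = 0.0  # intercept has no standardized analogue
    std = beta * sd_x / sd_y

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

    terms = list(X.columns)
    return PolyFit(
        spec=spec,
        terms=terms,
        coef=pd.Series(beta, index=terms, name="b"),
        std_beta=pd.Series(std, index=terms, name="beta"),
        cov=pd.DataFrame(robust.cov, index=terms, columns=terms),
        loglik=ll,
        n_used=n,
        n_clusters=robust.n_clusters,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        row_index=X.index,
        residuals=resid,
        design=X,
    )


@dataclass(frozen=True)
class NestedComparison:
    """Likelihood-ratio comparison of two nested fits on the same rows."""

    delta_chi_square: float
    delta_df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_nested(fit_lo: PolyFit, fit_hi: PolyFit) -> NestedComparison:
    """Plain likelihood-ratio test: 2*(ll_hi - ll_lo) ~ chi-square(delta_df).

    Requires the lower model's terms to be a subset of the higher model's and
    both fits to use exactly the same rows.
    """
    if not set(fit_lo.terms) <= set(fit_hi.terms):
        raise ComparisonError("models are not nested")
    if fit_lo.n_used != fit_hi.n_used or not fit_lo.row_index.equals(fit_hi.row_index):
        raise ComparisonError("nested comparison requires identical rows")
    delta_df = len(fit_hi.terms) - len(fit_lo.terms)
    delta = max(2.0 * (fit_hi.loglik - fit_lo.loglik), 0.0)
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta, delta_df))
    return NestedComparison(delta_chi_square=float(delta), delta_df=delta_df, p_value=p)


def standardize(fit: PolyFit, alpha: float = 0.05) -> pd.DataFrame:
    """Standardized coefficients beta_p = b_p * SD(x^p)/SD(y) with
    consistently transformed confidence intervals."""
    if fit.std_beta.abs().sum() == 0 and fit.coef.abs().sum() > 0:
        raise DegenerateOutcomeError("standardization unavailable (zero outcome variance)")
    ci = fit.conf_int(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = (fit.std_beta / fit.coef).replace([np.inf, -np.inf], 0.0).fillna(0.0)
    out = pd.DataFrame(
        {
            "beta": fit.std_beta,
            "lower": ci["lower"] * scale,
            "upper": ci["upper"] * scale,
        }
    )
    # a negative scale flips the interval orientation
    lo = out[["lower", "upper"]].min(axis=1)
    hi = out[["lower", "upper"]].max(axis=1)
    out["lower"], out["upper"] = lo, hi
    return out
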