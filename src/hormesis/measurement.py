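"""Latent adversity measurement: confirmatory factor analysis, fit indices,
regression-method factor scores, and single-indicator latent change scores.

Models are fitted by maximum likelihood on the correlation matrix of the
(standardized) indicators, with the latent variance fixed to 1 so estimated
loadings are directly on the standardized scale.  Ordinal items are treated
as continuous after standardization; categorical-data estimators are a
non-goal.  Two structures are supported: a single common factor, and a
higher-order model in which first-order factors over disjoint indicator
blocks load on one second-order factor.

The ML discrepancy minimized is

    F(Sigma) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,

whose (n-1)*F value at the minimum is the model chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "FactorModelSpec",
    "FactorFit",
    "FitIndices",
    "LatentChange",
    "fit_cfa",
    "fit_indices",
    "factor_scores",
    "latent_change",
    "ml_discrepancy",
]


class EstimationError(RuntimeError):
    """CFA estimation failed to converge; carries the best objective seen."""

    def __init__(self, message: str, best_objective: float | None = None):
        super().__init__(message)
        self.best_objective = best_objective


class EmptyResultError(ValueError):
    """No usable rows remained for the requested computation."""


UNIQUENESS_FLOOR = 1e-4


@dataclass(frozen=True)
class FactorModelSpec:
    """Declares a measurement model over table columns.

    For ``structure='higher_order'`` the ``partition`` maps first-order factor
    names to disjoint indicator blocks (>= 3 indicators each); the factor
    score produced is for the second-order factor.  ``reverse_scored`` columns
    are reflected (negated) before standardization so all items point in the
    risk direction.
    """

    name: str
    indicator_columns: Sequence[str]
    structure: str = "single_factor"  # or "higher_order"
    partition: Mapping[str, Sequence[str]] | None = None
    reverse_scored: Sequence[str] = ()

    def __post_init__(self):
        cols = list(self.indicator_columns)
        if len(set(cols)) != len(cols):
            raise ValueError("an indicator appears twice")
        if self.structure not in ("single_factor", "higher_order"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "higher_order":
            if not self.partition:
                raise ValueError("higher_order structure requires a partition")
            flat = [c for block in self.partition.values() for c in block]
            if sorted(flat) != sorted(cols):
                raise ValueError("partition must cover the indicator columns exactly")
            for fname, block in self.partition.items():
                if len(block) < 3:
                    raise ValueError(f"first-order factor {fname!r} has < 3 indicators")
        elif len(cols) < 3:
            raise ValueError("need >= 3 indicators")


@dataclass
class FitIndices:
    rmsea: float
    cfi: float
    tli: float
    srmr: float
    just_identified: bool = False


@dataclass
class FactorFit:
    """A fitted measurement model: standardized loadings, uniquenesses, fit
    statistics, and per-participant mean-centered factor scores."""

    spec: FactorModelSpec
    loadings: pd.Series  # first-order standardized loadings per indicator
    higher_order_loadings: pd.Series | None
    uniquenesses: pd.Series
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    indices: FitIndices
    factor_scores: pd.Series
    n_used: int
    converged: bool
    heywood: bool
    item_means: pd.Series = field(repr=False, default=None)
    item_sds: pd.Series = field(repr=False, default=None)
    implied_corr: np.ndarray = field(repr=False, default=None)
    sample_corr: np.ndarray = field(repr=False, default=None)
    partial_score_rows: int = 0  # participants scored from an indicator subset

    @property
    def rmsea(self):
        return self.indices.rmsea

    @property
    def cfi(self):
        return self.indices.cfi

    @property
    def tli(self):
        return self.indices.tli

    @property
    def srmr(self):
        return self.indices.srmr

    def general_loadings(self) -> pd.Series:
        """Loadings of each indicator on the factor being scored (for the
        higher-order model: lambda_j * gamma_block(j))."""
        if self.spec.structure == "single_factor" or self.higher_order_loadings is None:
            return self.loadings
        lam = self.loadings.copy()
        for fname, block in self.spec.partition.items():
            lam[list(block)] = lam[list(block)] * self.higher_order_loadings[fname]
        return lam


def ml_discrepancy(sigma: np.ndarray, sample: np.ndarray) -> float:
    """Maximum-likelihood discrepancy F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p."""
    p = sample.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(sample)
    return float(logdet_sigma - logdet_s + np.trace(sample @ np.linalg.inv(sigma)) - p)


def _implied(params, p, blocks):
    """Implied correlation matrix and pieces from the parameter vector.

    blocks is None for a single factor; otherwise a list of index arrays, one
    per first-order factor, and params = [lambda(p), gamma(m), theta(p)].
    """
    if blocks is None:
        lam = params[:p]
        theta = params[p:]
        sigma = np.outer(lam, lam) + np.diag(theta)
        return sigma, lam, None, theta
    m = len(blocks)
    lam = params[:p]
    gamma = params[p : p + m]
    theta = params[p + m :]
    L = np.zeros((p, m))
    for k, idx in enumerate(blocks):
        L[idx, k] = lam[idx]
    phi = np.outer(gamma, gamma)
    np.fill_diagonal(phi, 1.0)
    sigma = L @ phi @ L.T + np.diag(theta)
    return sigma, lam, (L, gamma, phi), theta


def _objective_and_grad(params, S, p, blocks):
    sigma, lam, hi, theta = _implied(params, p, blocks)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(params)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(params)
    _, logdet_s = np.linalg.slogdet(S)
    F = logdet_sigma - logdet_s + float(np.trace(S @ sigma_inv)) - p
    G = sigma_inv @ (sigma - S) @ sigma_inv
    if blocks is None:
        grad = np.concatenate([2.0 * G @ lam, np.diag(G)])
    else:
        L, gamma, phi = hi
        GLP = 2.0 * G @ L @ phi
        grad_lam = np.zeros(p)
        for k, idx in enumerate(blocks):
            grad_lam[idx] = GLP[idx, k]
        M = L.T @ G @ L
        m = len(blocks)
        grad_gamma = np.zeros(m)
        for k in range(m):
            grad_gamma[k] = 2.0 * sum(M[k, j] * gamma[j] for j in range(m) if j != k)
        grad = np.concatenate([grad_lam, grad_gamma, np.diag(G)])
    return F, grad


def _pairwise_corr(frame: pd.DataFrame):
    """Pairwise-complete correlation matrix, its effective n, and column moments."""
    corr = frame.corr(min_periods=2).to_numpy()
    if np.any(~np.isfinite(corr)):
        raise EstimationError("correlation matrix has undefined entries (too much missingness)")
    notna = frame.notna().to_numpy().astype(float)
    pair_n = notna.T @ notna
    iu = np.triu_indices_from(pair_n, k=1)
    n_eff = int(round(pair_n[iu].mean())) if iu[0].size else int(pair_n[0, 0])
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < 1e-8:
        warnings.warn("pairwise correlation matrix not positive definite; ridge applied")
        corr = corr + (1e-8 - eigmin) * np.eye(corr.shape[0])
    return corr, n_eff, frame.mean(), frame.std(ddof=1)


def fit_indices(
    chi_square: float,
    df: int,
    baseline_chi_square: float,
    baseline_df: int,
    n: int,
    residual_corr: np.ndarray | None = None,
) -> FitIndices:
    """Approximate-fit indices from model and baseline chi-squares.

    RMSEA = sqrt(max(chi2-df, 0) / (df*(n-1)));
    CFI   = 1 - max(chi2-df, 0) / max(chi2_b-df_b, chi2-df, 0);
    TLI   = ((chi2_b/df_b) - (chi2/df)) / ((chi2_b/df_b) - 1);
    SRMR  = root mean square of the residual correlations.

    A just-identified model (df = 0) has RMSEA defined as 0 and is flagged.
    TLI is reported raw and may exceed 1 when chi-square < df.
    """
    just = df == 0
    rmsea = 0.0 if just else float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    denom = max(baseline_chi_square - baseline_df, chi_square - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi_square - df, 0.0) / denom
    if just or baseline_df == 0:
        tli = float("nan")
    else:
        ratio_b = baseline_chi_square / baseline_df
        tli = (ratio_b - chi_square / df) / (ratio_b - 1.0)
    if residual_corr is None:
        srmr = float("nan")
    else:
        il = np.tril_indices_from(residual_corr)
        srmr = float(np.sqrt(np.mean(residual_corr[il] ** 2)))
    return FitIndices(rmsea=rmsea, cfi=float(cfi), tli=float(tli), srmr=srmr, just_identified=just)


def _free_params(p: int, blocks) -> int:
    return 2 * p if blocks is None else 2 * p + len(blocks)


def fit_cfa(table: pd.DataFrame, spec: FactorModelSpec, max_restarts: int = 5) -> FactorFit:
    """Fit the measurement model and score participants.

    Items are standardized first (reverse-scored items reflected), the model
    is estimated on the pairwise-complete correlation matrix with the latent
    variance fixed at 1, and regression-method factor scores are returned
    mean-centered at zero.  Negative uniquenesses (Heywood cases) are floored
    at 1e-4 and flagged.
    """
    cols = list(spec.indicator_columns)
    frame = table[cols].astype(float).copy()
    for c in spec.reverse_scored:
        frame[c] = -frame[c]

    blocks = None
    if spec.structure == "higher_order" and len(spec.partition) > 1:
        blocks = [np.array([cols.index(c) for c in block]) for block in spec.partition.values()]
    p = len(cols)

    S, n_used, means, sds = _pairwise_corr(frame)
    k_free = _free_params(p, blocks)
    if n_used <= k_free:
        raise EstimationError(f"n_used={n_used} does not exceed free parameter count {k_free}")

    n_lam = p
    n_gam = 0 if blocks is None else len(blocks)
    bounds = (
        [(-0.999, 0.999)] * (n_lam + n_gam) + [(UNIQUENESS_FLOOR, 10.0)] * p
    )

    mean_r = float(np.clip(np.mean(np.abs(S[np.triu_indices(p, 1)])), 0.05, 0.9))
    lam0 = np.full(p, np.sqrt(mean_r))
    start = np.concatenate(
        [lam0, np.full(n_gam, 0.7), np.clip(1.0 - lam0**2, UNIQUENESS_FLOOR, None)]
    )

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        x0 = start if attempt == 0 else np.clip(
            start + rng.normal(0, 0.15, size=start.size), -0.95, 5.0
        )
        x0[n_lam + n_gam :] = np.clip(x0[n_lam + n_gam :], UNIQUENESS_FLOOR, 10.0)
        res = minimize(
            _objective_and_grad,
            x0,
            args=(S, p, blocks),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        # projected gradient norm at the solution
        _, g = _objective_and_grad(res.x, S, p, blocks)
        proj = g.copy()
        for i, (lo, hi) in enumerate(bounds):
            if res.x[i] <= lo + 1e-12 and g[i] > 0:
                proj[i] = 0.0
            if res.x[i] >= hi - 1e-12 and g[i] < 0:
                proj[i] = 0.0
        if np.max(np.abs(proj)) < 1e-6:
            best = res
            converged = True
            break
    else:
        converged = False
    if not converged:
        raise EstimationError(
            "CFA did not converge after restarts", best_objective=float(best.fun)
        )

    x = best.x.copy()
    lam = x[:n_lam]
    gamma = x[n_lam : n_lam + n_gam]
    theta = x[n_lam + n_gam :]

    # sign canonicalization: each factor points with the majority of its items
    if blocks is None:
        if lam.sum() < 0:
            lam = -lam
    else:
        for k, idx in enumerate(blocks):
            if lam[idx].sum() < 0:
                lam[idx] = -lam[idx]
                gamma[k] = -gamma[k]
        if gamma.sum() < 0:
            gamma = -gamma

    heywood = bool(np.any(theta <= UNIQUENESS_FLOOR * 1.5))
    if heywood:
        warnings.warn(f"Heywood case in {spec.name!r}: uniqueness floored at {UNIQUENESS_FLOOR}")

    sigma, *_ = _implied(np.concatenate([lam, gamma, theta]), p, blocks)
    F_min = ml_discrepancy(sigma, S)
    chi_square = (n_used - 1) * F_min
    df = p * (p + 1) // 2 - _free_params(p, blocks)

    _, logdet_s = np.linalg.slogdet(S)
    baseline_chi = (n_used - 1) * (-logdet_s)
    baseline_df = p * (p - 1) // 2

    indices = fit_indices(chi_square, df, baseline_chi, baseline_df, n_used, S - sigma)

    loadings = pd.Series(lam, index=cols, name="loading")
    hol = (
        None
        if blocks is None
        else pd.Series(gamma, index=list(spec.partition.keys()), name="higher_order_loading")
    )
    uniq = pd.Series(theta, index=cols, name="uniqueness")

    fit = FactorFit(
        spec=spec,
        loadings=loadings,
        higher_order_loadings=hol,
        uniquenesses=uniq,
        chi_square=float(chi_square),
        df=int(df),
        baseline_chi_square=float(baseline_chi),
        baseline_df=int(baseline_df),
        indices=indices,
        factor_scores=pd.Series(dtype=float),
        n_used=n_used,
        converged=True,
        heywood=heywood,
        item_means=means,
        item_sds=sds,
        implied_corr=sigma,
        sample_corr=S,
    )
    scores, partial = factor_scores(fit, table)
    fit.factor_scores = scores
    fit.partial_score_rows = partial
    return fit


def factor_scores(fit: FactorFit, table: pd.DataFrame):
    """Regression-method (Thurstone) factor scores, mean-centered at zero.

    scores = Lambda' Sigma^-1 z for standardized indicators z; with a
    higher-order structure the score is for the second-order factor, using
    the indicators' general-factor loadings.  Participants with missing
    indicators are scored from the available-item submatrix and counted in
    the second return value; rows with no indicators get NaN.
    """
    cols = list(fit.spec.indicator_columns)
    frame = table[cols].astype(float).copy()
    for c in fit.spec.reverse_scored:
        frame[c] = -frame[c]
    z = (frame - fit.item_means) / fit.item_sds.replace(0, np.nan)

    lam_g = fit.general_loadings().to_numpy()
    sigma = fit.implied_corr
    try:
        weights_full = np.linalg.solve(sigma, lam_g)
    except np.linalg.LinAlgError as err:
        raise EstimationError("singular implied covariance") from err

    zv = z.to_numpy()
    obs = ~np.isnan(zv)
    scores = np.full(len(frame), np.nan)
    complete = obs.all(axis=1)
    scores[complete] = zv[complete] @ weights_full

    partial = 0
    if (~complete).any():
        patterns = {}
        for i in np.flatnonzero(~complete):
            key = obs[i].tobytes()
            patterns.setdefault(key, []).append(i)
        for key, rows in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            if not mask.any():
                continue
            sub = sigma[np.ix_(mask, mask)]
            w = np.linalg.solve(sub, lam_g[mask])
            idx = np.array(rows)
            scores[idx] = zv[np.ix_(idx, np.flatnonzero(mask))] @ w
            partial += len(rows)
    valid = ~np.isnan(scores)
    if valid.any():
        scores[valid] = scores[valid] - scores[valid].mean()
    return pd.Series(scores, index=table.index, name=f"{fit.spec.name}_score"), partial


@dataclass
class LatentChange:
    """Single-indicator latent change: per-participant later-minus-earlier
    difference with the change distribution's mean and variance."""

    change: pd.Series
    mean_change: float
    variance_change: float
    n_used: int
    n_excluded: int


def latent_change(table: pd.DataFrame, earlier_col: str, later_col: str) -> LatentChange:
    """Difference-score formulation of the just-identified single-indicator
    latent change model: change = later - earlier on the indicator's scale."""
    earlier = pd.to_numeric(table[earlier_col], errors="raise")
    later = pd.to_numeric(table[later_col], errors="raise")
    change = later - earlier
    valid = change.notna()
    if not valid.any():
        raise EmptyResultError(
            f"no participant has both {earlier_col!r} and {later_col!r}"
        )
    vals = change[valid]
    return LatentChange(
        change=change,
        mean_change=float(vals.mean()),
        variance_change=float(vals.var(ddof=1)) if len(vals) > 1 else 0.0,
        n_used=int(valid.sum()),
        n_excluded=int((~valid).sum()),
    )
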