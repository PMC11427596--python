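"""Moderation of the hormetic curve by connectivity change.

Four pieces, mirroring how a cubic-by-moderator effect is established and
then probed:

1. a full-sample regression with all polynomial-by-moderator product terms
   {1, x, x^2, x^3, w, x*w, x^2*w, x^3*w} and Benjamini-Hochberg correction
   of the interaction p-values;
2. simple-slope curves of the cubic at chosen moderator levels;
3. multi-group models parceled by hormesis region/zone (linear-by-linear
   within the four regions, quadratic-by-linear within the two zones) with
   Wald chi-square comparison of interaction paths between groups;
4. Johnson-Neyman areas of significance: the moderator range over which the
   focal conditional effect of adversity is significant, and the count of
   participants falling inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import cluster_robust_cov, wald_test

__all__ = [
    "ModerationSpec",
    "ModerationFit",
    "GroupFit",
    "MultiGroupResult",
    "JNResult",
    "FdrSession",
    "fit_cubic_moderation",
    "bh_adjust",
    "simple_slope_curves",
    "multigroup_by_zone",
    "wald_compare",
    "johnson_neyman_linear",
    "johnson_neyman_quadratic",
    "count_area_of_significance",
]

INTERACTION_TERMS = ("x:w", "x^2:w", "x^3:w")


class DegenerateModeratorError(ValueError):
    """Moderator has (near-)zero variance."""


@dataclass(frozen=True)
class ModerationSpec:
    """Specification of the moderation analysis.

    ``predictor`` (x) and ``moderator`` (w) must be mean-centered columns.
    With ``scale_moderator`` (default) w is additionally divided by its SD so
    interaction coefficients are per-SD of the moderator; Johnson-Neyman
    boundaries are then reported in moderator-SD units (the raw-scale value
    is boundary * w_sd).
    """

    outcome: str
    predictor: str
    moderator: str
    covariates: Sequence[str] = ("sex", "age", "income")
    cluster: str = "family_id"
    alpha: float = 0.05
    fdr_rate: float = 0.05
    scale_moderator: bool = True
    min_group_n: int = 50


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p are multiplied by m/rank and a cumulative minimum is taken from
    the largest rank down, then clipped to 1; the result is monotone
    non-decreasing in the raw ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class FdrSession:
    """Collects interaction p-values across all moderation tests in one
    pipeline run so the false-discovery-rate family spans the session."""

    def __init__(self, rate: float = 0.05):
        self.rate = rate
        self._entries: list[tuple] = []  # (fit, term, p)

    def add(self, fit: "ModerationFit", term: str, p: float) -> None:
        self._entries.append((fit, term, float(p)))

    def finalize(self) -> dict:
        if not self._entries:
            return {}
        adj = bh_adjust([p for _, _, p in self._entries])
        out = {}
        for (fit, term, _), q in zip(self._entries, adj):
            fit.p_adjusted[term] = q
            out[(id(fit), term)] = q
        return out


def _ols_cluster(X: pd.DataFrame, y: np.ndarray, clusters: np.ndarray):
    Xv = X.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    robust = cluster_robust_cov(Xv, resid, clusters)
    terms = list(X.columns)
    return (
        pd.Series(beta, index=terms),
        pd.DataFrame(robust.cov, index=terms, columns=terms),
        resid,
        robust.n_clusters,
    )


def _moderation_design(data: pd.DataFrame, spec: ModerationSpec, degree: int):
    x = data[spec.predictor].to_numpy(dtype=float)
    w = data[spec.moderator].to_numpy(dtype=float)
    w_sd = float(np.std(w, ddof=1))
    if w_sd < 1e-6:
        raise DegenerateModeratorError(
            f"moderator {spec.moderator!r} is (near-)constant in the analysis rows"
        )
    if spec.scale_moderator:
        w = w / w_sd
    cols = {"const": np.ones(len(data))}
    names = ["const"]
    for p in range(1, degree + 1):
        nm = "x" if p == 1 else f"x^{p}"
        cols[nm] = x**p
        names.append(nm)
    cols["w"] = w
    names.append("w")
    for p in range(1, degree + 1):
        nm = ("x" if p == 1 else f"x^{p}") + ":w"
        cols[nm] = (x**p) * w
        names.append(nm)
    for c in spec.covariates:
        cols[c] = data[c].to_numpy(dtype=float)
        names.append(c)
    return pd.DataFrame(cols, index=data.index)[names], w_sd


@dataclass
class ModerationFit:
    """Full-sample polynomial-by-moderator interaction fit."""

    spec: ModerationSpec
    degree: int
    terms: list[str]
    coef: pd.Series
    cov: pd.DataFrame
    n_used: int
    n_clusters: int
    w_sd: float
    p_raw: pd.Series = None
    p_adjusted: pd.Series = None
    row_index: pd.Index = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.terms)

    def pvalues(self) -> pd.Series:
        z = self.coef / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.terms)


def _check_centered(table: pd.DataFrame, col: str) -> None:
    if abs(table[col].astype(float).mean()) > 1e-6:
        raise ValueError(f"column {col!r} must be mean-centered (|mean| < 1e-6)")


def fit_cubic_moderation(
    table: pd.DataFrame, spec: ModerationSpec, session: FdrSession | None = None
) -> ModerationFit:
    """Single regression with all cubic-by-moderator product terms and
    family-clustered covariance.

    Interaction p-values are BH-adjusted: within this fit's three product
    terms when standalone, or across the whole session when an FdrSession is
    supplied (the session finalizes the adjustment once every moderation test
    has been registered).
    """
    _check_centered(table, spec.predictor)
    _check_centered(table, spec.moderator)
    need = [spec.outcome, spec.predictor, spec.moderator, *spec.covariates, spec.cluster]
    data = table[list(dict.fromkeys(need))].dropna()
    X, w_sd = _moderation_design(data, spec, degree=3)
    y = data[spec.outcome].to_numpy(dtype=float)
    coef, cov, _, n_clusters = _ols_cluster(X, y, data[spec.cluster].to_numpy())

    fit = ModerationFit(
        spec=spec,
        degree=3,
        terms=list(X.columns),
        coef=coef,
        cov=cov,
        n_used=len(data),
        n_clusters=n_clusters,
        w_sd=w_sd,
        row_index=data.index,
    )
    pv = fit.pvalues()
    fit.p_raw = pv[list(INTERACTION_TERMS)].copy()
    fit.p_adjusted = pd.Series(np.nan, index=list(INTERACTION_TERMS))
    if session is None:
        fit.p_adjusted[:] = bh_adjust(fit.p_raw.to_numpy())
    else:
        for term in INTERACTION_TERMS:
            session.add(fit, term, fit.p_raw[term])
    return fit


def simple_slope_curves(
    fit: ModerationFit,
    w_levels: Sequence[float] | None = None,
    x_grid: np.ndarray | None = None,
) -> dict:
    """Predicted cubic-in-x curves at chosen moderator levels.

    At moderator level w the curve has coefficients (b_p + g_p * w); levels
    default to -1 SD, mean, +1 SD of the (scaled) moderator.  Covariates are
    held at their contribution to the intercept implicitly (curves are
    relative; the constant uses the fitted intercept).
    """
    if w_levels is None:
        sd = 1.0 if fit.spec.scale_moderator else fit.w_sd
        w_levels = (-sd, 0.0, sd)
    if x_grid is None:
        x_grid = np.linspace(-3, 3, 121)
    out = {}
    c = fit.coef
    for w in w_levels:
        b = [
            c["const"] + c["w"] * w,
            c["x"] + c["x:w"] * w,
            c["x^2"] + c["x^2:w"] * w,
            c["x^3"] + c["x^3:w"] * w,
        ]
        yhat = b[0] + b[1] * x_grid + b[2] * x_grid**2 + b[3] * x_grid**3
        out[float(w)] = {"coefficients": [float(v) for v in b], "x": x_grid, "y": yhat}
    return out


@dataclass
class GroupFit:
    """One within-group interaction fit (linear x linear in a region,
    quadratic x linear in a zone)."""

    name: str
    kind: str  # "linear" or "quadratic"
    terms: list[str]
    coef: pd.Series
    cov: pd.DataFrame
    n_used: int
    n_clusters: int
    w_sd: float
    row_index: pd.Index = field(repr=False, default=None)
    families: frozenset = field(repr=False, default=frozenset())

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.terms)

    def pvalues(self) -> pd.Series:
        z = self.coef / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.terms)


@dataclass
class MultiGroupResult:
    """Per-region and per-zone interaction fits plus bookkeeping."""

    region_fits: dict
    zone_fits: dict
    skipped: list
    split_families: bool

    def get(self, group: str) -> GroupFit:
        if group in self.region_fits:
            return self.region_fits[group]
        if group in self.zone_fits:
            return self.zone_fits[group]
        raise KeyError(f"group {group!r} was not fitted (skipped or unknown)")


def multigroup_by_zone(
    table: pd.DataFrame, spec: ModerationSpec, labels: pd.DataFrame
) -> MultiGroupResult:
    """Fit interaction models within each hormesis region and zone.

    ``labels`` carries 'region' and 'zone' columns aligned to the table (from
    curve probing).  Regions get y ~ x + w + x:w (+covariates); zones get
    y ~ x + x^2 + w + x:w + x^2:w (+covariates).  Groups below the configured
    size floor are skipped with a warning.  Families spanning groups are
    flagged: the between-group Wald test then rests on an independence
    assumption that is not exactly met.
    """
    _check_centered(table, spec.predictor)
    _check_centered(table, spec.moderator)
    need = [spec.outcome, spec.predictor, spec.moderator, *spec.covariates, spec.cluster]
    base = table[list(dict.fromkeys(need))]

    def fit_group(name: str, mask: pd.Series, degree: int, kind: str):
        data = base[mask.reindex(base.index, fill_value=False)].dropna()
        if len(data) < spec.min_group_n:
            warnings.warn(f"group {name!r} has n={len(data)} < {spec.min_group_n}; skipped")
            return None
        X, w_sd = _moderation_design(data, spec, degree=degree)
        y = data[spec.outcome].to_numpy(dtype=float)
        coef, cov, _, n_clusters = _ols_cluster(X, y, data[spec.cluster].to_numpy())
        return GroupFit(
            name=name,
            kind=kind,
            terms=list(X.columns),
            coef=coef,
            cov=cov,
            n_used=len(data),
            n_clusters=n_clusters,
            w_sd=w_sd,
            row_index=data.index,
            families=frozenset(data[spec.cluster].tolist()),
        )

    region_fits, zone_fits, skipped = {}, {}, []
    for name in ("strengthening", "buffering", "rising_toxic", "falling_toxic"):
        gf = fit_group(name, labels["region"] == name, degree=1, kind="linear")
        if gf is None:
            skipped.append(name)
        else:
            region_fits[name] = gf
    for name in ("hormetic", "toxic"):
        gf = fit_group(name, labels["zone"] == name, degree=2, kind="quadratic")
        if gf is None:
            skipped.append(name)
        else:
            zone_fits[name] = gf

    fam_sets = [gf.families for gf in region_fits.values()]
    split = any(
        fam_sets[i] & fam_sets[j] for i in range(len(fam_sets)) for j in range(i + 1, len(fam_sets))
    )
    if split:
        warnings.warn("some families span hormesis groups; Wald independence is approximate")
    return MultiGroupResult(
        region_fits=region_fits, zone_fits=zone_fits, skipped=skipped, split_families=split
    )


def wald_compare(result: MultiGroupResult, group_a: str, group_b: str, term: str):
    """Wald chi-square(1) equality test of one interaction coefficient across
    two disjoint groups: W = (theta_a - theta_b)^2 / (var_a + var_b)."""
    fa, fb = result.get(group_a), result.get(group_b)
    if len(fa.row_index.intersection(fb.row_index)) > 0:
        raise ValueError("groups share participants; Wald comparison invalid")
    if fa.families & fb.families:
        warnings.warn(
            f"families shared between {group_a!r} and {group_b!r}; "
            "independence assumption violated"
        )
    return wald_test(
        float(fa.coef[term]), float(fb.coef[term]),
        float(fa.cov.loc[term, term]), float(fb.cov.loc[term, term]),
    )


@dataclass
class JNResult:
    """Johnson-Neyman boundaries for a conditional effect theta(w) = c0 + c1*w.

    ``intervals`` partitions the moderator axis into (lo, hi, significant,
    direction) pieces, where direction is the sign of theta(w) on the piece.
    Boundaries are on the moderator scale used in the fit (SD units when the
    moderator was scaled).
    """

    effect: str
    boundaries: list
    intervals: list
    t_crit: float
    alpha: float
    c0: float
    c1: float
    v00: float
    v01: float
    v11: float

    def theta(self, w):
        return self.c0 + self.c1 * np.asarray(w, dtype=float)

    def var_theta(self, w):
        w = np.asarray(w, dtype=float)
        return self.v00 + 2 * w * self.v01 + w**2 * self.v11

    def t_ratio(self, w):
        return self.theta(w) / np.sqrt(self.var_theta(w))

    def significant_mask(self, w) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        mask = np.zeros(w.shape, dtype=bool)
        for lo, hi, sig, _ in self.intervals:
            if sig:
                mask |= (w >= lo) & (w <= hi)
        return mask


def _jn_from_linear_form(effect, c0, c1, v00, v01, v11, alpha, t_crit):
    if t_crit is None:
        t_crit = float(stats.norm.ppf(1 - alpha / 2))
    A = c1**2 - t_crit**2 * v11
    B = 2 * (c0 * c1 - t_crit**2 * v01)
    C = c0**2 - t_crit**2 * v00

    boundaries: list[float] = []
    if abs(A) < 1e-300:
        if abs(B) > 0:
            boundaries = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc > 0:
            sq = np.sqrt(disc)
            boundaries = sorted([(-B - sq) / (2 * A), (-B + sq) / (2 * A)])

    edges = [-np.inf, *boundaries, np.inf]
    intervals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo) and np.isinf(hi):
            probe = 0.0
        elif np.isinf(lo):
            probe = hi - 1.0
        elif np.isinf(hi):
            probe = lo + 1.0
        else:
            probe = 0.5 * (lo + hi)
        theta = c0 + c1 * probe
        var = v00 + 2 * probe * v01 + probe**2 * v11
        sig = bool(theta**2 > t_crit**2 * var)
        direction = int(np.sign(theta)) if theta != 0 else 0
        intervals.append((float(lo), float(hi), sig, direction))
    return JNResult(
        effect=effect,
        boundaries=[float(b) for b in boundaries],
        intervals=intervals,
        t_crit=float(t_crit),
        alpha=alpha,
        c0=float(c0), c1=float(c1), v00=float(v00), v01=float(v01), v11=float(v11),
    )


def johnson_neyman_linear(
    group_fit: GroupFit, alpha: float = 0.05, t_crit: float | None = None
) -> JNResult:
    """Area of significance of the conditional linear effect of x:
    theta(w) = b_x + b_xw * w with Var theta(w) from the robust covariance.

    Boundaries are the real roots of theta(w)^2 - t_crit^2 * Var theta(w) = 0;
    with complex roots the effect is significant everywhere or nowhere,
    decided by the t-ratio at w = 0.
    """
    c = group_fit.coef
    V = group_fit.cov
    return _jn_from_linear_form(
        "d y / d x",
        c["x"], c["x:w"],
        V.loc["x", "x"], V.loc["x", "x:w"], V.loc["x:w", "x:w"],
        alpha, t_crit,
    )


def johnson_neyman_quadratic(
    group_fit: GroupFit, x_fixed: float = 0.0, alpha: float = 0.05,
    t_crit: float | None = None,
) -> JNResult:
    """Johnson-Neyman for a quadratic-by-linear fit, probing the conditional
    effect of x at a fixed x value (default: its mean, 0):

    theta(w) = (b_x + b_xw*w) + 2*(b_x2 + b_x2w*w)*x_fixed = c0 + c1*w.

    At x_fixed = 0 this reduces exactly to the linear machinery on the
    (x, x:w) sub-block.
    """
    c = group_fit.coef
    V = group_fit.cov.to_numpy()
    terms = group_fit.terms
    i = {t: terms.index(t) for t in ("x", "x^2", "x:w", "x^2:w")}
    a0 = np.zeros(len(terms))
    a0[i["x"]] = 1.0
    a0[i["x^2"]] = 2.0 * x_fixed
    a1 = np.zeros(len(terms))
    a1[i["x:w"]] = 1.0
    a1[i["x^2:w"]] = 2.0 * x_fixed
    c0 = float(a0 @ c.to_numpy())
    c1 = float(a1 @ c.to_numpy())
    v00 = float(a0 @ V @ a0)
    v01 = float(a0 @ V @ a1)
    v11 = float(a1 @ V @ a1)
    return _jn_from_linear_form(
        f"d y / d x at x={x_fixed:g}", c0, c1, v00, v01, v11, alpha, t_crit
    )


def count_area_of_significance(
    jn: JNResult, w_values: pd.Series | np.ndarray, region_mask=None
):
    """Number (and percent) of participants whose moderator value falls in a
    significant interval, optionally restricted to one hormesis region."""
    w = pd.Series(np.asarray(w_values, dtype=float)) if not isinstance(w_values, pd.Series) else w_values
    if region_mask is not None:
        w = w[np.asarray(region_mask, dtype=bool)]
    w = w.dropna()
    n = len(w)
    count = int(jn.significant_mask(w.to_numpy()).sum())
    return count, (100.0 * count / n if n else float("nan"))
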