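"""Hormetic geometry of a fitted cubic: vertices, inflection points, zone
boundaries, and per-participant zone assignment.

A hormetic (biphasic) exposure-outcome curve for a risk outcome dips below
the minimal-exposure reference at low doses and rises above it at high
doses.  For a cubic f(x) = b0 + b1 x + b2 x^2 + b3 x^3 with two real critical
points, the local minimum is the *hormetic zone vertex* (transition from the
strengthening to the buffering region), the local maximum the *toxic vertex*
(rising to falling toxic), and the hormetic and toxic zones are separated by
the *conceptual* inflection -- the exposure at which predicted risk climbs
back to the reference level -- which is distinct from the *statistical*
inflection -b2/(3 b3), the concavity pivot (always the midpoint of the two
critical points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CubicCurve",
    "HormesisProfile",
    "critical_points",
    "statistical_inflection",
    "conceptual_inflection",
    "assign_zones",
    "probe_curve",
]

REGIONS = ("strengthening", "buffering", "rising_toxic", "falling_toxic")
ZONES = ("hormetic", "toxic")


class NoHormeticGeometry(ValueError):
    """The cubic is monotone (no two real critical points)."""


@dataclass(frozen=True)
class CubicCurve:
    """Raw cubic coefficients on the outcome-change scale, versus the
    centered adversity score.  b3 must be nonzero for hormesis probing."""

    b0: float
    b1: float
    b2: float
    b3: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2 + self.b3 * x**3

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        return self.b1 + 2 * self.b2 * x + 3 * self.b3 * x**2


def critical_points(curve: CubicCurve) -> tuple[float, float]:
    """(hormetic_vertex, toxic_vertex): the roots of f'(x) = 0.

    The root where the curvature has the risk-reducing sign -- the local
    minimum of a risk outcome -- is the hormetic vertex; the other critical
    point is the toxic vertex.  Raises NoHormeticGeometry when the derivative
    has no two distinct real roots (monotone curve).
    """
    if curve.b3 == 0:
        raise NoHormeticGeometry("b3 = 0: no cubic geometry (quadratic fallback applies)")
    a, b, c = 3.0 * curve.b3, 2.0 * curve.b2, curve.b1
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        raise NoHormeticGeometry("monotone curve: derivative discriminant <= 0")
    sq = np.sqrt(disc)
    r1, r2 = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    # f'' = 2 b2 + 6 b3 x; local minimum where f'' > 0
    if 2 * curve.b2 + 6 * curve.b3 * r1 > 0:
        return float(r1), float(r2)
    return float(r2), float(r1)


def statistical_inflection(curve: CubicCurve) -> float:
    """Root of f''(x) = 0: -b2/(3 b3), the concavity pivot (equal to the
    midpoint of the two critical points)."""
    if curve.b3 == 0:
        raise NoHormeticGeometry("b3 = 0: inflection undefined")
    return float(-curve.b2 / (3.0 * curve.b3))


def conceptual_inflection(
    curve: CubicCurve,
    x_ref_policy: str = "percentile",
    observed_x: np.ndarray | None = None,
    x_ref: float | None = None,
    percentile: float = 5.0,
) -> tuple[float, bool]:
    """Exposure level at which predicted risk surpasses the minimal-exposure
    reference, separating the hormetic from the toxic zone.

    The reference f(x_ref) is set by policy:
      - "percentile" (default): x_ref is the given percentile (5th) of the
        observed adversity scores, representing none-to-minimal adversity;
      - "fixed": x_ref supplied by the caller;
      - "statistical": skip the reference construction and use the concavity
        pivot directly.

    The crossing is the smallest x > hormetic_vertex with f(x) = f(x_ref),
    found by bracketed root-finding on (hormetic_vertex, toxic_vertex] to
    1e-8.  If the curve never re-crosses the reference in that interval the
    statistical inflection is returned with the fallback flag set.

    Returns (value, fell_back).
    """
    hv, tv = critical_points(curve)
    if x_ref_policy == "statistical":
        return statistical_inflection(curve), False
    if x_ref_policy == "percentile":
        if observed_x is None or len(np.asarray(observed_x)) == 0:
            raise ValueError("percentile policy requires observed adversity scores")
        obs = np.asarray(observed_x, dtype=float)
        obs = obs[np.isfinite(obs)]
        if obs.size == 0:
            raise ValueError("percentile policy requires non-missing adversity scores")
        x_ref = float(np.percentile(obs, percentile))
    elif x_ref_policy == "fixed":
        if x_ref is None:
            raise ValueError("fixed policy requires x_ref")
    else:
        raise ValueError(f"unknown x_ref_policy {x_ref_policy!r}")

    f_ref = float(curve(x_ref))
    if hv >= tv:
        # benefit-coded outcome (local max precedes the crossing); conceptual
        # probing assumes a risk-coded outcome, so fall back and flag
        return statistical_inflection(curve), True
    lo, hi = hv, tv
    g = lambda x: float(curve(x)) - f_ref
    eps = 1e-12 * max(1.0, abs(hi - lo))
    if g(lo + eps) >= 0 or g(hi) < 0:
        return statistical_inflection(curve), True
    root = brentq(g, lo + eps, hi, xtol=1e-10, rtol=1e-12)
    return float(root), False


@dataclass
class HormesisProfile:
    """The probed cubic: breakpoints, per-participant zone labels, tallies."""

    curve: CubicCurve
    hormetic_vertex: float
    toxic_vertex: float
    statistical_inflection: float
    conceptual_inflection: float
    conceptual_fallback: bool
    region_bounds: tuple  # (hormetic_vertex, conceptual_inflection, toxic_vertex)
    z_equivalents: dict
    score_sd: float
    zone_labels: pd.DataFrame | None = None
    tallies: dict = field(default_factory=dict)
    n_used: int = 0
    n_missing: int = 0

    def to_json_dict(self) -> dict:
        return {
            "coefficients": [self.curve.b0, self.curve.b1, self.curve.b2, self.curve.b3],
            "hormetic_vertex": self.hormetic_vertex,
            "toxic_vertex": self.toxic_vertex,
            "statistical_inflection": self.statistical_inflection,
            "conceptual_inflection": self.conceptual_inflection,
            "conceptual_fallback": self.conceptual_fallback,
            "region_bounds": list(self.region_bounds),
            "z_equivalents": self.z_equivalents,
            "tallies": self.tallies,
            "n_used": self.n_used,
            "n_missing": self.n_missing,
        }


def assign_zones(profile: HormesisProfile, scores: pd.Series) -> HormesisProfile:
    """Label each participant by region and zone, and tally.

    Regions (half-open, ties to the lower-risk side):
      strengthening : x <  hormetic_vertex
      buffering     : hormetic_vertex <= x <= conceptual_inflection
      rising_toxic  : conceptual_inflection < x <= toxic_vertex
      falling_toxic : x >  toxic_vertex
    Zones: hormetic (x <= conceptual_inflection), toxic (x > it).
    Missing scores are excluded and counted.
    """
    hv, ci, tv = profile.region_bounds
    s = pd.to_numeric(scores, errors="coerce")
    valid = s.notna()
    x = s[valid].to_numpy(dtype=float)

    region = np.full(x.shape, "", dtype=object)
    region[x < hv] = "strengthening"
    region[(x >= hv) & (x <= ci)] = "buffering"
    region[(x > ci) & (x <= tv)] = "rising_toxic"
    region[x > tv] = "falling_toxic"
    zone = np.where(x <= ci, "hormetic", "toxic")

    labels = pd.DataFrame(index=scores.index, columns=["region", "zone"], dtype=object)
    labels.loc[valid, "region"] = region
    labels.loc[valid, "zone"] = zone

    n = int(valid.sum())
    tallies = {"n_used": n, "n_missing": int((~valid).sum()), "region": {}, "zone": {}}
    for name in REGIONS:
        cnt = int((region == name).sum())
        tallies["region"][name] = {"n": cnt, "percent": 100.0 * cnt / n if n else float("nan")}
    for name in ZONES:
        cnt = int((zone == name).sum())
        tallies["zone"][name] = {"n": cnt, "percent": 100.0 * cnt / n if n else float("nan")}

    profile.zone_labels = labels
    profile.tallies = tallies
    profile.n_used = n
    profile.n_missing = tallies["n_missing"]
    return profile


def probe_curve(
    curve: CubicCurve,
    scores: pd.Series | np.ndarray,
    x_ref_policy: str = "percentile",
    x_ref: float | None = None,
    percentile: float = 5.0,
) -> HormesisProfile:
    """Full hormesis probe: breakpoints, Z-equivalents (breakpoint divided by
    the observed score SD), zone labels and tallies."""
    scores = pd.Series(np.asarray(scores, dtype=float)) if not isinstance(scores, pd.Series) else scores
    hv, tv = critical_points(curve)
    si = statistical_inflection(curve)
    ci, fell_back = conceptual_inflection(
        curve, x_ref_policy=x_ref_policy, observed_x=scores.to_numpy(), x_ref=x_ref,
        percentile=percentile,
    )
    sd = float(pd.to_numeric(scores, errors="coerce").std(ddof=1))
    z_eq = {
        "hormetic_vertex": hv / sd if sd > 0 else float("nan"),
        "conceptual_inflection": ci / sd if sd > 0 else float("nan"),
        "toxic_vertex": tv / sd if sd > 0 else float("nan"),
    }
    profile = HormesisProfile(
        curve=curve,
        hormetic_vertex=hv,
        toxic_vertex=tv,
        statistical_inflection=si,
        conceptual_inflection=ci,
        conceptual_fallback=fell_back,
        region_bounds=(hv, ci, tv),
        z_equivalents=z_eq,
        score_sd=sd,
    )
    return assign_zones(profile, scores)
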