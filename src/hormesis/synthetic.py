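"""Seed-reproducible synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a large longitudinal youth cohort: ordinal adversity
indicator items arising from latent factors (family threat, socioeconomic
deprivation, and a higher-order family-unpredictability construct),
within-network resting-state connectivity measured at two timepoints whose
latent change moderates outcome curves, internalizing/externalizing symptom
scores at three timepoints whose change follows a cubic function of latent
adversity, family clustering, and configurable missingness.  Ground-truth
parameters and realized latent scores are recorded so every downstream stage
can be checked for parameter recovery.

Default loadings and polynomial coefficients are the study conditions the
package is calibrated against; see docs/methods.md for their provenance and
the conventions adopted where the literature reports no value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SimulatedStudy",
    "generate_adversity",
    "generate_connectivity",
    "generate_outcomes",
    "generate_study",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class AlignmentError(ValueError):
    """Input vectors are not row-aligned."""


# Item layout per adversity dimension.  Unpredictability is a higher-order
# construct: three first-order factors (primary caregiver, secondary
# caregiver, family disorder) loading on one second-order factor.
THREAT_ITEMS = [f"threat_i{j}" for j in range(1, 8)]
DEPRIVATION_ITEMS = [f"depriv_i{j}" for j in range(1, 7)]
UNPRED_BLOCKS = {
    "primary": [f"unpred_p{j}" for j in range(1, 4)],
    "secondary": [f"unpred_s{j}" for j in range(1, 4)],
    "disorder": [f"unpred_d{j}" for j in range(1, 5)],
}
UNPRED_ITEMS = [c for cols in UNPRED_BLOCKS.values() for c in cols]

OUTCOMES = ("internalizing", "externalizing")
TIMEPOINTS = ("t5", "t7")

_FIVE_CAT = (-1.5, -0.5, 0.5, 1.5)
_BINARY = (0.0,)


def _default_thresholds() -> dict:
    """Five ordered categories for conflict/disorder/scale items, two for the
    binary marital-status deprivation item."""
    thr = {c: _FIVE_CAT for c in THREAT_ITEMS + UNPRED_ITEMS + DEPRIVATION_ITEMS}
    thr["depriv_i5"] = _BINARY  # marital status (yes/no)
    return thr


def _default_outcome_coefficients() -> dict:
    """Raw polynomial coefficients (b0, b1, b2, b3) of each adversity dimension
    on each outcome-change score, keyed (adversity, outcome, timepoint).

    Threat acts cubically on internalizing change and linearly on
    externalizing; deprivation cubically on externalizing; unpredictability
    only linearly on externalizing.  Unlisted combinations are null.
    """
    return {
        ("threat", "internalizing", "t5"): (0.0, 0.15, 0.13, -0.17),
        ("threat", "externalizing", "t5"): (0.0, 0.14, 0.0, 0.0),
        ("threat", "externalizing", "t7"): (0.0, 0.02, 0.0, 0.0),
        ("deprivation", "externalizing", "t5"): (0.0, 0.22, -0.02, -0.07),
        ("unpredictability", "externalizing", "t5"): (0.0, 0.20, 0.0, 0.0),
        ("unpredictability", "externalizing", "t7"): (0.0, 0.20, 0.0, 0.0),
    }


def _default_moderation_coefficients() -> dict:
    """(g0, g1, g2, g3) multiplying the standardized latent connectivity
    change in each polynomial term; only the cubic threat-internalizing
    relation is moderated by default."""
    return {("threat", "internalizing", "t5"): (0.0, 0.0, 0.0, 0.10)}


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Loadings are standardized values in (0, 1); thresholds are strictly
    increasing per-item cut points discretizing a unit-variance continuous
    response into ordered categories 1..k+1.  `family_icc` splits the outcome
    noise variance `noise_sd**2` into a family random-intercept share and a
    residual share.  `dmn_change_reliability` in (0, 1] controls how much
    measurement noise separates the observed two-timepoint connectivity
    difference from the latent change.
    """

    n_participants: int = 11878
    n_families: int = 10000
    seed: int = 0
    threat_loadings: Sequence[float] = (0.81, 0.46, 0.74, 0.59, 0.63, 0.74, 0.50)
    deprivation_loadings: Sequence[float] = (0.42, 0.76, 0.83, 0.57, 0.54, 0.18)
    unpredictability_first_order: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "primary": (0.38, 0.61, 0.54),
            "secondary": (0.46, 0.66, 0.59),
            "disorder": (0.83, 0.82, 0.48, 0.62),
        }
    )
    unpredictability_higher_order: Sequence[float] = (0.89, 0.56, 0.58)
    item_thresholds: Mapping[str, Sequence[float]] = field(default_factory=_default_thresholds)
    outcome_coefficients: Mapping[tuple, Sequence[float]] = field(
        default_factory=_default_outcome_coefficients
    )
    moderation_coefficients: Mapping[tuple, Sequence[float]] = field(
        default_factory=_default_moderation_coefficients
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.58, "age": 0.01, "income": 0.01}
    )
    dmn_t1_mean: float = 0.30
    dmn_t1_sd: float = 0.10
    dmn_change_mean: float = 0.25
    dmn_change_sd: float = 0.0548  # sqrt(.003)
    dmn_change_reliability: float = 0.9
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"internalizing": 1.0, "externalizing": 1.0}
    )
    baseline_sd: float = 1.0
    family_icc: float = 0.10
    missing_rate: float = 0.0
    item_scale: str = "ordinal"  # "ordinal" or "continuous" indicator columns

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if not (1 <= self.n_families <= self.n_participants):
            raise ConfigurationError("need 1 <= n_families <= n_participants")
        for name, lam in self.loading_map().items():
            lam = np.asarray(lam, dtype=float)
            if np.any(~np.isfinite(lam)) or np.any(np.abs(lam) >= 1):
                raise ConfigurationError(f"loadings for {name} must have magnitude < 1")
        for item, thr in self.item_thresholds.items():
            t = np.asarray(thr, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ConfigurationError(f"thresholds for item {item!r} are not strictly increasing")
        if not (0.0 < self.dmn_change_reliability <= 1.0):
            raise ConfigurationError("dmn_change_reliability must be in (0, 1]")
        if not (0.0 <= self.family_icc < 1.0):
            raise ConfigurationError("family_icc must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.item_scale not in ("ordinal", "continuous"):
            raise ConfigurationError("item_scale must be 'ordinal' or 'continuous'")

    def loading_map(self) -> dict:
        return {
            "threat": list(self.threat_loadings),
            "deprivation": list(self.deprivation_loadings),
            **{f"unpred_{k}": list(v) for k, v in self.unpredictability_first_order.items()},
            "unpred_higher": list(self.unpredictability_higher_order),
        }

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_coefficients"] = {
            "|".join(k): list(v) for k, v in self.outcome_coefficients.items()
        }
        d["moderation_coefficients"] = {
            "|".join(k): list(v) for k, v in self.moderation_coefficients.items()
        }
        d["unpredictability_first_order"] = {
            k: list(v) for k, v in self.unpredictability_first_order.items()
        }
        d["item_thresholds"] = {k: list(v) for k, v in self.item_thresholds.items()}
        return d


@dataclass
class SimulatedStudy:
    """A generated cohort: the participant table plus the ground-truth record
    (config and realized latent scores) used by recovery tests."""

    table: pd.DataFrame
    truth: dict

    def write(self, table_path, truth_path) -> None:
        self.table.to_csv(table_path, index=False)
        truth = dict(self.truth)
        truth["config"] = truth["config"].to_json_dict()
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()
        }
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


def _discretize(cont: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Ordered categories 1..k+1 from cut points on the continuous response."""
    return np.searchsorted(np.asarray(thresholds, dtype=float), cont) + 1


def generate_adversity(config: GeneratorConfig, rng: np.random.Generator):
    """Draw latent adversity scores and their indicator items.

    Each item j is a threshold-discretized continuous response
    lambda_j * eta + eps_j with eps variance 1 - lambda_j^2, so the continuous
    responses have unit variance and inter-item correlation lambda_i*lambda_j.
    The unpredictability items are built hierarchically: first-order factors
    f_k = gamma_k * xi + zeta_k load items, and the second-order factor xi is
    the recorded latent score.

    Returns
    -------
    latents : dict of per-participant latent scores
        keys 'threat', 'deprivation', 'unpredictability' (the second-order
        factor) plus the three first-order unpredictability factors.
    continuous : DataFrame of continuous item responses
    ordinal : DataFrame of threshold-discretized item responses
    """
    config.validate()
    n = config.n_participants
    latents: dict[str, np.ndarray] = {}
    cont = {}

    def simple_factor(name, items, loadings):
        eta = rng.standard_normal(n)
        latents[name] = eta
        for item, lam in zip(items, loadings):
            eps = rng.standard_normal(n) * np.sqrt(1.0 - lam**2)
            cont[item] = lam * eta + eps
        return eta

    simple_factor("threat", THREAT_ITEMS, config.threat_loadings)
    simple_factor("deprivation", DEPRIVATION_ITEMS, config.deprivation_loadings)

    xi = rng.standard_normal(n)
    latents["unpredictability"] = xi
    for (block, items), gamma in zip(UNPRED_BLOCKS.items(), config.unpredictability_higher_order):
        f_k = gamma * xi + rng.standard_normal(n) * np.sqrt(1.0 - gamma**2)
        latents[f"unpred_{block}"] = f_k
        for item, lam in zip(items, config.unpredictability_first_order[block]):
            eps = rng.standard_normal(n) * np.sqrt(1.0 - lam**2)
            cont[item] = lam * f_k + eps

    continuous = pd.DataFrame(cont)
    ordinal = pd.DataFrame(
        {item: _discretize(vals.to_numpy(), config.item_thresholds[item])
         for item, vals in continuous.items()}
    )
    return latents, continuous, ordinal


def generate_connectivity(
    config: GeneratorConfig, rng: np.random.Generator, latent_change: np.ndarray
):
    """Two-timepoint connectivity columns from a latent change vector.

    The observed difference dmn_t5 - dmn_t1 equals the latent change plus
    measurement noise whose variance is var(latent)*(1-r)/r for reliability r,
    so r is the share of observed-change variance attributable to true change.
    """
    config.validate()
    w = np.asarray(latent_change, dtype=float)
    if w.shape[0] != config.n_participants:
        raise AlignmentError("latent_change length must equal n_participants")
    r = config.dmn_change_reliability
    t1 = config.dmn_t1_mean + config.dmn_t1_sd * rng.standard_normal(w.shape[0])
    if r >= 1.0:
        observed_change = w.copy()
    else:
        noise_sd = config.dmn_change_sd * np.sqrt((1.0 - r) / r)
        observed_change = w + noise_sd * rng.standard_normal(w.shape[0])
    return t1, t1 + observed_change


def generate_outcomes(
    config: GeneratorConfig,
    rng: np.random.Generator,
    latent_adversity: Mapping[str, np.ndarray],
    latent_change: np.ndarray,
    covariates: pd.DataFrame,
    family_effects: Mapping[tuple, np.ndarray],
):
    """Symptom scores at T2/T5/T7 whose change from baseline follows the
    configured polynomial-in-adversity model.

    change(T_k - T2) = sum_dims sum_p (b_p + g_p * w_std) * x^p
                       + covariate effects + family effect + noise,

    where w_std is the latent connectivity change standardized by its
    configured mean/SD (moderation coefficients live on the SD-of-moderator
    scale), the family effect carries variance family_icc*noise_sd^2, and the
    residual the remainder.  The T2 baseline is drawn independently of
    adversity.
    """
    n = config.n_participants
    for name, x in latent_adversity.items():
        if np.asarray(x).shape[0] != n:
            raise AlignmentError(f"latent adversity {name!r} is misaligned")
    w = np.asarray(latent_change, dtype=float)
    if w.shape[0] != n or len(covariates) != n:
        raise AlignmentError("latent_change and covariates must have n_participants rows")
    w_std = (w - config.dmn_change_mean) / config.dmn_change_sd

    cov_term = np.zeros(n)
    for cname, beta in config.covariate_effects.items():
        col = covariates[cname].to_numpy(dtype=float)
        cov_term = cov_term + beta * (col - col.mean())

    out: dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        sd = float(config.noise_sd[outcome])
        resid_sd = sd * np.sqrt(1.0 - config.family_icc)
        t2 = config.baseline_sd * rng.standard_normal(n)
        out[f"{outcome}_t2"] = t2
        for tp in TIMEPOINTS:
            signal = np.zeros(n)
            for dim, x in latent_adversity.items():
                b = np.asarray(
                    config.outcome_coefficients.get((dim, outcome, tp), (0.0, 0.0, 0.0, 0.0)),
                    dtype=float,
                )
                g = np.asarray(
                    config.moderation_coefficients.get((dim, outcome, tp), (0.0, 0.0, 0.0, 0.0)),
                    dtype=float,
                )
                x = np.asarray(x, dtype=float)
                for p in range(4):
                    signal = signal + (b[p] + g[p] * w_std) * x**p
            fam = family_effects.get((outcome, tp), np.zeros(n))
            change = signal + cov_term + fam + resid_sd * rng.standard_normal(n)
            out[f"{outcome}_{tp}"] = t2 + change
    return pd.DataFrame(out)


def _assign_families(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Every family gets at least one member; the overflow joins random
    families, yielding mostly singletons with some sibling pairs/triples."""
    n, f = config.n_participants, config.n_families
    fam = np.concatenate([np.arange(f), rng.integers(0, f, size=n - f)])
    rng.shuffle(fam)
    return fam


def generate_study(config: GeneratorConfig) -> SimulatedStudy:
    """Compose the generators into one participant table with truth record.

    Missingness is applied completely at random at `missing_rate` to every
    data column (never to identifiers or cluster labels).  Identical
    (seed, config) pairs produce bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    family = _assign_families(config, rng)
    scanner = rng.choice([1, 2, 3], size=n, p=[0.6, 0.25, 0.15])
    sex = (rng.random(n) < 0.478).astype(int) + 1  # 1 = female (47.8%), 2 = male
    age = 10.1 + 0.6 * rng.standard_normal(n)
    income = np.clip(np.rint(5.5 + 2.0 * rng.standard_normal(n)), 1, 10).astype(int)
    education = np.clip(np.rint(3.0 + 1.0 * rng.standard_normal(n)), 1, 5).astype(int)
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "income": income, "education": education}
    )

    latents, continuous, ordinal = generate_adversity(config, rng)
    items = ordinal if config.item_scale == "ordinal" else continuous

    latent_change = config.dmn_change_mean + config.dmn_change_sd * rng.standard_normal(n)
    dmn_t1, dmn_t5 = generate_connectivity(config, rng, latent_change)

    fam_sd = {o: float(config.noise_sd[o]) * np.sqrt(config.family_icc) for o in OUTCOMES}
    family_effects = {}
    for outcome in OUTCOMES:
        for tp in TIMEPOINTS:
            per_family = fam_sd[outcome] * rng.standard_normal(config.n_families)
            family_effects[(outcome, tp)] = per_family[family]

    adversity = {k: latents[k] for k in ("threat", "deprivation", "unpredictability")}
    outcomes = generate_outcomes(config, rng, adversity, latent_change, covariates, family_effects)

    table = pd.concat(
        [
            pd.DataFrame(
                {"pid": np.arange(1, n + 1), "family_id": family, "scanner": scanner}
            ),
            covariates,
            items,
            pd.DataFrame({"dmn_t1": dmn_t1, "dmn_t5": dmn_t5}),
            outcomes,
        ],
        axis=1,
    )

    if config.missing_rate > 0:
        protected = {"pid", "family_id", "scanner"}
        data_cols = [c for c in table.columns if c not in protected]
        mask = rng.random((n, len(data_cols))) < config.missing_rate
        block = table[data_cols].astype(float).to_numpy()
        block[mask] = np.nan
        table[data_cols] = block

    truth = {
        "config": config,
        "threat": latents["threat"],
        "deprivation": latents["deprivation"],
        "unpredictability": latents["unpredictability"],
        "dmn_latent_change": latent_change,
    }
    return SimulatedStudy(table=table, truth=truth)
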