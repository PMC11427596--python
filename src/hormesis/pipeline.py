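"""Pipeline orchestration: measurement -> polynomial fits + LRT ladder ->
hormesis probing -> moderation, with conditional stage gating.

Probing runs only where the cubic term is retained by the likelihood-ratio
ladder (and the cubic coefficient itself is significant); moderation probing
runs only where a hormetic profile exists.  Every run writes a manifest with
versions, seed, config hash, per-stage row counts and statuses, so a run is
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curve import CubicCurve, NoHormeticGeometry, probe_curve
from .io import read_table
from .measurement import FactorModelSpec, fit_cfa, latent_change
from .moderation import (
    FdrSession,
    ModerationSpec,
    count_area_of_significance,
    fit_cubic_moderation,
    johnson_neyman_linear,
    johnson_neyman_quadratic,
    multigroup_by_zone,
    wald_compare,
)
from .polynomial import PolyModelSpec, compare_nested, fit_poly, standardize
from .synthetic import (
    DEPRIVATION_ITEMS,
    THREAT_ITEMS,
    UNPRED_BLOCKS,
    UNPRED_ITEMS,
    GeneratorConfig,
    generate_study,
)

log = logging.getLogger("hormesis")


def default_measurement_specs() -> dict:
    """The three adversity measurement models over the generator's columns."""
    return {
        "threat": FactorModelSpec("threat", THREAT_ITEMS),
        "deprivation": FactorModelSpec("deprivation", DEPRIVATION_ITEMS),
        "unpredictability": FactorModelSpec(
            "unpredictability",
            UNPRED_ITEMS,
            structure="higher_order",
            partition=UNPRED_BLOCKS,
        ),
    }


def default_model_grid() -> list:
    return [
        (dim, outcome, tp)
        for dim in ("threat", "deprivation", "unpredictability")
        for outcome in ("internalizing", "externalizing")
        for tp in ("t5", "t7")
    ]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``input_path`` (a participant CSV) or ``generator`` (a synthetic
    cohort configuration) supplies the table.  The model grid crosses
    adversity dimension x outcome x timepoint.
    """

    output_dir: str = "hormesis_out"
    seed: int = 0
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    measurement: Mapping[str, FactorModelSpec] = field(default_factory=default_measurement_specs)
    model_grid: Sequence[tuple] = field(default_factory=default_model_grid)
    covariates: Sequence[str] = ("sex", "age", "income")
    cluster: str = "family_id"
    alpha: float = 0.05
    fdr_rate: float = 0.05
    x_ref_policy: str = "percentile"
    x_ref_percentile: float = 5.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in (
            "output_dir", "seed", "input_path", "alpha", "fdr_rate",
            "x_ref_policy", "x_ref_percentile", "log_level", "covariates", "cluster",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "generator" in raw and raw["generator"] is not None:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "measurement" in raw:
            specs = {}
            for name, m in raw["measurement"].items():
                specs[name] = FactorModelSpec(
                    name=name,
                    indicator_columns=m["columns"],
                    structure=m.get("structure", "single_factor"),
                    partition=m.get("partition"),
                    reverse_scored=m.get("reverse_scored", ()),
                )
            kwargs["measurement"] = specs
        if "models" in raw:
            kwargs["model_grid"] = [
                (m["adversity"], m["outcome"], m["timepoint"]) for m in raw["models"]
            ]
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (where results are written and
        how verbosely is not part of the analysis identity)."""
        payload = _jsonable(self)
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return str(obj)


def _validate_columns(table: pd.DataFrame, config: PipelineConfig) -> None:
    """Fail before any computation if a configured column is absent."""
    needed = set()
    for spec in config.measurement.values():
        needed.update(spec.indicator_columns)
    needed.update(config.covariates)
    needed.add(config.cluster)
    for _, outcome, tp in config.model_grid:
        needed.add(f"{outcome}_t2")
        needed.add(f"{outcome}_{tp}")
    needed.update(["dmn_t1", "dmn_t5"])
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(f"configured columns missing from table: {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts; returns the run manifest.

    Stage errors are recorded in the manifest; stages depending on a failed
    stage are skipped while independent branches proceed.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # ---- load / generate -------------------------------------------------
    if config.input_path:
        table = read_table(config.input_path)
        manifest["stages"]["load"] = {"status": "ok", "rows": len(table), "source": config.input_path}
    else:
        gen = config.generator or GeneratorConfig()
        if gen.seed != config.seed:
            gen = _reseed(gen, config.seed)
        study = generate_study(gen)
        table = study.table
        study.write(outdir / "table.csv", outdir / "truth.json")
        manifest["stages"]["load"] = {"status": "ok", "rows": len(table), "source": "generator"}
    _validate_columns(table, config)

    # ---- measurement -----------------------------------------------------
    fits = {}
    meas_rows = []
    try:
        for name, spec in config.measurement.items():
            fit = fit_cfa(table, spec)
            fits[name] = fit
            table[f"{name}_score"] = fit.factor_scores
            for item, lam in fit.loadings.items():
                meas_rows.append(
                    {"factor": name, "indicator": item, "loading": lam,
                     "uniqueness": fit.uniquenesses[item]}
                )
            if fit.higher_order_loadings is not None:
                for fo, g in fit.higher_order_loadings.items():
                    meas_rows.append(
                        {"factor": name, "indicator": f"[{fo}]", "loading": g,
                         "uniqueness": np.nan}
                    )
            meas_rows.append(
                {"factor": name, "indicator": "<fit>", "loading": np.nan, "uniqueness": np.nan,
                 "chi_square": fit.chi_square, "df": fit.df, "rmsea": fit.rmsea,
                 "cfi": fit.cfi, "tli": fit.tli, "srmr": fit.srmr, "n": fit.n_used}
            )
        dmn = latent_change(table, "dmn_t1", "dmn_t5")
        table["dmn_change"] = dmn.change - dmn.mean_change  # mean-centered moderator
        for _, outcome, tp in config.model_grid:
            col = f"{outcome}_{tp}_change"
            if col not in table:
                table[col] = latent_change(table, f"{outcome}_t2", f"{outcome}_{tp}").change
        pd.DataFrame(meas_rows).to_csv(outdir / "measurement.csv", index=False)
        manifest["stages"]["measurement"] = {
            "status": "ok",
            "factors": {n: {"n_used": f.n_used, "rmsea": f.rmsea, "cfi": f.cfi,
                            "srmr": f.srmr} for n, f in fits.items()},
            "dmn_mean_change": dmn.mean_change,
        }
    except Exception as err:  # noqa: BLE001 - recorded, downstream skipped
        log.exception("measurement stage failed")
        manifest["stages"]["measurement"] = {"status": "error", "error": str(err)}
        _finish(manifest, outdir, t0)
        return manifest

    # ---- polynomial fits + LRT ladder ------------------------------------
    model_rows = []
    cubic_fits = {}  # key -> (PolyFit degree 3, cubic retained?)
    try:
        for dim, outcome, tp in config.model_grid:
            key = (dim, outcome, tp)
            base = dict(
                outcome=f"{outcome}_{tp}_change",
                predictor=f"{dim}_score",
                covariates=tuple(config.covariates),
                cluster=config.cluster,
            )
            fit1 = fit_poly(table, PolyModelSpec(degree=1, **base))
            fit2 = fit_poly(table, PolyModelSpec(degree=2, **base))
            fit3 = fit_poly(table, PolyModelSpec(degree=3, **base))
            cmp21 = compare_nested(fit1, fit2)
            retained = fit2 if cmp21.p_value < config.alpha else fit1
            cmp3 = compare_nested(retained, fit3)
            cubic_term = f"{dim}_score^3"
            cubic_p = float(fit3.pvalues()[cubic_term])
            keep_cubic = cmp3.p_value < config.alpha and cubic_p < config.alpha
            cubic_fits[key] = (fit3, keep_cubic)

            for degree, fit in ((1, fit1), (2, fit2), (3, fit3)):
                std = standardize(fit)
                pv = fit.pvalues()
                ci = fit.conf_int()
                for term in fit.terms:
                    model_rows.append(
                        {"adversity": dim, "outcome": outcome, "timepoint": tp,
                         "model": degree, "term": term, "b": fit.coef[term],
                         "beta": std.loc[term, "beta"], "se": fit.se[term],
                         "ci_lower": ci.loc[term, "lower"], "ci_upper": ci.loc[term, "upper"],
                         "p": pv[term], "n": fit.n_used, "r_squared": fit.r_squared}
                    )
            model_rows.append(
                {"adversity": dim, "outcome": outcome, "timepoint": tp, "model": 2,
                 "term": "<LRT vs 1>", "b": cmp21.delta_chi_square, "p": cmp21.p_value,
                 "se": cmp21.delta_df}
            )
            model_rows.append(
                {"adversity": dim, "outcome": outcome, "timepoint": tp, "model": 3,
                 "term": f"<LRT vs {retained.spec.degree}>", "b": cmp3.delta_chi_square,
                 "p": cmp3.p_value, "se": cmp3.delta_df}
            )
        pd.DataFrame(model_rows).to_csv(outdir / "models.csv", index=False)
        manifest["stages"]["polynomial"] = {
            "status": "ok",
            "cubic_retained": {"|".join(k): kept for k, (_, kept) in cubic_fits.items()},
        }
    except Exception as err:  # noqa: BLE001
        log.exception("polynomial stage failed")
        manifest["stages"]["polynomial"] = {"status": "error", "error": str(err)}
        _finish(manifest, outdir, t0)
        return manifest

    # ---- hormesis probing (only retained cubics) --------------------------
    profiles = {}
    probe_info = {}
    for key, (fit3, kept) in cubic_fits.items():
        dim, outcome, tp = key
        if not kept:
            continue
        b0, b1, b2, b3 = fit3.poly_coefficients()
        scores = table[f"{dim}_score"]
        try:
            profile = probe_curve(
                CubicCurve(b0, b1, b2, b3), scores,
                x_ref_policy=config.x_ref_policy, percentile=config.x_ref_percentile,
            )
        except NoHormeticGeometry as err:
            probe_info["|".join(key)] = {"status": "no_hormetic_geometry", "detail": str(err)}
            continue
        profiles[key] = profile
        with open(outdir / f"profile_{dim}_{outcome}_{tp}.json", "w") as fh:
            json.dump(profile.to_json_dict(), fh, indent=1)
        table[f"{dim}_region"] = profile.zone_labels["region"]
        table[f"{dim}_zone"] = profile.zone_labels["zone"]
        probe_info["|".join(key)] = {
            "status": "ok",
            "hormetic_vertex": profile.hormetic_vertex,
            "conceptual_inflection": profile.conceptual_inflection,
            "toxic_vertex": profile.toxic_vertex,
            "tallies": profile.tallies,
        }
    manifest["stages"]["probe"] = {"status": "ok", "profiles": probe_info}

    # ---- moderation (only where a hormetic profile exists) ----------------
    mod_results = {}
    session = FdrSession(rate=config.fdr_rate)
    mod_fits = {}
    for key, profile in profiles.items():
        dim, outcome, tp = key
        spec = ModerationSpec(
            outcome=f"{outcome}_{tp}_change",
            predictor=f"{dim}_score",
            moderator="dmn_change",
            covariates=tuple(config.covariates),
            cluster=config.cluster,
            alpha=config.alpha,
            fdr_rate=config.fdr_rate,
        )
        try:
            mod_fits[key] = (fit_cubic_moderation(table, spec, session=session), spec, profile)
        except Exception as err:  # noqa: BLE001
            log.exception("moderation fit failed for %s", key)
            mod_results["|".join(key)] = {"status": "error", "error": str(err)}
    session.finalize()

    for key, (mfit, spec, profile) in mod_fits.items():
        dim, outcome, tp = key
        entry = {
            "status": "ok",
            "coefficients": mfit.coef.to_dict(),
            "p_raw": mfit.p_raw.to_dict(),
            "p_adjusted": mfit.p_adjusted.to_dict(),
            "n_used": mfit.n_used,
        }
        if mfit.p_adjusted["x^3:w"] < config.fdr_rate:
            labels = table[[f"{dim}_region", f"{dim}_zone"]].rename(
                columns={f"{dim}_region": "region", f"{dim}_zone": "zone"}
            )
            mg = multigroup_by_zone(table, spec, labels)
            wald = {}
            if "strengthening" in mg.region_fits:
                for other in ("buffering", "rising_toxic", "falling_toxic"):
                    if other in mg.region_fits:
                        W, df_w, p = wald_compare(mg, "strengthening", other, "x:w")
                        wald[f"strengthening_vs_{other}|x:w"] = {"W": W, "df": df_w, "p": p}
            if "hormetic" in mg.zone_fits and "toxic" in mg.zone_fits:
                W, df_w, p = wald_compare(mg, "hormetic", "toxic", "x^2:w")
                wald["hormetic_vs_toxic|x^2:w"] = {"W": W, "df": df_w, "p": p}
            jn_info = {}
            aos_total = 0
            if "strengthening" in mg.region_fits:
                jn = johnson_neyman_linear(mg.region_fits["strengthening"], alpha=config.alpha)
                mask = (labels["region"] == "strengthening").to_numpy()
                w_scaled = _scaled_w(table, spec)
                cnt, pct = count_area_of_significance(jn, w_scaled, mask)
                aos_total += cnt
                jn_info["strengthening"] = {
                    "boundaries": jn.boundaries, "n_affected": cnt, "percent": pct,
                }
            if "toxic" in mg.zone_fits:
                jn = johnson_neyman_quadratic(mg.zone_fits["toxic"], x_fixed=0.0, alpha=config.alpha)
                mask = (labels["zone"] == "toxic").to_numpy()
                w_scaled = _scaled_w(table, spec)
                cnt, pct = count_area_of_significance(jn, w_scaled, mask)
                aos_total += cnt
                jn_info["toxic"] = {
                    "boundaries": jn.boundaries, "n_affected": cnt, "percent": pct,
                }
            entry["multigroup"] = {
                "groups": {g: {"n": gf.n_used, "coef": gf.coef.to_dict(),
                               "p": gf.pvalues().to_dict()}
                           for g, gf in {**mg.region_fits, **mg.zone_fits}.items()},
                "skipped": mg.skipped,
                "wald": wald,
            }
            entry["johnson_neyman"] = jn_info
            entry["n_affected_total"] = aos_total
        mod_results["|".join(key)] = entry

    with open(outdir / "moderation.json", "w") as fh:
        json.dump(mod_results, fh, indent=1, default=float)
    manifest["stages"]["moderation"] = {"status": "ok", "models": sorted(mod_results)}

    table.to_csv(outdir / "analysis_table.csv", index=False)
    _finish(manifest, outdir, t0)
    return manifest


def _scaled_w(table: pd.DataFrame, spec: ModerationSpec) -> pd.Series:
    w = table[spec.moderator].astype(float)
    if spec.scale_moderator:
        w = w / w.std(ddof=1)
    return w


def _reseed(gen: GeneratorConfig, seed: int) -> GeneratorConfig:
    import dataclasses as _dc

    return _dc.replace(gen, seed=seed)


def _finish(manifest: dict, outdir: Path, t0: float) -> None:
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
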