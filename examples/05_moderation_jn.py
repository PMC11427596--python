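"""Probe moderation of the hormetic curve by brain-connectivity change.

Fits the full cubic-by-moderator regression, then parcels the cohort by
hormesis region/zone, compares interaction paths between groups with Wald
tests, and finds the Johnson-Neyman area of significance: the moderator
range over which adversity's conditional effect is significant."""

import numpy as np
import pandas as pd

from hormesis import (
    CubicCurve,
    ModerationSpec,
    count_area_of_significance,
    fit_cubic_moderation,
    johnson_neyman_linear,
    multigroup_by_zone,
    probe_curve,
    wald_compare,
)

rng = np.random.default_rng(5)
n = 8000
x = rng.standard_normal(n); x -= x.mean()
w = rng.standard_normal(n); w -= w.mean()
y = 0.15 * x + 0.13 * x**2 + (-0.17 + 0.10 * w) * x**3 + rng.standard_normal(n)
table = pd.DataFrame({"x": x, "w": w, "y": y, "family_id": np.arange(n)})
spec = ModerationSpec(outcome="y", predictor="x", moderator="w",
                      covariates=(), scale_moderator=False)

fit = fit_cubic_moderation(table, spec)
print(f"cubic x moderator coefficient: {fit.coef['x^3:w']:+.3f} "
      f"(generating +0.100), FDR-adjusted p = {fit.p_adjusted['x^3:w']:.2g}")

profile = probe_curve(CubicCurve(0, 0.15, 0.13, -0.17), table["x"],
                      x_ref_policy="fixed", x_ref=-1.2)
labels = profile.zone_labels
mg = multigroup_by_zone(table, spec, labels)
print("within-group interaction p-values:")
for name, gf in {**mg.region_fits, **mg.zone_fits}.items():
    term = "x:w" if gf.kind == "linear" else "x^2:w"
    print(f"  {name:>13} ({gf.kind}): n = {gf.n_used:5d}, p({term}) = {gf.pvalues()[term]:.3f}")

W, df, p = wald_compare(mg, "strengthening", "buffering", "x:w")
print(f"strengthening vs buffering interaction equality: W({df}) = {W:.2f}, p = {p:.3f}")

jn = johnson_neyman_linear(mg.region_fits["strengthening"])
print(f"Johnson-Neyman boundaries (strengthening region): "
      f"{[round(b, 3) for b in jn.boundaries]}")
mask = (labels["region"] == "strengthening").to_numpy()
count, pct = count_area_of_significance(jn, table["w"], mask)
print(f"area of significance: {count} youths ({pct:.0f}% of the region)")
print("  -> children whose connectivity change places them where the "
      "adversity effect is reliably nonzero")
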