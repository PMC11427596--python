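# hormesis

Modelling the *hormetic* (biphasic) relation between psychosocial adversity
and youth psychopathology: at low-to-moderate doses an environmental
stressor can reduce later symptom risk (strengthening), while higher doses
raise it (toxicity).  The package is written for developmental and
psychiatric epidemiologists who want to test this pattern in cohort data
with latent exposure measurement, family clustering, and a brain-development
moderator — and to verify every analysis step against synthetic data with
known ground truth.

## The model

Adversity dimensions (family threat, socioeconomic deprivation, family
unpredictability) are measured as latent factors from ordinal indicator
items by confirmatory factor analysis; mean-centered factor scores `x` enter
a hierarchical polynomial model of symptom change (later timepoint minus
baseline):

    Δy = b0 + b1·x + b2·x² + b3·x³ + γ'·covariates + ε,

with sandwich standard errors clustered on family and a likelihood-ratio
ladder (linear → quadratic → cubic) deciding whether curvature is retained.
A retained cubic with two real critical points is converted into hormesis
geometry:

- **hormetic zone vertex** — the local minimum of predicted risk, root of
  `b1 + 2b2·x + 3b3·x² = 0`; separates the *strengthening* from the
  *buffering* region;
- **statistical inflection** `-b2/(3b3)` — the concavity pivot (always the
  midpoint of the two critical points);
- **conceptual inflection** — where predicted risk climbs back to the
  minimal-adversity reference, separating the hormetic from the toxic zone;
- **toxic vertex** — the local maximum, splitting rising from falling
  toxicity.

Moderation of the curve by latent change in default-mode-network
resting-state connectivity (`w`, later minus earlier) is tested with the
full product model `{1, x, x², x³, w, xw, x²w, x³w}`, Benjamini–Hochberg
correction of the interaction p-values, multi-group region/zone models with
Wald equality tests, and Johnson–Neyman areas of significance — the
moderator range where the conditional adversity effect
`θ(w) = b_x + b_xw·w` satisfies `θ(w)² > t²_crit·Var θ(w)`.

## Worked example

```bash
python examples/04_probe_hormesis.py
```

```
hormetic vertex (strengthening -> buffering): -0.344
toxic vertex (rising -> falling toxic):      +0.854
statistical inflection (concavity pivot):     +0.255
  -> centered adversity units; the concavity pivot is the vertex midpoint
conceptual inflection (risk re-crosses the low-adversity reference): +0.333
  strengthening: n =  2836 (28%)
      buffering: n =  4165 (42%)
   rising_toxic: n =  2128 (21%)
  falling_toxic: n =   871 (9%)
  -> most of this cohort sits in the hormetic zone (strengthening+buffering)
wrote hormesis_zones.png
```

The cubic with raw coefficients `(b1, b2, b3) = (.15, .13, -.17)` has its
risk minimum 0.34 centered units below the mean and its local maximum 0.85
units above it; between them, predicted risk re-crosses the low-adversity
reference at +0.33, so about 70% of this simulated cohort falls in the
hormetic zone where limited adversity predicts the same or lower risk than
minimal adversity.  The other examples walk through cohort generation
(`01`), latent measurement (`02`), the polynomial ladder (`03`), moderation
with Johnson–Neyman probing (`05`), and the fully orchestrated pipeline
(`06`), each printing the numbers it computes and what they mean.

A thin CLI wraps the same stages:

```bash
hormesis fixtures --n 5000 --seed 1 --out cohort     # synthetic study CSV + truth
hormesis run --config pipeline.yaml                  # all stages from YAML
```

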