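import numpy as np
import pandas as pd
import pytest

from hormesis.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def study_continuous():
    """Mid-size cohort with continuous item responses, for measurement tests."""
    cfg = GeneratorConfig(
        n_participants=10000, n_families=8500, seed=42, item_scale="continuous"
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def study_default():
    """Mid-size cohort under the default (ordinal-item) conditions."""
    cfg = GeneratorConfig(n_participants=6000, n_families=5100, seed=7)
    return generate_study(cfg)


def make_regression_table(
    n=2000, seed=0, b=(0.0, 0.1, 0.0, 0.0), g=(0.0, 0.0, 0.0, 0.0),
    noise_sd=1.0, n_families=None, family_sd=0.0,
):
    """Minimal analysis table: centered x and w, outcome from a known
    polynomial-by-moderator model, singleton or paired families."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    w = rng.standard_normal(n)
    x -= x.mean()
    w -= w.mean()
    if n_families is None:
        fam = np.arange(n)
    else:
        fam = np.repeat(np.arange(n_families), int(np.ceil(n / n_families)))[:n]
    fam_effect = np.zeros(n)
    if family_sd > 0:
        per = family_sd * rng.standard_normal(fam.max() + 1)
        fam_effect = per[fam]
    y = sum((b[p] + g[p] * w) * x**p for p in range(4))
    y = y + fam_effect + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "w": w, "y": y, "family_id": fam})
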