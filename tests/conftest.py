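import numpy as np
import pandas as pd
import pytest

import taustage as ts


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject cohort with default (study-condition) parameters."""
    return ts.generate_cohort(ts.SynthConfig(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def harmonized(small_cohort):
    parts = ts.harmonize_amyloid(small_cohort.participants)
    parts, _ = ts.apply_inclusion(parts)
    return parts


@pytest.fixture(scope="session")
def truth_rates(small_cohort, harmonized):
    """Temporal meta-ROI rate table built from the generator's ground truth
    (bypasses the mixed model where the test target is downstream)."""
    r = small_cohort.truth[["id", "true_rate"]].rename(
        columns={"true_rate": "roc"})
    r["variable"] = "temporal_meta"
    return r[r["id"].isin(harmonized["id"])]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_stratum(n=300, slope=1e-3, intercept=0.0, noise=0.01, seed=0,
                 cl_low=0.0, cl_high=100.0):
    """Single-stratum rate data with a known linear Centiloid effect."""
    rng = np.random.default_rng(seed)
    cl = rng.uniform(cl_low, cl_high, n)
    return pd.DataFrame({
        "roc": intercept + slope * cl + rng.normal(0.0, noise, n),
        "centiloid": cl,
        "apoe4": np.where(rng.random(n) < 0.5, "carrier", "noncarrier"),
        "cohort": np.where(rng.random(n) < 0.5, "ADNI", "A05"),
    })
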