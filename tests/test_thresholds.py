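import numpy as np
import pandas as pd
import pytest

import taustage as ts
from taustage.thresholds import PredictionBand
from conftest import make_stratum


def test_severity_cutoff_arithmetic():
    rng = np.random.default_rng(0)
    ref = rng.normal(0, 1, 5000)
    cuts = ts.severity_cutoffs(ref, {"mild": 2.0})
    assert cuts.cutoff_values["mild"] == pytest.approx(
        ref.mean() + 2 * ref.std(ddof=1))
    cuts = ts.severity_cutoffs([0.005] * 10 + [0.015] * 10, {"severe": 3.0})
    # mean 0.01, sample SD of the two-point half/half mix
    sd = np.std([0.005] * 10 + [0.015] * 10, ddof=1)
    assert cuts.cutoff_values["severe"] == pytest.approx(0.01 + 3 * sd)


def test_severity_cutoffs_strictly_increasing_in_z(rng):
    cuts = ts.severity_cutoffs(rng.normal(0.005, 0.01, 100))
    v = [cuts.cutoff_values[s] for s in ("mild", "moderate", "severe")]
    assert v[0] < v[1] < v[2]


def test_degenerate_reference_errors():
    with pytest.raises(ValueError, match="SD"):
        ts.severity_cutoffs([0.01] * 30)
    with pytest.raises(ValueError, match="too small"):
        ts.severity_cutoffs([0.01, 0.02])


def _flat_band(upper, grid=None, a=None, b=None):
    grid = np.arange(0.0, 100.01, 0.01) if grid is None else grid
    n = 100
    return PredictionBand(grid, np.full_like(grid, upper / 2),
                          np.zeros_like(grid), np.full_like(grid, upper),
                          n, "test",
                          np.full(n, a if a is not None else upper),
                          np.full(n, b if b is not None else 0.0))


def test_extract_threshold_noncrossing_is_valid():
    thr, crossed = ts.extract_threshold(_flat_band(0.01), 0.05)
    assert not crossed and np.isnan(thr)


def test_extract_threshold_linear_band_closed_form():
    grid = np.arange(0.0, 100.01, 0.01)
    band = PredictionBand(grid, 0.001 * grid, 0.001 * grid, 0.001 * grid,
                          10, "test", np.zeros(10), np.full(10, 0.001))
    thr, crossed = ts.extract_threshold(band, 0.05)
    assert crossed and thr == pytest.approx(50.0, abs=1e-9)


def test_threshold_ci_identical_replicates():
    grid = np.arange(0.0, 100.01, 0.01)
    band = PredictionBand(grid, 0.001 * grid, 0.001 * grid, 0.001 * grid,
                          50, "t", np.zeros(50), np.full(50, 0.001))
    lo, hi, frac, reliable = ts.threshold_ci(band, 0.05)
    assert (lo, hi) == (pytest.approx(50.0), pytest.approx(50.0))
    assert frac == 0.0 and reliable


def test_threshold_ci_uniform_crossings():
    # replicate curves constructed to cross 0.05 at exactly 40, 41, ..., 60
    grid = np.arange(0.0, 100.01, 0.01)
    targets = np.arange(40.0, 61.0)
    b = np.full(len(targets), 0.001)
    a = 0.05 - b * targets
    band = PredictionBand(grid, 0.001 * grid, 0.001 * grid, 0.001 * grid,
                          len(targets), "t", a, b)
    lo, hi, frac, reliable = ts.threshold_ci(band, 0.05)
    assert lo == pytest.approx(np.percentile(targets, 2.5), abs=0.02)
    assert hi == pytest.approx(np.percentile(targets, 97.5), abs=0.02)


def test_threshold_ci_excludes_noncrossing_replicates():
    grid = np.arange(0.0, 100.01, 0.01)
    a = np.array([0.05 - 0.001 * 50.0] * 30 + [0.0] * 10)
    b = np.array([0.001] * 30 + [-0.001] * 10)
    band = PredictionBand(grid, 0.001 * grid, 0.001 * grid, 0.001 * grid,
                          40, "t", a, b)
    lo, hi, frac, reliable = ts.threshold_ci(band, 0.05)
    assert frac == pytest.approx(0.25)
    assert lo == pytest.approx(50.0) and hi == pytest.approx(50.0)
    assert reliable


def test_mostly_noncrossing_flags_unreliable():
    grid = np.arange(0.0, 100.01, 0.01)
    a = np.array([0.0] * 30 + [0.05] * 10)
    b = np.array([-0.001] * 30 + [0.001] * 10)
    band = PredictionBand(grid, 0.0 * grid, 0.0 * grid, 0.0 * grid,
                          40, "t", a, b)
    *_, reliable = ts.threshold_ci(band, 0.05)
    assert not reliable


def test_zero_noise_band_collapses_to_the_true_line():
    df = make_stratum(n=2000, slope=1e-3, noise=0.0, seed=4)
    grid = np.arange(0.0, 100.01, 0.5)
    band = ts.bootstrap_band(df, grid=grid, n_boot=200, seed=9)
    np.testing.assert_allclose(band.point_estimate, 1e-3 * grid, atol=1e-6)
    np.testing.assert_allclose(band.upper95, 1e-3 * grid, atol=1e-6)
    np.testing.assert_allclose(band.lower95, 1e-3 * grid, atol=1e-6)


def test_band_is_seed_deterministic_and_ordered():
    df = make_stratum(n=120, seed=5)
    grid = np.arange(0.0, 100.01, 1.0)
    b1 = ts.bootstrap_band(df, grid=grid, n_boot=100, seed=3)
    b2 = ts.bootstrap_band(df, grid=grid, n_boot=100, seed=3)
    np.testing.assert_array_equal(b1.upper95, b2.upper95)
    np.testing.assert_array_equal(b1.rep_slopes, b2.rep_slopes)
    assert (b1.lower95 <= b1.point_estimate + 1e-12).all()
    assert (b1.point_estimate <= b1.upper95 + 1e-12).all()


def test_stratified_thresholds_structure(harmonized, truth_rates):
    thr = ts.stratified_thresholds(harmonized, truth_rates, n_boot=100,
                                   seed=1, grid=ts.default_grid(0, 150, 0.05))
    # severity monotone within each crossed stratum
    for (sex, grp), sub in thr.groupby(["sex", "age_group"]):
        sub = sub.set_index("severity")
        if sub["crossed"].all():
            assert (sub.loc["mild", "threshold"]
                    <= sub.loc["moderate", "threshold"]
                    <= sub.loc["severe", "threshold"])
        ok = sub["crossed"]
        assert (sub.loc[ok, "ci_low"] <= sub.loc[ok, "threshold"] + 1e-9).all()
        assert (sub.loc[ok, "threshold"] <= sub.loc[ok, "ci_high"] + 1e-9).all()
    # small strata emitted with reason rather than dropped
    assert set(thr["age_group"]) <= {"all", "le65", "65to80", "gt80"}
    assert (thr.loc[~thr["crossed"], "reason"] != "").all()


def test_single_stratum_cohort_gets_three_rows(harmonized, truth_rates):
    fem = harmonized[harmonized["sex"] == "female"]
    thr = ts.stratified_thresholds(fem, truth_rates, n_boot=80, seed=2,
                                   grid=ts.default_grid(0, 150, 0.1),
                                   age_stratified=False)
    fem_rows = thr[thr["sex"] == "female"]
    assert len(fem_rows) == 3
    male_rows = thr[thr["sex"] == "male"]
    assert (~male_rows["crossed"]).all()


@pytest.mark.parametrize("cl,phase", [
    (35.0, "below_mild"), (50.0, "mild_moderate"), (40.0, "mild_moderate"),
    (60.0, "moderate_severe"), (70.0, "above_severe"), (99.0, "above_severe"),
])
def test_phase_membership_with_boundary_convention(cl, phase):
    assert ts.phase_from_thresholds(cl, (40.0, 56.0, 70.0)) == phase


def test_tau_by_phase_means_increase(small_cohort, harmonized, truth_rates):
    thr = ts.stratified_thresholds(harmonized, truth_rates, n_boot=80,
                                   seed=3, grid=ts.default_grid(0, 150, 0.1),
                                   age_stratified=False)
    summary = ts.tau_by_phase_summary(harmonized, truth_rates,
                                      small_cohort.tau_series, thr)
    rocs = summary["roc_mean"].dropna().to_numpy()
    assert len(rocs) >= 3
    assert np.all(np.diff(rocs) > 0)
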