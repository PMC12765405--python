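import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import taustage as ts
from taustage.interactions import huber_irls


def _design_and_outcome(n=400, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    beta = np.array([1.0, 2.0, -0.5])
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


def test_huber_irls_matches_statsmodels_rlm():
    import statsmodels.api as sm

    X, y = _design_and_outcome()
    beta, *_ = huber_irls(X, y)
    ref = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit(conv="coefs",
                                                       tol=1e-10)
    np.testing.assert_allclose(beta, ref.params, atol=1e-6)


def test_huber_reduces_to_ols_for_huge_tuning_constant():
    X, y = _design_and_outcome(seed=3)
    beta, *_ = huber_irls(X, y, c=1e6)
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(beta, ols, atol=1e-6)


def test_identically_zero_outcome_handled_without_division_error():
    rng = np.random.default_rng(0)
    design = pd.DataFrame({"x": rng.normal(size=50)})
    fit = ts.fit_robust(np.zeros(50), design)
    np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-12)
    assert fit.scale == 0.0
    assert np.all((fit.p_values == 1.0) | np.isfinite(fit.p_values))


def test_clean_gaussian_robust_close_to_ols():
    rng = np.random.default_rng(7)
    n = 500
    x = rng.normal(size=n)
    y = 0.5 + 1.5 * x + rng.normal(size=n)
    fit = ts.fit_robust(y, pd.DataFrame({"x": x}))
    X = np.column_stack([np.ones(n), x])
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(((y - X @ ols) ** 2).sum())
    se = np.sqrt(ssr / (n - 2) * np.diag(np.linalg.inv(X.T @ X)))
    assert np.all(np.abs(fit.coefficients.to_numpy() - ols) < 0.5 * se)


def test_rank_deficient_design_names_columns():
    rng = np.random.default_rng(1)
    x = rng.normal(size=60)
    design = pd.DataFrame({"x": x, "x_copy": x})
    with pytest.raises(ValueError, match="collinear"):
        ts.fit_robust(rng.normal(size=60), design)


def test_bonferroni_arithmetic():
    assert ts.bonferroni(0.002, 4) == pytest.approx(0.008)
    assert ts.bonferroni(0.5, 4) == 1.0


def brute_force_bh(p):
    """Benjamini-Hochberg by explicit sort: adjusted p_(i) =
    min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
@settings(deadline=None, max_examples=200)
def test_bh_matches_brute_force_oracle(pvals):
    from statsmodels.stats.multitest import multipletests

    _, adj, *_ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(adj, brute_force_bh(pvals), atol=1e-12)


def test_bh_trivial_cases():
    from statsmodels.stats.multitest import multipletests

    rej, adj, *_ = multipletests([1.0, 1.0, 1.0], method="fdr_bh")
    assert not rej.any()
    _, adj1, *_ = multipletests([0.037], method="fdr_bh")
    assert adj1[0] == pytest.approx(0.037)
    _, adj4, *_ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
    np.testing.assert_allclose(adj4, 0.04)


def test_interaction_analysis_recovers_negative_male_effect(
        harmonized, truth_rates):
    res = ts.interaction_analysis(truth_rates, harmonized, "male",
                                  outcomes=("temporal_meta",))
    r = res["temporal_meta"]
    assert r["interaction"] < 0
    assert r["p_bonferroni"] >= r["p_raw"]
    assert r["p_bonferroni"] == pytest.approx(min(1.0, 4 * r["p_raw"]))


def test_sex_strata_are_disjoint_and_exhaustive(harmonized, truth_rates):
    m = ts.interaction_analysis(truth_rates, harmonized, "male",
                                outcomes=("temporal_meta",))
    f = ts.interaction_analysis(truth_rates, harmonized, "female",
                                outcomes=("temporal_meta",))
    n_m = m["temporal_meta"]["fit"].n
    n_f = f["temporal_meta"]["fit"].n
    assert n_m + n_f == len(truth_rates)
    with pytest.raises(ValueError, match="empty stratum"):
        ts.interaction_analysis(truth_rates, harmonized[0:0], "male")


def test_regional_map_adjusts_within_scope():
    cfg = ts.SynthConfig(n_subjects=250, seed=21, n_parcels=8)
    c = ts.generate_cohort(cfg)
    parts = ts.harmonize_amyloid(c.participants)
    rates = []
    for k in range(8):
        r = c.truth[["id", "true_rate"]].rename(columns={"true_rate": "roc"})
        r["variable"] = f"parcel_{k:03d}"
        rates.append(r)
    rates = pd.concat(rates, ignore_index=True)
    out = ts.regional_map(rates, parts, "male")
    assert len(out) == 8
    ok = out["p_adj"].notna()
    assert (out.loc[ok, "p_adj"] >= out.loc[ok, "p"] - 1e-12).all()
    assert (out.loc[out["significant"], "p_adj"] < 0.05).all()


def test_percentile_window_covers_expected_age_range(rng):
    n = 2000
    age = rng.uniform(50, 90, n)
    parts = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)], "age": age, "sex": "male",
        "apoe4": "noncarrier", "cohort": "A",
        "centiloid": rng.uniform(0, 100, n),
    })
    rates = pd.DataFrame({"id": parts["id"], "variable": "temporal_meta",
                          "roc": rng.normal(0, 0.01, n)})
    w = ts.percentile_slopes(rates, parts, "male", n_boot=10, seed=0)
    mid = w[w["percentile"] == 50].iloc[0]
    assert mid["age_low"] == pytest.approx(np.percentile(age, 40), abs=0.5)
    assert mid["age_high"] == pytest.approx(np.percentile(age, 60), abs=0.5)
    assert mid["age_low"] == pytest.approx(66.0, abs=1.0)
    assert mid["age_high"] == pytest.approx(74.0, abs=1.0)
    assert len(w) == 9
    assert (w["ci_low"] <= w["slope"] + 1e-12).all()
    assert (w["slope"] <= w["ci_high"] + 1e-12).all()


def test_small_windows_are_flagged(rng):
    n = 40
    parts = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "age": rng.uniform(50, 90, n), "sex": "female",
        "apoe4": "noncarrier", "cohort": "A",
        "centiloid": rng.uniform(0, 100, n),
    })
    rates = pd.DataFrame({"id": parts["id"], "variable": "temporal_meta",
                          "roc": rng.normal(0, 0.01, n)})
    w = ts.percentile_slopes(rates, parts, "female", n_boot=5, seed=0,
                             min_n=30)
    assert w["flagged"].any()
    assert w.loc[w["flagged"], "ci_low"].isna().all()


def test_welch_t_known_values():
    tau = pd.DataFrame({
        "id": list("abcdef"), "time": 0.0, "roi": "temporal_meta",
        "suvr": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    parts = pd.DataFrame({"id": list("abcdef"),
                          "sex": ["male"] * 3 + ["female"] * 3,
                          "age": 70.0})
    out = ts.baseline_tau_comparison(tau, parts, rois=("temporal_meta",))
    row = out[out["age_group"] == "65to80"].iloc[0]
    assert row["t"] == pytest.approx(-3.674, abs=1e-3)

    parts["sex"] = ["male", "female"] * 3
    tau["suvr"] = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
    out = ts.baseline_tau_comparison(tau, parts, rois=("temporal_meta",))
    row = out[out["age_group"] == "65to80"].iloc[0]
    assert row["t"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0)


def test_one_sex_groups_are_skipped_with_note():
    tau = pd.DataFrame({"id": list("abc"), "time": 0.0,
                        "roi": "temporal_meta", "suvr": [1.0, 1.1, 1.2]})
    parts = pd.DataFrame({"id": list("abc"), "sex": "female", "age": 70.0})
    out = ts.baseline_tau_comparison(tau, parts, rois=("temporal_meta",))
    row = out[out["age_group"] == "65to80"].iloc[0]
    assert np.isnan(row["t"]) and "skip" in row["note"]
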