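"""Tauopathy phase assignment and its link to cognitive decline.

Subjects are classified against their sex- and age-specific Centiloid
thresholds (binary above/below each severity, and gradual four-level phase).
Differences in linear cognitive decline across phases are tested with
ANCOVAs (age, sex, education, cohort as covariates) and post hoc Tukey tests
on covariate-adjusted means.

Nonlinear decline timing is modelled with a logistic latent-time progression
model: the normalized disease score of subject i follows

    y_ij = p0 + (1 - p0) * logistic( v * exp(xi_i) * (t_ij - t0 - tau_i) )

with population midpoint t0 (years) and steepness v (1/year), and Gaussian
subject-level time-shift tau_i ~ N(0, s_tau^2) (positive = later onset) and
log-acceleration xi_i ~ N(0, s_xi^2).  The population parameters are
estimated by a damped alternating-maximisation EM (a deterministic
stochastic-approximation-style scheme: joint MAP of all subject parameters
by L-BFGS-B with analytic gradients, then population/hyper-parameter
updates with damping), under 10-fold cross-validation so that each subject
is personalized only by a population model that never saw them.

MMSE is reversed and normalized by its 30-point ceiling, ADAS-Cog11 by 70,
so both scores live on a [0, 1] increasing-with-disease scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .thresholds import lookup_thresholds, phase_from_thresholds
from .preprocess import assign_age_group

__all__ = [
    "PopulationCurve", "GroupComparison", "assign_phase", "ancova_compare",
    "fit_progression", "personalize", "compare_progression",
    "simulate_progression_data", "normalize_scores",
]

PHASE_ORDER = ("below_mild", "mild_moderate", "moderate_severe",
               "above_severe")


@dataclass
class PopulationCurve:
    """Population logistic curve and hyper-parameters of one training fold."""

    t0: float
    v: float
    p_floor: float
    sigma_y: float
    sigma_tau: float
    sigma_xi: float
    converged: bool = True


@dataclass
class GroupComparison:
    outcome: str
    groups: list
    adjusted_means: pd.Series
    f_stat: float
    df_num: int
    df_den: int
    p: float
    tukey: pd.DataFrame


# ---------------------------------------------------------------- phases

def assign_phase(participants: pd.DataFrame,
                 threshold_table: pd.DataFrame) -> pd.DataFrame:
    """Binary above-threshold flags and gradual phase per subject.

    A subject's Centiloid equal to a threshold counts as above it. Subjects
    whose stratum has no crossed threshold set are flagged unassignable.
    """
    grp = assign_age_group(participants["age"])
    strata = {key: lookup_thresholds(threshold_table, key[0], key[1])
              for key in set(zip(participants["sex"], grp))}
    rows = []
    for sid, sex, g, cl in zip(participants["id"], participants["sex"], grp,
                               participants["centiloid"]):
        thr = strata[(sex, g)]
        if thr is None:
            rows.append(dict(id=sid, assignable=False, above_mild=False,
                             above_moderate=False, above_severe=False,
                             phase=np.nan))
            continue
        cl = float(cl)
        mild, moderate, severe = thr
        rows.append(dict(id=sid, assignable=True,
                         above_mild=cl >= mild,
                         above_moderate=cl >= moderate,
                         above_severe=cl >= severe,
                         phase=phase_from_thresholds(cl, thr)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- ANCOVA

def ancova_compare(df: pd.DataFrame, outcome: str, group: str,
                   covariates: tuple[str, ...] = ()) -> GroupComparison:
    """ANCOVA group test plus Tukey HSD on covariate-adjusted means.

    The group F-statistic comes from the nested comparison of the linear
    model with and without the group factor; adjusted means are predictions
    with every subject reassigned to each group in turn, averaged over the
    observed covariate distribution.  Pairwise Tukey p-values use the
    studentized-range distribution on adjusted-mean differences.  With no
    covariates this reduces exactly to one-way ANOVA + classic Tukey.
    """
    import statsmodels.formula.api as smf

    missing = [c for c in (outcome, group, *covariates)
               if c not in df.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    data = df.dropna(subset=[outcome, group, *covariates]).copy()
    levels = sorted(data[group].dropna().unique().tolist())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 groups, got {levels}")
    for g in levels:
        if (data[group] == g).sum() < 3:
            raise ValueError(f"group {g!r} has n < 3")

    terms = [f"C({group})"]
    for c in covariates:
        terms.append(c if pd.api.types.is_numeric_dtype(data[c])
                     else f"C({c})")
    full = smf.ols(f"{outcome} ~ " + " + ".join(terms), data=data).fit()
    exog = full.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("singular design; aliased terms among "
                         f"{full.model.exog_names}")
    reduced_terms = terms[1:] or ["1"]
    reduced = smf.ols(f"{outcome} ~ " + " + ".join(reduced_terms),
                      data=data).fit()

    df_num = int(full.df_model - reduced.df_model)
    df_den = int(full.df_resid)
    if reduced.ssr - full.ssr <= 1e-12 * max(1.0, reduced.ssr):
        f_stat, p = 0.0, 1.0
    else:
        f_stat = float(((reduced.ssr - full.ssr) / df_num)
                       / (full.ssr / df_den))
        p = float(stats.f.sf(f_stat, df_num, df_den))

    # covariate-adjusted means: average prediction with group reassigned
    import patsy

    design_rows = {}
    for g in levels:
        shifted = data.copy()
        shifted[group] = g
        X = patsy.dmatrix(full.model.data.design_info, shifted,
                          return_type="dataframe")
        design_rows[g] = X.to_numpy().mean(axis=0)
    adj_means = pd.Series({g: float(design_rows[g] @ full.params.to_numpy())
                           for g in levels})

    V = full.cov_params().to_numpy()
    k = len(levels)
    y_scale = max(float(data[outcome].abs().max()), 1.0)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            c = design_rows[levels[j]] - design_rows[levels[i]]
            diff = float(c @ full.params.to_numpy())
            se = float(np.sqrt(max(c @ V @ c, 0.0)))
            if abs(diff) <= 1e-10 * y_scale:
                q = 0.0
            elif se <= 1e-14 * y_scale:
                q = np.inf
            else:
                q = abs(diff) / se * np.sqrt(2.0)
            p_adj = 1.0 if q == 0 else float(
                stats.studentized_range.sf(q, k, df_den))
            pairs.append((levels[i], levels[j], diff, se, q,
                          min(1.0, p_adj)))
    tukey = pd.DataFrame(pairs, columns=["group1", "group2", "diff", "se",
                                         "q", "p_adj"])
    return GroupComparison(outcome, levels, adj_means, f_stat, df_num,
                           df_den, p, tukey)


# ------------------------------------------------- progression model

def normalize_scores(cognition_series: pd.DataFrame, outcome: str
                     ) -> pd.DataFrame:
    """Normalized [0,1] increasing-with-disease score for one instrument."""
    df = cognition_series[["id", "time", outcome]].dropna().copy()
    if outcome == "mmse":
        y = (30.0 - df[outcome]) / 30.0
    elif outcome == "adas11":
        y = df[outcome] / 70.0
    else:
        raise ValueError(f"unknown cognitive outcome {outcome!r}")
    df["score"] = np.clip(y, 0.0, 1.0)
    return df[["id", "time", "score"]]


def _pack(df: pd.DataFrame):
    ids = df["id"].unique()
    idx = pd.Series(np.arange(len(ids)), index=ids)
    return (ids, idx[df["id"]].to_numpy(),
            df["time"].to_numpy(dtype=float),
            df["score"].to_numpy(dtype=float))


def _model(t, tau, xi, t0, v, p0):
    eta = v * np.exp(xi) * (t - t0 - tau)
    s = 1.0 / (1.0 + np.exp(-np.clip(eta, -60, 60)))
    mu = p0 + (1.0 - p0) * s
    dmu_deta = (1.0 - p0) * s * (1.0 - s)
    return eta, mu, dmu_deta


def _subject_objective(z, sub, t, y, n, pop):
    tau, xi = z[:n], z[n:]
    eta, mu, dmu = _model(t, tau[sub], xi[sub], pop.t0, pop.v, pop.p_floor)
    r = y - mu
    inv_sy2 = 1.0 / pop.sigma_y ** 2
    J = 0.5 * inv_sy2 * float(r @ r) \
        + 0.5 * float(tau @ tau) / pop.sigma_tau ** 2 \
        + 0.5 * float(xi @ xi) / pop.sigma_xi ** 2
    common = -r * dmu * inv_sy2
    g_tau = np.bincount(sub, weights=common * (-pop.v * np.exp(xi[sub])),
                        minlength=n) + tau / pop.sigma_tau ** 2
    g_xi = np.bincount(sub, weights=common * eta,
                       minlength=n) + xi / pop.sigma_xi ** 2
    return J, np.concatenate([g_tau, g_xi])


def _map_subjects(sub, t, y, n, pop, z0=None):
    z0 = np.zeros(2 * n) if z0 is None else z0
    res = optimize.minimize(
        _subject_objective, z0, args=(sub, t, y, n, pop), jac=True,
        method="L-BFGS-B",
        bounds=[(-40.0, 40.0)] * n + [(-3.0, 3.0)] * n,
        options=dict(maxiter=400, ftol=1e-12, gtol=1e-9))
    return res.x[:n], res.x[n:], res.success


def _population_objective(theta, sub, t, y, tau, xi, p0):
    t0, logv = theta
    v = np.exp(logv)
    eta, mu, dmu = _model(t, tau[sub], xi[sub], t0, v, p0)
    r = y - mu
    J = 0.5 * float(r @ r)
    g_t0 = float((-r * dmu) @ (-v * np.exp(xi[sub])))
    g_logv = float((-r * dmu) @ eta)
    return J, np.array([g_t0, g_logv])


def _init_population(t, y, p0, sigma_tau0, sigma_xi0):
    yc = np.clip((y - p0) / max(1.0 - p0, 1e-9), 1e-3, 1 - 1e-3)
    logit = np.log(yc / (1 - yc))
    tc = t - t.mean()
    denom = float(tc @ tc)
    v0 = float(tc @ (logit - logit.mean())) / denom if denom > 0 else 0.1
    v0 = min(max(v0, 0.02), 2.0)
    t0 = float(t.mean() - logit.mean() / v0)
    t0 = min(max(t0, t.min() - 30.0), t.max() + 30.0)
    sy = max(float(np.std(y)) * 0.5, 1e-2)
    return PopulationCurve(t0, v0, p0, sy, sigma_tau0, sigma_xi0)


def _fit_population(sub, t, y, n, p0, sigma_tau0, sigma_xi0,
                    n_outer=12, estimate_hyper=True, damping=0.4):
    pop = _init_population(t, y, p0, sigma_tau0, sigma_xi0)
    tau = np.zeros(n)
    xi = np.zeros(n)
    for _ in range(n_outer):
        tau, xi, _ = _map_subjects(sub, t, y, n, pop,
                                   np.concatenate([tau, xi]))
        res = optimize.minimize(
            _population_objective, np.array([pop.t0, np.log(pop.v)]),
            args=(sub, t, y, tau, xi, p0), jac=True, method="L-BFGS-B",
            bounds=[(t.min() - 40.0, t.max() + 40.0), (np.log(1e-3), 2.0)],
            options=dict(maxiter=200))
        pop.t0, pop.v = float(res.x[0]), float(np.exp(res.x[1]))
        _, mu, _ = _model(t, tau[sub], xi[sub], pop.t0, pop.v, p0)
        sy = max(float(np.sqrt(np.mean((y - mu) ** 2))), 1e-3)
        pop.sigma_y = (1 - damping) * pop.sigma_y + damping * sy
        if estimate_hyper:
            st = max(float(np.sqrt(np.mean(tau ** 2))), 0.3)
            sx = max(float(np.sqrt(np.mean(xi ** 2))), 0.05)
            pop.sigma_tau = (1 - damping) * pop.sigma_tau + damping * st
            pop.sigma_xi = (1 - damping) * pop.sigma_xi + damping * sx
    if pop.v < 1e-3:
        raise RuntimeError("population steepness collapsed: trajectories "
                           "are flat; progression model not identifiable")
    return pop, tau, xi


def personalize(pop: PopulationCurve, score_df: pd.DataFrame) -> pd.DataFrame:
    """MAP (tau, xi) for each subject under a fixed population curve."""
    ids, sub, t, y = _pack(score_df)
    tau, xi, ok = _map_subjects(sub, t, y, len(ids), pop)
    return pd.DataFrame({"id": ids, "time_shift": tau, "log_accel": xi,
                         "converged": ok})


def fit_progression(cognition_series: pd.DataFrame, outcome: str = "adas11",
                    n_folds: int = 10, seed: int = 0, p_floor: float = 0.0,
                    sigma_tau0: float = 3.0, sigma_xi0: float = 0.3,
                    n_outer: int = 12, estimate_hyper: bool = True
                    ) -> tuple[list[PopulationCurve], pd.DataFrame]:
    """Cross-validated latent-time progression fit.

    Subjects are split into ``n_folds`` folds (seeded shuffle); each fold's
    population curve is trained on the other folds and the held-out subjects
    are personalized against it, so no subject's (time_shift, log_accel)
    derives from a population model trained on that subject.  Deterministic
    given ``seed``.

    Returns (per-fold population curves, DataFrame with id, time_shift,
    log_accel, fold, converged).
    """
    scores = normalize_scores(cognition_series, outcome)
    all_ids = scores["id"].unique()
    if len(all_ids) < n_folds:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_ids))
    folds = np.array_split(all_ids[order], n_folds)

    pops, frames = [], []
    for f, test_ids in enumerate(folds):
        test_mask = scores["id"].isin(test_ids)
        train = scores[~test_mask] if n_folds > 1 else scores
        ids, sub, t, y = _pack(train)
        pop, _, _ = _fit_population(sub, t, y, len(ids), p_floor,
                                    sigma_tau0, sigma_xi0, n_outer=n_outer,
                                    estimate_hyper=estimate_hyper)
        pops.append(pop)
        pers = personalize(pop, scores[test_mask])
        pers["fold"] = f
        frames.append(pers)
    params = pd.concat(frames, ignore_index=True)
    return pops, params


def simulate_progression_data(n_subjects: int, times,
                              t0: float = 5.0, v: float = 0.4,
                              tau_sd: float = 3.0, xi_sd: float = 0.3,
                              noise_sd: float = 0.02, p_floor: float = 0.0,
                              seed: int | None = None
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate cognition series straight from the progression model.

    Returns (cognition_series with mmse/adas11 columns, truth with
    true_time_shift / true_log_accel). Synthetic by construction; used for
    parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    tau = rng.normal(0.0, tau_sd, n_subjects)
    xi = rng.normal(0.0, xi_sd, n_subjects)
    ids = np.array([f"P{i:05d}" for i in range(n_subjects)])
    lat = v * np.exp(xi)[:, None] * (times[None, :] - t0 - tau[:, None])
    y = p_floor + (1 - p_floor) / (1 + np.exp(-lat))
    y_obs = y + rng.normal(0.0, noise_sd, y.shape)
    cog = pd.DataFrame({
        "id": np.repeat(ids, len(times)),
        "time": np.tile(times, n_subjects),
        "mmse": np.clip(30 * (1 - y_obs.ravel()), 0, 30),
        "adas11": np.clip(70 * y_obs.ravel(), 0, 70),
    })
    truth = pd.DataFrame({"id": ids, "true_time_shift": tau,
                          "true_log_accel": xi})
    return cog, truth


def compare_progression(params: pd.DataFrame, phases: pd.DataFrame,
                        participants: pd.DataFrame,
                        covariates: tuple[str, ...] = ("age", "sex",
                                                       "education", "cohort")
                        ) -> dict[str, GroupComparison]:
    """ANCOVA + Tukey on time-shift and log-acceleration across phases.

    Returns comparisons for the gradual 4-level grouping and for each binary
    above-threshold split, keyed e.g. ``time_shift:phase`` or
    ``log_accel:above_mild``.
    """
    df = (params.merge(phases, on="id")
          .merge(participants, on="id"))
    df = df[df["assignable"] == True]  # noqa: E712
    out = {}
    for outcome in ("time_shift", "log_accel"):
        for grouping in ("phase", "above_mild", "above_moderate",
                         "above_severe"):
            sub = df.dropna(subset=[grouping])
            counts = sub.groupby(grouping)[outcome].count()
            if len(counts) < 2 or counts.min() < 3:
                continue
            out[f"{outcome}:{grouping}"] = ancova_compare(
                sub, outcome, grouping, covariates)
    return out
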