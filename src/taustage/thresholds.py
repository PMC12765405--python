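"""Amyloid (Centiloid) thresholds for the transition to tauopathy.

The onset of tauopathy is defined on the rate scale: a subject transitions to
mild / moderate / severe tauopathy when their temporal meta-ROI tau-PET
annual rate of change exceeds the cognitively-normal amyloid-negative
reference mean by z = 2 / 2.5 / 3 reference SDs.  Within each sex (and sex x
age-group) stratum, a Huber-robust regression of the tau rate on Centiloid
(adjusting for APOE e4 and cohort) is case-resampled 1000 times; the
pointwise 95% band of the predicted mean rate over a fine Centiloid grid
gives, for each severity cutoff, the threshold: the smallest grid value at
which the upper band first reaches the cutoff.  A per-replicate crossing
distribution provides the threshold's own CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import huber_irls
from .preprocess import AGE_GROUPS, assign_age_group

__all__ = [
    "SeverityCutoffs", "PredictionBand", "severity_cutoffs",
    "bootstrap_band", "extract_threshold", "threshold_ci",
    "stratified_thresholds", "tau_by_phase_summary", "lookup_thresholds",
    "phase_from_thresholds", "DEFAULT_Z_LEVELS", "default_grid",
]

DEFAULT_Z_LEVELS = {"mild": 2.0, "moderate": 2.5, "severe": 3.0}
SEVERITIES = ("mild", "moderate", "severe")


def default_grid(lo: float = 0.0, hi: float = 150.0,
                 step: float = 0.01) -> np.ndarray:
    """Centiloid grid over which bands and thresholds are evaluated.

    The default 0.01-Centiloid step matches the two-decimal precision at
    which thresholds are reported.
    """
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass
class SeverityCutoffs:
    """Tauopathy severity cutoffs on the rate (SUVR/year) scale."""

    reference_mean: float
    reference_sd: float
    z_levels: dict
    cutoff_values: dict
    n_reference: int


@dataclass
class PredictionBand:
    """Bootstrap band for the predicted mean tau rate over a Centiloid grid.

    Each bootstrap replicate's predicted curve is linear in Centiloid,
    ``a + b*CL`` with covariates fixed at stratum means, so only the
    per-replicate (a, b) pairs are retained.
    """

    grid: np.ndarray
    point_estimate: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_boot: int
    stratum: str
    rep_intercepts: np.ndarray = field(repr=False)
    rep_slopes: np.ndarray = field(repr=False)
    n_redrawn: int = 0


def severity_cutoffs(reference_rocs,
                     z_levels: dict | None = None,
                     min_n: int = 20) -> SeverityCutoffs:
    """Cutoffs = reference mean + z * reference SD (sample SD, ddof=1).

    The reference group is the CN Aβ− stratum's temporal meta-ROI rate of
    change, pooled across cohorts.
    """
    z_levels = DEFAULT_Z_LEVELS if z_levels is None else dict(z_levels)
    r = np.asarray(reference_rocs, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) < min_n:
        raise ValueError(f"reference group too small: {len(r)} < {min_n}")
    mean, sd = float(r.mean()), float(r.std(ddof=1))
    if sd <= 1e-15 + 1e-12 * abs(mean):
        raise ValueError("reference SD is zero; cutoffs undefined")
    cutoffs = {lev: mean + z * sd for lev, z in z_levels.items()}
    return SeverityCutoffs(mean, sd, z_levels, cutoffs, len(r))


def _band_design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    """Design intercept + centiloid + apoe4 + cohort dummies; returns
    (X, column means for prediction, names). Column 1 is centiloid."""
    cols = [np.ones(len(df)), df["centiloid"].to_numpy(dtype=float),
            (df["apoe4"] == "carrier").to_numpy(dtype=float)]
    names = ["intercept", "centiloid", "apoe4"]
    if df["cohort"].nunique() > 1:
        levels = sorted(df["cohort"].unique())[1:]
        for lev in levels:
            cols.append((df["cohort"] == lev).to_numpy(dtype=float))
            names.append(f"cohort_{lev}")
    X = np.column_stack(cols)
    means = X.mean(axis=0)
    means[1] = 0.0  # centiloid varies along the grid
    return X, means, names


def _marginal_line(beta: np.ndarray, means: np.ndarray) -> tuple[float, float]:
    """Predicted mean rate as a + b*CL at stratum-mean covariates."""
    a = float(beta @ means)
    b = float(beta[1])
    return a, b


def bootstrap_band(data: pd.DataFrame, grid: np.ndarray | None = None,
                   n_boot: int = 1000, seed: int | None = None,
                   stratum: str = "all", max_fail_frac: float = 0.1
                   ) -> PredictionBand:
    """Case-resampled robust-regression band for the predicted tau rate.

    ``data`` needs columns roc, centiloid, apoe4, cohort.  Each replicate
    refits ``roc ~ centiloid + apoe4 + cohort`` (Huber) on a with-replacement
    resample and predicts over the grid at stratum-mean covariates; the band
    is the pointwise 2.5th/97.5th percentile envelope.  Failed replicates are
    redrawn (counted); more than ``max_fail_frac`` failures aborts.
    Deterministic given ``seed``.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    X, means, _ = _band_design(data)
    y = data["roc"].to_numpy(dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError(f"stratum {stratum!r}: n={n} < 30")

    beta, *_ = huber_irls(X, y)
    a0, b0 = _marginal_line(beta, means)

    A = np.empty(n_boot)
    B = np.empty(n_boot)
    redrawn = 0
    max_redraws = int(np.ceil(max_fail_frac * n_boot))
    b_i = 0
    while b_i < n_boot:
        idx = rng.integers(0, n, n)
        bb, _, conv, _ = huber_irls(X[idx], y[idx])
        if not np.all(np.isfinite(bb)):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError(
                    f"stratum {stratum!r}: >{max_fail_frac:.0%} of bootstrap "
                    "fits failed")
            continue
        A[b_i], B[b_i] = _marginal_line(bb, means)
        b_i += 1

    lower = np.empty_like(grid)
    upper = np.empty_like(grid)
    chunk = 4000
    for s in range(0, len(grid), chunk):
        g = grid[s:s + chunk]
        curves = A[:, None] + B[:, None] * g[None, :]
        lower[s:s + chunk] = np.percentile(curves, 2.5, axis=0)
        upper[s:s + chunk] = np.percentile(curves, 97.5, axis=0)
    point = a0 + b0 * grid
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return PredictionBand(grid, point, lower, upper, n_boot, stratum,
                          A, B, redrawn)


def extract_threshold(band: PredictionBand, cutoff: float
                      ) -> tuple[float, bool]:
    """Smallest grid Centiloid where the upper 95% band reaches the cutoff.

    Non-crossing is a valid outcome: (nan, False).
    """
    hits = np.nonzero(band.upper95 >= cutoff)[0]
    if len(hits) == 0:
        return float("nan"), False
    return float(band.grid[hits[0]]), True


def threshold_ci(band: PredictionBand, cutoff: float
                 ) -> tuple[float, float, float, bool]:
    """CI for the threshold from per-replicate curve crossings.

    For each bootstrap replicate, the first grid crossing of that replicate's
    predicted mean curve with the cutoff is found (curves are linear, so the
    analytic crossing is snapped up to the grid); the CI is the 2.5th/97.5th
    percentile of crossings among replicates that cross.  Returns
    (ci_low, ci_high, fraction_noncrossing, reliable); fewer than 50% of
    replicates crossing flags the CI unreliable.
    """
    g0, g1 = float(band.grid[0]), float(band.grid[-1])
    step = float(band.grid[1] - band.grid[0]) if len(band.grid) > 1 else 0.01
    a, b = band.rep_intercepts, band.rep_slopes
    cross = np.full(len(a), np.nan)
    at_start = a + b * g0 >= cutoff
    cross[at_start] = g0
    rising = (~at_start) & (b > 0)
    x = (cutoff - a[rising]) / b[rising]
    x = np.ceil((x - g0) / step - 1e-9) * step + g0
    x[x > g1 + 1e-9] = np.nan
    cross[rising] = x
    ok = np.isfinite(cross)
    frac_non = 1.0 - ok.mean() if len(cross) else 1.0
    if ok.sum() == 0:
        return float("nan"), float("nan"), frac_non, False
    ci_low = float(np.percentile(cross[ok], 2.5))
    ci_high = float(np.percentile(cross[ok], 97.5))
    return ci_low, ci_high, frac_non, bool(ok.mean() >= 0.5)


def stratified_thresholds(participants: pd.DataFrame, rates: pd.DataFrame,
                          z_levels: dict | None = None,
                          grid: np.ndarray | None = None,
                          n_boot: int = 1000, seed: int | None = None,
                          min_n: int = 30, age_stratified: bool = True,
                          roc_variable: str = "temporal_meta"
                          ) -> pd.DataFrame:
    """Full threshold table: sex (and optionally sex x age group) strata.

    The severity cutoffs are computed once from the pooled CN Aβ− reference;
    cohort enters every stratum model as a covariate.  Strata below ``min_n``
    are emitted with crossed=False and a reason.
    """
    z_levels = DEFAULT_Z_LEVELS if z_levels is None else dict(z_levels)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    df = rates[rates["variable"] == roc_variable].merge(participants, on="id")
    ref = df[(df["diagnosis"] == "CN") & (df["abeta_status"] == "neg")]
    cuts = severity_cutoffs(ref["roc"], z_levels)

    df = df.assign(age_group=assign_age_group(df["age"]))
    strata: list[tuple[str, str]] = [(s, "all") for s in ("female", "male")]
    if age_stratified:
        strata += [(s, g) for s in ("female", "male") for g in AGE_GROUPS]

    rows = []
    for sex, agegrp in strata:
        sub = df[df["sex"] == sex]
        if agegrp != "all":
            sub = sub[sub["age_group"] == agegrp]
        if len(sub) < min_n:
            for sev in SEVERITIES:
                if sev in z_levels:
                    rows.append(dict(sex=sex, age_group=agegrp, severity=sev,
                                     threshold=np.nan, ci_low=np.nan,
                                     ci_high=np.nan, crossed=False,
                                     n=len(sub),
                                     reason=f"stratum n={len(sub)} < {min_n}"))
            continue
        band = bootstrap_band(sub, grid=grid, n_boot=n_boot,
                              seed=int(rng.integers(0, 2 ** 31 - 1)),
                              stratum=f"{sex}/{agegrp}")
        for sev in SEVERITIES:
            if sev not in z_levels:
                continue
            cutoff = cuts.cutoff_values[sev]
            thr, crossed = extract_threshold(band, cutoff)
            lo, hi, frac_non, reliable = threshold_ci(band, cutoff)
            if crossed and np.isfinite(lo):
                # the upper-band crossing and the 2.5th replicate-crossing
                # percentile are dual estimates that can disagree by less
                # than one grid step; keep the CI consistent with the point
                lo, hi = min(lo, thr), max(hi, thr)
            rows.append(dict(sex=sex, age_group=agegrp, severity=sev,
                             threshold=thr, ci_low=lo, ci_high=hi,
                             crossed=crossed, n=len(sub),
                             reason="" if crossed else "band never reaches "
                                                       "cutoff"))
    out = pd.DataFrame(rows)
    out.attrs["cutoffs"] = cuts
    return out


def lookup_thresholds(threshold_table: pd.DataFrame, sex: str,
                      age_group: str) -> tuple[float, float, float] | None:
    """Ordered (mild, moderate, severe) thresholds for a subject's stratum.

    Prefers the sex x age-group row set; falls back to the sex-level ("all")
    rows; returns None if no fully crossed row set exists.
    """
    for grp in (age_group, "all"):
        sub = threshold_table[(threshold_table["sex"] == sex) &
                              (threshold_table["age_group"] == grp)]
        if len(sub) == 0:
            continue
        vals = {r["severity"]: (r["threshold"], r["crossed"])
                for _, r in sub.iterrows()}
        if all(s in vals and vals[s][1] for s in SEVERITIES):
            return tuple(float(vals[s][0]) for s in SEVERITIES)
    return None


def phase_from_thresholds(centiloid: float,
                          thr: tuple[float, float, float]) -> str:
    """Gradual tauopathy phase; Centiloid equal to a threshold counts as
    above it (consistent with the >=-crossing convention)."""
    mild, moderate, severe = thr
    if centiloid >= severe:
        return "above_severe"
    if centiloid >= moderate:
        return "moderate_severe"
    if centiloid >= mild:
        return "mild_moderate"
    return "below_mild"


def tau_by_phase_summary(participants: pd.DataFrame, rates: pd.DataFrame,
                         tau_series: pd.DataFrame,
                         threshold_table: pd.DataFrame,
                         roc_variable: str = "temporal_meta") -> pd.DataFrame:
    """Baseline temporal meta SUVR and tau rate per amyloid-inferred phase."""
    base = (tau_series[tau_series["roi"] == roc_variable]
            .sort_values("time").groupby("id", as_index=False).first()
            .rename(columns={"suvr": "baseline_suvr"}))
    df = (rates[rates["variable"] == roc_variable]
          .merge(participants, on="id")
          .merge(base[["id", "baseline_suvr"]], on="id"))
    df["age_group"] = assign_age_group(df["age"])

    strata = {key: lookup_thresholds(threshold_table, key[0], key[1])
              for key in set(zip(df["sex"], df["age_group"]))}
    df["phase"] = [phase_from_thresholds(cl, strata[(sex, grp)])
                   if strata[(sex, grp)] is not None else np.nan
                   for sex, grp, cl in zip(df["sex"], df["age_group"],
                                           df["centiloid"])]
    order = ["below_mild", "mild_moderate", "moderate_severe", "above_severe"]
    g = (df.dropna(subset=["phase"]).groupby("phase")
         .agg(n=("id", "count"),
              baseline_suvr_mean=("baseline_suvr", "mean"),
              baseline_suvr_sd=("baseline_suvr", "std"),
              roc_mean=("roc", "mean"), roc_sd=("roc", "std"))
         .reindex(order).reset_index())
    return g
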