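"""Synthetic cohort generation for amyloid–tau–cognition analyses.

Generates cohorts with the statistical structure the downstream pipeline
assumes — a bimodal (Aβ−/Aβ+) Centiloid distribution, per-subject tau-PET
accumulation rates that are linear in amyloid burden with a sex-specific
amyloid×age interaction, repeated noisy SUVR measurements, a cognitively
normal Aβ− reference stratum with near-null rates, and sigmoidal cognitive
trajectories whose latent onset is tied to the true tau rate — together with
a ground-truth table so that estimator-recovery tests are possible.

The generator makes no attempt to match the marginal distributions of any
real cohort numerically; it reproduces the qualitative structure (directions
and rough magnitudes of effects) that the analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DEFAULT_CALIBRATIONS, TracerCalibration, assign_age_group

__all__ = [
    "CognitionGenParams",
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "summarize_cohort",
]


@dataclass
class CognitionGenParams:
    """Parameters of the latent-time logistic cognition generator.

    The latent disease score of subject *i* at time *t* is

        y_i(t) = p_floor + (1 - p_floor) * logistic(v * exp(xi_i) * (t - t0 - tau_i))

    with ``tau_i`` (years) the subject's time-shift and ``xi_i`` the
    log-acceleration.  MMSE is observed as ``30*(1-y)`` and ADAS-Cog11 as
    ``70*y``, each with Gaussian noise on the normalized scale and clipped to
    the instrument range.  ``onset_tie`` (years per SD) links the time-shift
    linearly to the rank-normalized true tau rate: faster tau accumulation
    implies earlier onset (more negative shift).
    """

    t0: float = 12.0          # population half-way point, years from baseline
    v: float = 0.3            # steepness, 1/year
    p_floor: float = 0.0      # lower asymptote of the normalized score
    onset_tie: float = 4.0    # years of onset advance per SD of tau rate
    tau_jitter_sd: float = 1.0   # residual SD of the time-shift, years
    xi_sd: float = 0.25       # SD of the log-acceleration factor
    noise_sd: float = 0.03    # observation noise on the normalized [0,1] scale


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    Rates are in SUVR/year; the per-subject true temporal meta-ROI rate is

        r_i = rate_intercept
              + [slope_sex + interaction_sex * (age_i - age_center)] * CL_i
              + Normal(0, rate_noise_sd)

    so a *negative* ``interaction_male`` means younger men accumulate tau
    faster per Centiloid, and the fitted Centiloid×age regression coefficient
    has the same (negative) sign.
    """

    n_subjects: int = 500
    seed: int = 0
    p_female: float = 0.5
    age_mean: float = 73.0
    age_sd: float = 8.0
    age_min: float = 50.0
    age_max: float = 95.0
    p_apoe4: float = 0.45
    p_abeta_pos: float = 0.6
    cl_neg_mean: float = 5.0
    cl_neg_sd: float = 8.0
    cl_pos_low: float = 25.0
    cl_pos_high: float = 140.0
    rate_intercept: float = 0.002
    rate_slope_male: float = 3.0e-4
    rate_slope_female: float = 4.5e-4
    interaction_male: float = -9.8e-6
    interaction_female: float = 0.0
    age_center: float = 75.0
    rate_noise_sd: float = 0.01
    suvr_baseline_mean: float = 1.2
    suvr_baseline_sd: float = 0.1
    suvr_meas_sd: float = 0.02
    n_visits: int = 3
    visit_spacing: float = 1.5
    visit_jitter_sd: float = 0.0
    n_parcels: int = 0
    outlier_frac: float = 0.0
    outlier_noise_mult: float = 10.0
    heteroscedastic_rates: bool = False
    edu_mean: float = 16.0
    edu_sd: float = 2.5
    cog_params: CognitionGenParams = field(default_factory=CognitionGenParams)
    cohort_labels: Sequence[tuple[str, float]] = (("ADNI", 0.7), ("A05", 0.3))
    p_tracer_florbetapir: float = 0.75

    def validate(self) -> None:
        probs = {
            "p_female": self.p_female,
            "p_apoe4": self.p_apoe4,
            "p_abeta_pos": self.p_abeta_pos,
            "outlier_frac": self.outlier_frac,
            "p_tracer_florbetapir": self.p_tracer_florbetapir,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2 (longitudinal design)")
        if not self.cl_pos_low > self.cl_neg_mean:
            raise ValueError("cl_pos_low must exceed cl_neg_mean")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        fracs = np.array([f for _, f in self.cohort_labels], dtype=float)
        if fracs.size == 0 or abs(fracs.sum() - 1.0) > 1e-8:
            raise ValueError("cohort_labels fractions must sum to 1")


@dataclass
class SynthCohort:
    """A generated cohort: participant table, longitudinal series, and truth."""

    participants: pd.DataFrame
    tau_series: pd.DataFrame        # columns: id, time, roi, suvr
    cognition_series: pd.DataFrame  # columns: id, time, mmse, adas11
    truth: pd.DataFrame             # id, true_rate, true_time_shift, true_log_accel
    config: SynthConfig | None = None

    def write(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.tau_series.to_csv(out / "tau_series.csv", index=False)
        self.cognition_series.to_csv(out / "cognition_series.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    ids = np.array([f"S{i:05d}" for i in range(n)])
    female = rng.random(n) < config.p_female
    sex = np.where(female, "female", "male")
    age = _truncnorm(rng, config.age_mean, config.age_sd,
                     config.age_min, config.age_max, n)
    apoe4 = np.where(rng.random(n) < config.p_apoe4, "carrier", "noncarrier")
    education = np.clip(rng.normal(config.edu_mean, config.edu_sd, n), 8.0, 22.0)

    labels = [lab for lab, _ in config.cohort_labels]
    fracs = np.array([f for _, f in config.cohort_labels], dtype=float)
    cohort = rng.choice(labels, size=n, p=fracs / fracs.sum())

    # bimodal Centiloid distribution
    abeta_pos = rng.random(n) < config.p_abeta_pos
    cl = np.empty(n)
    n_neg = int((~abeta_pos).sum())
    cl[~abeta_pos] = _truncnorm(rng, config.cl_neg_mean, config.cl_neg_sd,
                                config.cl_neg_mean - 3 * config.cl_neg_sd,
                                min(config.cl_pos_low - 10.0,
                                    config.cl_neg_mean + 2 * config.cl_neg_sd),
                                n_neg)
    cl[abeta_pos] = rng.uniform(config.cl_pos_low, config.cl_pos_high,
                                int(abeta_pos.sum()))

    tracer = np.where(rng.random(n) < config.p_tracer_florbetapir,
                      "florbetapir", "florbetaben")
    suvr = np.empty(n)
    for trc, calib in DEFAULT_CALIBRATIONS.items():
        m = tracer == trc
        suvr[m] = (cl[m] - calib.intercept) / calib.slope

    # diagnosis: Aβ− mostly CN (a few impaired, to exercise the exclusion rule),
    # Aβ+ spread across the clinical spectrum
    diagnosis = np.empty(n, dtype=object)
    d_neg = rng.choice(["CN", "MCI", "dementia"], size=n_neg, p=[0.90, 0.08, 0.02])
    d_pos = rng.choice(["CN", "MCI", "dementia"], size=n - n_neg,
                       p=[0.50, 0.35, 0.15])
    diagnosis[~abeta_pos] = d_neg
    diagnosis[abeta_pos] = d_pos

    # true tau accumulation rate (temporal meta-ROI)
    slope = np.where(female, config.rate_slope_female, config.rate_slope_male)
    inter = np.where(female, config.interaction_female, config.interaction_male)
    noise_sd = np.full(n, config.rate_noise_sd)
    if config.heteroscedastic_rates:
        noise_sd = noise_sd * (1.0 + np.maximum(cl, 0.0) / 100.0)
    outlier = rng.random(n) < config.outlier_frac
    noise_sd = np.where(outlier, noise_sd * config.outlier_noise_mult, noise_sd)
    r = (config.rate_intercept
         + (slope + inter * (age - config.age_center)) * cl
         + rng.normal(0.0, 1.0, n) * noise_sd)

    participants = pd.DataFrame({
        "id": ids, "age": age, "sex": sex, "apoe4": apoe4,
        "diagnosis": diagnosis, "cohort": cohort, "education": education,
        "tracer": tracer, "amyloid_suvr": suvr,
    })

    # visit grid (strictly increasing per subject even with jitter)
    times = np.arange(config.n_visits) * config.visit_spacing
    t = np.tile(times, (n, 1))
    if config.visit_jitter_sd > 0:
        jit = rng.normal(0.0, config.visit_jitter_sd, t.shape)
        jit[:, 0] = 0.0
        t = t + jit
        t = np.maximum.accumulate(t + 1e-6 * np.arange(config.n_visits), axis=1)

    # tau series: temporal meta-ROI + global + optional parcels
    baseline = rng.normal(config.suvr_baseline_mean, config.suvr_baseline_sd, n)
    rois = {"temporal_meta": (baseline, r)}
    g_base = rng.normal(config.suvr_baseline_mean - 0.05,
                        config.suvr_baseline_sd, n)
    g_rate = 0.8 * r + rng.normal(0.0, 1.0, n) * 0.3 * noise_sd
    rois["global"] = (g_base, g_rate)
    for k in range(config.n_parcels):
        loading = rng.uniform(0.3, 1.2)
        p_base = rng.normal(config.suvr_baseline_mean, config.suvr_baseline_sd, n)
        p_rate = loading * r + rng.normal(0.0, 1.0, n) * noise_sd
        rois[f"parcel_{k:03d}"] = (p_base, p_rate)

    frames = []
    for roi, (b, rr) in rois.items():
        vals = b[:, None] + rr[:, None] * t
        vals = vals + rng.normal(0.0, config.suvr_meas_sd, vals.shape)
        frames.append(pd.DataFrame({
            "id": np.repeat(ids, config.n_visits),
            "time": t.ravel(),
            "roi": roi,
            "suvr": vals.ravel(),
        }))
    tau_series = pd.concat(frames, ignore_index=True)

    # cognition via the latent-time logistic model, onset tied to the rank-
    # normalized true rate (faster tau accumulation => earlier onset)
    cp = config.cog_params
    ranks = stats.rankdata(r)
    z = stats.norm.ppf(ranks / (n + 1.0))
    tau_shift = -cp.onset_tie * z + rng.normal(0.0, cp.tau_jitter_sd, n)
    xi = rng.normal(0.0, cp.xi_sd, n)

    lat = cp.v * np.exp(xi)[:, None] * (t - cp.t0 - tau_shift[:, None])
    y = cp.p_floor + (1.0 - cp.p_floor) / (1.0 + np.exp(-lat))
    mmse = np.clip(30.0 * (1.0 - y + rng.normal(0.0, cp.noise_sd, y.shape)),
                   0.0, 30.0)
    adas = np.clip(70.0 * (y + rng.normal(0.0, cp.noise_sd, y.shape)),
                   0.0, 70.0)
    cognition_series = pd.DataFrame({
        "id": np.repeat(ids, config.n_visits),
        "time": t.ravel(),
        "mmse": mmse.ravel(),
        "adas11": adas.ravel(),
    })

    truth = pd.DataFrame({
        "id": ids,
        "true_rate": r,
        "true_centiloid": cl,
        "true_abeta_pos": abeta_pos,
        "true_time_shift": tau_shift,
        "true_log_accel": xi,
        "is_outlier": outlier,
    })
    return SynthCohort(participants, tau_series, cognition_series, truth,
                       config=config)


def summarize_cohort(cohort: SynthCohort) -> pd.DataFrame:
    """Per sex × age-group summary (n, Centiloid, true rates, APOE, diagnosis).

    Every sex × age-group cell is reported; empty strata appear with n=0 and
    missing statistics.
    """
    if len(cohort.participants) == 0:
        raise ValueError("empty cohort")
    p = cohort.participants.merge(cohort.truth[["id", "true_rate"]], on="id")
    from .preprocess import centiloid_from_table

    cl = centiloid_from_table(p)
    p = p.assign(centiloid=cl, age_group=assign_age_group(p["age"]))

    rows = []
    for sex in ("male", "female"):
        for grp in ("le65", "65to80", "gt80"):
            cell = p[(p["sex"] == sex) & (p["age_group"] == grp)]
            n = len(cell)
            row = {"sex": sex, "age_group": grp, "n": n}
            if n > 0:
                row.update(
                    centiloid_mean=cell["centiloid"].mean(),
                    centiloid_sd=cell["centiloid"].std(),
                    rate_mean=cell["true_rate"].mean(),
                    rate_sd=cell["true_rate"].std(),
                    apoe4_carriers=int((cell["apoe4"] == "carrier").sum()),
                    n_cn=int((cell["diagnosis"] == "CN").sum()),
                    n_mci=int((cell["diagnosis"] == "MCI").sum()),
                    n_dementia=int((cell["diagnosis"] == "dementia").sum()),
                )
            else:
                row.update(centiloid_mean=np.nan, centiloid_sd=np.nan,
                           rate_mean=np.nan, rate_sd=np.nan,
                           apoe4_carriers=0, n_cn=0, n_mci=0, n_dementia=0)
            rows.append(row)
    return pd.DataFrame(rows)
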