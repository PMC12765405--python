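"""Per-subject annual rates of change from linear mixed models.

The model for one variable (a tau-PET ROI or a cognitive test) is

    value_ij = (b0 + u0_i) + (b1 + u1_i) * t_ij + eps_ij,
    (u0_i, u1_i) ~ N(0, G),  eps_ij ~ N(0, sigma^2),

with time measured in years since each subject's first visit of that
modality.  A subject's annual rate of change (ROC) is the fixed slope plus
the conditional (shrinkage/BLUP) estimate of the random slope.  Estimation is
REML with an unstructured 2x2 random-effect covariance; if REML fails or the
random-slope variance is on the boundary, the fit falls back to ML and then
to per-subject OLS slopes, each fall-back flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MixedModelFit", "fit_lmm_roc", "fit_cognitive_roc",
           "per_subject_ols_slopes"]


@dataclass
class MixedModelFit:
    variable: str
    fixed_intercept: float
    fixed_slope: float
    re_cov: np.ndarray            # 2x2 random-effect covariance
    residual_sd: float
    converged: bool
    method: str                   # "reml" | "ml" | "ols" | "exact"
    rejected_ids: list = field(default_factory=list)


def _center_time(series: pd.DataFrame) -> pd.DataFrame:
    t0 = series.groupby("id")["time"].transform("min")
    return series.assign(time=series["time"] - t0)


def per_subject_ols_slopes(series: pd.DataFrame, value_col: str = "value"
                           ) -> pd.DataFrame:
    """Two-or-more-point OLS slope per subject: id, slope, resid_ss, n_visits."""
    g = series.groupby("id", sort=False)
    tc = series["time"] - g["time"].transform("mean")
    yc = series[value_col] - g[value_col].transform("mean")
    num = (tc * yc).groupby(series["id"], sort=False).sum()
    den = (tc * tc).groupby(series["id"], sort=False).sum()
    slope = (num / den.where(den > 0)).rename("slope")
    resid = yc - slope.reindex(series["id"]).to_numpy() * tc
    out = pd.DataFrame({
        "slope": slope,
        "resid_ss": (resid * resid).groupby(series["id"], sort=False).sum(),
        "n_visits": g["time"].count(),
        "followup_span": g["time"].max() - g["time"].min(),
    })
    return out.reset_index().rename(columns={"index": "id"})


def fit_lmm_roc(series: pd.DataFrame, variable: str = "value",
                value_col: str = "value", method: str = "blup"
                ) -> tuple[MixedModelFit, pd.DataFrame]:
    """Fit the random-intercept-random-slope model and return per-subject ROCs.

    Parameters
    ----------
    series
        Long table with columns ``id``, ``time`` (years), and ``value_col``.
    method
        ``"blup"`` (default): ROC = fixed slope + conditional random-slope
        mode.  ``"ols"``: per-subject OLS slopes, no pooling.

    Returns
    -------
    (MixedModelFit, DataFrame) with columns id, variable, roc, n_visits,
    followup_span.  Subjects with fewer than two visits are excluded and
    listed on the fit's ``rejected_ids``.
    """
    counts = series.groupby("id")["time"].count()
    rejected = counts.index[counts < 2].tolist()
    if rejected:
        series = series[~series["id"].isin(rejected)]
    if series["id"].nunique() == 0:
        raise ValueError(f"{variable}: no subject has >= 2 visits")
    series = _center_time(series.sort_values(["id", "time"]))

    ols = per_subject_ols_slopes(series, value_col)
    meta = ols.set_index("id")

    def _result(roc_by_id: pd.Series, fit: MixedModelFit):
        est = pd.DataFrame({
            "id": meta.index,
            "variable": variable,
            "roc": roc_by_id.reindex(meta.index).to_numpy(),
            "n_visits": meta["n_visits"].to_numpy(),
            "followup_span": meta["followup_span"].to_numpy(),
        })
        fit.rejected_ids = rejected
        return fit, est

    scale = max(float(series[value_col].std()), 1e-12)
    exact = float(ols["resid_ss"].sum()) <= (1e-12 * scale) ** 2 * len(series)
    if method == "ols" or exact:
        fit = MixedModelFit(variable, float("nan"), float(ols["slope"].mean()),
                            np.zeros((2, 2)), 0.0, True,
                            "exact" if exact and method != "ols" else "ols")
        return _result(ols.set_index("id")["slope"], fit)

    import statsmodels.formula.api as smf

    df = series.rename(columns={value_col: "_y"})[["id", "time", "_y"]]
    for reml in (True, False):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("_y ~ time", df, groups=df["id"],
                                    re_formula="~time")
                res = model.fit(reml=reml, method=["lbfgs", "cg"])
            cov_re = np.asarray(res.cov_re)
            slope_var = cov_re[1, 1]
            total_var = float(df["_y"].var())
            boundary = (not res.converged) or slope_var < 1e-10 * max(
                total_var, 1e-12)
            if boundary:
                continue
            b0, b1 = float(res.params["Intercept"]), float(res.params["time"])
            re = res.random_effects
            roc = pd.Series({sid: b1 + float(eff.iloc[1])
                             for sid, eff in re.items()})
            fit = MixedModelFit(variable, b0, b1, cov_re,
                                float(np.sqrt(res.scale)), bool(res.converged),
                                "reml" if reml else "ml")
            return _result(roc, fit)
        except (np.linalg.LinAlgError, ValueError):
            continue

    # boundary / non-convergence fallback: no pooling
    fit = MixedModelFit(variable, float("nan"), float(ols["slope"].mean()),
                        np.zeros((2, 2)), float("nan"), False, "ols")
    return _result(ols.set_index("id")["slope"], fit)


def fit_tau_roc(tau_series: pd.DataFrame, rois: list[str] | None = None,
                method: str = "blup") -> tuple[dict, pd.DataFrame]:
    """ROC per subject for each requested tau ROI (all ROIs by default)."""
    rois = list(tau_series["roi"].unique()) if rois is None else rois
    fits, frames = {}, []
    for roi in rois:
        sub = tau_series.loc[tau_series["roi"] == roi,
                             ["id", "time", "suvr"]].rename(
            columns={"suvr": "value"})
        fit, est = fit_lmm_roc(sub, variable=roi, method=method)
        fits[roi] = fit
        frames.append(est)
    return fits, pd.concat(frames, ignore_index=True)


def fit_cognitive_roc(cognition_series: pd.DataFrame,
                      tests: tuple[str, ...] = ("mmse", "adas11"),
                      method: str = "blup") -> tuple[dict, pd.DataFrame]:
    """ROC per subject for each cognitive test (MMSE, ADAS-Cog11)."""
    fits, frames = {}, []
    for test in tests:
        sub = cognition_series[["id", "time", test]].rename(
            columns={test: "value"}).dropna()
        fit, est = fit_lmm_roc(sub, variable=test, method=method)
        fits[test] = fit
        frames.append(est)
    return fits, pd.concat(frames, ignore_index=True)
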