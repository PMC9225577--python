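"""Growth-curve fitting, respiration, and measured interaction strengths.

Growth curves are fit to the logistic model

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t)),

yielding the maximum growth rate r (1/h), carrying capacity K (OD units),
initial size N0 and doubling time ln(2)/r.

The sequential growth experiment cultures each recipient in the spent
medium of each influencer and in fresh defined medium.  The measured
interaction strength is the relative change in growth,

    MIS_ri = Growth_{r,i} / Growth_{r,SDM} - 1,

bounded below by -1 (the recipient did not grow at all in the spent
medium).  Growth is quantified by two metrics: blank-corrected final OD and
cumulative respiration (the drop in MicroResp indicator absorbance at
570 nm after baseline correction with uninoculated-medium controls).
Per-recipient Dunnett families (each spent medium vs. the SDM reference)
supply the significance flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import GrowthTable, TableValidationError
from .stats import dunnett_pvalues

SDM = "SDM"


@dataclass
class GrowthParams:
    r: float  # maximum growth rate, 1/h
    K: float  # carrying capacity, OD units
    N0: float  # initial size, OD units
    t_dd: float  # doubling time ln(2)/r, h
    rss: float  # residual sum of squares
    converged: bool
    no_growth: bool = False


def _logistic(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def fit_logistic(
    time_h: np.ndarray, od: np.ndarray, growth_threshold: float = 0.02
) -> GrowthParams:
    """Least-squares logistic fit of one OD600 time series.

    A series whose total rise is below ``growth_threshold`` (or that only
    declines) is flagged no-growth and left unparameterized rather than
    forced through the optimizer.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if len(t) < 8:
        raise ValueError("need >=8 time points to fit a growth curve")
    if (y < 0).any():
        raise ValueError("negative OD")
    rise = y.max() - y[0]
    if rise < growth_threshold or y.max() <= 0:
        return GrowthParams(np.nan, np.nan, np.nan, np.nan, np.nan,
                            converged=False, no_growth=True)

    # init: N0 = first obs, K = max obs, r from log-linear early phase
    n0 = max(y[0], 1e-6)
    k0 = y.max()
    early = y < n0 + 0.5 * rise
    if early.sum() >= 3 and (y[early] > 0).all():
        slope = np.polyfit(t[early], np.log(y[early] + 1e-9), 1)[0]
        r0 = float(np.clip(slope, 0.01, 5.0))
    else:
        r0 = 0.5
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            y,
            p0=[k0, n0, r0],
            bounds=([1e-6, 1e-9, 1e-4], [10 * k0 + 1.0, k0 + 1.0, 20.0]),
            maxfev=20000,
        )
        K, N0, r = (float(v) for v in popt)
        rss = float(np.sum((y - _logistic(t, *popt)) ** 2))
        return GrowthParams(r, K, N0, log(2.0) / r, rss, converged=True)
    except RuntimeError:
        return GrowthParams(np.nan, np.nan, np.nan, np.nan, np.nan,
                            converged=False, no_growth=False)


def fit_growth_table(growth: GrowthTable) -> pd.DataFrame:
    """Logistic parameters for every (isolate, medium, replicate) series."""
    rows = []
    for (iso, medium, rep), grp in growth.od.groupby(
        ["isolate", "medium", "replicate"], sort=True
    ):
        if iso == "":
            continue
        p = fit_logistic(grp["time_h"].to_numpy(), grp["od600"].to_numpy())
        rows.append(
            {
                "isolate": iso, "medium": medium, "replicate": rep,
                "r": p.r, "K": p.K, "N0": p.N0, "t_dd": p.t_dd,
                "rss": p.rss, "converged": p.converged, "no_growth": p.no_growth,
            }
        )
    return pd.DataFrame(rows)


def cumulative_respiration(
    a570_initial: float,
    a570_final: float,
    control_pairs: list[tuple[float, float]],
) -> float:
    """Baseline-corrected cumulative respiration from indicator absorbance.

    (A_initial - A_final) of the sample minus the mean (A_initial - A_final)
    over the matched uninoculated-medium control pairs.
    """
    if not control_pairs:
        raise ValueError("at least one uninoculated control pair required")
    sample_drop = a570_initial - a570_final
    ctrl_drop = float(np.mean([ci - cf for ci, cf in control_pairs]))
    return sample_drop - ctrl_drop


def measured_interaction(growth_in_spent: float, growth_in_sdm: float) -> float:
    """MIS = growth in spent medium / growth in fresh medium - 1 (>= -1)."""
    if not growth_in_sdm > 0:
        raise ValueError("growth in fresh medium must be positive")
    if growth_in_spent < 0:
        raise ValueError("growth in spent medium must be non-negative")
    return growth_in_spent / growth_in_sdm - 1.0


@dataclass
class MISMatrix:
    """Measured interaction strengths, recipients x influencers, one metric.

    ``significant`` marks entries whose per-recipient Dunnett comparison of
    spent-medium growth vs. the SDM reference fell at or below alpha;
    insignificant entries are retained but flagged.
    """

    values: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    metric: str
    alpha: float = 0.05


def _final_od_growth(growth: GrowthTable, blank_correct: bool = True) -> pd.DataFrame:
    """Per-series growth = final OD minus the matched uninoculated-medium
    control at the same (final) time point, clamped at 0."""
    finals = (
        growth.od.groupby(["isolate", "medium", "replicate"], sort=True)
        .apply(lambda g: g["od600"].iloc[-1], include_groups=False)
        .rename("growth")
        .reset_index()
    )
    blanks = finals[finals["isolate"] == ""]
    finals = finals[finals["isolate"] != ""].copy()
    if blank_correct and not blanks.empty:
        blank_mean = blanks.groupby("medium")["growth"].mean()
        corr = finals["medium"].map(blank_mean).fillna(0.0)
        finals["growth"] = (finals["growth"] - corr).clip(lower=0.0)
    return finals


def _respiration_growth(growth: GrowthTable) -> pd.DataFrame:
    """Per-series growth = control-corrected A570 drop, clamped at 0."""
    if growth.respiration is None:
        raise TableValidationError("no respiration table attached")
    resp = growth.respiration.copy()
    resp["drop"] = resp["a570_initial"] - resp["a570_final"]
    blanks = resp[resp["isolate"] == ""]
    samples = resp[resp["isolate"] != ""].copy()
    ctrl = blanks.groupby("medium")["drop"].mean() if not blanks.empty else pd.Series(dtype=float)
    corr = samples["medium"].map(ctrl).fillna(0.0)
    samples["growth"] = (samples["drop"] - corr).clip(lower=0.0)
    return samples[["isolate", "medium", "replicate", "growth"]]


def mis_matrix(
    growth: GrowthTable,
    alpha: float = 0.05,
    metric: str = "final_od",
    blank_correct: bool = True,
) -> MISMatrix:
    """MIS matrix with Dunnett significance flags for one growth metric.

    metric is "final_od" or "cumulative_respiration"; each recipient's spent
    media are tested as one Dunnett family against its SDM reference.
    """
    if metric == "final_od":
        per_series = _final_od_growth(growth, blank_correct=blank_correct)
    elif metric == "cumulative_respiration":
        per_series = _respiration_growth(growth)
    else:
        raise ValueError(f"unknown growth metric {metric!r}")

    recipients = sorted(per_series["isolate"].unique())
    influencers = sorted(
        m for m in per_series["medium"].unique() if m != SDM
    )
    values = pd.DataFrame(np.nan, index=recipients, columns=influencers)
    pvals = pd.DataFrame(np.nan, index=recipients, columns=influencers)

    for rec in recipients:
        sub = per_series[per_series["isolate"] == rec]
        sdm = sub.loc[sub["medium"] == SDM, "growth"].to_numpy()
        if sdm.size == 0:
            raise TableValidationError(f"recipient {rec!r} has no SDM reference")
        media = [m for m in influencers if (sub["medium"] == m).any()]
        groups = [sub.loc[sub["medium"] == m, "growth"].to_numpy() for m in media]
        if not media:
            continue
        p = dunnett_pvalues(groups, sdm)
        sdm_mean = float(sdm.mean())
        for m, g, p_i in zip(media, groups, p):
            pvals.loc[rec, m] = p_i
            if sdm_mean > 0:
                values.loc[rec, m] = measured_interaction(float(g.mean()), sdm_mean)

    significant = (pvals <= alpha) & values.notna()
    return MISMatrix(values, pvals, significant, metric=metric, alpha=alpha)
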