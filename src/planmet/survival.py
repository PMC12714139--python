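"""Kaplan-Meier lifespan statistics and the log-rank test.

The product-limit estimator handles right-censoring with the standard
deaths-before-censorings tie convention.  Two summary ages follow the fly
lifespan-assay definitions:

* median lifespan — the age at which the survival curve drops to 50%,
  i.e. the smallest event time t with S(t) <= 0.5, without interpolation;
* maximum lifespan — the median death time of the longest-lived 10% of
  individuals (ceil(0.1 * n_deaths) deaths, censored flies excluded since
  their lifespans are unknown).

Group comparisons use the unweighted log-rank test: at each distinct
death time the observed deaths in group A are compared with the
hypergeometric expectation d * n_A / n, and the chi-squared statistic
(O - E)^2 / V on 1 degree of freedom sums the variance over death times.
Multi-arm designs are compared pairwise against a control arm with
unadjusted p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, validate_survival

__all__ = ["SurvivalCurve", "LogRankResult", "km_curve", "median_lifespan",
           "max_lifespan", "logrank_test", "survival_summary"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate: one row per distinct event (death or
    censoring) time with the at-risk count, deaths, censorings and S(t)."""

    table: pd.DataFrame     # columns: time, n_at_risk, deaths, censored, S

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    @property
    def survival(self) -> np.ndarray:
        return self.table["S"].to_numpy()


def _collapse(records: pd.DataFrame) -> pd.DataFrame:
    t = records["time"].to_numpy(dtype=float)
    dead = (records["status"] == "dead").to_numpy()
    frame = pd.DataFrame({"time": t, "deaths": dead.astype(int),
                          "censored": (~dead).astype(int)})
    return frame.groupby("time", sort=True).sum().reset_index()


def km_curve(records: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier curve for one group of individuals."""
    records = validate_survival(records)
    if not (records["status"] == "dead").any():
        raise ValidationError("no events: all records are censored")
    grouped = _collapse(records)
    n = len(records)
    at_risk = np.empty(len(grouped), dtype=int)
    s = np.empty(len(grouped))
    surv = 1.0
    for i, row in grouped.iterrows():
        at_risk[i] = n
        d = int(row["deaths"])
        if d:
            surv *= 1.0 - d / n          # deaths processed before censorings
        s[i] = surv
        n -= d + int(row["censored"])
    grouped["n_at_risk"] = at_risk
    grouped["S"] = s
    return SurvivalCurve(
        grouped[["time", "n_at_risk", "deaths", "censored", "S"]])


def median_lifespan(curve: SurvivalCurve) -> float:
    """Smallest event time at which S(t) <= 0.5; NaN when never reached."""
    below = curve.table.loc[curve.table["S"] <= 0.5, "time"]
    return float(below.iloc[0]) if len(below) else math.nan


def max_lifespan(records: pd.DataFrame) -> float:
    """Median death time of the longest-lived 10% (ceil rounding) of the
    uncensored individuals."""
    records = validate_survival(records)
    deaths = np.sort(records.loc[records["status"] == "dead",
                                 "time"].to_numpy(dtype=float),
                     kind="stable")
    if deaths.size == 0:
        raise ValidationError("no deaths: maximum lifespan undefined")
    top = deaths[-math.ceil(0.10 * deaths.size):]
    return float(np.median(top))


@dataclass
class LogRankResult:
    chi_squared: float
    df: int
    p: float


def logrank_test(records_a: pd.DataFrame,
                 records_b: pd.DataFrame) -> LogRankResult:
    """Unweighted two-group log-rank test (chi-squared, 1 df)."""
    a = validate_survival(records_a)
    b = validate_survival(records_b)
    for name, rec in (("A", a), ("B", b)):
        if not (rec["status"] == "dead").any():
            raise ValidationError(f"group {name} has no deaths")
    chi = _logrank_chi2(
        a["time"].to_numpy(float), (a["status"] == "dead").to_numpy(),
        b["time"].to_numpy(float), (b["status"] == "dead").to_numpy())
    return LogRankResult(chi, 1, float(stats.chi2.sf(chi, 1)))


def _logrank_chi2(ta: np.ndarray, da: np.ndarray,
                  tb: np.ndarray, db: np.ndarray) -> float:
    """Vectorised log-rank chi-squared from raw times/death flags."""
    times = np.concatenate([ta, tb])
    dead = np.concatenate([da, db]).astype(bool)
    in_a = np.zeros(times.size, dtype=bool)
    in_a[:ta.size] = True
    death_times = np.unique(times[dead])
    # risk sets: individuals with time >= t (deaths-first tie handling
    # keeps same-time censorings in the risk set, matching >=)
    n_at = (times[None, :] >= death_times[:, None])
    n_tot = n_at.sum(axis=1).astype(float)
    n_a = (n_at & in_a[None, :]).sum(axis=1).astype(float)
    is_death_here = dead[None, :] & (times[None, :] == death_times[:, None])
    d_tot = is_death_here.sum(axis=1).astype(float)
    d_a = (is_death_here & in_a[None, :]).sum(axis=1).astype(float)
    exp_a = d_tot * n_a / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(n_tot > 1,
                       d_tot * (n_a / n_tot) * (1 - n_a / n_tot)
                       * (n_tot - d_tot) / (n_tot - 1), 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d_a.sum() - exp_a.sum()) ** 2 / v)


def survival_summary(records: pd.DataFrame, control: str | None = None,
                     ) -> dict[str, dict]:
    """Per-group curve summaries plus pairwise log-rank tests against a
    control arm (unadjusted p, as in dose-vs-control comparisons)."""
    records = validate_survival(records)
    groups = sorted(records["group"].unique())
    if control is None:
        control = groups[0]
    if control not in groups:
        raise ValidationError(f"control group {control!r} not present")
    out: dict[str, dict] = {}
    by_group = {g: records.loc[records["group"] == g] for g in groups}
    for g in groups:
        curve = km_curve(by_group[g])
        med = median_lifespan(curve)
        out[g] = {
            "n": int(len(by_group[g])),
            "deaths": int((by_group[g]["status"] == "dead").sum()),
            "median_lifespan": med if not math.isnan(med) else None,
            "max_lifespan": max_lifespan(by_group[g]),
        }
    for g in groups:
        if g == control:
            continue
        lr = logrank_test(by_group[control], by_group[g])
        out[g]["logrank_vs_control"] = {
            "chi_squared": lr.chi_squared, "df": lr.df, "p": lr.p}
    return out
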