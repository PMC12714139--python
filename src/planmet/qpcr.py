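"""ΔΔCt relative quantification with a reference-gene stability check.

Per replicate, ΔCt = Ct_target - Ct_reference; ΔΔCt subtracts the mean
ΔCt of the calibrator condition; relative quantification RQ = 2^-ΔΔCt
(amplification efficiency fixed at 2, the classic assumption).  The mean
calibrator ΔΔCt is 0 by construction, so the calibrator's geometric-mean
RQ is exactly 1.  Per-replicate RQ values are retained for error bars and
downstream factorial testing.

``reference_stability`` checks the normaliser gene: a two-factor ANOVA of
its raw Ct on treatment x age, with stability declared when no effect is
significant (a perfectly constant reference short-circuits to stable with
all p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError, validate_ct
from .differential import two_way_anova
from .simulate import condition_label

__all__ = ["RQResult", "compute_rq", "reference_stability",
           "ReferenceStability"]

COND_KEY = ["treatment", "age_days"]


@dataclass
class RQResult:
    """Per-replicate ΔCt/ΔΔCt/RQ plus per-condition mean RQ and s.e.m."""

    per_replicate: pd.DataFrame
    per_condition: pd.DataFrame
    calibrator: str


def compute_rq(table: pd.DataFrame, calibrator: str) -> RQResult:
    """Relative expression of the target gene per condition.

    ``calibrator`` is a condition label ``"<treatment>_d<age>"`` (see
    :func:`planmet.simulate.condition_label`).  Every (condition,
    replicate) must carry both a target and a reference well.
    """
    table = validate_ct(table)
    tgt = table.loc[table["role"] == "target"]
    ref = table.loc[table["role"] == "reference"]
    key = COND_KEY + ["replicate"]
    merged = tgt.merge(ref[key + ["ct"]], on=key, how="left",
                       suffixes=("_target", "_reference"))
    if merged["ct_reference"].isna().any():
        bad = merged.loc[merged["ct_reference"].isna(),
                         ["sample_id"] + COND_KEY].iloc[0]
        raise ValidationError(
            f"missing reference well for sample {bad['sample_id']!r}, "
            f"condition ({bad['treatment']}, day {bad['age_days']})")
    merged["condition"] = [
        condition_label(t, a) for t, a in
        zip(merged["treatment"], merged["age_days"])]
    merged["dct"] = merged["ct_target"] - merged["ct_reference"]
    cal = merged.loc[merged["condition"] == calibrator, "dct"]
    if cal.empty:
        raise ValidationError(
            f"calibrator condition {calibrator!r} not present; available: "
            f"{sorted(merged['condition'].unique())}")
    merged["ddct"] = merged["dct"] - cal.mean()
    merged["rq"] = 2.0 ** (-merged["ddct"])
    per_rep = merged[["condition", "treatment", "age_days", "replicate",
                      "dct", "ddct", "rq"]].sort_values(
        ["condition", "replicate"], kind="mergesort").reset_index(drop=True)
    summary = per_rep.groupby("condition", sort=True).agg(
        mean_rq=("rq", "mean"),
        sem_rq=("rq", lambda v: v.std(ddof=1) / np.sqrt(len(v))
                if len(v) > 1 else 0.0),
        n=("rq", "size")).reset_index()
    return RQResult(per_rep, summary, calibrator)


@dataclass
class ReferenceStability:
    p_treatment: float
    p_age: float
    p_interaction: float
    stable: bool


def reference_stability(table: pd.DataFrame,
                        alpha: float = 0.05) -> ReferenceStability:
    """Two-factor ANOVA of the reference gene's Ct on treatment x age.

    Stability means no effect p-value below ``alpha``.  A constant
    reference Ct has zero variance everywhere and is declared stable with
    all p = 1 by convention.
    """
    table = validate_ct(table)
    ref = table.loc[table["role"] == "reference"]
    for col in COND_KEY:
        if ref[col].nunique() < 2:
            raise ValidationError(
                f"reference Ct needs >= 2 levels of {col!r}")
    if np.ptp(ref["ct"].to_numpy()) == 0:
        return ReferenceStability(1.0, 1.0, 1.0, True)
    res = two_way_anova(ref["ct"], ref["treatment"], ref["age_days"])
    ps = {eff: res.p(eff) for eff in ("treatment", "age", "interaction")}
    return ReferenceStability(
        ps["treatment"], ps["age"], ps["interaction"],
        stable=all(p > alpha for p in ps.values()))
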