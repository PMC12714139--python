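"""Feature retention filtering and preprocessing transforms.

A feature (metabolite) survives quality control when it is

(a) present — intensity strictly positive — in *every* sample of at least
    one experimental group, where a group is the finest design cell
    (tissue x genotype x treatment x age); and
(b) at least ``blank_fold`` (default 5) times more abundant, on average
    across all study samples, than in the extraction blanks.

Zeros encode missing measurements, so criterion (a) reads "detected in all
samples of some condition".  A blank mean of zero makes the ratio +inf and
the feature passes (b) trivially.  Whether the blank comparison should use
means, medians or maxima is not pinned down by convention; the mean/mean
ratio used here is recorded per feature in the report for audit.

After filtering, multivariate analysis expects ``log10_transform`` (zeros
imputed to half the feature's minimum positive value) followed by
``uv_scale`` (per-feature centring and unit-variance scaling, n-1
denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, ConfigError, ValidationError

__all__ = ["FilterReport", "filter_features", "log10_transform", "uv_scale"]

GROUP_KEY = ["tissue", "genotype", "treatment", "age_days"]


@dataclass
class FilterReport:
    """Per-feature filter outcome.

    ``table`` columns: metabolite, kept (0/1), reason (kept /
    absent_in_all_groups / below_blank_fold), presence_group (the first
    design cell in which the feature was detected in every sample, empty if
    none), blank_ratio (mean study abundance / mean blank abundance).
    """

    table: pd.DataFrame
    blank_fold: float

    @property
    def kept_ids(self) -> list[str]:
        return self.table.loc[self.table["kept"] == 1, "metabolite"].tolist()


def filter_features(matrix: AbundanceMatrix, blank_fold: float = 5.0,
                    ) -> tuple[AbundanceMatrix, FilterReport]:
    """Apply the presence + blank-ratio retention rule.

    Returns the retained matrix with blank samples removed, plus the
    per-feature report.  Requires at least one blank sample.
    """
    if blank_fold <= 0:
        raise ConfigError("blank_fold must be positive")
    blanks = matrix.blank_mask()
    if not blanks.any():
        raise ConfigError("no blank samples present; the retention rule "
                          "needs extraction blanks")
    x = matrix.intensities
    study = x[:, ~blanks]
    sheet = matrix.sheet.loc[~blanks]

    # criterion (a): positive in every sample of >= 1 design cell
    groups = sheet.groupby(GROUP_KEY, sort=True).indices
    present_group = np.full(x.shape[0], "", dtype=object)
    present = np.zeros(x.shape[0], dtype=bool)
    for key in sorted(groups):
        idx = groups[key]
        all_pos = (study[:, idx] > 0).all(axis=1)
        newly = all_pos & ~present
        present_group[newly] = "/".join(map(str, key))
        present |= all_pos

    # criterion (b): mean over study samples vs mean over blanks
    study_mean = study.mean(axis=1)
    blank_mean = x[:, blanks].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(blank_mean > 0, study_mean / blank_mean, np.inf)
    above = ratio >= blank_fold

    kept = present & above
    reason = np.where(kept, "kept",
                      np.where(~present, "absent_in_all_groups",
                               "below_blank_fold"))
    report = FilterReport(pd.DataFrame({
        "metabolite": matrix.metabolite_ids,
        "kept": kept.astype(int),
        "reason": reason,
        "presence_group": present_group,
        "blank_ratio": ratio,
    }), blank_fold=blank_fold)

    kept_ids = [m for m, k in zip(matrix.metabolite_ids, kept) if k]
    study_ids = [s for s, b in zip(matrix.sample_ids, blanks) if not b]
    filtered = AbundanceMatrix(
        kept_ids, study_ids,
        x[np.ix_(kept, ~blanks)], matrix.sample_sheet, stage=matrix.stage)
    return filtered, report


def log10_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log10-transform intensities, imputing zeros per feature to half the
    feature's minimum positive value.  A feature that is zero everywhere
    should have been filtered and raises."""
    x = matrix.intensities.copy()
    all_zero = ~(x > 0).any(axis=1)
    if all_zero.any():
        bad = [m for m, z in zip(matrix.metabolite_ids, all_zero) if z]
        raise ValidationError(
            f"features with no positive value (run filter_features first): "
            f"{bad[:10]}")
    for i in np.nonzero((x == 0).any(axis=1))[0]:
        row = x[i]
        row[row == 0] = row[row > 0].min() / 2.0
    return matrix.with_values(np.log10(x), stage="log10")


def uv_scale(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Unit-variance scale each feature across samples (subtract the mean,
    divide by the n-1 standard deviation).  Constant features raise, named."""
    x = matrix.intensities
    sd = x.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = [m for m, z in zip(matrix.metabolite_ids, zero) if z]
        raise ValidationError(f"zero-variance features: {bad[:10]}")
    scaled = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return matrix.with_values(scaled, stage="uv")
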