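"""Per-metabolite inferential statistics.

The central test is a classical balanced two-factor ANOVA of each
metabolite's log10 abundance on treatment x age with interaction,
followed by Tukey's HSD across the treatment x age cell means.  A
metabolite counts as responsive when the *interaction* p-value falls below
alpha — a treatment whose effect grows with age — and the cross-genotype
classification (shared / exclusive to either genotype / neither) compares
those flags between the two mutant lines.

Only balanced designs are accepted: the emulated study is 2 treatments x
4 ages x 3 replicates, and for unbalanced data the sum-of-squares
decomposition is ambiguous (Type I/II/III), so unbalance is a hard error
rather than a silent choice.

A Shapiro-Wilk-gated univariate route is also provided
(:func:`two_group_test`): normally distributed groups get Welch's
unpaired two-tailed t-test, skewed ones the Mann-Whitney test.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .io import AbundanceMatrix, ValidationError

__all__ = [
    "AnovaResult", "TwoGroupResult", "two_way_anova", "two_way_anova_matrix",
    "tukey_hsd", "tukey_sf", "shapiro_wilk", "two_group_test",
    "differential_table", "classify_overlap", "CLASS_LABELS",
]

CLASS_LABELS = ("shared", "genotypeA_only", "genotypeB_only", "neither")
EFFECTS = ("treatment", "age", "interaction", "residual")


@dataclass
class AnovaResult:
    """Two-factor decomposition: one row per effect with ss, df, ms, F, p."""

    table: pd.DataFrame

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def _codes(labels) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(np.asarray(labels)))
    lookup = {lv: i for i, lv in enumerate(levels)}
    return np.array([lookup[v] for v in np.asarray(labels)]), levels


def two_way_anova_matrix(values: np.ndarray, treatment_labels,
                         age_labels) -> dict[str, np.ndarray]:
    """Vectorised balanced two-factor ANOVA over many response rows.

    ``values`` is (n_rows, n_obs); labels have length n_obs.  Returns a
    dict of per-row arrays ``ss_*``, ``df_*`` (scalars), ``F_*`` and
    ``p_*`` for treatment, age and interaction, plus residual terms.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    t_code, t_levels = _codes(treatment_labels)
    a_code, a_levels = _codes(age_labels)
    n = y.shape[1]
    if len(t_code) != n or len(a_code) != n:
        raise ValidationError("label length does not match observations")
    T, A = len(t_levels), len(a_levels)
    cell = t_code * A + a_code
    counts = np.bincount(cell, minlength=T * A)
    if counts.min() != counts.max():
        raise ValidationError(
            "unbalanced design (unequal replicates per treatment x age "
            "cell); this implementation supports balanced designs only — "
            "see the documented limitation")
    r = int(counts[0])
    df_resid = n - T * A
    if df_resid <= 0:
        raise ValidationError(
            "zero residual degrees of freedom: need >= 2 replicates/cell")

    grand = y.mean(axis=1, keepdims=True)
    dev = y - grand
    ss_total = (dev ** 2).sum(axis=1)

    def _group_ss(code: np.ndarray, k: int) -> np.ndarray:
        # sum over levels of N_level * (level mean - grand)^2
        onehot = np.zeros((n, k))
        onehot[np.arange(n), code] = 1.0
        nper = onehot.sum(axis=0)
        means = (y @ onehot) / nper
        return (nper * (means - grand) ** 2).sum(axis=1)

    ss_t = _group_ss(t_code, T) if T > 1 else np.zeros(y.shape[0])
    ss_a = _group_ss(a_code, A) if A > 1 else np.zeros(y.shape[0])
    ss_cells = _group_ss(cell, T * A)
    ss_i = np.maximum(ss_cells - ss_t - ss_a, 0.0)
    ss_r = np.maximum(ss_total - ss_cells, 0.0)

    df_t, df_a = T - 1, A - 1
    df_i = df_t * df_a
    ms_r = ss_r / df_resid
    out: dict[str, np.ndarray] = {
        "ss_treatment": ss_t, "ss_age": ss_a, "ss_interaction": ss_i,
        "ss_residual": ss_r, "ss_total": ss_total,
        "df_treatment": df_t, "df_age": df_a, "df_interaction": df_i,
        "df_residual": df_resid, "ms_residual": ms_r,
        "n_per_cell": r, "n_cells": T * A,
    }
    for name, ss, df in (("treatment", ss_t, df_t), ("age", ss_a, df_a),
                         ("interaction", ss_i, df_i)):
        if df > 0:
            f = (ss / df) / ms_r
            out[f"F_{name}"] = f
            out[f"p_{name}"] = stats.f.sf(f, df, df_resid)
        else:
            out[f"F_{name}"] = np.full(y.shape[0], np.nan)
            out[f"p_{name}"] = np.full(y.shape[0], np.nan)
    return out


def two_way_anova(values, treatment_labels, age_labels) -> AnovaResult:
    """Balanced two-factor ANOVA with interaction for one response vector."""
    res = two_way_anova_matrix(np.asarray(values, float)[None, :],
                               treatment_labels, age_labels)
    rows = []
    for eff in ("treatment", "age", "interaction"):
        ss = float(res[f"ss_{eff}"][0])
        df = int(res[f"df_{eff}"])
        rows.append((eff, ss, df, ss / df if df else np.nan,
                     float(res[f"F_{eff}"][0]), float(res[f"p_{eff}"][0])))
    ss_r = float(res["ss_residual"][0])
    df_r = int(res["df_residual"])
    rows.append(("residual", ss_r, df_r, ss_r / df_r, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["effect", "ss", "df", "ms", "F", "p"]
                         ).set_index("effect")
    return AnovaResult(table)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=32)
def _tukey_grid(k: int, df: int, qmax: float) -> PchipInterpolator:
    # monotone interpolant of log sf on a dense grid; used only for large
    # batches where per-point quadrature would dominate runtime
    qs = np.linspace(0.0, qmax, 801)
    sf = stats.studentized_range.sf(qs[1:], k, df)
    logsf = np.concatenate([[0.0], np.log(np.maximum(sf, 1e-300))])
    return PchipInterpolator(qs, np.minimum.accumulate(logsf))


def tukey_sf(q, k: int, df: int) -> np.ndarray | float:
    """Survival function of the studentized range; exact quadrature for
    small batches, cached monotone interpolation for large ones."""
    q = np.asarray(q, dtype=float)
    if q.size <= 64:
        return stats.studentized_range.sf(q, k, df)
    qmax = float(max(25.0, np.ceil(q.max()) + 1.0))
    interp = _tukey_grid(int(k), int(df), qmax)
    return np.exp(interp(np.clip(q, 0.0, qmax)))


def tukey_hsd(cell_means, n_per_cell: int, ms_residual: float,
              df_residual: int, labels=None) -> pd.DataFrame:
    """Tukey's HSD over a set of balanced cell means.

    q = |m_i - m_j| / sqrt(ms_residual / n_per_cell); the adjusted p comes
    from the studentized-range distribution with k = number of cells.
    Returns one row per unordered pair.
    """
    means = np.asarray(cell_means, dtype=float)
    k = means.size
    if df_residual < 1:
        raise ValidationError("df_residual must be >= 1")
    if labels is None:
        labels = [str(i) for i in range(k)]
    se = np.sqrt(ms_residual / n_per_cell)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_residual)
                      ) if np.isfinite(q) else 0.0
            rows.append((labels[i], labels[j], diff, q, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "diff",
                                       "q", "p_adj"])


# ---------------------------------------------------------------------------
# univariate route
# ---------------------------------------------------------------------------

def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValidationError(
            f"Shapiro-Wilk defined for 3 <= n <= 5000, got n={values.size}")
    w, p = stats.shapiro(values)
    return float(w), float(p)


@dataclass
class TwoGroupResult:
    test: str           # "t", "mannwhitney" or "tied"
    statistic: float
    p: float
    all_tied: bool = False


def two_group_test(values_a, values_b, alpha: float = 0.05) -> TwoGroupResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run on each group at ``alpha``; if both pass, an
    unpaired two-tailed t-test (Welch) is used, otherwise the two-sided
    Mann-Whitney test (exact enumeration for n <= 20 without ties, normal
    approximation with tie correction above).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied in both groups; p set to 1")
        return TwoGroupResult("tied", np.nan, 1.0, all_tied=True)
    normal = (np.ptp(a) > 0 and np.ptp(b) > 0
              and shapiro_wilk(a)[1] > alpha and shapiro_wilk(b)[1] > alpha)
    if normal:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return TwoGroupResult("t", float(t), float(p))
    u, p = _mann_whitney(a, b)
    return TwoGroupResult("mannwhitney", float(u), float(p))


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney: exact enumeration for n <= 20 without ties,
    otherwise normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) \
        else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(u), float(p)


# ---------------------------------------------------------------------------
# pipeline table + cross-genotype classification
# ---------------------------------------------------------------------------

def differential_table(matrix: AbundanceMatrix, genotype: str,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-(tissue, metabolite) two-factor ANOVA for one genotype.

    ``matrix`` should hold log10-transformed study samples (blanks already
    removed).  Returns one row per (tissue, metabolite) with the full
    decomposition and the interaction significance flag.
    """
    sheet = matrix.sheet
    frames = []
    for tissue in sorted(sheet.loc[~sheet["is_blank"], "tissue"].unique()):
        mask = ((sheet["tissue"] == tissue)
                & (sheet["genotype"] == genotype)
                & (~sheet["is_blank"])).to_numpy()
        if not mask.any():
            continue
        sub = sheet.loc[mask]
        res = two_way_anova_matrix(matrix.intensities[:, mask],
                                   sub["treatment"], sub["age_days"])
        frame = pd.DataFrame({
            "tissue": tissue,
            "genotype": genotype,
            "metabolite": matrix.metabolite_ids,
        })
        for eff in ("treatment", "age", "interaction"):
            frame[f"ss_{eff}"] = res[f"ss_{eff}"]
            frame[f"F_{eff}"] = res[f"F_{eff}"]
            frame[f"p_{eff}"] = res[f"p_{eff}"]
        frame["ss_residual"] = res["ss_residual"]
        frame["ms_residual"] = res["ms_residual"]
        frame["significant"] = (frame["p_interaction"] < alpha).astype(int)
        frames.append(frame)
    if not frames:
        raise ValidationError(f"no samples for genotype {genotype!r}")
    return pd.concat(frames, ignore_index=True)


def tukey_treatment_contrasts(matrix: AbundanceMatrix, genotype: str,
                              ) -> pd.DataFrame:
    """Within-age control-vs-DA contrasts, Tukey-adjusted across all
    treatment x age cell means (the comparisons figure panels annotate)."""
    sheet = matrix.sheet
    rows = []
    for tissue in sorted(sheet.loc[~sheet["is_blank"], "tissue"].unique()):
        mask = ((sheet["tissue"] == tissue)
                & (sheet["genotype"] == genotype)
                & (~sheet["is_blank"])).to_numpy()
        if not mask.any():
            continue
        sub = sheet.loc[mask]
        y = matrix.intensities[:, mask]
        res = two_way_anova_matrix(y, sub["treatment"], sub["age_days"])
        ages = sorted(sub["age_days"].unique())
        k = res["n_cells"]
        df_r = int(res["df_residual"])
        se = np.sqrt(res["ms_residual"] / res["n_per_cell"])
        for age in ages:
            ctrl = ((sub["treatment"] == "control")
                    & (sub["age_days"] == age)).to_numpy()
            trt = ((sub["treatment"] == "DA")
                   & (sub["age_days"] == age)).to_numpy()
            diff = y[:, trt].mean(axis=1) - y[:, ctrl].mean(axis=1)
            q = np.abs(diff) / se
            p = np.minimum(np.asarray(tukey_sf(q, k, df_r)), 1.0)
            rows.append(pd.DataFrame({
                "tissue": tissue, "genotype": genotype, "age_days": age,
                "metabolite": matrix.metabolite_ids,
                "diff_log10": diff, "q": q, "p_adj": p,
            }))
    return pd.concat(rows, ignore_index=True)


def classify_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Cross-genotype classification per (tissue, metabolite).

    ``shared`` when the interaction is significant in both genotypes,
    ``genotypeA_only``/``genotypeB_only`` when in exactly one, else
    ``neither``.  The two tables must cover the same universe.
    """
    key = ["tissue", "metabolite"]
    a = table_a.set_index(key)["p_interaction"]
    b = table_b.set_index(key)["p_interaction"]
    sym = set(a.index.tolist()) ^ set(b.index.tolist())
    if sym:
        raise ValidationError(
            f"tables cover different (tissue, metabolite) universes; "
            f"symmetric difference: {sorted(sym)[:10]}")
    b = b.reindex(a.index)
    sig_a = (a < alpha).to_numpy()
    sig_b = (b < alpha).to_numpy()
    cls = np.where(sig_a & sig_b, "shared",
                   np.where(sig_a, "genotypeA_only",
                            np.where(sig_b, "genotypeB_only", "neither")))
    out = a.index.to_frame(index=False)
    out["sig_A"] = sig_a.astype(int)
    out["sig_B"] = sig_b.astype(int)
    out["classification"] = cls
    return out
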