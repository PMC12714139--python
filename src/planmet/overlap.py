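"""Cross-genotype overlap: is the shared significant set bigger than chance?

For each tissue, count the metabolites whose treatment x age interaction
is significant in each genotype and the overlap k between the two sets.
The chance probability that a *single* metabolite is significant in both
genotypes is, under the default independence null,

    p_single = (n_sig_A / n_total) * (n_sig_B / n_total),

and the likelihood that k metabolites overlap by chance is the simple
multiple-event product ``p_single ** k`` (e.g. p_single = 0.1 and k = 10
gives 1e-10, i.e. 0.00000001%).  A ``conditional`` mode reproduces the
literal chain rule p(A) * p(B|A) when a conditional probability is
supplied externally — note that with p(B|A) estimated from the same data
the identity is tautological, which is why independence is the default
null.  Because the p^k rule ignores the without-replacement structure of
drawing from a finite panel, a hypergeometric tail probability and an
optional permutation check are reported alongside it (never replacing it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = ["single_overlap_probability", "multi_overlap_likelihood",
           "format_percent", "overlap_report", "TissueOverlap"]


def single_overlap_probability(n_sig_a: int, n_sig_b: int, n_total: int,
                               mode: str = "independence",
                               p_conditional: float | None = None) -> float:
    """Chance probability that one metabolite is significant in both
    genotypes."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not (0 <= n_sig_a <= n_total and 0 <= n_sig_b <= n_total):
        raise ValidationError(
            f"significant counts ({n_sig_a}, {n_sig_b}) must lie in "
            f"[0, {n_total}]")
    if mode == "independence":
        return (n_sig_a / n_total) * (n_sig_b / n_total)
    if mode == "conditional":
        if p_conditional is None:
            raise ValidationError("conditional mode requires p_conditional")
        if not 0 <= p_conditional <= 1:
            raise ValidationError("p_conditional must be in [0,1]")
        return (n_sig_a / n_total) * p_conditional
    raise ValidationError(f"unknown mode {mode!r}")


def _check_pk(p_single: float, k: int) -> None:
    if not 0 <= p_single <= 1:
        raise ValidationError("p_single must be in [0,1]")
    if not isinstance(k, (int, np.integer)) or k < 0:
        raise ValidationError("k must be a non-negative integer")


def multi_overlap_likelihood(p_single: float, k: int) -> float:
    """Probability that k metabolites overlap by chance: p_single ** k.

    Computed in log space; use :func:`log10_multi_overlap_likelihood` when
    the product falls below the smallest representable float (reports
    always carry the log10 value alongside).
    """
    _check_pk(p_single, k)
    if k == 0:
        return 1.0
    if p_single == 0:
        return 0.0
    return math.exp(k * math.log(p_single))


def log10_multi_overlap_likelihood(p_single: float, k: int) -> float:
    """log10 of p_single ** k, exact for any k (no underflow)."""
    _check_pk(p_single, k)
    if k == 0:
        return 0.0
    if p_single == 0:
        return -math.inf
    return k * math.log10(p_single)


def format_percent(p: float, sig_figs: int = 2) -> str:
    """Probability as a percentage string rounded to 2 significant
    figures (e.g. 1e-10 -> '1.0e-08%')."""
    return f"{p * 100:.{sig_figs - 1}e}%"


@dataclass
class TissueOverlap:
    tissue: str
    n_total: int
    n_sig_a: int
    n_sig_b: int
    k: int
    p_single: float
    chance_likelihood: float
    log10_chance_likelihood: float
    chance_likelihood_percent: str
    hypergeom_p: float
    mode: str
    permutation_p: float | None = None


def overlap_report(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   alpha: float = 0.05, mode: str = "independence",
                   p_conditional: float | None = None,
                   permutation_reps: int = 0, seed: int = 0,
                   ) -> dict[str, TissueOverlap]:
    """Per-tissue overlap statistics from two per-genotype differential
    tables (columns tissue, metabolite, p_interaction).

    ``permutation_reps > 0`` additionally estimates, by shuffling each
    genotype's significance labels across the shared universe, the chance
    that the k metabolites observed to overlap would all be significant in
    both genotypes — the without-replacement analogue of p_single ** k.
    """
    rng = np.random.default_rng(seed)
    key = ["tissue", "metabolite"]
    a = table_a.set_index(key)["p_interaction"]
    b = table_b.set_index(key)["p_interaction"]
    out: dict[str, TissueOverlap] = {}
    tissues = sorted(table_a["tissue"].unique())
    for tissue in tissues:
        ai = a.loc[tissue]
        bi = b.loc[tissue] if tissue in b.index.get_level_values(0) else None
        if bi is None or set(ai.index) != set(bi.index):
            raise ValidationError(
                f"tissue {tissue!r}: metabolite universes differ between "
                f"genotypes")
        bi = bi.reindex(ai.index)
        n_total = len(ai)
        if n_total == 0:
            raise ValidationError(f"tissue {tissue!r}: empty universe")
        sig_a = (ai < alpha).to_numpy()
        sig_b = (bi < alpha).to_numpy()
        na, nb = int(sig_a.sum()), int(sig_b.sum())
        k = int((sig_a & sig_b).sum())
        p1 = single_overlap_probability(na, nb, n_total, mode=mode,
                                        p_conditional=p_conditional)
        chance = multi_overlap_likelihood(p1, k)
        hyper = float(stats.hypergeom.sf(k - 1, n_total, na, nb))
        perm_p = None
        if permutation_reps > 0 and k > 0:
            shared_idx = np.flatnonzero(sig_a & sig_b)
            hits = 0
            for _ in range(permutation_reps):
                pa = rng.permutation(sig_a)
                pb = rng.permutation(sig_b)
                if pa[shared_idx].all() and pb[shared_idx].all():
                    hits += 1
            perm_p = hits / permutation_reps
        out[tissue] = TissueOverlap(
            tissue=tissue, n_total=n_total, n_sig_a=na, n_sig_b=nb, k=k,
            p_single=p1, chance_likelihood=chance,
            log10_chance_likelihood=log10_multi_overlap_likelihood(p1, k),
            chance_likelihood_percent=format_percent(chance),
            hypergeom_p=hyper, mode=mode, permutation_p=perm_p)
    return out
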