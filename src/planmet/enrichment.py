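"""Pathway enrichment score: observed minus expected significant counts.

For a tissue, let ``total_sig`` be the number of significant metabolites
among ``total_measured`` on the panel, and for a pathway let
``sig_in_pathway`` of its ``measured_in_pathway`` members be significant.
Two conventions for the chance expectation are supported:

* ``literal`` (default):
  ``expected = (sig_in_pathway / total_sig) * measured_in_pathway`` —
  the size correction exactly as the source protocol words it.  Note its
  odd algebra: the expectation depends on the observed count itself and
  can exceed it; the conservation identity sum(expected) = total_sig does
  not hold (a notice is logged when it fails).
* ``standard``: ``expected = (total_sig / total_measured) *
  measured_in_pathway`` — the conventional uniform-rate expectation, under
  which expected counts over disjoint pathways covering the panel sum to
  ``total_sig``.

Either way ``enrichment = observed - expected``; metabolites belonging to
several pathways count in each (KEGG-style double counting), and
metabolites in no pathway enter the totals but score in no pathway.  No
p-value is attached to the score; an optional hypergeometric tail
probability is available as a diagnostic column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwayMap, ValidationError

logger = logging.getLogger("planmet")

__all__ = ["expected_count", "enrich_all"]


def expected_count(sig_in_pathway: int, total_sig: int,
                   measured_in_pathway: int, total_measured: int,
                   convention: str = "literal") -> float:
    """Expected significant metabolites in one pathway; 0 when
    total_sig == 0 under both conventions."""
    if total_measured <= 0:
        raise ValidationError("total_measured must be positive")
    if total_sig < 0 or sig_in_pathway < 0 or measured_in_pathway < 0:
        raise ValidationError("counts must be non-negative")
    if sig_in_pathway > measured_in_pathway:
        raise ValidationError(
            f"sig_in_pathway ({sig_in_pathway}) exceeds "
            f"measured_in_pathway ({measured_in_pathway})")
    if total_sig == 0:
        return 0.0
    if convention == "literal":
        return (sig_in_pathway / total_sig) * measured_in_pathway
    if convention == "standard":
        return (total_sig / total_measured) * measured_in_pathway
    raise ValidationError(f"unknown convention {convention!r}")


def enrich_all(flags: pd.DataFrame, pathways: PathwayMap,
               convention: str = "literal",
               hypergeom_column: bool = False) -> pd.DataFrame:
    """Per-(tissue, pathway) enrichment from per-metabolite significance.

    ``flags`` needs columns tissue, metabolite, significant (0/1) — one
    row per (tissue, metabolite).  Pathway member sets are intersected
    with the measured panel; pathways with no measured member are omitted
    with a logged notice.  Rows are sorted by enrichment, descending.
    """
    required = {"tissue", "metabolite", "significant"}
    if not required <= set(flags.columns):
        raise ValidationError(f"flags table needs columns {sorted(required)}")
    rows = []
    for tissue in sorted(flags["tissue"].unique()):
        sub = flags.loc[flags["tissue"] == tissue]
        panel = set(sub["metabolite"])
        sig = set(sub.loc[sub["significant"] == 1, "metabolite"])
        restricted = pathways.restricted_to(panel)
        total_measured = len(panel)
        total_sig = len(sig)
        expected_sum = 0.0
        for pid in sorted(restricted.members):
            members = restricted.members[pid]
            measured = len(members)
            observed = len(members & sig)
            exp = expected_count(observed, total_sig, measured,
                                 total_measured, convention=convention)
            expected_sum += exp
            row = {
                "tissue": tissue, "pathway": pid,
                "measured_in_pathway": measured,
                "sig_in_pathway": observed,
                "total_sig": total_sig,
                "total_measured": total_measured,
                "expected": exp,
                "enrichment": observed - exp,
                "convention": convention,
            }
            if hypergeom_column:
                row["hypergeom_p"] = float(stats.hypergeom.sf(
                    observed - 1, total_measured, measured, total_sig))
            rows.append(row)
        if convention == "literal" and not np.isclose(
                expected_sum, total_sig) and total_sig > 0:
            logger.info(
                "tissue %s: literal-convention expected counts sum to "
                "%.3f, not total_sig=%d (known property of the literal "
                "formula)", tissue, expected_sum, total_sig)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["tissue", "enrichment", "pathway"],
                                  ascending=[True, False, True],
                                  kind="mergesort").reset_index(drop=True)
    return table
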