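"""Cross-ancestry ranking and locus classification.

Within each ancestry, PAR estimates are ranked from highest to lowest
(dense ranks: ties share a rank).  The per-ancestry ranked lists are then
assembled into a loci x ancestries comparison matrix, from which loci are
classified as universal (top-k in at least m ancestries),
population-enriched (top-k in some but fewer than m), shared (present in
several ancestries, top-k in none) or single (observed in exactly one
ancestry).  The top-k / min-ancestries rule is a deliberately explicit
operationalization of "universally high across ancestries"; both knobs
are exposed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import PAREstimate, ValidationError


@dataclass
class AncestryComparison:
    """Loci x ancestries grids of PAR values and per-ancestry dense ranks.

    Cells are NaN where a locus lacks a qualifying variant in that
    ancestry.  Rows are ordered by descending mean of present PARs.
    """

    loci: list[str]
    ancestries: list[str]
    par_matrix: pd.DataFrame
    rank_matrix: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format (locus, ancestry, par, rank) table, present cells only."""
        rows = []
        for locus in self.loci:
            for anc in self.ancestries:
                par = self.par_matrix.at[locus, anc]
                if pd.notna(par):
                    rows.append(
                        {
                            "locus": locus,
                            "ancestry": anc,
                            "par": par,
                            "rank": int(self.rank_matrix.at[locus, anc]),
                        }
                    )
        return pd.DataFrame(rows, columns=["locus", "ancestry", "par", "rank"])


def rank_within_ancestry(estimates: Sequence[PAREstimate]) -> list[PAREstimate]:
    """Assign dense ranks, 1 = highest PAR; ties share a rank.

    All estimates must belong to one ancestry.  Output is ordered by
    descending PAR, ties by variant id, so ranking is invariant to input
    permutation.
    """
    estimates = list(estimates)
    if not estimates:
        return []
    ancestries = {e.ancestry for e in estimates}
    if len(ancestries) > 1:
        raise ValidationError(f"mixed ancestries in one ranking: {sorted(ancestries)}")
    distinct = sorted({e.par for e in estimates}, reverse=True)
    rank_of = {par: i + 1 for i, par in enumerate(distinct)}
    ordered = sorted(estimates, key=lambda e: (-e.par, e.variant_id))
    return [dataclasses.replace(e, rank=rank_of[e.par]) for e in ordered]


def build_comparison(
    per_ancestry: Mapping[str, Sequence[PAREstimate]],
) -> AncestryComparison:
    """Assemble the cross-ancestry matrix over the union of loci.

    Each cell is the locus's (lead-variant) PAR in that ancestry, or NaN
    when absent.  A duplicate locus within one ancestry is a usage error
    (lead selection guarantees uniqueness upstream).
    """
    if not per_ancestry:
        raise ValidationError("at least one ancestry required")
    ancestries = list(per_ancestry)
    loci: list[str] = []
    seen = set()
    for anc in ancestries:
        anc_loci = [e.locus for e in per_ancestry[anc]]
        if len(set(anc_loci)) != len(anc_loci):
            dupes = sorted({l for l in anc_loci if anc_loci.count(l) > 1})
            raise ValidationError(f"duplicate loci in ancestry {anc}: {dupes}")
        for locus in anc_loci:
            if locus not in seen:
                seen.add(locus)
                loci.append(locus)

    par = pd.DataFrame(np.nan, index=loci, columns=ancestries)
    rank = pd.DataFrame(np.nan, index=loci, columns=ancestries)
    for anc in ancestries:
        for e in per_ancestry[anc]:
            par.at[e.locus, anc] = e.par
            rank.at[e.locus, anc] = e.rank

    # order rows by descending mean of present PARs, ties by locus label
    means = par.mean(axis=1, skipna=True)
    order = sorted(loci, key=lambda l: (-means[l], l))
    return AncestryComparison(
        loci=order,
        ancestries=ancestries,
        par_matrix=par.loc[order],
        rank_matrix=rank.loc[order],
    )


def classify_loci(
    cmp: AncestryComparison, top_k: int = 10, min_ancestries: int | None = None
) -> dict[str, str]:
    """Label each locus by the breadth of its attributable-risk signal.

    universal
        ranks in the top_k of >= min_ancestries ancestries (default: all).
    enriched:<ancestries>
        top_k in at least one but fewer than min_ancestries (listed).
    single
        present in exactly one ancestry.
    shared
        present in several ancestries but top_k in none.
    """
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    if min_ancestries is None:
        min_ancestries = len(cmp.ancestries)
    if min_ancestries < 1 or min_ancestries > len(cmp.ancestries):
        raise ValidationError(f"min_ancestries {min_ancestries} outside [1, {len(cmp.ancestries)}]")

    out: dict[str, str] = {}
    for locus in cmp.loci:
        ranks = cmp.rank_matrix.loc[locus]
        present = ranks.notna()
        top = [anc for anc in cmp.ancestries if present[anc] and ranks[anc] <= top_k]
        if present.sum() == 1:
            out[locus] = "single"
        elif len(top) >= min_ancestries:
            out[locus] = "universal"
        elif top:
            out[locus] = "enriched:" + ",".join(top)
        else:
            out[locus] = "shared"
    return out
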