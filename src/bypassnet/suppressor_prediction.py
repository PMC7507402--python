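"""Rank genes on an aneuploid chromosome as candidate suppressors.

When a suppressor strain carries an extra chromosome copy, any gene on
that chromosome could be the causal dosage suppressor. Candidates are
ranked by their functional relationship to the query gene in strict
lexicographic priority: cocomplex (highest), copathway, coexpression,
colocalization (lowest). Encoding the four predicates as bits of a 4-bit
integer (8/4/2/1) makes the lexicographic order a plain descending sort,
and within a priority tier the remaining predicates break ties exactly as
the priority list dictates. Exact ties share the mean (fractional) rank
for evaluation; display order within a tie group is stable by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .functional_standards import FunctionalCompendium, relatedness_vector

__all__ = ["RankedCandidates", "rank_aneuploid_genes", "evaluate_ranking"]


@dataclass
class RankedCandidates:
    """Priority-ordered candidate suppressors on one chromosome."""

    query: str
    chromosome: Optional[int]
    table: pd.DataFrame  # gene_id, priority_value, rank, fractional_rank, is_query

    def fractional_rank_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene]
        if row.empty:
            raise KeyError(f"{gene!r} not among ranked candidates")
        return float(row["fractional_rank"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def rank_aneuploid_genes(
    query: str,
    chromosome_genes: Sequence[str],
    compendium: FunctionalCompendium,
    chromosome: Optional[int] = None,
) -> RankedCandidates:
    """Rank the genes of an aneuploid chromosome by functional connection
    to the query.

    Genes are sorted by the 4-bit priority code descending; ``rank`` is the
    1-based display position (stable by gene id within ties) and
    ``fractional_rank`` the mean rank of each tie group, used for
    evaluation. The query gene itself, if present on the chromosome, is
    listed and flagged (self-amplification) but ranked like any other gene
    is not meaningful, so its priority is reported as the maximum code.
    """
    if not chromosome_genes:
        raise ValueError("chromosome_genes must be non-empty")
    rows = []
    for gene in chromosome_genes:
        if gene == query:
            rows.append({"gene_id": gene, "priority_value": 15, "is_query": True})
            continue
        v = relatedness_vector(query, gene, compendium)
        rows.append(
            {"gene_id": gene, "priority_value": v.priority_value, "is_query": False}
        )
    table = pd.DataFrame(rows).sort_values(
        ["priority_value", "gene_id"], ascending=[False, True]
    )
    table = table.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["fractional_rank"] = (
        table["priority_value"].rank(method="average", ascending=False)
    )
    return RankedCandidates(query=query, chromosome=chromosome, table=table)


def evaluate_ranking(
    cases: Iterable[tuple[RankedCandidates, str]],
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare confirmed-suppressor ranks against a random-list baseline.

    For each (ranking, confirmed suppressor) case the confirmed gene's
    fractional rank is recorded; the baseline draws ``n_random`` uniformly
    random orderings of the same candidate list per case (no ties, so the
    fractional rank is the position itself). Returns the median observed
    rank, the baseline median, and a two-sided Mann-Whitney U p-value
    comparing the two rank samples. Confirmed genes absent from their
    candidate list are excluded and counted in ``n_missing``.
    """
    rng = np.random.default_rng(seed)
    observed: list[float] = []
    baseline: list[float] = []
    n_missing = 0
    for ranked, confirmed in cases:
        try:
            observed.append(ranked.fractional_rank_of(confirmed))
        except KeyError:
            n_missing += 1
            continue
        n = len(ranked)
        baseline.extend(rng.integers(1, n + 1, size=n_random).astype(float))
    if not observed:
        raise ValueError("no evaluable cases (all confirmed suppressors missing)")
    if len(set(observed)) == 1 and set(observed) == set(baseline):
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(observed, baseline, alternative="two-sided").pvalue
        )
    return {
        "median_rank": float(np.median(observed)),
        "random_median_rank": float(np.median(baseline)),
        "p_value": p,
        "n_cases": len(observed),
        "n_missing": n_missing,
        "observed_ranks": observed,
    }
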