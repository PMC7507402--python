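"""Colony-size normalization and overexpression-screen scoring.

Fitness of suppressor strains is measured from pinned colony arrays:
border positions are discarded, replicate colony areas averaged per
strain and condition, divided by the wild-type control mean of that
condition, and averaged across conditions. Aneuploidy-complementation
overexpression screens are scored per array gene as the number of
empty-vector standard deviations separating the median colony size of
query colonies overexpressing the gene from the empty-vector median;
hits require Z > 1.5 and p < 0.05. Genes hit in three or more screens
are frequent flyers (systematic artifacts) and removed; plasmids
carrying the query gene itself are excluded from final hits but kept in
a positive-control report.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_colony_sizes",
    "score_overexpression_screen",
    "filter_screen_hits",
    "Z_THRESHOLD",
    "P_THRESHOLD",
]

Z_THRESHOLD = 1.5
P_THRESHOLD = 0.05


def normalize_colony_sizes(
    plates: Iterable[pd.DataFrame],
    wild_type_label: str,
) -> pd.DataFrame:
    """Normalize colony areas to per-strain fitness values.

    Each plate is a long-form table with columns ``row``, ``col``,
    ``strain``, ``area``, ``condition`` and optionally ``rough`` (manual
    flag for colonies that did not pin properly; dropped). Border
    positions (first and last row and column of each plate) are removed,
    replicate areas averaged per strain and condition, divided by the
    wild-type mean for that condition, and finally averaged across
    conditions.

    Returns a DataFrame indexed by strain with per-condition normalized
    values and a ``fitness`` column (cross-condition mean). Strains seen
    only in border positions are absent from the output.
    """
    kept = []
    for plate in plates:
        required = {"row", "col", "strain", "area", "condition"}
        if not required.issubset(plate.columns):
            raise ValueError(f"plate needs columns {sorted(required)}")
        interior = plate.loc[
            (plate["row"] > plate["row"].min())
            & (plate["row"] < plate["row"].max())
            & (plate["col"] > plate["col"].min())
            & (plate["col"] < plate["col"].max())
        ]
        if "rough" in interior.columns:
            interior = interior.loc[~interior["rough"].astype(bool)]
        kept.append(interior)
    data = pd.concat(kept, ignore_index=True)
    means = (
        data.groupby(["condition", "strain"])["area"].mean().unstack("condition")
    )
    if wild_type_label not in means.index:
        raise ValueError(
            f"degenerate input: no interior wild-type ({wild_type_label!r}) colonies"
        )
    wt = means.loc[wild_type_label]
    norm = means / wt
    norm["fitness"] = norm.mean(axis=1)
    return norm


def score_overexpression_screen(
    colonies: pd.DataFrame,
    p_method: str = "normal",
) -> pd.DataFrame:
    """Score one overexpression screen per array gene.

    ``colonies`` is a long-form table with columns ``array_gene``,
    ``colony_size`` and ``is_empty_vector`` (plus optionally ``query``,
    ``plasmid``, ``screen_id`` which are carried through). The Z-score of
    an array gene is
    ``(median_gene - median_empty) / sd_empty`` with ``sd_empty`` the
    sample standard deviation of empty-vector colony sizes. The p-value
    is the two-sided standard-normal tail of Z (``p_method='normal'``,
    default) or the empirical two-sided tail of the centred empty-vector
    sizes (``p_method='empirical'``). A gene is a hit iff Z > 1.5 and
    p < 0.05.
    """
    required = {"array_gene", "colony_size", "is_empty_vector"}
    if not required.issubset(colonies.columns):
        raise ValueError(f"colonies needs columns {sorted(required)}")
    empty = colonies.loc[colonies["is_empty_vector"].astype(bool), "colony_size"]
    if len(empty) < 2:
        raise ValueError("need >= 2 empty-vector colonies")
    med_empty = float(empty.median())
    sd_empty = float(empty.std(ddof=1))
    if sd_empty == 0:
        raise ValueError("degenerate input: empty-vector sizes have zero spread")
    genes = colonies.loc[~colonies["is_empty_vector"].astype(bool)]
    rows = []
    carry = [c for c in ("query", "plasmid", "screen_id") if c in colonies.columns]
    for gene, sub in genes.groupby("array_gene", sort=True):
        z = (float(sub["colony_size"].median()) - med_empty) / sd_empty
        if p_method == "normal":
            p = 2 * stats.norm.sf(abs(z))
        elif p_method == "empirical":
            centred = (empty - med_empty) / sd_empty
            p = (1 + int((np.abs(centred) >= abs(z)).sum())) / (1 + len(centred))
        else:
            raise ValueError("p_method must be 'normal' or 'empirical'")
        row = {"array_gene": gene, "z": z, "p": float(p),
               "hit": bool(z > Z_THRESHOLD and p < P_THRESHOLD)}
        for c in carry:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def filter_screen_hits(
    hits: pd.DataFrame,
    flyer_threshold: int = 3,
    self_plasmids: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter hit lists across screens.

    ``hits`` is the concatenation of per-screen score tables (must carry
    ``screen_id`` and ``array_gene``; only rows with ``hit == True`` are
    considered). Genes that are a hit in ``flyer_threshold`` or more
    distinct screens are frequent flyers and removed everywhere.
    ``self_plasmids`` maps screen_id (or query) context: when the hit row's
    ``query`` equals its ``array_gene``, the hit is excluded from the
    final list but retained in the control report, since overexpressing
    the query gene itself is expected to rescue and serves as a positive
    control.

    Returns ``(final_hits, control_report)`` where the control report
    contains the excluded self-plasmid hits and flagged frequent flyers.
    """
    required = {"array_gene", "screen_id", "hit"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hits needs columns {sorted(required)}")
    hit_rows = hits.loc[hits["hit"].astype(bool)].copy()
    screens_per_gene = hit_rows.groupby("array_gene")["screen_id"].nunique()
    flyers = set(screens_per_gene.index[screens_per_gene >= flyer_threshold])
    hit_rows["frequent_flyer"] = hit_rows["array_gene"].isin(flyers)
    if "query" in hit_rows.columns:
        hit_rows["self_plasmid"] = hit_rows["array_gene"] == hit_rows["query"]
    elif self_plasmids is not None:
        hit_rows["self_plasmid"] = [
            row.array_gene == self_plasmids.get(row.screen_id)
            for row in hit_rows.itertuples()
        ]
    else:
        hit_rows["self_plasmid"] = False
    excluded = hit_rows["frequent_flyer"] | hit_rows["self_plasmid"]
    final = hit_rows.loc[~excluded].reset_index(drop=True)
    control = hit_rows.loc[excluded].reset_index(drop=True)
    return final, control
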