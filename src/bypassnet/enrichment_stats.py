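"""Enrichment and group-comparison statistics for suppression networks.

Covers the statistical toolkit of the study: exact 2x2 tests, pairwise
fold enrichment of query-suppressor pairs against a constructed background
for each functional standard, functional-class enrichment of gene subsets,
binary/continuous group property comparisons with AUROC effect sizes, and
a permutation test for the functional relatedness of co-occurring
suppressor pairs. Pairs whose predicate status is unknown (missing data
for either gene) are excluded from both numerator and denominator: only
gene pairs with functional data available for both genes are considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .functional_standards import (
    FunctionalCompendium,
    RelatednessVector,
    relatedness_vector,
)

__all__ = [
    "EnrichmentResult",
    "fisher_exact",
    "fold_enrichment",
    "class_enrichment",
    "compare_gene_properties",
    "permutation_relatedness_test",
    "STANDARD_PREDICATES",
]

#: Predicate accessors by standard name.
STANDARD_PREDICATES: dict[str, Callable[[RelatednessVector], Optional[bool]]] = {
    "cocomplex": lambda v: v.cocomplex,
    "copathway": lambda v: v.copathway,
    "coexpressed": lambda v: v.coexpressed,
    "colocalized": lambda v: v.colocalized,
    "coannotated_process": lambda v: v.coannotated_process,
}


@dataclass(frozen=True)
class EnrichmentResult:
    standard: str
    observed_fraction: float
    background_fraction: float
    fold: float
    p_value: float
    n_observed: int
    n_background: int
    sided: str = "two"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def fisher_exact(
    table: Sequence[Sequence[int]], sided: str = "two"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 contingency table.

    ``sided='one'`` gives the upper hypergeometric tail (enrichment of the
    top-left cell); ``sided='two'`` sums all tables with point probability
    <= the observed one. Returns ``(p_value, odds_ratio)`` with the odds
    ratio ``ad/bc`` (``inf`` when ``bc == 0`` and ``ad > 0``, ``nan`` for
    0/0).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'one' or 'two'")
    res = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return float(res.pvalue), odds


def _evaluable_counts(
    pairs: Iterable[tuple[str, str]],
    predicate: Callable[[RelatednessVector], Optional[bool]],
    compendium: FunctionalCompendium,
) -> tuple[int, int]:
    """(number of pairs with predicate true, number evaluable)."""
    true_n = 0
    eval_n = 0
    for a, b in pairs:
        status = predicate(relatedness_vector(a, b, compendium))
        if status is None:
            continue
        eval_n += 1
        true_n += int(status)
    return true_n, eval_n


def fold_enrichment(
    observed_pairs: Iterable[tuple[str, str]],
    standard: str,
    background_pairs: Iterable[tuple[str, str]],
    compendium: FunctionalCompendium,
    sided: str = "two",
) -> EnrichmentResult:
    """Fold enrichment of a functional standard among observed
    query-suppressor pairs relative to a background pair set.

    Fold = (fraction of evaluable observed pairs with the predicate true)
    / (same fraction over the background); significance from Fisher's
    exact test on the 2x2 of origin x predicate status. Pairs unknown for
    the standard are dropped from both sets.
    """
    if standard not in STANDARD_PREDICATES:
        raise ValueError(f"unknown standard {standard!r}")
    pred = STANDARD_PREDICATES[standard]
    obs_true, obs_n = _evaluable_counts(observed_pairs, pred, compendium)
    bg_true, bg_n = _evaluable_counts(background_pairs, pred, compendium)
    if obs_n == 0 or bg_n == 0:
        raise ValueError(
            f"no evaluable pairs for standard {standard!r} "
            f"(observed {obs_n}, background {bg_n})"
        )
    obs_frac = obs_true / obs_n
    bg_frac = bg_true / bg_n
    fold = obs_frac / bg_frac if bg_frac > 0 else float("inf")
    p, _ = fisher_exact(
        [[obs_true, obs_n - obs_true], [bg_true, bg_n - bg_true]], sided=sided
    )
    return EnrichmentResult(
        standard=standard,
        observed_fraction=obs_frac,
        background_fraction=bg_frac,
        fold=fold,
        p_value=p,
        n_observed=obs_n,
        n_background=bg_n,
        sided=sided,
    )


def class_enrichment(
    gene_subset: Iterable[str],
    tested_universe: Iterable[str],
    class_map: Mapping[str, str],
    sided: str = "two",
) -> pd.DataFrame:
    """Per-class enrichment of a gene subset within a tested universe.

    Genes without a class assignment (e.g. highly pleiotropic or poorly
    characterized) are excluded from the analysis. For each class a 2x2
    (in subset vs not) x (in class vs not) Fisher test is run over the
    remaining universe; fold = subset class-fraction / universe
    class-fraction. Classes left with fewer than 2 genes after exclusions
    are skipped (``skipped=True`` row).
    """
    universe = [g for g in tested_universe if g in class_map]
    subset = {g for g in gene_subset if g in class_map}
    if not set(subset) <= set(universe):
        raise ValueError("gene_subset must be contained in tested_universe")
    rows = []
    classes = sorted({class_map[g] for g in universe})
    for cls in classes:
        members = {g for g in universe if class_map[g] == cls}
        if len(members) < 2:
            rows.append(
                {"class": cls, "n_class": len(members), "skipped": True,
                 "fold": np.nan, "p_value": np.nan}
            )
            continue
        a = len(subset & members)
        b = len(subset) - a
        c = len(members) - a
        d = len(universe) - len(subset) - c
        p, _ = fisher_exact([[a, b], [c, d]], sided=sided)
        subset_frac = a / len(subset) if subset else np.nan
        uni_frac = len(members) / len(universe)
        rows.append(
            {
                "class": cls,
                "n_class": len(members),
                "n_in_subset": a,
                "subset_fraction": subset_frac,
                "universe_fraction": uni_frac,
                "fold": subset_frac / uni_frac,
                "p_value": p,
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def _auroc(a: np.ndarray, b: np.ndarray) -> float:
    """AUROC for group a vs group b via the rank-sum statistic."""
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def compare_gene_properties(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    binary_features: Sequence[str] = (),
    continuous_features: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-feature comparison of two gene groups.

    Binary features are tested with two-sided Fisher's exact tests on the
    2x2 of group x feature; continuous features with two-sided
    Mann-Whitney U tests, with the AUROC (rank-sum statistic normalised to
    [0, 1]) and its deviation from the chance value 0.5 as effect size.
    Missing continuous values are dropped per feature. A feature constant
    across both groups is flagged uninformative (p = 1, AUROC = 0.5).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 items")
    rows = []
    for feat in binary_features:
        xa = group_a[feat].astype(bool)
        xb = group_b[feat].astype(bool)
        a, b = int(xa.sum()), int((~xa).sum())
        c, d = int(xb.sum()), int((~xb).sum())
        if (a + c == 0) or (b + d == 0):
            rows.append(
                {"feature": feat, "kind": "binary", "p_value": 1.0,
                 "auroc": 0.5, "auroc_deviation": 0.0, "direction": 0,
                 "uninformative": True}
            )
            continue
        p, _ = fisher_exact([[a, b], [c, d]], sided="two")
        fa, fb = a / (a + b), c / (c + d)
        auroc = 0.5 + (fa - fb) / 2  # probability interpretation for 0/1 data
        rows.append(
            {
                "feature": feat, "kind": "binary",
                "fraction_a": fa, "fraction_b": fb,
                "p_value": p, "auroc": auroc,
                "auroc_deviation": auroc - 0.5,
                "direction": int(np.sign(fa - fb)),
                "uninformative": False,
            }
        )
    for feat in continuous_features:
        xa = group_a[feat].dropna().to_numpy(dtype=float)
        xb = group_b[feat].dropna().to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"feature {feat!r} has <2 non-missing values in a group")
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            rows.append(
                {"feature": feat, "kind": "continuous", "p_value": 1.0,
                 "auroc": 0.5, "auroc_deviation": 0.0, "direction": 0,
                 "uninformative": True}
            )
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        auroc = _auroc(xa, xb)
        rows.append(
            {
                "feature": feat, "kind": "continuous",
                "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
                "p_value": float(res.pvalue), "auroc": auroc,
                "auroc_deviation": auroc - 0.5,
                "direction": int(np.sign(auroc - 0.5)),
                "uninformative": False,
            }
        )
    return pd.DataFrame(rows)


def permutation_relatedness_test(
    observed_pairs: Sequence[tuple[str, str]],
    compendium: FunctionalCompendium,
    universe: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test for functional relatedness of gene pairs.

    The statistic is the fraction of pairs with any relatedness predicate
    true. The null resamples the same number of pairs uniformly from the
    universe (self-pairs excluded); the empirical p-value uses the add-one
    rule ``p = (1 + #null >= observed) / (1 + n_permutations)`` and can
    therefore never be zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed_pairs = list(observed_pairs)
    if not observed_pairs:
        raise ValueError("observed_pairs must be non-empty")
    universe = list(universe)
    rng = np.random.default_rng(seed)

    def related_fraction(pairs: Iterable[tuple[str, str]]) -> float:
        flags = [
            relatedness_vector(a, b, compendium).any_related for a, b in pairs
        ]
        return float(np.mean(flags))

    observed = related_fraction(observed_pairs)
    k = len(observed_pairs)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        pairs = []
        while len(pairs) < k:
            a, b = rng.choice(len(universe), size=2, replace=False)
            pairs.append((universe[a], universe[b]))
        null[i] = related_fraction(pairs)
    p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    return {
        "observed_fraction": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_permutations > 1 else float("nan"),
        "p_value": float(p),
        "n_permutations": n_permutations,
    }
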