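"""Dispensability prediction and essential-gene classification.

A bagged decision-tree ensemble (random forest) predicts which essential
genes are dispensable (bypassable) from gene-level features, with the
class imbalance handled by undersampling the majority (indispensable)
class to the minority size in every training replicate. Evaluation uses
genes not seen in training: the out-of-bag predictions for sampled rows
plus the majority rows left out by undersampling. Classification rules
then combine experiment, prediction and literature evidence into a
core-essential vs dispensable-essential gene list, and CRISPR
gene-dependency scores (CERES-like, more negative = more essential)
classify human genes into indispensable / context-dependent /
nonessential by the fraction of cell lines in which they are essential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .enrichment_stats import fisher_exact

__all__ = [
    "ModelReport",
    "train_dispensability_model",
    "feature_ablation",
    "classify_core_essential",
    "classify_cell_line_essentiality",
    "conservation_profile",
    "median_z_normalize",
]

LABEL_COLUMN = "label"
DISPENSABLE, INDISPENSABLE, UNTESTED = "dispensable", "indispensable", "untested"


@dataclass
class ModelReport:
    auroc: float  # mean held-out AUROC across undersampling replicates
    auroc_range: tuple[float, float]
    scores: pd.Series  # per-gene dispensability score in [0, 1]
    n_replicates: int
    feature_importances: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    replicate_class_counts: list[tuple[int, int]] = field(default_factory=list)


def _labeled_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    if LABEL_COLUMN not in features.columns:
        raise ValueError(f"feature table needs a {LABEL_COLUMN!r} column")
    labeled = features.loc[features[LABEL_COLUMN].isin([DISPENSABLE, INDISPENSABLE])]
    y = (labeled[LABEL_COLUMN] == DISPENSABLE).astype(int)
    X = labeled.drop(columns=[LABEL_COLUMN])
    for cls, n in y.value_counts().items():
        if n < 10:
            raise ValueError("need >= 10 genes per class among labeled rows")
    if y.nunique() < 2:
        raise ValueError("both classes must be present")
    return X, y


def train_dispensability_model(
    features: pd.DataFrame,
    seed: int = 0,
    n_replicates: int = 5,
    n_trees: int = 1000,
) -> ModelReport:
    """Train the dispensability classifier with class-balanced
    undersampling and held-out evaluation.

    ``features`` has genes as the index, feature columns, and a ``label``
    column in {dispensable, indispensable, untested}; untested rows are
    scored but never trained on. Per replicate, the majority class is
    undersampled to the minority size, a random forest is fitted with
    bootstrap aggregation, and evaluation scores come from rows the
    forest did not train on: out-of-bag predictions for training rows and
    ordinary predictions for the left-out majority rows. The report's
    AUROC is the mean over replicates with its min-max range; per-gene
    scores average over replicates.
    """
    X, y = _labeled_matrix(features)
    rng = np.random.default_rng(seed)
    minority = y.value_counts().idxmin()
    n_min = int(y.value_counts().min())
    aurocs = []
    score_sum = pd.Series(0.0, index=features.index)
    score_n = pd.Series(0, index=features.index)
    importances = np.zeros(X.shape[1])
    class_counts: list[tuple[int, int]] = []
    X_all = features.drop(columns=[LABEL_COLUMN])
    for _ in range(n_replicates):
        idx_min = y.index[y == minority]
        idx_maj = y.index[y != minority]
        take = rng.choice(len(idx_maj), size=n_min, replace=False)
        idx_train = idx_min.append(idx_maj[take])
        held_out = idx_maj.difference(idx_train)
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            oob_score=True,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        y_train = y.loc[idx_train]
        class_counts.append(
            (int((y_train == 1).sum()), int((y_train == 0).sum()))
        )
        clf.fit(X.loc[idx_train], y_train)
        # held-out evaluation: OOB for training rows, predict for the rest
        pos = list(clf.classes_).index(1)
        oob = clf.oob_decision_function_[:, pos]
        eval_scores = pd.Series(oob, index=idx_train)
        eval_y = y.loc[idx_train]
        if len(held_out):
            held_scores = pd.Series(
                clf.predict_proba(X.loc[held_out])[:, pos], index=held_out
            )
            eval_scores = pd.concat([eval_scores, held_scores])
            eval_y = pd.concat([eval_y, y.loc[held_out]])
        mask = ~np.isnan(eval_scores.to_numpy())
        aurocs.append(
            float(roc_auc_score(eval_y.to_numpy()[mask], eval_scores.to_numpy()[mask]))
        )
        importances += clf.feature_importances_
        # per-gene scores: held-out/OOB where available, model score elsewhere
        all_scores = pd.Series(
            clf.predict_proba(X_all)[:, pos], index=X_all.index
        )
        all_scores.loc[eval_scores.index] = eval_scores
        ok = ~all_scores.isna()
        score_sum[ok] += all_scores[ok]
        score_n[ok] += 1
    scores = score_sum / score_n.replace(0, np.nan)
    return ModelReport(
        auroc=float(np.mean(aurocs)),
        auroc_range=(float(np.min(aurocs)), float(np.max(aurocs))),
        scores=scores,
        n_replicates=n_replicates,
        feature_importances=pd.Series(
            importances / n_replicates, index=X.columns
        ).sort_values(ascending=False),
        replicate_class_counts=class_counts,
    )


def feature_ablation(
    features: pd.DataFrame,
    seed: int = 0,
    n_replicates: int = 3,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Retrain with one feature removed at a time.

    Returns a table with one row per removed feature: the AUROC without
    it and the drop relative to the full model, sorted by drop
    descending (the most load-bearing feature first).
    """
    feature_cols = [c for c in features.columns if c != LABEL_COLUMN]
    if len(feature_cols) < 2:
        raise ValueError("ablation needs at least 2 features")
    full = train_dispensability_model(
        features, seed=seed, n_replicates=n_replicates, n_trees=n_trees
    )
    rows = []
    for feat in feature_cols:
        reduced = features.drop(columns=[feat])
        rep = train_dispensability_model(
            reduced, seed=seed, n_replicates=n_replicates, n_trees=n_trees
        )
        rows.append(
            {"removed_feature": feat, "auroc": rep.auroc,
             "auroc_drop": full.auroc - rep.auroc}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("auroc_drop", ascending=False)
        .reset_index(drop=True)
    )


def classify_core_essential(
    experimental_outcomes: Mapping[str, str],
    prediction_scores: Mapping[str, float],
    literature_bypass: Iterable[str] = (),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify essential genes as dispensable or core essential.

    Rules, in precedence order: genes bypassed in the experiments are
    dispensable essential (experimental); untested genes with prediction
    score strictly above the threshold are dispensable essential
    (predicted); genes not bypassed experimentally, or untested with
    score strictly below the threshold, are core essential — unless a
    bypass suppressor is described in the literature, which reclassifies
    them as dispensable essential (literature). A score exactly at the
    threshold leaves an untested gene unclassified.
    """
    literature = set(literature_bypass)
    valid = {"bypassed", "not_bypassed", "untested"}
    rows = []
    for gene, outcome in experimental_outcomes.items():
        if outcome not in valid:
            raise ValueError(f"invalid experimental outcome {outcome!r} for {gene!r}")
        if outcome == "bypassed":
            cls, prov = "dispensable_essential", "experimental"
        elif outcome == "not_bypassed":
            if gene in literature:
                cls, prov = "dispensable_essential", "literature"
            else:
                cls, prov = "core_essential", "experimental"
        else:  # untested
            score = prediction_scores.get(gene)
            if score is None:
                raise ValueError(f"untested gene {gene!r} has no prediction score")
            if score > threshold:
                cls, prov = "dispensable_essential", "predicted"
            elif score < threshold:
                if gene in literature:
                    cls, prov = "dispensable_essential", "literature"
                else:
                    cls, prov = "core_essential", "predicted"
            else:
                cls, prov = "unclassified", "predicted"
        rows.append({"gene": gene, "class": cls, "provenance": prov})
    return pd.DataFrame(rows)


def classify_cell_line_essentiality(
    score_matrix: pd.DataFrame,
    tau: float = -0.7,
    hi: float = 0.90,
    lo: float = 0.10,
) -> pd.DataFrame:
    """Classify genes by the fraction of cell lines where they are
    essential.

    A gene is essential in a cell line when its dependency score is
    strictly below ``tau`` (default CERES -0.7). Genes essential in
    strictly more than ``hi`` of lines are indispensable; in strictly
    fewer than ``lo``, nonessential; the rest context-dependent. Missing
    scores are excluded from the gene's denominator. The alternative
    thresholds of the sensitivity analysis (tau=-0.5, lo=0.50) are passed
    through the same parameters.
    """
    if not lo < hi:
        raise ValueError("thresholds must satisfy lo < hi")
    if score_matrix.empty:
        raise ValueError("empty score matrix")
    essential = score_matrix < tau
    n_valid = score_matrix.notna().sum(axis=1)
    frac = essential.sum(axis=1) / n_valid
    def classify(f: float) -> str:
        if f > hi:
            return "indispensable"
        if f < lo:
            return "nonessential"
        return "context_dependent"
    return pd.DataFrame(
        {
            "essential_line_fraction": frac,
            "n_lines": n_valid,
            "n_missing": score_matrix.isna().sum(axis=1),
            "class": frac.map(classify),
        }
    )


def conservation_profile(
    orthologs: pd.DataFrame,
    yeast_classes: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-species conservation profile and dispensable-vs-indispensable
    contrasts.

    ``orthologs`` has columns ``gene``, ``species``, ``status`` in
    {absent, duplicated, one_to_one} and ``essential`` (boolean, defined
    only for one_to_one orthologs). Returns per-gene species counts
    (absent / duplicated / nonessential / essential, plus the count of
    species with a 1-to-1 essential ortholog) and a per-species contrast
    table: Fisher's exact test for "has a 1-to-1 essential ortholog in
    this species" between the two yeast dispensability classes, plus a
    rank-sum comparison of the per-gene not-essential species counts.
    """
    required = {"gene", "species", "status"}
    if not required.issubset(orthologs.columns):
        raise ValueError(f"orthologs needs columns {sorted(required)}")
    df = orthologs.copy()
    one_to_one = df["status"] == "one_to_one"
    ess = df.get("essential")
    df["bucket"] = np.where(
        ~one_to_one,
        df["status"],
        np.where(ess.map(lambda x: bool(x) if pd.notna(x) else False),
                 "essential", "nonessential"),
    )
    counts = (
        df.pivot_table(
            index="gene", columns="bucket", aggfunc="size", fill_value=0
        )
        .reindex(columns=["absent", "duplicated", "nonessential", "essential"],
                 fill_value=0)
    )
    counts["essential_1to1_species"] = counts["essential"]
    counts["not_essential_species"] = (
        counts["absent"] + counts["duplicated"] + counts["nonessential"]
    )

    disp = [g for g, c in yeast_classes.items() if c == DISPENSABLE]
    indisp = [g for g, c in yeast_classes.items() if c == INDISPENSABLE]
    rows = []
    for species, sub in df.groupby("species"):
        flag = sub.set_index("gene")["bucket"] == "essential"
        a = int(flag.reindex(disp).fillna(False).sum())
        b = len(disp) - a
        c = int(flag.reindex(indisp).fillna(False).sum())
        d = len(indisp) - c
        p, odds = fisher_exact([[a, b], [c, d]], sided="two")
        rows.append(
            {"species": species, "n_dispensable_essential_ortholog": a,
             "n_indispensable_essential_ortholog": c, "odds_ratio": odds,
             "p_value": p}
        )
    contrasts = pd.DataFrame(rows)
    ne = counts["not_essential_species"]
    disp_ne = ne.reindex(disp).dropna()
    indisp_ne = ne.reindex(indisp).dropna()
    dist_p = np.nan
    if len(disp_ne) >= 2 and len(indisp_ne) >= 2:
        dist_p = float(
            stats.mannwhitneyu(disp_ne, indisp_ne, alternative="two-sided").pvalue
        )
    contrasts.attrs["not_essential_count_p"] = dist_p
    return counts, contrasts


def median_z_normalize(
    values: Sequence[float], reference_values: Sequence[float]
) -> np.ndarray:
    """Z-score normalization against a reference group, centring on the
    reference *median* (robust to skew) rather than the mean; the spread
    is the reference sample standard deviation."""
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[~np.isnan(ref)]
    if len(np.unique(ref)) < 2:
        raise ValueError("degenerate input: reference group has no spread")
    sd = float(np.std(ref, ddof=1))
    med = float(np.median(ref))
    return (np.asarray(values, dtype=float) - med) / sd
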