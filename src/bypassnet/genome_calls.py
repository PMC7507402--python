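"""Genome-content calls from binned read depth, and suppressor nomination.

Aneuploidies are called from mean read depth per chromosome relative to a
robust per-genome baseline: a disome in a haploid has ~2x the euploid
depth, a trisome in a diploid ~1.5x, so ``copy = round(ratio * ploidy)``
with the strain's overall ploidy supplied externally (e.g. from flow
cytometry). Partial amplifications are recovered by mean-shift changepoint
segmentation of the bin-depth sequence. Genome size sums chromosome
lengths weighted by absolute copy number plus extra copies of amplified
segments, ignoring amplifications in telomeric regions or at the rDNA
locus. Candidate suppressor genes are nominated from filtered
nonsynonymous variants using four criteria flags, and unmarked suppressor
loci are mapped from genome-ordered genetic-interaction scores by an
explicit low-score run detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .functional_standards import FunctionalCompendium, relatedness_vector

__all__ = [
    "StrainCall",
    "AmplifiedSegment",
    "LinkageLocus",
    "call_chromosome_copy_numbers",
    "segment_partial_amplifications",
    "compute_genome_size",
    "filter_recurrent_variants",
    "nominate_suppressor_candidates",
    "detect_linkage_locus",
]

#: |ratio * ploidy - round(...)| at or above this is flagged low-confidence.
LOW_CONFIDENCE_DEVIATION = 0.25


@dataclass(frozen=True)
class AmplifiedSegment:
    chromosome: int
    start_bp: int
    end_bp: int  # half-open [start_bp, end_bp)
    copy_number: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class StrainCall:
    """Genome-content call for one strain."""

    strain_id: str
    ploidy: int
    copy_numbers: dict[int, int]
    partial_amplifications: list[AmplifiedSegment] = field(default_factory=list)
    genome_size_bp: Optional[int] = None
    fitness: Optional[float] = None

    @property
    def aneuploid_chromosomes(self) -> list[int]:
        return [c for c, k in self.copy_numbers.items() if k != self.ploidy]

    @property
    def has_genome_content_change(self) -> bool:
        return bool(self.aneuploid_chromosomes or self.partial_amplifications)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def call_chromosome_copy_numbers(
    profile: pd.DataFrame, ploidy: int
) -> pd.DataFrame:
    """Call per-chromosome copy numbers from a binned depth profile.

    Parameters
    ----------
    profile
        Depth table with columns ``chromosome``, ``bin_start``, ``bin_end``,
        ``depth`` (mean reads per base in the bin) for one strain.
    ploidy
        Overall ploidy of the strain (>= 1), an external measurement.

    Returns
    -------
    DataFrame indexed by chromosome with columns ``mean_depth``, ``ratio``
    (depth relative to the per-genome baseline, the median of per-chromosome
    means), ``copy_number`` (= round(ratio * ploidy), ties up),
    ``aneuploid`` and ``low_confidence`` (ratio*ploidy further than 0.25
    from an integer).
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    required = {"chromosome", "depth"}
    if not required.issubset(profile.columns):
        raise ValueError(f"profile must have columns {sorted(required)}")
    means = profile.groupby("chromosome")["depth"].mean()
    baseline = float(means.median())
    if baseline <= 0:
        raise ValueError("degenerate depth profile: all-zero depth")
    ratio = means / baseline
    scaled = ratio * ploidy
    copy = scaled.map(_round_half_up).astype(int)
    out = pd.DataFrame(
        {
            "mean_depth": means,
            "ratio": ratio,
            "copy_number": copy,
            "aneuploid": copy != ploidy,
            "low_confidence": (scaled - copy).abs() >= LOW_CONFIDENCE_DEVIATION,
        }
    )
    return out


def _binary_segmentation(y: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Breakpoint indices (split positions) by recursive binary splitting
    with squared-error cost; a split is kept when it reduces the cost by
    more than ``penalty``."""

    def sse(a: int, b: int) -> float:
        seg = y[a:b]
        return float(((seg - seg.mean()) ** 2).sum()) if b > a else 0.0

    breaks: list[int] = []

    def recurse(a: int, b: int) -> None:
        if b - a < 2 * min_size:
            return
        base = sse(a, b)
        seg = y[a:b]
        n = len(seg)
        csum = np.cumsum(seg)
        csq = np.cumsum(seg**2)
        best_gain, best_k = 0.0, -1
        for k in range(min_size, n - min_size + 1):
            left = csq[k - 1] - csum[k - 1] ** 2 / k
            right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
            gain = base - (left + right)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k > 0 and best_gain > penalty:
            recurse(a, a + best_k)
            breaks.append(a + best_k)
            recurse(a + best_k, b)

    recurse(0, len(y))
    return sorted(breaks)


def segment_partial_amplifications(
    profile: pd.DataFrame,
    chromosome: int,
    ploidy: int,
    min_bins: int = 3,
    min_ratio_step: float = 0.3,
    penalty_scale: float = 10.0,
) -> list[AmplifiedSegment]:
    """Detect partial (sub-chromosomal) copy-number changes on one chromosome.

    The bin-depth sequence is segmented by binary mean-shift changepoint
    search with squared-error cost; the penalty is ``penalty_scale *
    sigma^2 * log(n)`` with sigma estimated robustly from successive bin
    differences, calibrated so flat noise yields no segments. Segments
    spanning >= ``min_bins`` bins whose rounded copy number differs from
    the chromosome-level call — and whose depth ratio departs from the
    chromosome ratio by at least ``min_ratio_step`` — are reported with
    breakpoints at bin boundaries. A whole-chromosome change is the
    chromosome call's business and yields no segment here.
    """
    chrom_bins = profile.loc[profile["chromosome"] == chromosome].sort_values(
        "bin_start"
    )
    if chrom_bins.empty:
        raise ValueError(f"chromosome {chromosome!r} not present in profile")
    if min_bins > len(chrom_bins):
        raise ValueError("min_bins exceeds the number of bins on the chromosome")
    calls = call_chromosome_copy_numbers(profile, ploidy)
    baseline = float(
        profile.groupby("chromosome")["depth"].mean().median()
    )
    per_copy = baseline / ploidy
    chrom_copy = int(calls.loc[chromosome, "copy_number"])
    chrom_ratio = float(calls.loc[chromosome, "ratio"]) * ploidy

    y = chrom_bins["depth"].to_numpy(dtype=float)
    diffs = np.diff(y)
    sigma = float(np.median(np.abs(diffs))) / (math.sqrt(2.0) * 0.6745) if len(diffs) else 0.0
    penalty = max(penalty_scale * sigma**2 * math.log(max(len(y), 2)), 1e-9)
    breaks = _binary_segmentation(y, penalty, min_size=1)

    starts = chrom_bins["bin_start"].to_numpy()
    ends = chrom_bins["bin_end"].to_numpy()
    bounds = [0, *breaks, len(y)]
    segments: list[AmplifiedSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_bins or (a == 0 and b == len(y)):
            continue
        seg_copies = float(y[a:b].mean()) / per_copy
        copy = _round_half_up(seg_copies)
        if copy != chrom_copy and abs(seg_copies - chrom_ratio) >= min_ratio_step:
            segments.append(
                AmplifiedSegment(chromosome, int(starts[a]), int(ends[b - 1]), copy)
            )
    return segments


def compute_genome_size(
    call: StrainCall,
    chromosome_lengths: Mapping[int, int],
    excluded_regions: Iterable[tuple[int, int, int]] = (),
) -> int:
    """Total genome size in bp, taking full and partial aneuploidies into
    account but disregarding amplifications in excluded (telomeric / rDNA)
    regions.

    Size = sum over chromosomes of length * absolute copy number, plus
    (segment copy - chromosome copy) * segment length for each partial
    amplification that does not overlap an excluded region.
    """
    missing = set(call.copy_numbers) - set(chromosome_lengths)
    if missing:
        raise ValueError(f"no length for chromosomes {sorted(missing)}")
    size = sum(
        chromosome_lengths[c] * k for c, k in call.copy_numbers.items()
    )
    excluded = list(excluded_regions)
    for seg in call.partial_amplifications:
        if seg.start_bp < 0 or seg.end_bp > chromosome_lengths[seg.chromosome]:
            raise ValueError(f"segment {seg} outside chromosome bounds")
        if any(
            c == seg.chromosome and seg.start_bp < e and s < seg.end_bp
            for c, s, e in excluded
        ):
            continue
        extra = seg.copy_number - call.copy_numbers[seg.chromosome]
        size += extra * seg.length_bp
    return int(size)


def filter_recurrent_variants(
    variants: pd.DataFrame, max_strains: int = 4
) -> pd.DataFrame:
    """Drop variant sites present in more than ``max_strains`` distinct
    strains (default: sites in >= 5 strains are removed, excluding
    pre-existing variants and systematic artifacts).

    The site key is built from the available columns among ``chromosome``,
    ``position_bp`` and ``alt``; ``position_bp`` is required.
    """
    if "position_bp" not in variants.columns or "strain_id" not in variants.columns:
        raise ValueError("variants need 'strain_id' and 'position_bp' columns")
    key_cols = [c for c in ("chromosome", "position_bp", "alt") if c in variants.columns]
    n_strains = variants.groupby(key_cols)["strain_id"].transform("nunique")
    return variants.loc[n_strains <= max_strains].copy()


def nominate_suppressor_candidates(
    variants: pd.DataFrame,
    query: str,
    compendium: FunctionalCompendium,
    locus_genes: Optional[Mapping[str, Iterable[str]]] = None,
) -> pd.DataFrame:
    """Nominate candidate suppressor genes for the strains of one query.

    Candidates are genes carrying at least one nonsynonymous variant
    (``variants`` is expected to be recurrence-filtered already). Four
    criteria flags are set per (strain, gene): a unique nonsynonymous
    mutation in the gene; location within the genetically mapped
    suppressor locus (when a locus is available for the strain); mutation
    recurrence in independent isolates of the same query; a functional
    connection between candidate and query. Candidates are ranked within
    each strain by (number of true flags desc, relatedness priority
    desc, gene_id asc) with dense 1-based ranks.
    """
    if variants.empty:
        return pd.DataFrame(
            columns=[
                "strain_id", "gene_id", "unique_nonsyn", "in_locus", "recurrent",
                "functional_connection", "n_criteria", "priority_value", "rank",
            ]
        )
    nonsyn = variants.loc[
        variants["nonsynonymous"].astype(bool) & variants["gene_id"].notna()
    ]
    gene_strains = nonsyn.groupby("gene_id")["strain_id"].nunique()
    rows = []
    for strain_id, sub in nonsyn.groupby("strain_id"):
        for gene in sorted(sub["gene_id"].unique()):
            if gene == query:
                continue
            loci = locus_genes.get(strain_id) if locus_genes else None
            in_locus = bool(loci is not None and gene in set(loci))
            recurrent = bool(gene_strains[gene] >= 2)
            vec = relatedness_vector(query, gene, compendium)
            functional = vec.any_related
            flags = (True, in_locus, recurrent, functional)
            rows.append(
                {
                    "strain_id": strain_id,
                    "gene_id": gene,
                    "unique_nonsyn": True,
                    "in_locus": in_locus,
                    "recurrent": recurrent,
                    "functional_connection": functional,
                    "n_criteria": sum(flags),
                    "priority_value": vec.priority_value,
                }
            )
    columns = [
        "strain_id", "gene_id", "unique_nonsyn", "in_locus", "recurrent",
        "functional_connection", "n_criteria", "priority_value",
    ]
    if not rows:
        return pd.DataFrame(columns=[*columns, "rank"])
    out = pd.DataFrame(rows, columns=columns)
    out = out.sort_values(
        ["strain_id", "n_criteria", "priority_value", "gene_id"],
        ascending=[True, False, False, True],
    ).reset_index(drop=True)
    ranks = np.empty(len(out), dtype=int)
    for _, g in out.groupby("strain_id"):
        r, prev = 0, None
        for i, key in zip(
            g.index, zip(g["n_criteria"], g["priority_value"])
        ):
            if key != prev:  # dense rank over the (flags, priority) sort key
                r, prev = r + 1, key
            ranks[i] = r
    out["rank"] = ranks
    return out


@dataclass(frozen=True)
class LinkageLocus:
    chromosome: int
    start_index: int  # positional index into the genome-ordered score table
    end_index: int  # inclusive
    mean_score: float
    gene_ids: tuple[str, ...] = ()


def detect_linkage_locus(
    array_scores: pd.DataFrame,
    window: int = 10,
    threshold: float = -0.2,
) -> Optional[LinkageLocus]:
    """Detect the suppressor linkage locus from genome-ordered SGA scores.

    Array-gene deletion alleles in linkage with an unmarked suppressor
    locus produce a collinear run of reduced double-mutant colony sizes;
    this replaces visual inspection with an explicit rule: the maximal run
    of >= ``window`` consecutive genes (within one chromosome) with score
    <= ``threshold``. Among multiple qualifying runs the one with the
    lowest mean score wins. Returns ``None`` when no run qualifies.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    required = {"chromosome", "score"}
    if not required.issubset(array_scores.columns):
        raise ValueError(f"array_scores must have columns {sorted(required)}")
    best: Optional[LinkageLocus] = None
    scores = array_scores.reset_index(drop=True)
    for _, chrom_df in scores.groupby("chromosome", sort=False):
        idx = chrom_df.index.to_numpy()
        low = (chrom_df["score"] <= threshold).to_numpy()
        run_start = None
        for i, flag in enumerate([*low, False]):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                length = i - run_start
                if length >= window:
                    lo, hi = idx[run_start], idx[i - 1]
                    mean = float(scores.loc[lo:hi, "score"].mean())
                    genes = (
                        tuple(scores.loc[lo:hi, "gene_id"])
                        if "gene_id" in scores.columns
                        else ()
                    )
                    cand = LinkageLocus(
                        int(chrom_df["chromosome"].iloc[0]), int(lo), int(hi), mean, genes
                    )
                    if best is None or cand.mean_score < best.mean_score:
                        best = cand
                run_start = None
    return best
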