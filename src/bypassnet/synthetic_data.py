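"""Seeded synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a genome-scale
bypass-suppression study in budding yeast: a compact genome (~6,000 genes
on 16 unequal chromosomes, ~18% essential), a functional compendium
(complexes, pathways, a scored coexpression network, localizations,
process terms), a suppressor-isolation cohort in which ~17% of query
genes prove dispensable and roughly half of suppressor strains carry
genome-content changes (aneuploidies, partial amplifications or
whole-genome duplication), strains carrying a median of 2-3 unique
nonsynonymous variants, binned read-depth profiles whose expected depth
is proportional to planted copy number, overexpression-screen colony
sizes, gene feature tables with planted group effects, and cross-species
ortholog/essentiality panels with a CRISPR-dependency score matrix.

Every generator is a pure function of its parameters and seed. Per-entity
random streams are derived by stable keyed hashing of (seed, entity key),
so generating more strains never perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .functional_standards import FunctionalCompendium

__all__ = [
    "SyntheticTruth",
    "StrainTruth",
    "generate_genome",
    "generate_compendium",
    "generate_suppression_study",
    "generate_depth_profiles",
    "generate_overexpression_screen",
    "generate_screen_series",
    "generate_feature_table",
    "generate_species_panel",
    "DEFAULT_MECHANISM_MIX",
    "DEFAULT_TIER_MIX",
]

MECHANISMS = ("snp", "aneuploidy", "partial_amplification", "wgd")

# ~49% of suppressor strains carried genome-content changes; of those,
# whole-genome duplication was the single largest class.
DEFAULT_MECHANISM_MIX = {
    "snp": 0.51,
    "aneuploidy": 0.25,
    "wgd": 0.17,
    "partial_amplification": 0.07,
}

# Tier chosen when functional coupling fires: dominated by close
# (complex/pathway) relationships at the pair level.
DEFAULT_TIER_MIX = {
    "cocomplex": 0.4,
    "copathway": 0.3,
    "coexpressed": 0.2,
    "colocalized": 0.1,
}


def _sub_rng(seed: int, *keys) -> np.random.Generator:
    """Independent generator derived from (seed, keys) by stable hashing."""
    h = hashlib.sha256(repr(keys).encode()).digest()
    return np.random.default_rng([int(seed), int.from_bytes(h[:8], "little")])


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    n_genes: int = 6000,
    n_chromosomes: int = 16,
    genome_bp: int = 12_000_000,
    frac_essential: float = 0.18,
    frac_paralog: float = 0.30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene annotation table and chromosome-length table.

    Chromosome lengths are drawn unequal and size-ordered (chromosome 1
    largest). Genes are non-overlapping and sorted within chromosomes;
    essential flags hit the requested fraction to within one gene; the
    first and last gene of every chromosome are flagged telomeric and
    exactly one internal locus is flagged rDNA.
    """
    if n_chromosomes < 1 or n_genes < n_chromosomes:
        raise ValueError("need n_genes >= n_chromosomes >= 1")
    if not 0 <= frac_essential <= 1:
        raise ValueError("frac_essential must be in [0, 1]")
    if genome_bp < 10 * n_genes:
        raise ValueError("genome_bp too small for the requested gene count")
    rng = np.random.default_rng(seed)
    props = np.sort(rng.dirichlet(np.full(n_chromosomes, 5.0)))[::-1]
    lengths = np.floor(props * genome_bp).astype(int)
    lengths[-1] += genome_bp - lengths.sum()
    chromosomes = pd.DataFrame(
        {"chromosome": np.arange(1, n_chromosomes + 1), "length_bp": lengths}
    )

    # at least one gene per chromosome, remainder proportional to length
    counts = np.ones(n_chromosomes, dtype=int)
    extra = rng.multinomial(n_genes - n_chromosomes, props)
    counts += extra

    rows = []
    gene_idx = 0
    for c in range(n_chromosomes):
        n_c, L = counts[c], lengths[c]
        cuts = np.sort(rng.uniform(0, L, size=2 * n_c)).astype(int)
        for i in range(n_c):
            start = int(cuts[2 * i]) + 1  # 1-based inclusive coordinates
            end = int(max(cuts[2 * i + 1], start + 1))
            rows.append(
                {
                    "gene_id": f"G{gene_idx:04d}",
                    "chromosome": c + 1,
                    "start_bp": start,
                    "end_bp": min(end, int(L)),
                    "telomeric": i == 0 or i == n_c - 1,
                    "rdna": False,
                }
            )
            gene_idx += 1
    genes = pd.DataFrame(rows)

    n_essential = int(round(frac_essential * n_genes))
    essential_idx = rng.choice(n_genes, size=n_essential, replace=False)
    genes["essential"] = False
    genes.loc[essential_idx, "essential"] = True
    genes["has_paralog"] = rng.random(n_genes) < frac_paralog
    internal = genes.index[~genes["telomeric"]]
    rdna_pick = internal[rng.integers(len(internal))] if len(internal) else genes.index[0]
    genes.loc[rdna_pick, "rdna"] = True
    return genes, chromosomes


# ---------------------------------------------------------------------------
# compendium


def generate_compendium(
    genome: pd.DataFrame,
    n_complexes: int = 200,
    complex_size_mean: float = 4.0,
    n_pathways: int = 60,
    pathway_size_mean: float = 15.0,
    coexpr_density: float = 0.01,
    coexpr_score_loc: float = 0.5,
    coexpr_score_scale: float = 0.75,
    n_localizations: int = 15,
    n_processes: int = 80,
    annotated_fraction: float = 0.8,
    pleiotropy_fraction: float = 0.05,
    seed: int = 0,
) -> FunctionalCompendium:
    """Generate a functional compendium over the genome's gene universe.

    A configurable fraction of genes carries no annotation in each
    standard, exercising the rule that only pairs with data for both
    genes are evaluable. Complex sizes are 2 + Poisson; coexpression is a
    symmetric scored edge list at the requested density with scores drawn
    Normal(loc, scale) — the analysis cutoff is score > 1.
    """
    if not 0 <= coexpr_density <= 1 or not 0 <= annotated_fraction <= 1:
        raise ValueError("densities/fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = genome["gene_id"].to_numpy()
    n = len(gene_ids)

    def annotatable(stream: str) -> np.ndarray:
        r = _sub_rng(seed, "annotatable", stream)
        k = int(round(annotated_fraction * n))
        return r.choice(gene_ids, size=k, replace=False)

    cx_pool = annotatable("complex")
    if n_complexes > len(cx_pool) // 2:
        raise ValueError("more complexes requested than representable")
    complexes = {}
    for i in range(n_complexes):
        size = 2 + rng.poisson(max(complex_size_mean - 2, 0))
        size = min(size, len(cx_pool))
        members = rng.choice(cx_pool, size=size, replace=False)
        complexes[f"CPX{i:03d}"] = frozenset(members)

    pw_pool = annotatable("pathway")
    pathways = {}
    for i in range(n_pathways):
        size = max(2, rng.poisson(pathway_size_mean))
        size = min(size, len(pw_pool))
        members = rng.choice(pw_pool, size=size, replace=False)
        pathways[f"PWY{i:03d}"] = frozenset(members)

    ce_pool = annotatable("coexpression")
    m = len(ce_pool)
    n_edges = int(round(coexpr_density * m * (m - 1) / 2))
    coexpression: dict[tuple[str, str], float] = {}
    while len(coexpression) < n_edges:
        a, b = rng.integers(0, m, size=2)
        if a == b:
            continue
        key = tuple(sorted((ce_pool[a], ce_pool[b])))
        if key not in coexpression:
            coexpression[key] = float(rng.normal(coexpr_score_loc, coexpr_score_scale))

    loc_pool = annotatable("localization")
    compartments = [f"LOC{i:02d}" for i in range(n_localizations)]
    localization = {
        g: frozenset(
            rng.choice(compartments, size=rng.integers(1, 3), replace=False)
        )
        for g in loc_pool
    }

    proc_pool = annotatable("process")
    terms = [f"BP{i:03d}" for i in range(n_processes)]
    processes = {
        g: frozenset(rng.choice(terms, size=rng.integers(1, 4), replace=False))
        for g in proc_pool
    }
    n_pleio = int(round(pleiotropy_fraction * len(proc_pool)))
    pleio = frozenset(rng.choice(proc_pool, size=n_pleio, replace=False))

    return FunctionalCompendium(
        complexes=complexes,
        pathways=pathways,
        coexpression=coexpression,
        localization=localization,
        processes=processes,
        pleiotropy_flags=pleio,
    )


# ---------------------------------------------------------------------------
# suppression study


@dataclass
class StrainTruth:
    strain_id: str
    query_gene: str
    true_suppressor_genes: list[str]
    mechanism: str  # snp | aneuploidy | partial_amplification | wgd | none
    ploidy: int
    copy_numbers: dict[int, int]
    partial_segments: list[tuple[int, int, int, int]]  # (chrom, start, end, copy)
    planted_variants: list[dict]
    coupling_tier: Optional[str]
    fitness: float


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    strains: dict[str, StrainTruth] = field(default_factory=dict)
    dispensable_queries: set[str] = field(default_factory=set)
    tested_queries: set[str] = field(default_factory=set)
    planted_hits: dict[str, str] = field(default_factory=dict)  # screen_id -> gene
    frequent_flyers: list[str] = field(default_factory=list)
    planted_effects: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "strains": {k: asdict(v) for k, v in self.strains.items()},
            "dispensable_queries": sorted(self.dispensable_queries),
            "tested_queries": sorted(self.tested_queries),
            "planted_hits": self.planted_hits,
            "frequent_flyers": self.frequent_flyers,
            "planted_effects": self.planted_effects,
        }
        return json.dumps(payload, indent=1, default=str)


def _related_partners(
    query: str, compendium: FunctionalCompendium, genes: Sequence[str]
) -> dict[str, list[str]]:
    """Partner genes of the query per coupling tier, tiers disjoint in
    priority order (cocomplex > copathway > coexpressed > colocalized)."""
    cocomplex: set[str] = set()
    for cid in compendium.complexes_of(query):
        cocomplex |= set(compendium.complexes[cid])
    cocomplex.discard(query)
    copathway: set[str] = set()
    for pid in compendium.pathways_of(query):
        copathway |= set(compendium.pathways[pid])
    copathway -= cocomplex | {query}
    coexpressed = {
        g
        for g in genes
        if g != query
        and (compendium.coexpression_score(query, g) or 0) > compendium.coexpression_cutoff
    } - cocomplex - copathway
    q_loc = compendium.localization.get(query, frozenset())
    colocalized = {
        g
        for g in genes
        if g != query and compendium.localization.get(g, frozenset()) & q_loc
    } - cocomplex - copathway - coexpressed
    return {
        "cocomplex": sorted(cocomplex),
        "copathway": sorted(copathway),
        "coexpressed": sorted(coexpressed),
        "colocalized": sorted(colocalized),
    }


def generate_suppression_study(
    genome: pd.DataFrame,
    compendium: FunctionalCompendium,
    n_queries: int = 100,
    frac_dispensable: float = 0.17,
    mechanism_mix: Optional[Mapping[str, float]] = None,
    passenger_rate: float = 2.0,
    functional_coupling: float = 0.7,
    tier_mix: Optional[Mapping[str, float]] = None,
    experiments_per_query: int = 5,
    detection_p: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a suppressor-isolation cohort with known ground truth.

    Returns ``(strains, variants, experiments, truth)``. Query genes are
    sampled from the essential genes; each is dispensable with
    probability ``frac_dispensable``. Every experiment of a dispensable
    query succeeds with probability ``detection_p`` and each success
    yields one suppressor strain with a mechanism drawn from
    ``mechanism_mix``. With probability ``functional_coupling`` the true
    suppressor is functionally related to its query, the relation tier
    drawn from ``tier_mix`` (falling through to lower tiers when the
    query has no partner at the drawn tier). Passenger nonsynonymous
    variants are Poisson with the stated mean; aneuploidy-mechanism
    strains carry the suppressor's chromosome at copy 2 (haploid), WGD
    strains are ploidy 2 throughout with no SNP suppressor planted.
    """
    mechanism_mix = dict(mechanism_mix or DEFAULT_MECHANISM_MIX)
    tier_mix = dict(tier_mix or DEFAULT_TIER_MIX)
    if abs(sum(mechanism_mix.values()) - 1) > 1e-9:
        raise ValueError("mechanism_mix must sum to 1")
    if not 0 <= functional_coupling <= 1:
        raise ValueError("functional_coupling must be in [0, 1]")
    if functional_coupling > 0 and not (
        compendium.complexes or compendium.pathways or compendium.coexpression
        or compendium.localization
    ):
        raise ValueError("functional coupling requires a non-empty compendium")

    rng = np.random.default_rng(seed)
    essential = genome.loc[genome["essential"], "gene_id"].to_numpy()
    if n_queries > len(essential):
        raise ValueError("more queries requested than essential genes available")
    queries = rng.choice(essential, size=n_queries, replace=False)
    gene_ids = genome["gene_id"].to_numpy()
    gene_chrom = dict(zip(genome["gene_id"], genome["chromosome"]))
    gene_span = {
        r.gene_id: (r.start_bp, r.end_bp) for r in genome.itertuples()
    }
    chrom_len = genome.groupby("chromosome")["end_bp"].max().to_dict()

    mech_names = list(mechanism_mix)
    mech_probs = np.array([mechanism_mix[m] for m in mech_names])
    tier_names = list(tier_mix)
    tier_probs = np.array([tier_mix[t] for t in tier_names], dtype=float)
    tier_probs = tier_probs / tier_probs.sum()

    strain_rows, variant_rows, experiment_rows = [], [], []
    truth = SyntheticTruth(tested_queries=set(queries))
    strain_no = 0
    for query in queries:
        qrng = _sub_rng(seed, "query", str(query))
        dispensable = bool(qrng.random() < frac_dispensable)
        if dispensable:
            truth.dispensable_queries.add(query)
        partners = _related_partners(query, compendium, gene_ids)
        for exp_i in range(experiments_per_query):
            exp_id = f"{query}_e{exp_i + 1}"
            success = dispensable and qrng.random() < detection_p
            if not success:
                experiment_rows.append(
                    {"query_gene": query, "experiment_id": exp_id,
                     "outcome": "none", "suppressor_gene": None}
                )
                continue
            mech = mech_names[qrng.choice(len(mech_names), p=mech_probs)]
            # choose the true suppressor
            tier: Optional[str] = None
            if mech == "wgd":
                suppressor = None
            else:
                if qrng.random() < functional_coupling:
                    for t in [tier_names[qrng.choice(len(tier_names), p=tier_probs)],
                              *("cocomplex", "copathway", "coexpressed", "colocalized")]:
                        if partners.get(t):
                            tier = t
                            break
                if tier is not None:
                    pool = partners[tier]
                    suppressor = pool[qrng.integers(len(pool))]
                else:
                    suppressor = str(qrng.choice(gene_ids))
                    while suppressor == query:
                        suppressor = str(qrng.choice(gene_ids))
            strain_no += 1
            strain_id = f"ES{strain_no:04d}"
            ploidy = 2 if mech == "wgd" else 1
            copy_numbers = {int(c): ploidy for c in chrom_len}
            segments: list[tuple[int, int, int, int]] = []
            planted_variants: list[dict] = []
            if mech == "aneuploidy":
                copy_numbers[int(gene_chrom[suppressor])] = 2
            elif mech == "partial_amplification":
                c = int(gene_chrom[suppressor])
                s, e = gene_span[suppressor]
                # a *partial* amplification covers at most ~40% of the
                # chromosome so the chromosome-level call stays euploid
                length = int(
                    min(qrng.integers(50_000, 200_000), 0.4 * chrom_len[c])
                )
                start = max(0, int(s) - int(qrng.integers(0, max(length // 2, 1))))
                end = min(int(chrom_len[c]), start + length)
                segments.append((c, start, end, 2))
            elif mech == "snp":
                s, e = gene_span[suppressor]
                planted_variants.append(
                    {
                        "gene_id": suppressor,
                        "kind": "missense",
                        "nonsynonymous": True,
                        "position_bp": int(qrng.integers(s, e + 1)),
                        "chromosome": int(gene_chrom[suppressor]),
                    }
                )
            # passenger variants
            n_pass = int(qrng.poisson(passenger_rate))
            for _ in range(n_pass):
                g = str(qrng.choice(gene_ids))
                s, e = gene_span[g]
                nonsyn = bool(qrng.random() < 0.8)
                planted_variants.append(
                    {
                        "gene_id": g,
                        "kind": "missense" if nonsyn else "synonymous",
                        "nonsynonymous": nonsyn,
                        "position_bp": int(qrng.integers(s, e + 1)),
                        "chromosome": int(gene_chrom[g]),
                    }
                )
            fitness = float(0.3 + 0.7 * qrng.beta(5, 2))
            strain_rows.append(
                {"strain_id": strain_id, "query_gene": query, "ploidy": ploidy,
                 "fitness": fitness}
            )
            for v in planted_variants:
                variant_rows.append({"strain_id": strain_id, **v})
            experiment_rows.append(
                {"query_gene": query, "experiment_id": exp_id,
                 "outcome": "dispensable_found", "suppressor_gene": suppressor}
            )
            truth.strains[strain_id] = StrainTruth(
                strain_id=strain_id,
                query_gene=str(query),
                true_suppressor_genes=[suppressor] if suppressor else [],
                mechanism=mech,
                ploidy=ploidy,
                copy_numbers=copy_numbers,
                partial_segments=segments,
                planted_variants=planted_variants,
                coupling_tier=tier,
                fitness=fitness,
            )
    strains = pd.DataFrame(
        strain_rows, columns=["strain_id", "query_gene", "ploidy", "fitness"]
    )
    variants = pd.DataFrame(
        variant_rows,
        columns=["strain_id", "gene_id", "kind", "nonsynonymous",
                 "position_bp", "chromosome"],
    )
    experiments = pd.DataFrame(
        experiment_rows,
        columns=["query_gene", "experiment_id", "outcome", "suppressor_gene"],
    )
    return strains, variants, experiments, truth


# ---------------------------------------------------------------------------
# depth profiles


def generate_depth_profiles(
    truth: SyntheticTruth,
    chromosomes: pd.DataFrame,
    bin_bp: int = 10_000,
    mean_depth: float = 30.0,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned read-depth profiles for every strain in the truth object.

    Expected bin depth is ``mean_depth * copy / ploidy`` (euploid bins sit
    at the mean); partial amplifications raise only the bins inside the
    planted segment; noise is multiplicative Gaussian with the stated
    coefficient of variation.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    min_len = int(chromosomes["length_bp"].min())
    if bin_bp > min_len:
        raise ValueError("bin larger than the smallest chromosome")
    rows = []
    lengths = dict(zip(chromosomes["chromosome"], chromosomes["length_bp"]))
    for strain_id, st in truth.strains.items():
        rng = _sub_rng(seed, "depth", strain_id)
        for chrom, L in lengths.items():
            copy = st.copy_numbers.get(int(chrom), st.ploidy)
            edges = np.arange(0, int(L), bin_bp)
            for start in edges:
                end = min(start + bin_bp, int(L))
                c = copy
                for sc, ss, se, k in st.partial_segments:
                    # a bin takes the segment's copy number when at least
                    # half of it lies inside the segment
                    overlap = min(end, se) - max(int(start), ss)
                    if sc == chrom and overlap >= 0.5 * (end - start):
                        c = k
                expected = mean_depth * c / st.ploidy
                depth = expected
                if noise_cv > 0:
                    depth = max(expected * rng.normal(1.0, noise_cv), 0.0)
                rows.append(
                    {"strain_id": strain_id, "chromosome": int(chrom),
                     "bin_start": int(start), "bin_end": int(end),
                     "depth": float(depth)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overexpression screens


def generate_overexpression_screen(
    query: str,
    chromosome_genes: Sequence[str],
    true_suppressor: Optional[str],
    effect_size: float = 0.5,
    noise_sd: float = 0.1,
    n_replicates: int = 4,
    frequent_flyer_genes: Sequence[str] = (),
    include_self_plasmid: bool = False,
    n_empty: int = 64,
    screen_id: str = "S1",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One aneuploidy-complementation overexpression screen.

    Empty-vector colonies are drawn around 1.0; colonies overexpressing
    the true suppressor (and any frequent-flyer gene, which is shifted in
    every generated screen) are shifted up by ``effect_size``. Suppression
    raises colony size, so a negative effect size is invalid.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0 (suppression raises colony size)")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if true_suppressor is not None and true_suppressor not in chromosome_genes:
        raise ValueError("true_suppressor must be among chromosome_genes (or None)")
    rng = _sub_rng(seed, "screen", screen_id)
    rows = []
    for _ in range(n_empty):
        rows.append(
            {"query": query, "array_gene": "EMPTY", "plasmid": "empty",
             "colony_size": float(rng.normal(1.0, noise_sd)),
             "screen_id": screen_id, "is_empty_vector": True}
        )
    flyers = set(frequent_flyer_genes)
    array_genes = list(chromosome_genes) + sorted(flyers - set(chromosome_genes))
    if include_self_plasmid and query not in array_genes:
        array_genes.append(query)
    for gene in array_genes:
        shift = 0.0
        if gene == true_suppressor or gene in flyers or (
            include_self_plasmid and gene == query
        ):
            shift = effect_size
        for _ in range(n_replicates):
            rows.append(
                {"query": query, "array_gene": gene, "plasmid": f"p-{gene}",
                 "colony_size": float(rng.normal(1.0 + shift, noise_sd)),
                 "screen_id": screen_id, "is_empty_vector": False}
            )
    truth = {
        "screen_id": screen_id,
        "query": query,
        "true_suppressor": true_suppressor,
        "frequent_flyers": sorted(flyers),
    }
    return pd.DataFrame(rows), truth


def generate_screen_series(
    screens: Sequence[tuple[str, Sequence[str], Optional[str]]],
    n_frequent_flyers: int = 2,
    flyer_pool: Optional[Sequence[str]] = None,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """A series of screens sharing the same planted frequent flyers.

    ``screens`` is a list of (query, chromosome_genes, true_suppressor).
    Frequent flyers are drawn once from ``flyer_pool`` (default: union of
    all chromosome gene lists) and planted as shifted in *every* screen.
    """
    rng = np.random.default_rng(seed)
    pool = list(flyer_pool) if flyer_pool is not None else sorted(
        {g for _, genes, _ in screens for g in genes}
    )
    flyers = (
        [str(g) for g in rng.choice(pool, size=n_frequent_flyers, replace=False)]
        if n_frequent_flyers
        else []
    )
    frames = []
    truth = SyntheticTruth(frequent_flyers=list(flyers))
    for i, (query, genes, suppressor) in enumerate(screens):
        sid = f"S{i + 1}"
        df, _ = generate_overexpression_screen(
            query, genes, suppressor,
            frequent_flyer_genes=flyers, screen_id=sid, seed=seed, **kwargs,
        )
        frames.append(df)
        if suppressor is not None:
            truth.planted_hits[sid] = suppressor
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# feature tables

DEFAULT_PLANTED_EFFECTS: dict[str, dict] = {
    # dispensable genes are enriched for paralogs and membrane proteins,
    # depleted for complex members, and have lower coexpression degree
    "has_paralog": {"kind": "binary", "p_dispensable": 0.45, "p_indispensable": 0.20},
    "complex_member": {"kind": "binary", "p_dispensable": 0.35, "p_indispensable": 0.60},
    "membrane_associated": {"kind": "binary", "p_dispensable": 0.30, "p_indispensable": 0.12},
    "coexpression_degree": {
        "kind": "continuous", "mean_dispensable": 18.0, "mean_indispensable": 28.0,
        "sd": 9.0,
    },
    "dn_ds": {
        "kind": "continuous", "mean_dispensable": 0.12, "mean_indispensable": 0.07,
        "sd": 0.03,
    },
    "expression_variance": {
        "kind": "continuous", "mean_dispensable": 1.3, "mean_indispensable": 1.0,
        "sd": 0.4,
    },
    # zero-effect negative controls
    "control_binary": {"kind": "binary", "p_dispensable": 0.3, "p_indispensable": 0.3},
    "control_continuous": {
        "kind": "continuous", "mean_dispensable": 0.0, "mean_indispensable": 0.0,
        "sd": 1.0,
    },
}


def generate_feature_table(
    genome: pd.DataFrame,
    compendium: Optional[FunctionalCompendium] = None,
    planted_effects: Optional[Mapping[str, Mapping]] = None,
    n_dispensable: Optional[int] = None,
    n_indispensable: Optional[int] = None,
    frac_dispensable: float = 0.17,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Gene feature table with dispensability labels and planted effects.

    Essential genes are labeled dispensable/indispensable (group sizes
    explicit or by fraction); the rest stay ``untested`` with features
    drawn from the indispensable distributions. Binary features come from
    group-specific Bernoulli rates, continuous features from
    group-shifted normals; zero-effect features act as negative controls.
    """
    effects = dict(planted_effects or DEFAULT_PLANTED_EFFECTS)
    for name, spec in effects.items():
        if spec.get("kind") not in ("binary", "continuous"):
            raise ValueError(f"unknown feature kind for {name!r}: {spec.get('kind')}")
    rng = np.random.default_rng(seed)
    essential = genome.loc[genome["essential"], "gene_id"].tolist()
    if n_dispensable is None:
        n_dispensable = int(round(frac_dispensable * len(essential)))
    if n_indispensable is None:
        n_indispensable = len(essential) - n_dispensable
    if n_dispensable + n_indispensable > len(essential):
        raise ValueError("not enough essential genes for the requested groups")
    order = rng.permutation(len(essential))
    disp = [essential[i] for i in order[:n_dispensable]]
    indisp = [essential[i] for i in order[n_dispensable:n_dispensable + n_indispensable]]
    rest = [essential[i] for i in order[n_dispensable + n_indispensable:]]
    labels = (
        {g: "dispensable" for g in disp}
        | {g: "indispensable" for g in indisp}
        | {g: "untested" for g in rest}
    )
    table = pd.DataFrame(index=sorted(labels), columns=list(effects), dtype=float)
    for name, spec in effects.items():
        frng = _sub_rng(seed, "feature", name)
        for g in table.index:
            group = labels[g]
            if spec["kind"] == "binary":
                p = (
                    spec["p_dispensable"]
                    if group == "dispensable"
                    else spec["p_indispensable"]
                )
                table.loc[g, name] = float(frng.random() < p)
            else:
                mu = (
                    spec["mean_dispensable"]
                    if group == "dispensable"
                    else spec["mean_indispensable"]
                )
                table.loc[g, name] = float(frng.normal(mu, spec["sd"]))
    table["label"] = [labels[g] for g in table.index]
    table.index.name = "gene_id"
    truth = SyntheticTruth(planted_effects={k: dict(v) for k, v in effects.items()})
    truth.dispensable_queries = set(disp)
    return table, truth


# ---------------------------------------------------------------------------
# species panel


def generate_species_panel(
    genome: pd.DataFrame,
    yeast_classes: Optional[Mapping[str, str]] = None,
    n_species: int = 4,
    status_probs: Optional[Mapping[str, Sequence[float]]] = None,
    essential_given_1to1: Optional[Mapping[str, float]] = None,
    n_cell_lines: int = 739,
    ceres_params: Optional[Mapping[str, tuple[float, float]]] = None,
    indispensable_like: Optional[Iterable[str]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Cross-species ortholog/essentiality panel and dependency matrix.

    Each essential yeast gene gets an ortholog status per species
    (absent / duplicated / one_to_one, probabilities conditional on its
    dispensability class) and, for 1-to-1 orthologs, an essentiality
    flag. A CERES-like score matrix over ``n_cell_lines`` cell lines is
    drawn so that a planted indispensable-like subset scores below the
    essentiality threshold (-0.7) in > 90% of lines.
    """
    status_probs = dict(
        status_probs
        or {
            # (absent, duplicated, one_to_one)
            "dispensable": (0.35, 0.25, 0.40),
            "indispensable": (0.12, 0.15, 0.73),
        }
    )
    essential_given_1to1 = dict(
        essential_given_1to1 or {"dispensable": 0.30, "indispensable": 0.75}
    )
    # (group mean, within-gene sd across lines, between-gene sd of means)
    ceres_params = dict(
        ceres_params
        or {"indispensable_like": (-1.3, 0.25, 0.08), "other": (-0.2, 0.25, 0.3)}
    )
    genes = genome.loc[genome["essential"], "gene_id"].tolist()
    classes = dict(yeast_classes or {})
    rows = []
    for g in genes:
        cls = classes.get(g, "indispensable")
        probs = status_probs.get(cls, status_probs["indispensable"])
        grng = _sub_rng(seed, "ortholog", g)
        for s in range(n_species):
            status = ("absent", "duplicated", "one_to_one")[
                grng.choice(3, p=np.asarray(probs) / np.sum(probs))
            ]
            essential = (
                bool(grng.random() < essential_given_1to1.get(cls, 0.75))
                if status == "one_to_one"
                else None
            )
            rows.append(
                {"gene": g, "species": f"SP{s + 1}", "status": status,
                 "essential": essential}
            )
    orthologs = pd.DataFrame(rows)

    planted = set(
        indispensable_like
        if indispensable_like is not None
        else [g for g in genes if classes.get(g, "indispensable") == "indispensable"]
    )
    crng = _sub_rng(seed, "ceres")
    mat = np.empty((len(genes), n_cell_lines))
    for i, g in enumerate(genes):
        params = ceres_params["indispensable_like" if g in planted else "other"]
        mu, sd = params[0], params[1]
        between = params[2] if len(params) > 2 else 0.0
        mu_g = float(crng.normal(mu, between)) if between else mu
        mat[i] = crng.normal(mu_g, sd, size=n_cell_lines)
    ceres = pd.DataFrame(
        mat, index=genes, columns=[f"CL{j:03d}" for j in range(n_cell_lines)]
    )
    ceres.index.name = "gene"
    truth = SyntheticTruth()
    truth.planted_effects = {"indispensable_like": sorted(planted)}
    return orthologs, ceres, truth
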