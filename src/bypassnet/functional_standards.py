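"""Functional compendium and pairwise functional-relatedness predicates.

A *functional compendium* bundles the annotation standards used throughout
the analysis of bypass-suppression interactions: protein-complex membership,
pathway membership, a scored coexpression network, subcellular localization,
and biological-process annotation. From these, pairwise predicates
(cocomplex, copathway, coexpressed, colocalized, coannotated) are computed
with an explicit *unknown* state for missing data: a pair is only evaluable
for a standard when both genes carry data for that standard.

The four core predicates drive a lexicographic priority code used for
suppressor-gene ranking: cocomplex (weight 8) > copathway (4) >
coexpressed (2) > colocalized (1). Unknown counts as 0 in the code (missing
data must not be rewarded) but pairs with unknown status are excluded from
enrichment denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Optional

__all__ = [
    "FunctionalCompendium",
    "RelatednessVector",
    "relatedness_vector",
    "classify_suppression_mechanism",
    "is_multifunctional",
    "build_background_pairs",
    "PRIORITY_WEIGHTS",
]

#: Lexicographic weights of the four ranking predicates (highest first).
PRIORITY_WEIGHTS = {"cocomplex": 8, "copathway": 4, "coexpressed": 2, "colocalized": 1}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class RelatednessVector:
    """Tri-state functional-connection predicates for one gene pair.

    Each predicate is ``True``, ``False`` or ``None`` (unknown — one of the
    two genes lacks data for that standard). ``priority_value`` is the
    4-bit integer built from (cocomplex, copathway, coexpressed,
    colocalized) with unknown treated as 0; the fifth predicate
    (``coannotated_process``) is carried for mechanism classification and
    enrichment but does not enter the code.
    """

    cocomplex: Optional[bool]
    copathway: Optional[bool]
    coexpressed: Optional[bool]
    colocalized: Optional[bool]
    coannotated_process: Optional[bool]

    @property
    def priority_value(self) -> int:
        return (
            (8 if self.cocomplex else 0)
            + (4 if self.copathway else 0)
            + (2 if self.coexpressed else 0)
            + (1 if self.colocalized else 0)
        )

    @property
    def any_related(self) -> bool:
        """True if any predicate (including shared process) is true."""
        return bool(
            self.cocomplex
            or self.copathway
            or self.coexpressed
            or self.colocalized
            or self.coannotated_process
        )


@dataclass
class FunctionalCompendium:
    """Annotation standards over a gene universe.

    Parameters
    ----------
    complexes, pathways
        Mapping of complex/pathway id to its member gene set (size >= 2).
    coexpression
        Mapping of unordered gene pair (sorted tuple) to a coexpression
        score. Genes that appear in at least one scored pair are treated
        as having coexpression data; a scored pair is *coexpressed* when
        its score is strictly greater than ``coexpression_cutoff``.
    localization
        Mapping gene -> set of subcellular compartments.
    processes
        Mapping gene -> set of biological-process terms.
    pleiotropy_flags
        Genes annotated as highly pleiotropic.
    """

    complexes: Mapping[str, FrozenSet[str]] = field(default_factory=dict)
    pathways: Mapping[str, FrozenSet[str]] = field(default_factory=dict)
    coexpression: Mapping[tuple[str, str], float] = field(default_factory=dict)
    localization: Mapping[str, FrozenSet[str]] = field(default_factory=dict)
    processes: Mapping[str, FrozenSet[str]] = field(default_factory=dict)
    pleiotropy_flags: FrozenSet[str] = frozenset()
    coexpression_cutoff: float = 1.0

    def __post_init__(self) -> None:
        for name, groups in (("complex", self.complexes), ("pathway", self.pathways)):
            for gid, members in groups.items():
                if len(members) < 2:
                    raise ValueError(f"{name} {gid!r} has fewer than 2 members")
        self._gene_complexes: dict[str, set[str]] = {}
        for cid, members in self.complexes.items():
            for g in members:
                self._gene_complexes.setdefault(g, set()).add(cid)
        self._gene_pathways: dict[str, set[str]] = {}
        for pid, members in self.pathways.items():
            for g in members:
                self._gene_pathways.setdefault(g, set()).add(pid)
        self._coexpr: dict[tuple[str, str], float] = {}
        self._coexpr_genes: set[str] = set()
        for (a, b), score in self.coexpression.items():
            if a == b:
                raise ValueError(f"self-pair in coexpression data: {a!r}")
            if not (score == score and abs(score) != float("inf")):
                raise ValueError(f"non-finite coexpression score for ({a}, {b})")
            self._coexpr[_pair_key(a, b)] = float(score)
            self._coexpr_genes.update((a, b))

    # -- per-standard availability --------------------------------------
    def has_complex_data(self, gene: str) -> bool:
        return gene in self._gene_complexes

    def has_pathway_data(self, gene: str) -> bool:
        return gene in self._gene_pathways

    def has_coexpression_data(self, gene: str) -> bool:
        return gene in self._coexpr_genes

    def has_localization_data(self, gene: str) -> bool:
        return bool(self.localization.get(gene))

    def has_process_data(self, gene: str) -> bool:
        return bool(self.processes.get(gene))

    def coexpression_score(self, a: str, b: str) -> Optional[float]:
        return self._coexpr.get(_pair_key(a, b))

    def complexes_of(self, gene: str) -> set[str]:
        return self._gene_complexes.get(gene, set())

    def pathways_of(self, gene: str) -> set[str]:
        return self._gene_pathways.get(gene, set())


def relatedness_vector(
    gene_a: str, gene_b: str, compendium: FunctionalCompendium
) -> RelatednessVector:
    """Compute the tri-state relatedness predicates for a gene pair.

    Only pairs for which both genes carry data in a standard are evaluable
    for that standard; otherwise the predicate is unknown (``None``).
    Cocomplex is true iff some complex contains both genes and false iff
    both genes are annotated to complexes but to distinct, nonoverlapping
    ones. Coexpressed is true iff the pair's score is strictly greater
    than the cutoff (default 1.0).

    Raises
    ------
    ValueError
        For a self-pair.
    """
    if gene_a == gene_b:
        raise ValueError(f"self-pair {gene_a!r}: relatedness is undefined")
    c = compendium

    def _shared(avail_a: bool, avail_b: bool, set_a, set_b) -> Optional[bool]:
        if not (avail_a and avail_b):
            return None
        return bool(set_a & set_b)

    cocomplex = _shared(
        c.has_complex_data(gene_a),
        c.has_complex_data(gene_b),
        c.complexes_of(gene_a),
        c.complexes_of(gene_b),
    )
    copathway = _shared(
        c.has_pathway_data(gene_a),
        c.has_pathway_data(gene_b),
        c.pathways_of(gene_a),
        c.pathways_of(gene_b),
    )
    if c.has_coexpression_data(gene_a) and c.has_coexpression_data(gene_b):
        score = c.coexpression_score(gene_a, gene_b)
        coexpressed = score is not None and score > c.coexpression_cutoff
    else:
        coexpressed = None
    colocalized = _shared(
        c.has_localization_data(gene_a),
        c.has_localization_data(gene_b),
        c.localization.get(gene_a, frozenset()),
        c.localization.get(gene_b, frozenset()),
    )
    coannotated = _shared(
        c.has_process_data(gene_a),
        c.has_process_data(gene_b),
        c.processes.get(gene_a, frozenset()),
        c.processes.get(gene_b, frozenset()),
    )
    return RelatednessVector(cocomplex, copathway, coexpressed, colocalized, coannotated)


#: Mechanism classes in priority order.
MECHANISM_CLASSES = (
    "same complex",
    "same pathway",
    "same process",
    "other functional",
    "unrelated/unknown",
)


def classify_suppression_mechanism(
    query: str, suppressor: str, compendium: FunctionalCompendium
) -> str:
    """Assign a query-suppressor pair to a mechanism class.

    The first matching class in the priority order
    complex > pathway > process > other functional (coexpressed or
    colocalized) > unrelated/unknown.
    """
    v = relatedness_vector(query, suppressor, compendium)
    return mechanism_class_from_vector(v)


def mechanism_class_from_vector(v: RelatednessVector) -> str:
    if v.cocomplex:
        return "same complex"
    if v.copathway:
        return "same pathway"
    if v.coannotated_process:
        return "same process"
    if v.coexpressed or v.colocalized:
        return "other functional"
    return "unrelated/unknown"


def is_multifunctional(
    gene: str,
    compendium: FunctionalCompendium,
    functional_gene_sets: Mapping[str, Iterable[str]],
) -> bool:
    """A gene is multifunctional if flagged highly pleiotropic or annotated
    to two or more broadly defined functional gene sets."""
    if gene in compendium.pleiotropy_flags:
        return True
    return len(set(functional_gene_sets.get(gene, ()))) >= 2


def build_background_pairs(
    query_set: Iterable[str],
    universe: Iterable[str],
    observed_pairs: Iterable[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Background pair set for enrichment: every (query, genome gene) pair
    minus self-pairs and minus the observed suppression-interaction pairs.

    Pairs are directional (query, candidate-suppressor); observed pairs
    are removed with set semantics.
    """
    queries = set(query_set)
    genes = set(universe)
    observed = set(observed_pairs)
    return {
        (q, g) for q in queries for g in genes if g != q and (q, g) not in observed
    }
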