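import numpy as np
import pytest

from bypassnet import synthetic_data as sd
from bypassnet.functional_standards import FunctionalCompendium


@pytest.fixture(scope="session")
def small_genome():
    """400 genes on 8 unequal chromosomes, ~2 Mb."""
    return sd.generate_genome(
        n_genes=400, n_chromosomes=8, genome_bp=2_000_000, seed=101
    )


@pytest.fixture(scope="session")
def small_compendium(small_genome):
    genes, _ = small_genome
    return sd.generate_compendium(
        genes, n_complexes=40, n_pathways=20, coexpr_density=0.01, seed=101
    )


@pytest.fixture()
def toy_compendium():
    """Hand-built compendium with fully known predicate structure.

    A,B,C share complex X; D,E share complex Y; A,D share pathway P;
    A-F coexpressed at 2.0; A-G scored exactly 1.0 (below the strict
    cutoff); A,H colocalized; A,B share a process term. Gene Z has no
    annotation anywhere.
    """
    return FunctionalCompendium(
        complexes={"X": frozenset("ABC"), "Y": frozenset("DE")},
        pathways={"P": frozenset("AD")},
        coexpression={("A", "F"): 2.0, ("A", "G"): 1.0},
        localization={"A": frozenset(["nuc"]), "H": frozenset(["nuc"]),
                      "B": frozenset(["cyto"])},
        processes={"A": frozenset(["t1"]), "B": frozenset(["t1"]),
                   "C": frozenset(["t2"])},
        pleiotropy_flags=frozenset(["Q"]),
    )


def random_compendium(rng: np.random.Generator, genes: list[str]) -> FunctionalCompendium:
    """Small random compendium for property tests."""
    n = len(genes)
    complexes = {}
    for i in range(max(1, n // 10)):
        size = int(rng.integers(2, 5))
        complexes[f"X{i}"] = frozenset(rng.choice(genes, size=size, replace=False))
    pathways = {}
    for i in range(max(1, n // 12)):
        size = int(rng.integers(2, 7))
        pathways[f"P{i}"] = frozenset(rng.choice(genes, size=size, replace=False))
    coexpression = {}
    for _ in range(n):
        a, b = rng.choice(genes, size=2, replace=False)
        coexpression[tuple(sorted((a, b)))] = float(rng.normal(0.8, 0.8))
    comps = [f"L{i}" for i in range(5)]
    localization = {
        g: frozenset(rng.choice(comps, size=int(rng.integers(1, 3)), replace=False))
        for g in genes
        if rng.random() < 0.7
    }
    terms = [f"T{i}" for i in range(12)]
    processes = {
        g: frozenset(rng.choice(terms, size=int(rng.integers(1, 3)), replace=False))
        for g in genes
        if rng.random() < 0.7
    }
    return FunctionalCompendium(
        complexes=complexes, pathways=pathways, coexpression=coexpression,
        localization=localization, processes=processes,
    )
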