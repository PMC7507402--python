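"""Plain-TSV readers and writers for every pipeline table.

All tables are tab-separated with a header row; the same schemas are
produced by the synthetic generators and accepted for real data. The
functional compendium is a directory of five/six TSVs (complexes,
pathways, coexpression, localization, processes, and optional pleiotropy
flags).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .functional_standards import FunctionalCompendium
from .synthetic_data import SyntheticTruth

__all__ = [
    "read_table",
    "write_table",
    "write_compendium",
    "read_compendium",
    "write_truth",
]

PathLike = Union[str, Path]


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_compendium(compendium: FunctionalCompendium, out_dir: PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"complex_id": cid, "gene_id": g}
        for cid, members in compendium.complexes.items()
        for g in sorted(members)
    ]
    write_table(pd.DataFrame(rows, columns=["complex_id", "gene_id"]),
                out / "complexes.tsv")
    rows = [
        {"pathway_id": pid, "gene_id": g}
        for pid, members in compendium.pathways.items()
        for g in sorted(members)
    ]
    write_table(pd.DataFrame(rows, columns=["pathway_id", "gene_id"]),
                out / "pathways.tsv")
    rows = [
        {"gene_a": a, "gene_b": b, "score": s}
        for (a, b), s in sorted(compendium.coexpression.items())
    ]
    write_table(pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]),
                out / "coexpression.tsv")
    rows = [
        {"gene_id": g, "compartment": c}
        for g, comps in sorted(compendium.localization.items())
        for c in sorted(comps)
    ]
    write_table(pd.DataFrame(rows, columns=["gene_id", "compartment"]),
                out / "localization.tsv")
    rows = [
        {"gene_id": g, "term": t}
        for g, terms in sorted(compendium.processes.items())
        for t in sorted(terms)
    ]
    write_table(pd.DataFrame(rows, columns=["gene_id", "term"]),
                out / "processes.tsv")
    write_table(
        pd.DataFrame({"gene_id": sorted(compendium.pleiotropy_flags)}),
        out / "pleiotropy.tsv",
    )


def read_compendium(in_dir: PathLike) -> FunctionalCompendium:
    d = Path(in_dir)
    cx = read_table(d / "complexes.tsv")
    complexes = {
        cid: frozenset(sub["gene_id"]) for cid, sub in cx.groupby("complex_id")
    }
    pw = read_table(d / "pathways.tsv")
    pathways = {
        pid: frozenset(sub["gene_id"]) for pid, sub in pw.groupby("pathway_id")
    }
    ce = read_table(d / "coexpression.tsv")
    coexpression = {
        (r.gene_a, r.gene_b): float(r.score) for r in ce.itertuples()
    }
    lc = read_table(d / "localization.tsv")
    localization = {
        g: frozenset(sub["compartment"]) for g, sub in lc.groupby("gene_id")
    }
    pr = read_table(d / "processes.tsv")
    processes = {g: frozenset(sub["term"]) for g, sub in pr.groupby("gene_id")}
    pleio_path = d / "pleiotropy.tsv"
    pleio = (
        frozenset(read_table(pleio_path)["gene_id"])
        if pleio_path.exists()
        else frozenset()
    )
    return FunctionalCompendium(
        complexes=complexes,
        pathways=pathways,
        coexpression=coexpression,
        localization=localization,
        processes=processes,
        pleiotropy_flags=pleio,
    )


def write_truth(truth: SyntheticTruth, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(truth.to_json())
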