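"""Readers and writers for the pipeline's on-disk formats.

Hybridizations, truth tables, contrast matrices and DE tables travel as
plain TSV; the toy ontology as OBO 1.2 (read back through obonet); gene
annotations as GAF 2.1 (read back through Biopython's GOA parser); run
metadata as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .preprocess import ContrastMatrix
from .simulate import HybridizationArray

ARRAY_COLUMNS = ("probe_id", "gene_id", "dye_orientation", "red", "green")


def write_array_tsv(array: HybridizationArray, path: str | Path) -> None:
    frame = array.spots.copy()
    frame["dye_orientation"] = array.dye_orientation
    frame[list(ARRAY_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_array_tsv(
    path: str | Path,
    array_id: str,
    contrast_id: str,
    bio_rep: int,
) -> HybridizationArray:
    frame = pd.read_csv(path, sep="\t")
    missing = set(ARRAY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    orientations = frame["dye_orientation"].unique()
    if len(orientations) != 1:
        raise ValueError(f"{path}: mixed dye orientations")
    spots = frame[["probe_id", "gene_id", "red", "green"]].copy()
    spots["floored"] = False
    return HybridizationArray(
        array_id=array_id,
        contrast_id=contrast_id,
        bio_rep=bio_rep,
        dye_orientation=str(orientations[0]),
        spots=spots,
    )


def read_genepix_tsv(
    path: str | Path,
    array_id: str,
    contrast_id: str,
    bio_rep: int,
    dye_orientation: str,
    columns: dict[str, str] | None = None,
) -> HybridizationArray:
    """Read a generic GenePix-like spot table with configurable column names.

    `columns` maps the canonical names (probe_id, gene_id, red, green) to
    the column names in the file; defaults assume the canonical names.
    """
    columns = columns or {}
    mapping = {
        columns.get(k, k): k for k in ("probe_id", "gene_id", "red", "green")
    }
    frame = pd.read_csv(path, sep="\t")
    missing = set(mapping) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spots = frame[list(mapping)].rename(columns=mapping)
    spots["floored"] = False
    return HybridizationArray(
        array_id=array_id,
        contrast_id=contrast_id,
        bio_rep=bio_rep,
        dye_orientation=dye_orientation,
        spots=spots,
    )


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the response class "null" is a literal string
    return pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=[],
        dtype={"gene_id": str, "response_class": str},
    )


def write_contrast_matrix(matrix: ContrastMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, sep="\t", float_format="%.10g")


def read_contrast_matrix(path: str | Path, contrast_id: str) -> ContrastMatrix:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ContrastMatrix(contrast_id=contrast_id, table=table)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    cols = ["lfc", "s2", "df", "n", "s2_tilde", "t_mod", "p_raw", "p_adj", "call"]
    de[[c for c in cols if c in de.columns]].to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# -- ontology / annotation ---------------------------------------------------

def write_obo(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Serialize a term DAG as OBO 1.2 (id, name, namespace, is_a,
    relationship stanza lines), round-trippable through obonet."""
    lines = ["format-version: 1.2", "ontology: synarray-toy", ""]
    for term in sorted(graph.nodes):
        data = graph.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        lines.append(f"namespace: {data.get('namespace', '')}")
        for _, parent, key in sorted(graph.out_edges(term, keys=True)):
            if key == "is_a":
                lines.append(f"is_a: {parent} ! {graph.nodes[parent].get('name', '')}")
            else:
                lines.append(
                    f"relationship: {key} {parent} "
                    f"! {graph.nodes[parent].get('name', '')}"
                )
        lines.append("")
    Path(path).write_text("\n".join(lines))


GAF_COLUMNS = [
    "DB", "DB_Object_ID", "DB_Object_Symbol", "Qualifier", "GO_ID",
    "DB:Reference", "Evidence", "With", "Aspect", "DB_Object_Name",
    "Synonym", "DB_Object_Type", "Taxon_ID", "Date", "Assigned_By",
    "Annotation_Extension", "Gene_Product_Form_ID",
]


def write_gaf(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write a gene/GO/aspect table as GAF 2.1 (columns 2, 5 and 9 carry the
    gene id, GO id and aspect code)."""
    rows = []
    for gene, term, aspect in annotation[
        ["gene_id", "go_id", "aspect"]
    ].itertuples(index=False):
        rows.append(
            [
                "synarray", gene, gene, "", term, "SYN:0000000", "IEA", "",
                aspect, "", "", "gene", "taxon:3880", "20250101", "synarray",
                "", "",
            ]
        )
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read a GAF 2.x file into a gene_id/go_id/aspect table."""
    from Bio.UniProt.GOA import gafiterator

    rows = []
    with open(path) as fh:
        for rec in gafiterator(fh):
            rows.append((rec["DB_Object_ID"], rec["GO_ID"], rec["Aspect"]))
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "aspect"])


def write_slim_list(slim_terms: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(slim_terms)) + "\n")


def read_slim_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


# -- manifest ----------------------------------------------------------------

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    input_files: Sequence[str | Path] = (),
    timestamp: str | None = None,
) -> None:
    """Run manifest: config snapshot, input checksums, package version.

    No wall-clock timestamp is recorded unless one is passed explicitly, so
    repeated runs with the same seed stay byte-identical.
    """
    from . import __version__

    manifest = {
        "package": "synarray",
        "version": __version__,
        "config": config,
        "inputs": {str(p): sha256_file(p) for p in input_files},
    }
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
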