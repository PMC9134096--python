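"""Readers and writers for the pipeline's canonical on-disk formats.

Canonical dialect: UTF-8 TSV with a header row; matrices carry features in
rows and samples in columns with the feature id in the first column; gene
sets use the Broad GMT convention (name, description, tab-separated gene
ids).  Floats are serialised with 12 significant digits so repeated runs
produce byte-identical files.  All loaders validate table invariants and
name the offending row/column on failure.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import (
    AbundanceMatrix,
    CovariateTable,
    GeneSetCollection,
    GenomeHitTable,
    LipidTable,
    OrfDepthTable,
)

__all__ = [
    "read_lipid_table",
    "write_lipid_table",
    "read_genome_hits",
    "write_genome_hits",
    "read_orf_depths",
    "write_orf_depths",
    "read_covariates",
    "write_covariates",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_yaml_config",
    "write_yaml_config",
    "canonical_tsv_bytes",
    "file_sha256",
]

_FLOAT_FMT = "%.12g"


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def canonical_tsv_bytes(frame: pd.DataFrame) -> bytes:
    """Pinned byte representation of a table (12-significant-digit floats)."""
    return frame.to_csv(sep="\t", float_format=_FLOAT_FMT).encode()


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _check_numeric(frame: pd.DataFrame, path, non_negative: bool = True) -> None:
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric values in the data block")
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} (explicit zeros required)"
        )
    if non_negative and (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )


# -- lipid tables (species rows x sample columns + separate label file) -----

def write_lipid_table(table: LipidTable, path, labels_path) -> None:
    frame = table.concentrations.T
    frame.index.name = "species_id"
    _write_tsv(frame, path)
    labels = table.group_labels.to_frame()
    labels.index.name = "sample_id"
    _write_tsv(labels, labels_path)


def read_lipid_table(path, labels_path) -> LipidTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    _check_numeric(frame, path)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["group"]
    return LipidTable(concentrations=frame.T, group_labels=labels)


# -- genome hit tables ------------------------------------------------------

def write_genome_hits(hits: GenomeHitTable, path) -> None:
    frame = pd.concat(
        [hits.genome_lengths.rename("length"), hits.lineages.rename("lineage"),
         hits.best_hit_counts],
        axis=1,
    )
    frame.index.name = "genome_id"
    _write_tsv(frame, path)


def read_genome_hits(path) -> GenomeHitTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("length", "lineage"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    counts = frame.drop(columns=["length", "lineage"])
    _check_numeric(counts, path)
    return GenomeHitTable(
        best_hit_counts=counts,
        genome_lengths=frame["length"],
        lineages=frame["lineage"],
    )


# -- ORF depth tables -------------------------------------------------------

def write_orf_depths(orfs: OrfDepthTable, path) -> None:
    frame = pd.concat([orfs.gene_annotations.rename("gene_id"), orfs.depths], axis=1)
    frame.index.name = "orf_id"
    _write_tsv(frame, path)


def read_orf_depths(path) -> OrfDepthTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    depths = frame.drop(columns=["gene_id"])
    _check_numeric(depths, path)
    return OrfDepthTable(depths=depths, gene_annotations=frame["gene_id"])


# -- covariates -------------------------------------------------------------

def write_covariates(cov: CovariateTable, path) -> None:
    frame = cov.data.copy()
    frame.index.name = "sample_id"
    _write_tsv(frame, path)


def read_covariates(path) -> CovariateTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CovariateTable(data=frame)


# -- generic abundance matrices --------------------------------------------

def write_matrix(matrix: AbundanceMatrix, path) -> None:
    frame = matrix.values.copy()
    frame.index.name = f"feature_id:{matrix.level}"
    _write_tsv(frame, path)


def read_matrix(path, level: str | None = None,
                relative: bool = False) -> AbundanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    _check_numeric(frame, path)
    tag = frame.index.name or ""
    if level is None:
        level = tag.split(":", 1)[1] if ":" in tag else "gene"
    frame.index.name = "feature_id"
    return AbundanceMatrix(values=frame, level=level, relative=relative)


# -- GMT gene sets ----------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        if len(set(genes)) != len(genes):
            raise ValueError(f"{path}:{lineno}: set {name!r} has duplicated gene ids")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- YAML configs -----------------------------------------------------------

def read_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return data


def write_yaml_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
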