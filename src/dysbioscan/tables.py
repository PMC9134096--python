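"""Typed in-memory tables shared by all pipeline stages.

Every container wraps a pandas object and validates its invariants at
construction, so that a table loaded from disk or produced by a generator
is known-good before any statistics run on it.  Features live in rows and
samples in columns for abundance-style matrices; the lipid concentration
table follows the samples x species layout used by metabolomics tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LipidTable",
    "GenomeHitTable",
    "OrfDepthTable",
    "CovariateTable",
    "AbundanceMatrix",
    "GeneSetCollection",
    "TAXONOMIC_LEVELS",
]

#: Aggregation levels: phylum (L2) down to species (L7), plus "gene".
TAXONOMIC_LEVELS = ("L2", "L3", "L4", "L5", "L6", "L7")

_N_LINEAGE_RANKS = 7  # kingdom..species, semicolon delimited


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class LipidTable:
    """Lipid species concentrations (samples x species) with HC/CD labels.

    concentrations : DataFrame, index = sample ids, columns = species ids,
        non-negative values (pmol per unit sample mass).
    group_labels : Series over the same samples, values ``"HC"``/``"CD"``.
    """

    concentrations: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.concentrations.columns, "species ids")
        _check_unique(self.concentrations.index, "sample ids")
        if (self.concentrations.to_numpy() < 0).any():
            bad = self.concentrations.lt(0)
            cell = [(i, c) for i in bad.index for c in bad.columns if bad.at[i, c]][0]
            raise ValueError(f"negative concentration at sample {cell[0]!r}, species {cell[1]!r}")
        missing = self.concentrations.index.difference(self.group_labels.index)
        if len(missing):
            raise ValueError(f"samples without group label: {missing.tolist()}")
        self.group_labels = self.group_labels.reindex(self.concentrations.index)
        bad_labels = set(self.group_labels.unique()) - {"HC", "CD"}
        if bad_labels:
            raise ValueError(f"unknown group labels: {sorted(bad_labels)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def species_ids(self) -> pd.Index:
        return self.concentrations.columns

    def is_case(self) -> np.ndarray:
        return (self.group_labels == "CD").to_numpy()


@dataclass
class GenomeHitTable:
    """Per-genome best-hit read counts with genome lengths and lineages.

    best_hit_counts : DataFrame, genomes x samples, non-negative integers.
    genome_lengths : Series of positive base-pair lengths per genome.
    lineages : Series of 7-rank semicolon-delimited strings
        (``k__...;p__...;c__...;o__...;f__...;g__...;s__...``).
    """

    best_hit_counts: pd.DataFrame
    genome_lengths: pd.Series
    lineages: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.best_hit_counts.index, "genome ids")
        counts = self.best_hit_counts.to_numpy()
        if (counts < 0).any():
            raise ValueError("negative best-hit count")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("best-hit counts must be integral")
        self.genome_lengths = self.genome_lengths.reindex(self.best_hit_counts.index)
        if self.genome_lengths.isna().any() or (self.genome_lengths <= 0).any():
            raise ValueError("every genome needs a positive length")
        self.lineages = self.lineages.reindex(self.best_hit_counts.index)
        for lineno, (gid, lin) in enumerate(self.lineages.items(), start=1):
            if not isinstance(lin, str) or len(lin.split(";")) != _N_LINEAGE_RANKS:
                raise ValueError(
                    f"lineage for genome {gid!r} (line {lineno}) does not have "
                    f"{_N_LINEAGE_RANKS} semicolon-delimited ranks: {lin!r}"
                )

    @property
    def genome_ids(self) -> pd.Index:
        return self.best_hit_counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.best_hit_counts.columns


@dataclass
class OrfDepthTable:
    """Per-ORF mean coverage depths with an optional ORF -> KEGG gene map."""

    depths: pd.DataFrame
    gene_annotations: pd.Series  # index = ORF id, value = gene id or NaN

    def __post_init__(self) -> None:
        _check_unique(self.depths.index, "ORF ids")
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("negative ORF depth")
        self.gene_annotations = self.gene_annotations.reindex(self.depths.index)

    @property
    def orf_ids(self) -> pd.Index:
        return self.depths.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.depths.columns


@dataclass
class CovariateTable:
    """Per-sample nuisance covariates: sex (0/1) and age in years."""

    data: pd.DataFrame  # index = sample ids, columns include "sex", "age"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        for col in ("sex", "age"):
            if col not in self.data.columns:
                raise ValueError(f"covariate table lacks column {col!r}")
        if self.data[["sex", "age"]].isna().any().any():
            raise ValueError("missing covariate values are not supported")
        if not set(np.unique(self.data["sex"])) <= {0, 1}:
            raise ValueError("sex must be coded 0/1")
        if (self.data["age"] <= 0).any():
            raise ValueError("age must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def design_columns(self) -> pd.DataFrame:
        return self.data[["sex", "age"]].astype(float)


@dataclass
class AbundanceMatrix:
    """Features x samples abundance values with a rank-level tag.

    ``relative`` marks columns normalised to sum to one (checked to 1e-9
    over the retained features at construction).
    """

    values: pd.DataFrame
    level: str  # one of L2..L7 or "gene"
    relative: bool = False

    def __post_init__(self) -> None:
        allowed = set(TAXONOMIC_LEVELS) | {"gene", "genome"}
        if self.level not in allowed:
            raise ValueError(f"unknown level tag {self.level!r}")
        _check_unique(self.values.index, "feature ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundance value")
        if self.relative:
            colsums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(colsums, 1.0, atol=1e-9):
                raise ValueError("relative matrix columns must sum to 1")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, no duplicates in a set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicated gene ids")

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}
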