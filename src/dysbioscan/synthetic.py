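"""Seeded synthetic case-control cohorts with the statistical structure the
downstream stages assume.

The generators emulate the two study designs the pipeline targets: a small
fecal-lipidomics cohort (12 healthy controls vs 11 Crohn's-disease cases,
log-normal concentrations) and a shotgun-metagenomics cohort (40 vs 43
samples, compositional per-genome counts plus per-ORF depths and sex/age
covariates).  Group effects are planted on the leading features so recovery
power and type-I error of every downstream test can be simulated.

All randomness flows from ``SyntheticConfig.seed`` through named
``numpy.random.SeedSequence`` substreams, so adding one generator call never
perturbs another's output and identical configs give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import (
    CovariateTable,
    GeneSetCollection,
    GenomeHitTable,
    LipidTable,
    OrfDepthTable,
)

__all__ = [
    "SyntheticConfig",
    "gen_lipid_cohort",
    "gen_metagenome_cohort",
    "gen_gene_sets",
]

def _preset(defaults: dict, overrides: dict) -> "SyntheticConfig":
    merged = {**defaults, **overrides}
    if "n_effect_features" not in overrides:
        # shrinking the panel below the preset's planted count is fine
        merged["n_effect_features"] = min(merged["n_effect_features"],
                                          merged["n_features"])
    return SyntheticConfig(**merged)


# substream keys: one fixed integer per generator / table
_STREAM_LIPID = 1
_STREAM_TAXA = 2
_STREAM_ORF = 3
_STREAM_COVARIATE = 4
_STREAM_GENESETS = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs driving every generator.

    effect_log2fc is the planted log2 group difference on the leading
    ``n_effect_features`` features; ``noise_sd`` is the log2-scale SD of the
    within-group variation; ``covariate_effect`` shifts case ages (years) to
    exercise covariate adjustment; ``depth`` is the per-sample sequencing
    depth used for multinomial count sampling.
    """

    seed: int = 0
    n_control: int = 12
    n_case: int = 11
    n_features: int = 529
    n_effect_features: int = 15
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    covariate_effect: float = 0.0
    zero_inflation: float = 0.0
    depth: int = 100_000

    def __post_init__(self) -> None:
        for name in ("n_control", "n_case", "n_features"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"configuration error: {name} must be >= 1")
        if self.n_effect_features < 0 or self.n_effect_features > self.n_features:
            raise ValueError(
                "configuration error: n_effect_features must lie in "
                f"[0, n_features]; got {self.n_effect_features}"
            )
        if self.noise_sd <= 0:
            raise ValueError("configuration error: noise_sd must be > 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("configuration error: zero_inflation must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("configuration error: depth must be >= 1")

    # -- study-shaped presets -------------------------------------------------
    @staticmethod
    def lipid_default(seed: int = 0, **overrides) -> "SyntheticConfig":
        """12 HC vs 11 CD, 529 lipid species, 15 planted effects."""
        defaults = dict(seed=seed, n_control=12, n_case=11, n_features=529,
                        n_effect_features=15, effect_log2fc=2.0, noise_sd=0.25)
        return _preset(defaults, overrides)

    @staticmethod
    def metagenome_default(seed: int = 0, **overrides) -> "SyntheticConfig":
        """40 HC vs 43 CD, desk-scale genome panel with 5 planted effects."""
        defaults = dict(seed=seed, n_control=40, n_case=43, n_features=200,
                        n_effect_features=5, effect_log2fc=2.0, noise_sd=1.0,
                        depth=100_000)
        return _preset(defaults, overrides)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )

    def labels(self) -> pd.Series:
        ids = [f"HC{i + 1:02d}" for i in range(self.n_control)] + [
            f"CD{i + 1:02d}" for i in range(self.n_case)
        ]
        values = ["HC"] * self.n_control + ["CD"] * self.n_case
        return pd.Series(values, index=pd.Index(ids, name="sample_id"), name="group")


def gen_lipid_cohort(config: SyntheticConfig) -> LipidTable:
    """Log-normal lipid concentrations with a planted case shift.

    Concentration of species j in sample i is ``2**(mu_j + beta_j*case_i +
    noise_sd*z_ij)`` with ``beta_j = effect_log2fc`` for the first
    ``n_effect_features`` species and 0 otherwise; optional zero inflation
    replaces values by 0 at the configured rate.
    """
    rng = config.rng(_STREAM_LIPID)
    labels = config.labels()
    n = len(labels)
    m = config.n_features
    case = (labels == "CD").to_numpy(dtype=float)

    mu = rng.uniform(2.0, 10.0, size=m)  # baseline log2 pmol levels
    beta = np.zeros(m)
    beta[: config.n_effect_features] = config.effect_log2fc
    z = rng.standard_normal((n, m))
    log2_conc = mu[None, :] + case[:, None] * beta[None, :] + config.noise_sd * z
    conc = np.exp2(log2_conc)
    if config.zero_inflation > 0:
        conc[rng.random((n, m)) < config.zero_inflation] = 0.0

    species = pd.Index([f"lipid_{j + 1:04d}" for j in range(m)], name="species_id")
    frame = pd.DataFrame(conc, index=labels.index, columns=species)
    return LipidTable(concentrations=frame, group_labels=labels)


def _nested_lineages(n_genomes: int) -> pd.Series:
    """Deterministic 7-rank lineages in which genomes nest into a taxonomy.

    Successive ranks split by integer division so that every child clade has
    exactly one parent (hierarchical conservation is testable).
    """
    # branching: phyla of 24 genomes, classes of 12, orders of 6, families of 3,
    # genera of 2 (span sizes chosen so several levels are non-trivial even for
    # small panels); species are one per genome.
    spans = {"p": 24, "c": 12, "o": 6, "f": 3, "g": 2}
    lineages = []
    for i in range(n_genomes):
        parts = ["k__Bacteria"]
        for rank, span in spans.items():
            parts.append(f"{rank}__{rank.upper()}{i // span + 1:03d}")
        parts.append(f"s__S{i + 1:04d}")
        lineages.append(";".join(parts))
    idx = pd.Index([f"genome_{i + 1:04d}" for i in range(n_genomes)], name="genome_id")
    return pd.Series(lineages, index=idx, name="lineage")


def gen_metagenome_cohort(
    config: SyntheticConfig,
) -> tuple[GenomeHitTable, OrfDepthTable, CovariateTable, pd.Series]:
    """Compositional per-genome counts, per-ORF depths, and covariates.

    Latent per-genome log2 relative abundances are Gaussian with a planted
    case shift of ``effect_log2fc`` on the leading ``n_effect_features``
    genomes; counts are multinomial draws of ``depth`` reads per sample.  The
    ORF table carries 2 ORFs per synthetic gene (first ``n_effect_features``
    genes planted the same way) plus an unannotated background ORF pool.  If
    ``covariate_effect`` is non-zero, case ages are shifted by that many
    years so covariate adjustment can be exercised.
    """
    labels = config.labels()
    n = len(labels)
    m = config.n_features
    case = (labels == "CD").to_numpy(dtype=float)

    # --- taxa ---------------------------------------------------------------
    rng = config.rng(_STREAM_TAXA)
    base = rng.normal(0.0, 2.0, size=m)  # spread of latent log2 abundances
    beta = np.zeros(m)
    beta[: config.n_effect_features] = config.effect_log2fc
    logit = (
        base[None, :]
        + case[:, None] * beta[None, :]
        + config.noise_sd * rng.standard_normal((n, m))
    )
    if config.zero_inflation > 0:
        logit[rng.random((n, m)) < config.zero_inflation] = -np.inf
    rel = np.exp2(logit)
    all_off = rel.sum(axis=1) == 0
    if all_off.any():
        raise ValueError("zero_inflation left a sample with no detectable genome")
    rel /= rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.depth, p) for p in rel]).T  # genomes x samples
    lineages = _nested_lineages(m)
    lengths = pd.Series(
        rng.integers(1_000_000, 8_000_000, size=m), index=lineages.index, name="length"
    )
    hits = GenomeHitTable(
        best_hit_counts=pd.DataFrame(counts, index=lineages.index, columns=labels.index),
        genome_lengths=lengths,
        lineages=lineages,
    )

    # --- ORFs / genes -------------------------------------------------------
    rng_orf = config.rng(_STREAM_ORF)
    n_genes = m  # one synthetic KEGG gene per genome-scale feature
    orfs_per_gene = 2
    gene_mu = rng_orf.normal(3.0, 1.0, size=n_genes)
    gene_log2 = (
        gene_mu[None, :]
        + case[:, None] * beta[None, :]
        + config.noise_sd * rng_orf.standard_normal((n, n_genes))
    )
    gene_depth = np.exp2(gene_log2)  # samples x genes
    share = rng_orf.dirichlet(np.ones(orfs_per_gene), size=n_genes)  # genes x orfs
    orf_depths = np.einsum("sg,go->gos", gene_depth, share).reshape(
        n_genes * orfs_per_gene, n
    )
    orf_ids = [
        f"orf_{g + 1:04d}_{k + 1}" for g in range(n_genes) for k in range(orfs_per_gene)
    ]
    annotations = [f"K{g + 1:05d}" for g in range(n_genes) for _ in range(orfs_per_gene)]
    # unannotated background ORFs: contribute to per-sample totals only
    n_bg = max(4, n_genes // 4)
    bg = np.exp2(rng_orf.normal(3.0, 1.0, size=(n_bg, n)))
    orf_ids += [f"orf_bg_{k + 1:04d}" for k in range(n_bg)]
    annotations += [np.nan] * n_bg
    idx = pd.Index(orf_ids, name="orf_id")
    orf_table = OrfDepthTable(
        depths=pd.DataFrame(
            np.vstack([orf_depths, bg]), index=idx, columns=labels.index
        ),
        gene_annotations=pd.Series(annotations, index=idx, name="gene_id"),
    )

    # --- covariates ---------------------------------------------------------
    rng_cov = config.rng(_STREAM_COVARIATE)
    sex = rng_cov.integers(0, 2, size=n)
    age = rng_cov.normal(45.0, 10.0, size=n)
    age = np.clip(age, 18.0, None)  # adult cohort
    age = age + config.covariate_effect * case
    covariates = CovariateTable(
        data=pd.DataFrame({"sex": sex, "age": age}, index=labels.index)
    )
    return hits, orf_table, covariates, labels


def gen_gene_sets(
    config: SyntheticConfig,
    gene_ids: list[str],
    set_sizes: list[int],
    loaded_set: bool = False,
) -> GeneSetCollection:
    """Named gene sets sampled without replacement from ``gene_ids``.

    With ``loaded_set=True`` an extra set is added that contains every
    planted-effect gene (the leading ``n_effect_features`` ids) padded with
    random genes up to the first requested size, to give enrichment tests a
    positive control.
    """
    rng = config.rng(_STREAM_GENESETS)
    universe = list(gene_ids)
    for k, size in enumerate(set_sizes):
        if size > len(universe):
            raise ValueError(
                f"requested gene-set size {size} exceeds the {len(universe)}-gene universe"
            )
    sets: dict[str, list[str]] = {}
    for k, size in enumerate(set_sizes):
        members = rng.choice(universe, size=size, replace=False)
        sets[f"set_{k + 1:03d}"] = sorted(members.tolist())
    if loaded_set:
        planted = universe[: config.n_effect_features]
        target = max(set_sizes[0] if set_sizes else len(planted), len(planted))
        rest = [g for g in universe if g not in planted]
        pad = rng.choice(rest, size=target - len(planted), replace=False).tolist()
        sets["set_loaded"] = planted + sorted(pad)
    return GeneSetCollection(sets=sets)
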