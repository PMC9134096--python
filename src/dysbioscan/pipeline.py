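"""End-to-end orchestration of the lipid and metagenome pipelines.

``run_pipeline`` chains the stages in dependency order on a synthetic
cohort — lipids: differential test -> rank-order score -> ROC/cutoff;
metagenome: quantify -> filter -> Box-Cox -> covariate-adjusted GLM ->
permutation threshold -> (gene route) RINT -> GLM -> GSEA -> diversity —
and emits a manifest of seeds, per-stage outputs and content hashes.
Reruns with an identical config reproduce identical output bytes, so the
manifest hash is a reproducibility fingerprint.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .association import (
    assoc_glm,
    gsea_effect_ranked,
    min_p_permutation,
    pca_covariates,
    threshold_with_ci,
)
from .biomarker import RankOrderScorer
from .lipidomics import moderated_t_test
from .metagenome import (
    BoxCoxNormalizer,
    RankInverseNormal,
    bray_curtis,
    filter_features,
    gene_abundance,
    permanova,
    quantify_and_aggregate,
    shannon_diversity,
)
from .synthetic import SyntheticConfig, gen_gene_sets, gen_lipid_cohort, gen_metagenome_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles and knobs for a full synthetic run."""

    master_seed: int = 0
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 500
    gsea_perm: int = 200
    pc_count: int = 15
    taxa_level: str = "L7"
    run_lipid: bool = True
    run_score: bool = True
    run_metagenome: bool = True
    run_gsea: bool = True
    run_diversity: bool = True
    lipid: dict = field(default_factory=dict)  # SyntheticConfig overrides
    metagenome: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_boot", "gsea_perm", "pc_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        return PipelineConfig(**data)


def _panel_as_lipid_cohort(cfg: SyntheticConfig):
    table = gen_lipid_cohort(cfg)
    # name the first five species after the scored lysophospholipid panel so
    # the scorer's default panel resolves on synthetic cohorts
    from .biomarker import DEFAULT_PANEL

    renames = dict(zip(table.concentrations.columns[: len(DEFAULT_PANEL)], DEFAULT_PANEL))
    table.concentrations = table.concentrations.rename(columns=renames)
    return table


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages and write TSV/JSON outputs plus a manifest."""
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": {}, "stages": []}
    hashes: dict[str, str] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        path.write_bytes(dio.canonical_tsv_bytes(frame))
        hashes[name] = dio.file_sha256(path)
        manifest["outputs"][name] = hashes[name]

    # ---- lipid pipeline ----------------------------------------------------
    if config.run_lipid:
        lip_cfg = SyntheticConfig.lipid_default(seed=config.master_seed, **config.lipid)
        table = _panel_as_lipid_cohort(lip_cfg)
        _, diff = moderated_t_test(table, alpha=config.alpha)
        emit("lipid_diff.tsv", diff.table)
        manifest["stages"].append("lipid_diff")

        if config.run_score:
            scorer = RankOrderScorer().fit(table)
            scores = pd.DataFrame(
                {
                    "group": table.group_labels,
                    "total_score": scorer.score_table_.total_score,
                    "outlier": scorer.predict(table),
                }
            )
            emit("lipid_scores.tsv", scores)
            manifest["roc"] = {
                "auc": scorer.auc_,
                "auc_p": scorer.roc_.auc_p,
                "cutoff": scorer.cutoff_,
                "sensitivity": scorer.cutoff_result_.sensitivity,
            }
            manifest["stages"].append("lipid_score")

    # ---- metagenome pipeline ----------------------------------------------
    if config.run_metagenome:
        mg_cfg = SyntheticConfig.metagenome_default(
            seed=config.master_seed + 1, **config.metagenome
        )
        hits, orfs, covs, labels = gen_metagenome_cohort(mg_cfg)
        levels = quantify_and_aggregate(hits)
        taxa = filter_features(levels[config.taxa_level], labels, mode="taxa")
        x = taxa.values.to_numpy().T  # samples x features
        x_bc = BoxCoxNormalizer().fit(x).transform(x)
        k = min(config.pc_count, min(x_bc.shape) - 1)
        pcs = pca_covariates(x_bc.T, k)
        design_cov = np.column_stack([covs.design_columns().to_numpy(), pcs])
        assoc = assoc_glm(
            pd.DataFrame(x_bc.T, index=taxa.feature_ids, columns=taxa.sample_ids),
            labels, covariates=design_cov,
        )
        emit("assoc_taxa.tsv", assoc.table)
        null = min_p_permutation(x_bc, labels, covariates=design_cov,
                                 n_iter=config.n_perm, seed=config.master_seed + 2)
        thr = threshold_with_ci(null, n_boot=config.n_boot,
                                seed=config.master_seed + 3)
        sig = assoc.table.index[
            -np.log10(assoc.table["p_value"]) > thr.neg_log10_p_sig
        ].tolist()
        manifest["threshold"] = {
            "neg_log10_p_sig": thr.neg_log10_p_sig,
            "ci_low": thr.ci_low,
            "ci_high": thr.ci_high,
            "n_iter": null.n_iter,
            "significant_clades": sig,
        }
        manifest["stages"].append("assoc_threshold")

        genes = filter_features(gene_abundance(orfs), labels, mode="gene")
        g = genes.values.to_numpy().T
        g_rint = RankInverseNormal().fit(g).transform(g)
        assoc_genes = assoc_glm(
            pd.DataFrame(g_rint.T, index=genes.feature_ids, columns=genes.sample_ids),
            labels, covariates=design_cov,
        )
        emit("assoc_genes.tsv", assoc_genes.table)
        manifest["stages"].append("assoc_genes")

        if config.run_gsea:
            n_genes = len(assoc_genes.feature_ids)
            size = min(50, max(2, n_genes // 2))
            sets = gen_gene_sets(
                mg_cfg, list(assoc_genes.feature_ids), [size, size],
                loaded_set=True,
            )
            gsea = gsea_effect_ranked(
                assoc_genes, sets, n_perm=config.gsea_perm,
                seed=config.master_seed + 4,
                min_size=min(50, size), max_size=30000,
            )
            emit("gsea.tsv", gsea.table)
            manifest["stages"].append("gsea")

        if config.run_diversity:
            shannon = shannon_diversity(levels[config.taxa_level])
            dist = bray_curtis(levels[config.taxa_level])
            f_stat, p = permanova(dist, labels, n_perm=999,
                                  seed=config.master_seed + 5)
            emit("shannon.tsv", shannon.to_frame())
            manifest["diversity"] = {"permanova_f": f_stat, "permanova_p": p}
            manifest["stages"].append("diversity")

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(hashes, sort_keys=True).encode()
    ).hexdigest()
    manifest["runtime_s"] = round(time.monotonic() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
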