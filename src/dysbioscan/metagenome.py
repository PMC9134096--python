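"""Quantification, filtering, normalisation and diversity statistics for
taxon- and gene-level metagenome tables.

Per-genome read counts are length-normalised and summed into clade
abundances at six taxonomic levels (L2 phylum .. L7 species), each level
renormalised to per-sample relative abundance.  Detection-rate and
mean-abundance filters mirror the case-control study design; abundances are
normalised with a profile-likelihood Box-Cox power transform (taxa) or a
rank-based inverse normal transform (genes) before association testing.
Diversity statistics cover rarefied Shannon entropy, Bray-Curtis
dissimilarity and a seeded PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import TAXONOMIC_LEVELS, AbundanceMatrix, GenomeHitTable, OrfDepthTable

__all__ = [
    "quantify_and_aggregate",
    "filter_features",
    "gene_abundance",
    "orf_depth",
    "box_cox",
    "BoxCoxResult",
    "BoxCoxNormalizer",
    "rint_transform",
    "RankInverseNormal",
    "shannon_diversity",
    "bray_curtis",
    "permanova",
    "allowlist_filter",
    "pca_outlier_mask",
]


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify_and_aggregate(hits: GenomeHitTable) -> dict[str, AbundanceMatrix]:
    """Length-normalised per-genome values aggregated to clades at L2..L7.

    Per-genome value = best-hit count / genome length; a clade's value is the
    sum over its member genomes; each level's columns are renormalised to
    relative abundance.  The genome-level matrix is returned under the key
    ``"genome"``.
    """
    per_genome = hits.best_hit_counts.div(hits.genome_lengths, axis=0)
    totals = per_genome.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with no mapped reads: {empty}")

    out: dict[str, AbundanceMatrix] = {
        "genome": AbundanceMatrix(values=per_genome.div(totals, axis=1),
                                  level="genome", relative=True)
    }
    split = hits.lineages.str.split(";")
    for depth, level in enumerate(TAXONOMIC_LEVELS, start=2):
        clade = split.str[:depth].str.join(";")
        agg = per_genome.groupby(clade).sum()
        agg.index.name = "clade"
        out[level] = AbundanceMatrix(values=agg.div(agg.sum(axis=0), axis=1),
                                     level=level, relative=True)
    return out


def filter_features(
    matrix: AbundanceMatrix,
    labels: pd.Series,
    mode: str = "taxa",
    detection_rate: float = 0.20,
    min_mean_relative: float = 1e-5,
) -> AbundanceMatrix:
    """Remove undetectable features before association testing.

    Rules ("detected" = abundance strictly positive):
      (a) detected in fewer than 20% of all samples;
      (b) detected in no case sample or in no control sample;
      (c) taxa only: mean relative abundance below 0.001% (1e-5).
    """
    if mode not in {"taxa", "gene"}:
        raise ValueError(f"unknown filter mode {mode!r}")
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("labels must cover every sample")
    case = (labels == "CD").to_numpy()

    vals = matrix.values
    detected = vals.gt(0)
    keep_a = detected.mean(axis=1) >= detection_rate
    keep_b = detected.loc[:, case].any(axis=1) & detected.loc[:, ~case].any(axis=1)
    keep = keep_a & keep_b
    if mode == "taxa":
        keep &= vals.mean(axis=1) >= min_mean_relative
    return AbundanceMatrix(values=vals.loc[keep], level=matrix.level,
                           relative=False)


def gene_abundance(orfs: OrfDepthTable) -> AbundanceMatrix:
    """Annotated gene abundance from ORF depths.

    Gene value = sum of depths of the ORFs annotated to it; each sample's
    column is then divided by that sample's total ORF depth over ALL ORFs
    (annotated or not), correcting for per-sample sequencing effort.
    """
    annotated = orfs.gene_annotations.dropna()
    if annotated.empty:
        raise ValueError("no annotated ORFs; cannot compute gene abundance")
    totals = orfs.depths.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a sample has zero total ORF depth")
    gene_vals = orfs.depths.loc[annotated.index].groupby(annotated).sum()
    gene_vals.index.name = "gene_id"
    return AbundanceMatrix(values=gene_vals.div(totals, axis=1), level="gene")


def orf_depth(coverage, interval: tuple[int, int]) -> float:
    """Mean per-base coverage over a 0-based half-open interval."""
    coverage = np.asarray(coverage, dtype=float)
    start, end = interval
    if not 0 <= start < end <= coverage.size:
        raise ValueError(
            f"invalid interval [{start}, {end}) for coverage of length {coverage.size}"
        )
    return float(coverage[start:end].mean())


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxResult:
    lambda_hat: float
    shift: float
    transformed: np.ndarray


def _boxcox_apply(y: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-6:
        return np.log(y)
    return (y**lam - 1.0) / lam


def box_cox(vector, lambda_range: tuple[float, float] = (-3.0, 3.0)) -> BoxCoxResult:
    """Profile-maximum-likelihood Box-Cox power transform.

    Zeros are shifted by half the minimum positive value before the power
    transform (abundance vectors are non-negative but sparse); the optimal
    exponent is found by bounded scalar maximisation of the normal profile
    log-likelihood over ``lambda_range``.
    """
    y = np.asarray(vector, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite values in Box-Cox input")
    if (y < 0).any():
        raise ValueError("Box-Cox input must be non-negative")
    shift = 0.0
    if (y == 0).any():
        pos = y[y > 0]
        if pos.size == 0:
            raise ValueError("Box-Cox input is identically zero")
        shift = pos.min() / 2.0
        y = y + shift
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, y),
        bounds=lambda_range,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    # the bounded optimiser can park at an interior stationary point when the
    # profile likelihood is monotone; compare against the boundary values
    candidates = [lam, lambda_range[0], lambda_range[1]]
    lam = max(candidates, key=lambda c: stats.boxcox_llf(c, y))
    return BoxCoxResult(lambda_hat=lam, shift=shift,
                        transformed=_boxcox_apply(y, lam))


class BoxCoxNormalizer(TransformerMixin, BaseEstimator):
    """Per-feature Box-Cox normalisation of a samples x features matrix.

    ``fit`` records each column's zero-shift and profile-ML exponent;
    ``transform`` applies them, optionally standardising the output to zero
    mean and unit variance (the association model is scale-free either way).
    """

    def __init__(self, lambda_range: tuple[float, float] = (-3.0, 3.0),
                 standardize: bool = False):
        self.lambda_range = lambda_range
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.lambdas_ = np.empty(X.shape[1])
        self.shifts_ = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            res = box_cox(X[:, j], self.lambda_range)
            self.lambdas_[j] = res.lambda_hat
            self.shifts_[j] = res.shift
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            out[:, j] = _boxcox_apply(X[:, j] + self.shifts_[j], self.lambdas_[j])
        if self.standardize:
            out = (out - out.mean(axis=0)) / out.std(axis=0, ddof=0)
        return out


def rint_transform(vector) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    value_i -> Phi^{-1}((r_i - 3/8) / (n + 1/4)) with mid-ranks for ties.
    """
    y = np.asarray(vector, dtype=float)
    if y.size < 2:
        raise ValueError("rank-based inverse normal transform needs n >= 2")
    ranks = stats.rankdata(y, method="average")
    return special.ndtri((ranks - 0.375) / (y.size + 0.25))


class RankInverseNormal(TransformerMixin, BaseEstimator):
    """Column-wise rank-based inverse normal transform (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([rint_transform(X[:, j]) for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def shannon_diversity(counts, rarefy_depth: int | None = None,
                      seed: int | None = None) -> pd.Series:
    """Shannon entropy H = -sum p ln p (nats) per sample.

    With ``rarefy_depth`` each sample is first down-sampled to the same
    number of reads by seeded multinomial subsampling, removing the
    depth-dependence of observed richness.
    """
    if isinstance(counts, AbundanceMatrix):
        counts = counts.values
    frame = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    mat = frame.to_numpy(dtype=float)
    if rarefy_depth is not None:
        totals = mat.sum(axis=0)
        shallow = np.flatnonzero(totals < rarefy_depth)
        if shallow.size:
            raise ValueError(
                f"sample(s) shallower than rarefy depth {rarefy_depth}: "
                f"{[str(frame.columns[i]) for i in shallow]}"
            )
        rng = np.random.default_rng(seed)
        mat = np.column_stack(
            [rng.multinomial(rarefy_depth, col / col.sum()) for col in mat.T]
        ).astype(float)
    h = np.array([stats.entropy(col[col > 0]) for col in mat.T])
    return pd.Series(h, index=frame.columns, name="shannon")


def bray_curtis(matrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns.

    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j); a pair of all-zero samples is
    assigned distance 0 with a warning.
    """
    if isinstance(matrix, AbundanceMatrix):
        matrix = matrix.values
    frame = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    x = frame.to_numpy(dtype=float).T  # samples x features
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero_pairs = den == 0
    if (x.sum(axis=1) == 0).sum() >= 2:  # an off-diagonal all-zero pair exists
        warnings.warn("all-zero sample pair; Bray-Curtis distance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero_pairs, 0.0, num / np.where(zero_pairs, 1.0, den))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=frame.columns, columns=frame.columns)


def permanova(distance, labels, n_perm: int = 999,
              seed: int | None = None) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)) from the squared
    inter-point distances; P = (1 + #{F* >= F}) / (1 + n_perm) over seeded
    label permutations.
    """
    frame = distance if isinstance(distance, pd.DataFrame) else pd.DataFrame(distance)
    d = frame.to_numpy(dtype=float)
    labels = np.asarray(pd.Series(labels).reindex(frame.index)
                        if isinstance(labels, pd.Series) else labels)
    groups, inv = np.unique(labels, return_inverse=True)
    if groups.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise ValueError("each group needs at least 2 samples")
    n = d.shape[0]
    a = groups.size
    d2 = d**2

    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(assign: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(a):
            idx = np.flatnonzero(assign == g)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            exceed += 1
    return float(f_obs), (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# optional, configurable exclusions
# ---------------------------------------------------------------------------

def allowlist_filter(matrix: AbundanceMatrix, allowed_ids) -> AbundanceMatrix:
    """Keep only features on an external allow-list (batch-effect control)."""
    keep = matrix.values.index.intersection(pd.Index(allowed_ids))
    return AbundanceMatrix(values=matrix.values.loc[keep], level=matrix.level,
                           relative=False)


def pca_outlier_mask(matrix: AbundanceMatrix, k_sd: float = 6.0) -> pd.Series:
    """Flag samples beyond ``k_sd`` standard deviations on PC1 or PC2."""
    x = matrix.values.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    sd = scores.std(axis=0, ddof=1)
    flag = (np.abs(scores) > k_sd * sd).any(axis=1)
    return pd.Series(flag, index=matrix.sample_ids, name="pca_outlier")
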