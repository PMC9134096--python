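"""Covariate-adjusted case-control association, the permutation-derived
metagenome-wide significance threshold, and effect-size-ranked gene-set
enrichment.

The association model regresses each (already normalised) feature on case
status plus nuisance covariates (sex, age, top principal components) by
ordinary least squares — a Gaussian identity-link GLM — and reports the
case-status coefficient beta, its standard error, and a two-sided t-test P
value.  The family-wise significance threshold is estimated empirically:
case/control labels are permuted (covariates stay attached to their
samples), the minimum P value across features is recorded per iteration,
and -log10(P_sig) is the Harrell-Davis 95th percentile of -log10(P_min),
with a percentile-bootstrap confidence interval.  Pathway-level signal is
assessed by a weighted Kolmogorov-Smirnov enrichment score over genes
ranked by their effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .lipidomics import bh_adjust
from .tables import AbundanceMatrix, CovariateTable, GeneSetCollection

__all__ = [
    "AssociationResult",
    "PermutationNull",
    "ThresholdEstimate",
    "GseaResult",
    "pca_covariates",
    "assoc_glm",
    "CaseControlGLM",
    "min_p_permutation",
    "hd_quantile",
    "threshold_with_ci",
    "PermutationThreshold",
    "enrichment_score",
    "gsea_effect_ranked",
]


@dataclass
class AssociationResult:
    """Per-feature case-status effect size, SE and two-sided P."""

    table: pd.DataFrame  # columns: beta, se, p_value
    n_tested: int

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class PermutationNull:
    n_iter: int
    min_p: np.ndarray
    seed: int | None


@dataclass
class ThresholdEstimate:
    neg_log10_p_sig: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass
class GseaResult:
    table: pd.DataFrame  # index set id; columns: es, p_value, adj_p, set_size
    dropped_gene_ids: int = 0


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def pca_covariates(matrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the samples.

    ``matrix`` is features x samples (AbundanceMatrix or array); features are
    centred across samples and the scores are the leading singular
    projections of the sample cloud.  Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    if isinstance(matrix, AbundanceMatrix):
        matrix = matrix.values
    x = np.asarray(matrix, dtype=float).T  # samples x features
    n, m = x.shape
    if not 0 < k < min(n, m):
        raise ValueError(f"k must satisfy 0 < k < min(n_features, n_samples)={min(n, m)}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    scores = (u * s) * signs
    return scores[:, :k]


def _case_vector(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == "CD").astype(float)
    return arr.astype(float)


def _build_design(case: np.ndarray, covariates) -> np.ndarray:
    cols = [np.ones_like(case), case]
    if covariates is not None:
        if isinstance(covariates, CovariateTable):
            covariates = covariates.design_columns().to_numpy()
        elif isinstance(covariates, pd.DataFrame):
            covariates = covariates.to_numpy(dtype=float)
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != case.size:
            covariates = covariates.T
        cols.extend(covariates.T)
    design = np.column_stack(cols)
    if design.shape[0] <= design.shape[1]:
        raise ValueError("fewer samples than model parameters")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates)")
    return design


def _ols_case_stats(y: np.ndarray, design: np.ndarray):
    """Vectorised OLS of each column of y on the design; stats for column 1.

    Returns (beta, se, p) arrays for the case-status coefficient.
    """
    n, p = design.shape
    q, r = np.linalg.qr(design)
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - design @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(r.T @ r)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    beta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    # a response constant across samples carries no signal: beta 0, P 1
    constant = y.var(axis=0) == 0
    beta = np.where(constant, 0.0, beta)
    se = np.where(constant, 0.0, se)
    pvals = np.where(constant, 1.0, pvals)
    return beta, se, pvals


class CaseControlGLM(BaseEstimator):
    """Per-feature Gaussian GLM of transformed abundance on case status.

    ``fit(X, y, covariates=...)`` with X samples x features (already
    Box-Cox- or RINT-transformed), y case/control labels, and optional
    covariate columns (sex, age, PCs).  ``family="logistic"`` flips the
    model direction (case status ~ abundance + covariates, one fit per
    feature) as a sensitivity analysis.

    Fitted attributes: ``beta_``, ``se_``, ``p_values_``, ``n_tested_``.
    """

    def __init__(self, family: str = "gaussian"):
        self.family = family

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=float)
        case = _case_vector(y)
        if self.family == "gaussian":
            design = _build_design(case, covariates)
            beta, se, p = _ols_case_stats(X, design)
        elif self.family == "logistic":
            beta, se, p = self._fit_logistic(X, case, covariates)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        self.beta_ = beta
        self.se_ = se
        self.p_values_ = p
        self.n_tested_ = X.shape[1]
        return self

    @staticmethod
    def _fit_logistic(X, case, covariates):
        import statsmodels.api as sm

        betas, ses, ps = [], [], []
        for j in range(X.shape[1]):
            design = _build_design(X[:, j], covariates)  # intercept, feature, covs
            fit = sm.Logit(case, design).fit(disp=0)
            betas.append(fit.params[1])
            ses.append(fit.bse[1])
            ps.append(fit.pvalues[1])
        return np.array(betas), np.array(ses), np.array(ps)


def assoc_glm(matrix, labels, covariates=None,
              family: str = "gaussian") -> AssociationResult:
    """Case-control association for every feature of an abundance matrix.

    ``matrix`` may be an AbundanceMatrix / DataFrame (features x samples) or
    an array (samples x features).
    """
    if isinstance(matrix, AbundanceMatrix):
        matrix = matrix.values
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        X = matrix.to_numpy(dtype=float).T
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[1])
    est = CaseControlGLM(family=family).fit(X, labels, covariates=covariates)
    frame = pd.DataFrame(
        {"beta": est.beta_, "se": est.se_, "p_value": est.p_values_}, index=index
    )
    return AssociationResult(table=frame, n_tested=est.n_tested_)


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def min_p_permutation(matrix, labels, covariates=None, n_iter: int = 1000,
                      seed: int | None = None) -> PermutationNull:
    """Empirical null of the minimum association P value.

    Case/control labels are permuted across samples (covariates stay with
    their samples), the per-feature Gaussian GLM is re-run, and the minimum
    P over features is recorded for each of ``n_iter`` iterations.  The
    permuted label vectors are regressed in one batched pass: features and
    labels are projected off the covariate space once, after which each
    permutation reduces to per-feature simple regressions.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100: the min-P threshold will be unstable")
    if isinstance(matrix, AbundanceMatrix):
        matrix = matrix.values
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float).T  # samples x features
    else:
        X = np.asarray(matrix, dtype=float)
    case = _case_vector(labels)
    n, m = X.shape

    # covariate-only design (intercept + covariates): project it out once;
    # the dummy case column only serves _build_design's rank validation
    base = np.delete(_build_design(case, covariates), 1, axis=1)
    q, _ = np.linalg.qr(base)
    resid_x = X - q @ (q.T @ X)
    p_full = base.shape[1] + 1
    dof = n - p_full

    rng = np.random.default_rng(seed)
    perms = np.column_stack([case[rng.permutation(n)] for _ in range(n_iter)])
    g = perms - q @ (q.T @ perms)  # residualised permuted labels, n x B
    gg = (g**2).sum(axis=0)  # B
    if (gg == 0).any():
        raise ValueError("a permuted phenotype is collinear with the covariates")
    c = g.T @ resid_x  # B x m
    yy = (resid_x**2).sum(axis=0)  # m
    beta = c / gg[:, None]
    ssr = np.maximum(yy[None, :] - c**2 / gg[:, None], 0.0)
    sigma2 = ssr / dof
    se = np.sqrt(sigma2 / gg[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    min_p = np.clip(pvals.min(axis=1), np.nextafter(0, 1), 1.0)
    return PermutationNull(n_iter=n_iter, min_p=min_p, seed=seed)


def hd_quantile(sample, q: float) -> float:
    """Harrell-Davis distribution-free quantile estimator.

    A weighted average of all order statistics with Beta((n+1)q, (n+1)(1-q))
    CDF-increment weights — smoother than a single order statistic.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("Harrell-Davis estimation needs n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in sample")
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level q must lie in (0, 1)")
    a = (n + 1) * q
    b = (n + 1) * (1.0 - q)
    edges = special.betainc(a, b, np.arange(n + 1) / n)
    w = np.diff(edges)
    return float(w @ x)


def threshold_with_ci(null: PermutationNull, q: float = 0.95,
                      n_boot: int = 2000, seed: int | None = None) -> ThresholdEstimate:
    """-log10(P_sig) point estimate with a percentile-bootstrap 95% CI.

    Point estimate: Harrell-Davis ``q``-quantile of -log10(min_p); CI:
    resample min_p with replacement, re-estimate, take the 2.5th/97.5th
    percentiles.
    """
    if null.min_p.size == 0:
        raise ValueError("empty permutation null")
    if n_boot < 100:
        warnings.warn("n_boot < 100: the bootstrap CI will be unstable")
    neglog = -np.log10(null.min_p)
    point = hd_quantile(neglog, q)
    rng = np.random.default_rng(seed)
    boots = np.array([
        hd_quantile(rng.choice(neglog, size=neglog.size, replace=True), q)
        for _ in range(n_boot)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ThresholdEstimate(neg_log10_p_sig=point, ci_low=float(min(lo, point)),
                             ci_high=float(max(hi, point)), n_boot=n_boot)


class PermutationThreshold(BaseEstimator):
    """Estimate the family-wise significance threshold from one cohort.

    ``fit(X, y, covariates=...)`` runs the phenotype-permutation procedure
    and stores ``min_p_``, ``neg_log10_p_sig_`` and the bootstrap CI.
    """

    def __init__(self, n_iter: int = 1000, q: float = 0.95, n_boot: int = 2000,
                 seed: int | None = None):
        self.n_iter = n_iter
        self.q = q
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, covariates=None):
        null = min_p_permutation(X, y, covariates=covariates,
                                 n_iter=self.n_iter, seed=self.seed)
        boot_seed = None if self.seed is None else self.seed + 1
        est = threshold_with_ci(null, q=self.q, n_boot=self.n_boot, seed=boot_seed)
        self.null_ = null
        self.min_p_ = null.min_p
        self.neg_log10_p_sig_ = est.neg_log10_p_sig
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        return self


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def enrichment_score(ranked_scores: np.ndarray, in_set: np.ndarray,
                     exponent: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    ``ranked_scores`` are the effect sizes sorted descending; hit steps are
    proportional to |score|^exponent, miss steps uniform; the ES is the
    running sum's maximum deviation from zero (signed).
    """
    in_set = np.asarray(in_set, dtype=bool)
    scores = np.abs(np.asarray(ranked_scores, dtype=float)) ** exponent
    n_hit = int(in_set.sum())
    n = in_set.size
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    hit_total = scores[in_set].sum()
    if hit_total == 0:  # all member effects exactly zero: fall back to uniform
        steps = np.where(in_set, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(in_set, scores / hit_total, -1.0 / (n - n_hit))
    walk = np.cumsum(steps)
    return float(walk[np.abs(walk).argmax()])


def gsea_effect_ranked(assoc: AssociationResult, sets: GeneSetCollection,
                       n_perm: int = 1000, seed: int | None = None,
                       min_size: int = 50, max_size: int = 30000,
                       exponent: float = 1.0) -> GseaResult:
    """Effect-size-ranked GSEA over retained KEGG-style gene sets.

    Genes are sorted by their association effect size beta (descending);
    sets with fewer than ``min_size`` or more than ``max_size`` resolvable
    genes are excluded; significance comes from a gene-label permutation
    null, two-sided on |ES|, with BH adjustment across retained sets.
    """
    betas = assoc.table["beta"]
    order = np.argsort(-betas.to_numpy(), kind="stable")
    ranked_ids = betas.index.to_numpy()[order]
    ranked_scores = betas.to_numpy()[order]
    pos = {g: i for i, g in enumerate(ranked_ids)}
    n = ranked_ids.size

    retained: dict[str, np.ndarray] = {}
    dropped = 0
    for name, genes in sets.sets.items():
        hit_idx = [pos[g] for g in genes if g in pos]
        dropped += len(genes) - len(hit_idx)
        if min_size <= len(hit_idx) <= max_size and len(hit_idx) < n:
            mask = np.zeros(n, dtype=bool)
            mask[hit_idx] = True
            retained[name] = mask
    if not retained:
        raise ValueError("no gene set survives the size filter")

    rng = np.random.default_rng(seed)
    rows = []
    for name, mask in retained.items():
        es = enrichment_score(ranked_scores, mask, exponent)
        size = int(mask.sum())
        exceed = 0
        for _ in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=size, replace=False)] = True
            if abs(enrichment_score(ranked_scores, perm_mask, exponent)) >= abs(es):
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append((name, es, p, size))
    frame = pd.DataFrame(rows, columns=["set_id", "es", "p_value", "set_size"])
    frame = frame.set_index("set_id")
    frame["adj_p"] = bh_adjust(frame["p_value"].to_numpy())
    return GseaResult(table=frame[["es", "p_value", "adj_p", "set_size"]],
                      dropped_gene_ids=dropped)
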