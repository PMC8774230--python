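"""Probe-to-gene collapse, log-scale detection, study merging, empirical-
Bayes location/scale batch adjustment, and a PCA batch audit.

Probe scoring follows a product rule: specificity (1 / number of annotated
genes) x coverage (fraction of samples above the study-wide 25th
percentile) x robustness (mean / (sd + 0.01)).  Each component penalizes
exactly one failure mode of the synthetic degraded probes.

The batch adjustment is the parametric location/scale model: per-gene
standardization on a covariate-preserving fit, method-of-moments priors per
batch (normal for the location effect, inverse-gamma for the squared scale
effect), one-step shrinkage, back-transformation with covariate effects
restored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iohub import ExpressionTable, PhenotypeTable

__all__ = [
    "ProbeScore",
    "BatchAudit",
    "score_probes",
    "select_best_probes",
    "detect_log_scale",
    "split_by_batch",
    "merge_studies",
    "combat_adjust",
    "pca_batch_report",
    "preprocess_bundle",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeScore:
    probe_id: str
    gene_id: str
    specificity: float
    coverage: float
    robustness: float

    @property
    def total(self) -> float:
        return self.specificity * self.coverage * self.robustness


@dataclass(frozen=True)
class BatchAudit:
    """R-squared of batch and histology groupings on PC1-2."""

    batch_r2: float
    histology_r2: float
    pc_coords: pd.DataFrame
    variance_explained: tuple[float, ...]
    degenerate: bool = False


def score_probes(
    expr: ExpressionTable, annotation: dict[str, tuple[str, ...]]
) -> list[ProbeScore]:
    """Score every annotated probe; unannotated probes are warned and dropped."""
    values = expr.data.values
    threshold = float(np.percentile(values, 25))
    scores: list[ProbeScore] = []
    for i, probe in enumerate(expr.features):
        genes = annotation.get(probe)
        if not genes:
            warnings.warn(f"probe {probe!r} has no gene annotation; excluded")
            continue
        row = values[i]
        specificity = 1.0 / len(genes)
        coverage = float(np.mean(row > threshold))
        robustness = float(row.mean() / (row.std(ddof=0) + 0.01))
        # A probe competes for its primary (first-annotated) gene only.
        scores.append(ProbeScore(probe, genes[0], specificity, coverage, robustness))
    return scores


def select_best_probes(
    scores: list[ProbeScore], expr: ExpressionTable
) -> tuple[ExpressionTable, dict[str, str]]:
    """One row per gene: the winning probe's values.

    Ties on total score break to the lexicographically smallest probe id.
    Returns the gene-level table and the gene -> chosen probe map.
    """
    best: dict[str, ProbeScore] = {}
    for s in sorted(scores, key=lambda s: s.probe_id):
        cur = best.get(s.gene_id)
        if cur is None or s.total > cur.total:
            best[s.gene_id] = s
    genes = sorted(best)
    chosen = {g: best[g].probe_id for g in genes}
    data = expr.data.loc[[chosen[g] for g in genes]]
    data.index = pd.Index(genes, name="gene")
    return ExpressionTable(data, scale=expr.scale), chosen


def detect_log_scale(expr: ExpressionTable, threshold: float = 30.0) -> ExpressionTable:
    """log2(x + 1) if the 99th percentile exceeds the threshold; idempotent."""
    p99 = float(np.percentile(expr.data.values, 99))
    if p99 <= threshold:
        return ExpressionTable(expr.data.copy(), scale="log2")
    if (expr.data.values < 0).any():
        raise ValueError("raw-scale data contains negative values; cannot log-transform")
    return ExpressionTable(np.log2(expr.data + 1.0), scale="log2")


def split_by_batch(
    expr: ExpressionTable, pheno: PhenotypeTable
) -> list[tuple[str, ExpressionTable]]:
    pheno.check_covers(expr)
    out = []
    batches = pheno.batch.loc[expr.samples]
    for batch_id in dict.fromkeys(batches):
        cols = [s for s, b in batches.items() if b == batch_id]
        out.append((batch_id, expr.subset_samples(cols)))
    return out


def merge_studies(
    studies: list[tuple[str, ExpressionTable]]
) -> tuple[ExpressionTable, pd.Series]:
    """Concatenate >= 2 gene-level studies on their common genes.

    Returns the merged table and a per-sample batch series.
    """
    if len(studies) < 2:
        raise ValueError("merge_studies needs at least 2 studies")
    common: pd.Index | None = None
    for _, tab in studies:
        common = tab.features if common is None else common.intersection(tab.features)
    assert common is not None
    if len(common) == 0:
        raise ValueError("no common genes across studies")
    common = common.sort_values()
    blocks = [tab.data.loc[common] for _, tab in studies]
    merged = pd.concat(blocks, axis=1)
    batch = pd.Series(
        np.concatenate(
            [[bid] * tab.shape[1] for bid, tab in studies]
        ),
        index=merged.columns,
        name="batch",
    )
    return ExpressionTable(merged, scale=studies[0][1].scale), batch


def _design_matrix(batch: pd.Series, covariates: pd.DataFrame | None) -> np.ndarray:
    batch_dummies = pd.get_dummies(batch).astype(float)
    parts = [batch_dummies]
    if covariates is not None:
        parts.append(covariates.astype(float))
    design = pd.concat(parts, axis=1).values
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "batch is confounded with covariates: design matrix of batch "
            f"indicators {list(batch_dummies.columns)} plus covariates "
            f"{list(covariates.columns) if covariates is not None else []} "
            "is rank-deficient"
        )
    return design


def histology_covariates(pheno: PhenotypeTable, samples: pd.Index) -> pd.DataFrame:
    """Histology indicator columns (reference level dropped) for adjustment."""
    hist = pheno.histology.loc[samples]
    dummies = pd.get_dummies(hist, drop_first=True).astype(float)
    return dummies


def combat_adjust(
    expr: ExpressionTable,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ExpressionTable:
    """Parametric empirical-Bayes location/scale batch adjustment.

    ``batch`` and ``covariates`` (sample x indicator columns) are indexed by
    sample id.  A single batch is returned unchanged.  Requires every batch
    to hold >= 2 samples and the batch/covariate design to be full rank.
    """
    batch = batch.loc[expr.samples]
    levels = list(dict.fromkeys(batch))
    if len(levels) < 2:
        return ExpressionTable(expr.data.copy(), scale=expr.scale)
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")
    if covariates is not None:
        covariates = covariates.loc[expr.samples]

    X = expr.data.values  # genes x samples
    n_genes, n = X.shape
    design = _design_matrix(batch, covariates)
    n_batches = len(levels)
    batch_onehot = design[:, :n_batches]
    frac = batch_onehot.sum(axis=0) / n

    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # params x genes
    grand_mean = frac @ beta[:n_batches]                  # per gene
    if covariates is not None:
        cov_effect = design[:, n_batches:] @ beta[n_batches:]  # samples x genes
    else:
        cov_effect = np.zeros((n, n_genes))
    fitted = design @ beta                                # samples x genes
    resid = X.T - fitted
    pooled_var = (resid**2).mean(axis=0)                  # per gene, ddof 0
    pooled_var = np.maximum(pooled_var, 1e-12)
    pooled_sd = np.sqrt(pooled_var)

    # Standardized data: remove grand mean and covariate effects only.
    Z = (X.T - grand_mean[None, :] - cov_effect) / pooled_sd[None, :]  # samples x genes

    Zadj = np.empty_like(Z)
    for b, level in enumerate(levels):
        mask = batch_onehot[:, b] > 0.5
        nb = int(mask.sum())
        Zb = Z[mask]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        # Inverse-gamma moment estimators (shape lam, scale theta).
        lam = (2.0 * d_var + d_mean**2) / max(d_var, 1e-12)
        theta = (d_mean * d_var + d_mean**3) / max(d_var, 1e-12)

        # One-step (non-iterative) EB shrinkage.
        gamma_star = (nb * tau2 * gamma_hat + delta_hat * gamma_bar) / (
            nb * tau2 + delta_hat
        )
        ssq = ((Zb - gamma_star[None, :]) ** 2).sum(axis=0)
        delta_star = (theta + 0.5 * ssq) / (nb / 2.0 + lam - 1.0)
        delta_star = np.maximum(delta_star, 1e-12)

        Zadj[mask] = (Zb - gamma_star[None, :]) / np.sqrt(delta_star[None, :])

    adjusted = (Zadj * pooled_sd[None, :]) + grand_mean[None, :] + cov_effect
    out = pd.DataFrame(adjusted.T, index=expr.features, columns=expr.samples)
    return ExpressionTable(out, scale=expr.scale)


def _grouping_r2(coords: np.ndarray, groups: pd.Series) -> float:
    """Fraction of PC1-2 variance explained by a one-way grouping."""
    overall = coords.mean(axis=0)
    ss_total = float(((coords - overall) ** 2).sum())
    if ss_total <= 0:
        return 0.0
    ss_within = 0.0
    for g in groups.unique():
        sub = coords[(groups == g).values]
        ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return 1.0 - ss_within / ss_total


def pca_batch_report(
    expr: ExpressionTable, pheno: PhenotypeTable, n_components: int = 5
) -> BatchAudit:
    """PCs of gene-standardized data + batch/histology R-squared on PC1-2."""
    pheno.check_covers(expr)
    X = expr.data.values.T  # samples x genes
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a PCA audit")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    degenerate = bool(np.all(sd == 0))
    if degenerate:
        k = min(n_components, n)
        coords = pd.DataFrame(
            np.zeros((n, k)),
            index=expr.samples,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return BatchAudit(0.0, 0.0, coords, tuple([0.0] * k), degenerate=True)
    Xs = (X - mu) / np.where(sd == 0, 1.0, sd)
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    k = min(n_components, len(S))
    pcs = U[:, :k] * S[:k]
    total_var = float((S**2).sum())
    var_explained = tuple(float(s**2) / total_var for s in S[:k])
    coords = pd.DataFrame(
        pcs, index=expr.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    pc12 = pcs[:, : min(2, k)]
    batch_r2 = _grouping_r2(pc12, pheno.batch.loc[expr.samples])
    hist_r2 = _grouping_r2(pc12, pheno.histology.loc[expr.samples])
    return BatchAudit(batch_r2, hist_r2, coords, var_explained)


def preprocess_bundle(
    expr: ExpressionTable,
    pheno: PhenotypeTable,
    annotation: dict[str, tuple[str, ...]],
    use_histology_covariate: bool = True,
) -> tuple[ExpressionTable, pd.Series]:
    """The standard path: per-study probe collapse + log detection, merge on
    common genes, then batch adjustment.  Returns adjusted gene-level data
    and the batch series."""
    studies = split_by_batch(expr, pheno)
    gene_level: list[tuple[str, ExpressionTable]] = []
    for batch_id, tab in studies:
        tab = detect_log_scale(tab)
        scores = score_probes(tab, annotation)
        collapsed, _ = select_best_probes(scores, tab)
        gene_level.append((batch_id, collapsed))
    if len(gene_level) == 1:
        merged, batch = gene_level[0][1], pd.Series(
            [gene_level[0][0]] * gene_level[0][1].shape[1],
            index=gene_level[0][1].samples,
            name="batch",
        )
    else:
        merged, batch = merge_studies(gene_level)
    covs = (
        histology_covariates(pheno, merged.samples) if use_histology_covariate else None
    )
    adjusted = combat_adjust(merged, batch, covs)
    logger.info(
        "preprocessed %d genes x %d samples across %d batches",
        adjusted.shape[0], adjusted.shape[1], len(gene_level),
    )
    return adjusted, batch
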