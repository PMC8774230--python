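"""Iterated random-gene-subset 2-D embedding + density clustering consensus.

Each iteration draws ``gene_count`` genes without replacement, embeds the
samples with UMAP, clusters the 2-D coordinates with DBSCAN (eps either
fixed or chosen per iteration from a k-distance elbow), and aligns the
resulting partition to a reference partition (the first iteration that
yields >= 2 clusters) by solving the assignment problem on the contingency
table.  A sample's final group is its modal aligned group provided the
support fraction reaches the consensus threshold (inclusive); otherwise it
is "ambiguous".  Noise assignments are excluded from a sample's support
denominator by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from ._seeds import stage_int_seed, stage_rng
from .iohub import ExpressionTable, PhenotypeTable

__all__ = [
    "UmapParams",
    "DbscanParams",
    "EnsembleConfig",
    "ConsensusResult",
    "ConcordanceReport",
    "embed_2d",
    "cluster_density",
    "choose_eps_elbow",
    "separation_score",
    "grid_search",
    "align_labels",
    "run_ensemble",
    "concordance",
    "hierarchical_cluster",
]

logger = logging.getLogger(__name__)

NOISE = -1
AMBIGUOUS = "ambiguous"

_METRICS = ("cosine", "manhattan", "euclidean")


@dataclass(frozen=True)
class UmapParams:
    n_neighbors: int = 20
    min_dist: float = 0.01
    metric: str = "manhattan"
    gene_count: int = 1000

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.gene_count < 1:
            raise ValueError("gene_count must be positive")


@dataclass(frozen=True)
class DbscanParams:
    eps: float | None = None  # None -> per-iteration elbow choice
    min_pts: int = 5

    def __post_init__(self) -> None:
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass(frozen=True)
class EnsembleConfig:
    n_iterations: int = 1000
    consensus_threshold: float = 0.70
    seed: int = 0
    strict_denominator: bool = False  # count noise iterations against support

    def __post_init__(self) -> None:
        if not 0.5 < self.consensus_threshold <= 1.0:
            raise ValueError("consensus_threshold must be in (0.5, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ConsensusResult:
    """Final per-sample call plus the full iteration record."""

    assignments: pd.Series          # group id (str) or "ambiguous"
    support: pd.Series              # fraction in [0, 1]
    iteration_labels: pd.DataFrame  # iterations x samples, int labels, -1 noise
    coclustering: pd.DataFrame      # samples x samples frequency matrix
    threshold: float
    eps_used: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        assigned = self.assignments != AMBIGUOUS
        if ((self.support < 0) | (self.support > 1)).any():
            raise ValueError("support fractions outside [0, 1]")
        bad = assigned & (self.support < self.threshold - 1e-12)
        if bad.any():
            raise ValueError("assigned sample below consensus threshold")


def embed_2d(expr: ExpressionTable, params: UmapParams, seed: int) -> pd.DataFrame:
    """UMAP the samples of a gene-subset matrix into 2-D; deterministic."""
    import umap  # deferred: numba compilation is slow at import time

    n_samples = expr.shape[1]
    if n_samples < params.n_neighbors + 1:
        raise ValueError(
            f"{n_samples} samples is fewer than n_neighbors+1={params.n_neighbors + 1}"
        )
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        n_components=2,
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(expr.data.values.T)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    return pd.DataFrame(coords, index=expr.samples, columns=["x", "y"])


def cluster_density(coords: pd.DataFrame | np.ndarray, params: DbscanParams) -> np.ndarray:
    """DBSCAN labels (0..k-1, noise = -1); min_pts counts the point itself."""
    pts = np.asarray(coords, dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    eps = params.eps
    if eps is None:
        raise ValueError("eps not set; call choose_eps_elbow or fix eps")
    labels = DBSCAN(eps=eps, min_samples=params.min_pts).fit_predict(pts)
    return labels


def choose_eps_elbow(coords: pd.DataFrame | np.ndarray, min_pts: int) -> float:
    """k-distance elbow: eps at maximum perpendicular distance to the chord.

    Each point's distance to its min_pts-th neighbor (self excluded) is
    sorted ascending; the knee is the point furthest from the straight line
    joining the curve's endpoints.
    """
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    if n < min_pts + 1:
        raise ValueError(f"need at least min_pts+1={min_pts + 1} points")
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(pts)
    dist, _ = nn.kneighbors(pts)
    kdist = np.sort(dist[:, -1])
    if kdist[-1] <= 0:
        raise ValueError("all points identical; k-distance curve is degenerate")
    x = np.arange(n, dtype=float)
    x0, y0 = x[0], kdist[0]
    x1, y1 = x[-1], kdist[-1]
    # Perpendicular distance of each curve point to the endpoint chord.
    norm = np.hypot(x1 - x0, y1 - y0)
    perp = np.abs((y1 - y0) * x - (x1 - x0) * kdist + x1 * y0 - y1 * x0) / norm
    knee = int(np.argmax(perp))
    return float(kdist[knee])


def separation_score(
    coords: pd.DataFrame | np.ndarray, labels: np.ndarray, floor: float = 1e-9
) -> float:
    """Mean inter-centroid distance over mean within-cluster spread."""
    pts = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    cluster_ids = sorted(set(labels[labels != NOISE]))
    if len(cluster_ids) < 2:
        raise ValueError("separation score needs >= 2 clusters")
    centroids = np.array([pts[labels == c].mean(axis=0) for c in cluster_ids])
    inter = pdist(centroids).mean()
    within = np.concatenate(
        [
            np.linalg.norm(pts[labels == c] - centroids[i], axis=1)
            for i, c in enumerate(cluster_ids)
        ]
    ).mean()
    return float(inter / max(within, floor))


def align_labels(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Map iteration cluster ids onto reference group ids by maximum overlap.

    Solves the assignment problem on the contingency table; clusters left
    unmatched receive fresh ids beyond the reference's. Noise (-1) passes
    through unmapped.
    """
    reference = np.asarray(reference)
    labels = np.asarray(labels)
    if reference.shape != labels.shape:
        raise ValueError("partitions must cover the same samples")
    ref_ids = sorted(set(reference[reference != NOISE]))
    lab_ids = sorted(set(labels[labels != NOISE]))
    if not ref_ids or not lab_ids:
        return labels.copy()
    table = np.zeros((len(lab_ids), len(ref_ids)))
    for i, li in enumerate(lab_ids):
        for j, rj in enumerate(ref_ids):
            table[i, j] = np.sum((labels == li) & (reference == rj))
    rows, cols = linear_sum_assignment(-table)
    mapping: dict[int, int] = {}
    for r, c in zip(rows, cols):
        if table[r, c] > 0:
            mapping[lab_ids[r]] = ref_ids[c]
    next_id = (max(ref_ids) + 1) if ref_ids else 0
    out = np.full_like(labels, NOISE)
    for li in lab_ids:
        if li not in mapping:
            mapping[li] = next_id
            next_id += 1
    for li, ri in mapping.items():
        out[labels == li] = ri
    return out


def run_ensemble(
    expr: ExpressionTable,
    umap_params: UmapParams | None = None,
    dbscan_params: DbscanParams | None = None,
    config: EnsembleConfig | None = None,
) -> ConsensusResult:
    """The full iterated consensus procedure. Deterministic in config.seed."""
    umap_params = umap_params or UmapParams()
    dbscan_params = dbscan_params or DbscanParams()
    config = config or EnsembleConfig()
    n_genes, n_samples = expr.shape
    if umap_params.gene_count > n_genes:
        raise ValueError(
            f"gene_count {umap_params.gene_count} exceeds available genes {n_genes}"
        )

    gene_rng = stage_rng(config.seed, "ensemble:gene-subsets")
    samples = expr.samples
    n_iter = config.n_iterations
    iter_labels = np.full((n_iter, n_samples), NOISE, dtype=int)
    reference: np.ndarray | None = None
    eps_used: list[float] = []

    for it in range(n_iter):
        subset_idx = gene_rng.choice(n_genes, size=umap_params.gene_count, replace=False)
        sub = ExpressionTable(expr.data.iloc[np.sort(subset_idx)], scale=expr.scale)
        emb_seed = stage_int_seed(config.seed, f"ensemble:embed:{it}")
        coords = embed_2d(sub, umap_params, emb_seed)
        eps = dbscan_params.eps
        if eps is None:
            eps = choose_eps_elbow(coords, dbscan_params.min_pts)
        eps_used.append(float(eps))
        labels = cluster_density(coords, DbscanParams(eps=eps, min_pts=dbscan_params.min_pts))
        n_clusters = len(set(labels[labels != NOISE]))
        if n_clusters < 2:
            continue  # recorded as all-noise
        if reference is None:
            reference = labels.copy()
        iter_labels[it] = align_labels(reference, labels)

    if reference is None:
        raise RuntimeError("no structure found: every iteration yielded < 2 clusters")

    assignments, support = _plurality_vote(
        iter_labels, samples, config.consensus_threshold, config.strict_denominator
    )
    cocluster = _coclustering(iter_labels, samples)
    result = ConsensusResult(
        assignments=assignments,
        support=support,
        iteration_labels=pd.DataFrame(
            iter_labels,
            index=[f"iter{i + 1}" for i in range(n_iter)],
            columns=samples,
        ),
        coclustering=cocluster,
        threshold=config.consensus_threshold,
        eps_used=eps_used,
    )
    n_amb = int((assignments == AMBIGUOUS).sum())
    logger.info(
        "consensus over %d iterations: %d groups, %d ambiguous of %d samples",
        n_iter, len(set(a for a in assignments if a != AMBIGUOUS)), n_amb, n_samples,
    )
    return result


def _plurality_vote(
    iter_labels: np.ndarray,
    samples: pd.Index,
    threshold: float,
    strict: bool,
) -> tuple[pd.Series, pd.Series]:
    n_iter, n_samples = iter_labels.shape
    assignments = []
    supports = []
    for j in range(n_samples):
        col = iter_labels[:, j]
        counted = col[col != NOISE]
        denom = n_iter if strict else len(counted)
        if denom == 0 or len(counted) == 0:
            assignments.append(AMBIGUOUS)
            supports.append(0.0)
            continue
        ids, counts = np.unique(counted, return_counts=True)
        top = int(np.argmax(counts))
        frac = counts[top] / denom
        if frac >= threshold:
            assignments.append(f"group{ids[top] + 1}")
        else:
            assignments.append(AMBIGUOUS)
        supports.append(float(frac))
    return (
        pd.Series(assignments, index=samples, name="group"),
        pd.Series(supports, index=samples, name="support"),
    )


def _coclustering(iter_labels: np.ndarray, samples: pd.Index) -> pd.DataFrame:
    clustered = iter_labels != NOISE  # iterations x samples
    both = clustered.astype(float).T @ clustered.astype(float)
    together = np.zeros_like(both)
    for row in iter_labels:
        mask = row != NOISE
        if not mask.any():
            continue
        same = (row[:, None] == row[None, :]) & mask[:, None] & mask[None, :]
        together += same
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(both > 0, together / both, 0.0)
    np.fill_diagonal(freq, 1.0)
    return pd.DataFrame(freq, index=samples, columns=samples)


@dataclass
class ConcordanceReport:
    accuracy: float                    # over non-ambiguous samples
    accuracy_with_ambiguous: float     # ambiguous counted as errors
    ambiguous_rate: float
    confusion: pd.DataFrame            # group x histology counts
    group_to_histology: dict[str, str]
    per_class: pd.DataFrame            # sensitivity/specificity per histology


def concordance(
    consensus: ConsensusResult, pheno: PhenotypeTable, exclude: tuple[str, ...] = ("N",)
) -> ConcordanceReport:
    """Compare consensus groups with histology on tumor samples.

    Groups are mapped to histology labels by majority composition among
    non-ambiguous samples; accuracy is computed over non-ambiguous samples,
    with a stricter variant counting ambiguous samples as errors.
    """
    hist = pheno.histology.loc[consensus.assignments.index]
    keep = ~hist.isin(exclude)
    groups = consensus.assignments[keep]
    hist = hist[keep]
    assigned = groups != AMBIGUOUS
    confusion = pd.crosstab(groups[assigned], hist[assigned])
    mapping = {g: confusion.loc[g].idxmax() for g in confusion.index}
    predicted = groups[assigned].map(mapping)
    correct = int((predicted == hist[assigned]).sum())
    n_assigned = int(assigned.sum())
    n_total = int(keep.sum())
    accuracy = correct / n_assigned if n_assigned else 0.0
    per_class_rows = {}
    for h in hist.unique():
        tp = int(((predicted == h) & (hist[assigned] == h)).sum())
        fn = int((hist[assigned] == h).sum()) - tp
        fp = int((predicted == h).sum()) - tp
        tn = n_assigned - tp - fn - fp
        per_class_rows[h] = {
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }
    return ConcordanceReport(
        accuracy=accuracy,
        accuracy_with_ambiguous=correct / n_total if n_total else 0.0,
        ambiguous_rate=1.0 - (n_assigned / n_total if n_total else 0.0),
        confusion=confusion,
        group_to_histology=mapping,
        per_class=pd.DataFrame(per_class_rows).T,
    )


def hierarchical_cluster(
    expr: ExpressionTable, n_clusters: int = 2
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering on 1 - Pearson correlation between samples.

    Returns the scipy linkage matrix and a per-sample label series from
    cutting the tree at ``n_clusters``.
    """
    X = expr.data.values.T  # samples x genes
    sd = X.std(axis=1)
    constant = np.where(sd == 0)[0]
    if len(constant):
        names = [str(expr.samples[i]) for i in constant]
        raise ValueError(f"constant sample profiles (correlation undefined): {names}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=expr.samples, name="cluster")


def grid_search(
    expr: ExpressionTable,
    gene_counts: list[int],
    n_neighbors_grid: list[int],
    min_dist_grid: list[float],
    metrics: list[str],
    dbscan_params: DbscanParams | None = None,
    seed: int = 0,
) -> tuple[UmapParams, pd.DataFrame]:
    """Evaluate every hyperparameter combination once with a fixed seed.

    Each combination draws its gene subset and embedding from seeds derived
    from ``seed``, clusters, and is scored by :func:`separation_score`
    (NaN when fewer than 2 clusters emerge).  Returns the best parameters
    and the full ranked table.
    """
    if not (gene_counts and n_neighbors_grid and min_dist_grid and metrics):
        raise ValueError("all grids must be non-empty")
    dbscan_params = dbscan_params or DbscanParams()
    rows = []
    n_genes = expr.shape[0]
    rng = stage_rng(seed, "grid:gene-subsets")
    for gc in gene_counts:
        if gc > n_genes:
            raise ValueError(f"gene_count {gc} exceeds available genes {n_genes}")
        subset = np.sort(rng.choice(n_genes, size=gc, replace=False))
        sub = ExpressionTable(expr.data.iloc[subset], scale=expr.scale)
        for nn in n_neighbors_grid:
            for md in min_dist_grid:
                for metric in metrics:
                    params = UmapParams(
                        n_neighbors=nn, min_dist=md, metric=metric, gene_count=gc
                    )
                    emb_seed = stage_int_seed(seed, f"grid:{gc}:{nn}:{md}:{metric}")
                    coords = embed_2d(sub, params, emb_seed)
                    eps = dbscan_params.eps
                    if eps is None:
                        eps = choose_eps_elbow(coords, dbscan_params.min_pts)
                    labels = cluster_density(
                        coords, DbscanParams(eps=eps, min_pts=dbscan_params.min_pts)
                    )
                    try:
                        score = separation_score(coords, labels)
                    except ValueError:
                        score = float("nan")
                    rows.append(
                        {
                            "gene_count": gc,
                            "n_neighbors": nn,
                            "min_dist": md,
                            "metric": metric,
                            "eps": eps,
                            "n_clusters": len(set(labels[labels != NOISE])),
                            "score": score,
                        }
                    )
    table = pd.DataFrame(rows).sort_values("score", ascending=False, na_position="last")
    table = table.reset_index(drop=True)
    best_row = table.iloc[0]
    best = UmapParams(
        n_neighbors=int(best_row["n_neighbors"]),
        min_dist=float(best_row["min_dist"]),
        metric=str(best_row["metric"]),
        gene_count=int(best_row["gene_count"]),
    )
    return best, table
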