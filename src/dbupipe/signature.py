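"""Moderated differential expression, per-gene percentile-cutpoint ROC
profiling, and the staged marker-selection cascade.

The moderated t-statistic shrinks per-gene pooled variances toward a prior
estimated by moment-matching the distribution of log sample variances
(digamma/trigamma inversion), then tests on augmented degrees of freedom.
The cascade applies the nested filters (adjusted p, linear fold change,
AUROC, then joint sensitivity/specificity/AUROC/accuracy thresholds) and
ranks survivors by a weighted priority score to emit a fixed-size panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .iohub import ExpressionTable

__all__ = [
    "DgeResult",
    "RocProfile",
    "SelectionCascade",
    "CascadeResult",
    "moderated_t_test",
    "bh_adjust",
    "roc_auc",
    "percentile_profile",
    "profile_genes",
    "run_cascade",
    "evaluate_signature",
    "weighted_accuracy",
]

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = [
    "gene",
    "optimum_cutpoint",
    "accuracy",
    "sensitivity",
    "specificity",
    "auroc",
    "fold_change",
    "adj_p",
    "positive_class",
    "direction",
]


@dataclass
class DgeResult:
    """Per-gene moderated-t differential expression for one two-group contrast."""

    table: pd.DataFrame  # gene-indexed: mean_a, mean_b, log2fc, fold_change, t, p, adj_p
    group_a: str
    group_b: str
    prior_df: float      # d0; inf when variances are fully pooled
    prior_var: float     # s0^2

    def __post_init__(self) -> None:
        if (self.table["adj_p"] < self.table["p"] - 1e-12).any():
            raise ValueError("adjusted p below raw p")


@dataclass
class RocProfile:
    """Percentile-cutpoint classification profile of one gene."""

    gene: str
    auroc: float
    positive_class: str
    direction: str                  # "high" = positive class has higher values
    percentiles: pd.DataFrame       # percentile-indexed: cutpoint, sensitivity, specificity, accuracy
    optimum_percentile: int | None
    optimum_cutpoint: float | None
    optimum_sensitivity: float | None
    optimum_specificity: float | None
    optimum_accuracy: float | None
    degenerate: bool = False        # constant values: no usable cutpoint


@dataclass(frozen=True)
class SelectionCascade:
    """Thresholds and priority weights of the staged selection."""

    adj_p_max: float = 0.05
    fc_min: float = 2.0
    auroc_min: float = 0.90
    sens_min: float = 0.91
    spec_min: float = 0.91
    auroc_strict_min: float = 0.92
    acc_min: float = 0.92
    k: int = 30
    weight_fc: float = 1.0
    weight_breadth: float = 1.0
    weight_relevance: float = 0.0
    relevance: dict[str, float] = field(default_factory=dict)


@dataclass
class CascadeResult:
    stages: dict[str, list[str]]    # ordered stage name -> surviving genes
    signature: pd.DataFrame          # top-k rows with SIGNATURE_COLUMNS

    def stage_sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.stages.items()}


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a good starting value)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        diff = (tri - y) / special.polygamma(2, x)
        x = x - diff
        if abs(diff) < 1e-10 * x:
            break
    return float(x)


def _fit_log_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log sample variances.

    Under the scaled-chi-square model, z = log(s2) has
    E[z] = log(s0^2) + psi(df/2) - log(df/2) + psi... combined per Smyth's
    moment equations; d0 solves trigamma(d0/2) = var(z) - trigamma(df/2).
    Returns (inf, geometric-mean variance) when log variances are less
    dispersed than sampling noise alone.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t_test(
    expr: ExpressionTable,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> DgeResult:
    """Empirical-Bayes moderated two-sample t-test per gene.

    ``labels`` maps sample id to group; samples outside the two groups are
    ignored.  ``prior_df`` overrides the estimated d0 (0 gives the ordinary
    t-test; inf pools all gene variances).
    """
    labels = labels.loc[labels.index.intersection(expr.samples)]
    a_ids = labels.index[labels == group_a]
    b_ids = labels.index[labels == group_b]
    n1, n2 = len(a_ids), len(b_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group (got {n1} {group_a}, {n2} {group_b})")
    A = expr.data[a_ids].values
    B = expr.data[b_ids].values
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if np.all(s2 == 0):
        raise ValueError("zero variance in every gene; nothing to test")

    n_genes = expr.shape[0]
    if prior_df is not None:
        d0 = float(prior_df)
        positive = s2[s2 > 0]
        s02 = float(np.exp(np.mean(np.log(positive)))) if len(positive) else 0.0
    elif n_genes < 2:
        warnings.warn("single gene: falling back to the ordinary t-test (no shrinkage target)")
        d0, s02 = 0.0, 0.0
    else:
        floor = max(s2[s2 > 0].min() * 1e-6, 1e-12)
        d0, s02 = _fit_log_variance_prior(np.maximum(s2, floor), df)

    if d0 == 0.0:
        s2_post = s2
        total_df = float(df)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        total_df = float("inf")
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        total_df = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": delta,
            "fold_change": np.exp2(np.abs(delta)),
            "t": t,
            "p": p,
            "adj_p": adj,
        },
        index=expr.features,
    )
    return DgeResult(table, group_a, group_b, d0, s02)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def roc_auc(values: np.ndarray, labels: np.ndarray, positive) -> float:
    """Rank-based (Mann-Whitney) AUROC with ties counted one half."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def percentile_profile(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    class_a: str,
    class_b: str,
    gene: str = "",
) -> RocProfile:
    """Sensitivity/specificity/accuracy at percentile cutpoints 1..99.

    The positive class is whichever class has the higher mean; prediction is
    positive when the value lies on the positive side of the cutpoint
    (>= cutpoint for a high-positive gene, <= for low).  The optimum
    maximizes accuracy, ties broken by larger Youden's J then smaller
    cutpoint.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a_vals = values[labels == class_a]
    b_vals = values[labels == class_b]
    if len(a_vals) == 0 or len(b_vals) == 0:
        raise ValueError("both classes must be present")
    pooled = np.concatenate([a_vals, b_vals])
    if len(pooled) < 5:
        raise ValueError("need at least 5 samples")

    if a_vals.mean() >= b_vals.mean():
        positive, pos_vals, neg_vals = class_a, a_vals, b_vals
    else:
        positive, pos_vals, neg_vals = class_b, b_vals, a_vals
    direction = "high"
    n_pos, n_neg = len(pos_vals), len(neg_vals)

    if np.ptp(pooled) == 0:
        return RocProfile(
            gene=gene, auroc=0.5, positive_class=positive, direction=direction,
            percentiles=pd.DataFrame(
                columns=["cutpoint", "sensitivity", "specificity", "accuracy"]
            ),
            optimum_percentile=None, optimum_cutpoint=None,
            optimum_sensitivity=None, optimum_specificity=None,
            optimum_accuracy=None, degenerate=True,
        )

    pos_label = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    auroc = roc_auc(np.concatenate([pos_vals, neg_vals]), pos_label, True)

    pcts = np.arange(1, 100)
    cuts = np.percentile(pooled, pcts)
    rows = []
    for pct, cut in zip(pcts, cuts):
        sens = float(np.mean(pos_vals >= cut))
        spec = float(np.mean(neg_vals < cut))
        acc = weighted_accuracy(sens, spec, n_pos, n_neg)
        rows.append((int(pct), float(cut), sens, spec, acc))
    table = pd.DataFrame(
        rows, columns=["percentile", "cutpoint", "sensitivity", "specificity", "accuracy"]
    ).set_index("percentile")

    youden = table["sensitivity"] + table["specificity"] - 1.0
    order = sorted(
        table.index,
        key=lambda i: (-table.at[i, "accuracy"], -youden[i], table.at[i, "cutpoint"]),
    )
    opt = order[0]
    return RocProfile(
        gene=gene,
        auroc=auroc,
        positive_class=positive,
        direction=direction,
        percentiles=table,
        optimum_percentile=int(opt),
        optimum_cutpoint=float(table.at[opt, "cutpoint"]),
        optimum_sensitivity=float(table.at[opt, "sensitivity"]),
        optimum_specificity=float(table.at[opt, "specificity"]),
        optimum_accuracy=float(table.at[opt, "accuracy"]),
    )


def weighted_accuracy(sens: float, spec: float, n_pos: int, n_neg: int) -> float:
    """Class-size-weighted accuracy; equals sens (= spec) when the two match."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both class sizes must be positive")
    return (sens * n_pos + spec * n_neg) / (n_pos + n_neg)


def profile_genes(
    expr: ExpressionTable,
    labels: pd.Series,
    class_a: str,
    class_b: str,
    genes: list[str] | None = None,
) -> dict[str, RocProfile]:
    labels = labels.loc[labels.index.intersection(expr.samples)]
    keep = labels.index[labels.isin([class_a, class_b])]
    sub = expr.subset_samples(list(keep))
    lab = labels.loc[keep].values
    genes = list(genes) if genes is not None else list(expr.features)
    out = {}
    for g in genes:
        out[g] = percentile_profile(sub.data.loc[g].values, lab, class_a, class_b, gene=g)
    return out


def run_cascade(
    dge: DgeResult,
    profiles: dict[str, RocProfile],
    cascade: SelectionCascade | None = None,
) -> CascadeResult:
    """Apply the nested filters in order and emit the ranked top-k panel.

    Stage order: adjusted p, linear fold change, AUROC, then the joint
    sensitivity/specificity/AUROC/accuracy thresholds.  Survivors are ranked
    by weight_fc * z(log2 |FC|) + weight_breadth * z(breadth) +
    weight_relevance * relevance, where breadth counts percentile cutpoints
    whose accuracy clears the accuracy threshold.  With all weights zero the
    ranking falls back to AUROC, then adjusted p, then gene id.
    """
    cascade = cascade or SelectionCascade()
    t = dge.table
    stages: dict[str, list[str]] = {"tested": list(t.index)}
    de = t.index[t["adj_p"] < cascade.adj_p_max]
    stages["adj_p"] = list(de)
    fc = [g for g in de if t.at[g, "fold_change"] >= cascade.fc_min]
    stages["fold_change"] = fc
    auc = [g for g in fc if g in profiles and profiles[g].auroc >= cascade.auroc_min]
    stages["auroc"] = auc
    joint = [
        g
        for g in auc
        if not profiles[g].degenerate
        and profiles[g].optimum_sensitivity > cascade.sens_min
        and profiles[g].optimum_specificity > cascade.spec_min
        and profiles[g].auroc > cascade.auroc_strict_min
        and profiles[g].optimum_accuracy > cascade.acc_min
    ]
    stages["joint_metrics"] = joint

    if len(joint) < cascade.k:
        warnings.warn(
            f"only {len(joint)} genes survive the cascade; requested k={cascade.k}"
        )

    ranked = _rank_survivors(joint, t, profiles, cascade)
    top = ranked[: cascade.k]
    stages["signature"] = top

    rows = []
    for g in top:
        p = profiles[g]
        rows.append(
            {
                "gene": g,
                "optimum_cutpoint": p.optimum_cutpoint,
                "accuracy": p.optimum_accuracy,
                "sensitivity": p.optimum_sensitivity,
                "specificity": p.optimum_specificity,
                "auroc": p.auroc,
                "fold_change": float(t.at[g, "fold_change"]),
                "adj_p": float(t.at[g, "adj_p"]),
                "positive_class": p.positive_class,
                "direction": p.direction,
            }
        )
    signature = pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)
    logger.info("cascade stages: %s", {k: len(v) for k, v in stages.items()})
    return CascadeResult(stages=stages, signature=signature)


def _rank_survivors(
    genes: list[str],
    table: pd.DataFrame,
    profiles: dict[str, RocProfile],
    cascade: SelectionCascade,
) -> list[str]:
    if not genes:
        return []
    weights = (cascade.weight_fc, cascade.weight_breadth, cascade.weight_relevance)
    if all(w == 0 for w in weights):
        return sorted(
            genes,
            key=lambda g: (-profiles[g].auroc, table.at[g, "adj_p"], g),
        )
    lfc = np.array([abs(table.at[g, "log2fc"]) for g in genes])
    breadth = np.array(
        [
            float((profiles[g].percentiles["accuracy"] > cascade.acc_min).sum())
            for g in genes
        ]
    )
    rel = np.array([cascade.relevance.get(g, 0.0) for g in genes])

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    score = cascade.weight_fc * z(lfc) + cascade.weight_breadth * z(breadth) + (
        cascade.weight_relevance * rel
    )
    order = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
    return [genes[i] for i in order]


def evaluate_signature(
    expr: ExpressionTable,
    signature: pd.DataFrame,
    classes: tuple[str, str],
) -> pd.DataFrame:
    """Per-sample majority vote of per-gene cutpoint calls on a new dataset.

    ``classes`` names the two candidate labels; each gene votes for its
    recorded positive class when the sample's value lies on the positive
    side of its cutpoint, for the other class otherwise.  Requires >= 50%
    of signature genes in the matrix; missing genes are listed in the error.
    """
    genes = list(signature["gene"])
    present = [g for g in genes if g in expr.features]
    missing = [g for g in genes if g not in expr.features]
    if len(present) < 0.5 * len(genes):
        raise ValueError(
            f"only {len(present)}/{len(genes)} signature genes present; missing: {missing}"
        )
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    bad = set(signature["positive_class"]) - set(classes)
    if bad:
        raise ValueError(f"signature positive classes {sorted(bad)} not in {classes}")
    other = {classes[0]: classes[1], classes[1]: classes[0]}
    sig = signature.set_index("gene")
    sub = expr.data.loc[present]
    rows = []
    for sample in sub.columns:
        votes = {classes[0]: 0, classes[1]: 0}
        for g in present:
            call_high = sub.at[g, sample] >= sig.at[g, "optimum_cutpoint"]
            is_pos = call_high if sig.at[g, "direction"] == "high" else not call_high
            pos = sig.at[g, "positive_class"]
            votes[pos if is_pos else other[pos]] += 1
        predicted = max(classes, key=lambda c: (votes[c], c == classes[0]))
        rows.append(
            {
                "sample": sample,
                f"votes_{classes[0]}": votes[classes[0]],
                f"votes_{classes[1]}": votes[classes[1]],
                "predicted": predicted,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
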