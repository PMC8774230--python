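"""Preranked gene-set enrichment: weighted running-sum score, gene-label
permutation null, sign-stratified normalization, BH adjustment."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .iohub import GeneSetCollection
from .signature import bh_adjust

__all__ = [
    "RankedList",
    "EnrichmentRow",
    "enrichment_score",
    "preranked_gsea",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Gene ids ordered by a descending real-valued statistic."""

    genes: tuple[str, ...]
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.stats) > 1e-12):
            raise ValueError("stats must be sorted descending")

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        ordered = scores.sort_values(ascending=False, kind="mergesort")
        return cls(tuple(ordered.index), ordered.values)

    def __len__(self) -> int:
        return len(self.genes)


def enrichment_score(
    ranked: RankedList, members: set[str] | frozenset[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov-like running sum over the ranked list.

    Hits add |stat|^weight normalized by the set total; misses subtract
    1/(N - set size).  Returns (ES, running sum); ES is the extremum of
    largest magnitude (positive extremum wins exact-magnitude ties).
    """
    hit = np.array([g in members for g in ranked.genes])
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("no set members found in the ranked universe")
    n = len(ranked)
    if n_hits == n:
        running = np.cumsum(np.abs(ranked.stats) ** weight)
        running /= running[-1]
        return 1.0, running
    w = np.abs(ranked.stats) ** weight
    total = w[hit].sum()
    if total == 0:
        raise ValueError("all member statistics are zero under this weight")
    steps = np.where(hit, w / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


def _es_from_positions(
    positions: np.ndarray, weights_all: np.ndarray, n: int
) -> float:
    """ES for a set occupying ``positions`` (sorted ascending) of the list.

    Equivalent to walking the full list but O(k): between hits the running
    sum decays linearly, so extrema occur right after a hit (peaks) or right
    before one (troughs).
    """
    k = len(positions)
    w = weights_all[positions]
    total = w.sum()
    if total == 0:
        return 0.0
    miss = 1.0 / (n - k)
    cum_w = np.cumsum(w) / total
    idx = np.arange(k)
    after_hit = cum_w - (positions + 1 - (idx + 1)) * miss
    before_hit = np.concatenate([[0.0], cum_w[:-1]]) - (positions - idx) * miss
    peak = after_hit.max()
    trough = before_hit.min()
    return float(peak if peak >= -trough else trough)


def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation-based enrichment for every admissible set.

    The null permutes gene labels of the ranking statistic, i.e. each
    permutation scores a uniformly random same-size subset of positions.
    p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #same-sign perms);
    NES = ES / mean(|same-sign null ES|).  Sets outside [min_size, max_size]
    after restriction to the universe are excluded and logged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    universe = set(ranked.genes)
    weights_all = np.abs(ranked.stats) ** weight

    # The null depends only on (seed, set size), so equal-size sets share it:
    # duplicate sets get identical p and NES, and the cache saves work.
    null_cache: dict[int, np.ndarray] = {}

    def null_for(size: int) -> np.ndarray:
        if size not in null_cache:
            rng = stage_rng(seed, f"gsea:permutations:size={size}")
            null = np.empty(n_perm)
            for i in range(n_perm):
                pos = np.sort(rng.choice(n, size=size, replace=False))
                null[i] = _es_from_positions(pos, weights_all, n)
            null_cache[size] = null
        return null_cache[size]

    rows = []
    for name, members in collection:
        restricted = frozenset(members) & universe
        size = len(restricted)
        if size < min_size or size > max_size:
            logger.info("set %r excluded (size %d outside [%d, %d])", name, size, min_size, max_size)
            continue
        es, _ = enrichment_score(ranked, restricted, weight=weight)
        null = null_for(size)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1.0 + extreme) / (1.0 + n_same)
        denom = np.abs(null[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append(
            {"set": name, "size": size, "es": es, "nes": nes, "p": p}
        )
    if not rows:
        raise ValueError("no admissible gene sets")
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = bh_adjust(out["p"].values)
    return out
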