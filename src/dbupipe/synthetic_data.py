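"""Synthetic multi-study expression data with planted ground truth.

Generates probe-level log2 expression matrices for a configurable set of
study batches containing three sample classes (chRCC, RO, N), with

* per-gene baselines drawn once per gene universe,
* planted differentially expressed genes (chRCC vs RO) with fold changes
  drawn uniformly from a linear-scale range,
* per-batch additive location shifts and multiplicative residual scale
  effects,
* 1..k probes per gene, exactly one faithful, the rest degraded by one of
  three failure modes (low signal, inflated noise, multi-gene annotation),
* an RNA-seq-like platform that draws negative-binomial counts and log-CPM
  transforms them.

The gene universe (ids, baselines, planted effects, probe layout) depends
only on the universe-shaping fields of the design and the seed, so bundles
generated with the same seed share planted truth.  This is what lets a
signature learned on the discovery surrogate be evaluated on the validation
surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .iohub import ExpressionTable, PhenotypeTable

__all__ = [
    "StudyDesign",
    "SyntheticTruth",
    "StudyBundle",
    "generate_study",
    "generate_discovery_surrogate",
    "generate_validation_surrogate",
    "DISCOVERY_STUDIES",
]

# Discovery batch composition: (batch id, n_chRCC, n_RO, n_N).
DISCOVERY_STUDIES: tuple[tuple[str, int, int, int], ...] = (
    ("batch1", 6, 7, 12),
    ("batch2", 4, 4, 5),
    ("batch3", 15, 15, 0),
    ("batch4", 10, 10, 0),
    ("batch5", 18, 0, 0),
)

_DEGRADE_MODES = ("low_signal", "high_variance", "cross_map")


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a synthetic multi-batch bundle."""

    studies: tuple[tuple[str, int, int, int], ...]
    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)
    frac_de: float = 0.15
    fc_range: tuple[float, float] = (2.0, 56.0)
    batch_loc_sd: float = 1.5
    batch_scale_shape: float = 25.0
    noise_sd: float = 0.7
    platform: str = "array_log2"
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.platform not in ("array_log2", "rnaseq_logcpm"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if not self.studies:
            raise ValueError("design has no studies")
        for batch_id, n_ch, n_ro, n_n in self.studies:
            if min(n_ch, n_ro, n_n) < 0:
                raise ValueError(f"negative sample count in study {batch_id!r}")
            if n_ch + n_ro + n_n == 0:
                raise ValueError(f"study {batch_id!r} has zero samples")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        lo, hi = self.fc_range
        if lo < 1.0:
            raise ValueError("fc_range lower bound must be >= 1")
        if hi < lo:
            raise ValueError("fc_range is inverted")
        plo, phi = self.probes_per_gene
        if plo < 1 or phi < plo:
            raise ValueError("probes_per_gene must be a valid range with lower bound >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.batch_scale_shape <= 2.0:
            raise ValueError("batch_scale_shape must exceed 2 (finite-variance prior)")

    def universe_key(self) -> tuple:
        """Fields that shape the gene universe (shared across platforms)."""
        return (
            self.n_genes,
            self.probes_per_gene,
            self.frac_de,
            self.fc_range,
            self.baseline_mean,
            self.baseline_sd,
            self.noise_sd,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    ``de_log2fc`` maps each planted gene to its signed chRCC-vs-RO log2 fold
    change; class means are baseline +/- half that shift, so the implied
    tumor-vs-normal shift is half the tumor-vs-tumor shift.
    ``population_auroc`` is the noise-model AUROC Phi(|lfc| / (sd * sqrt(2)))
    for the chRCC-vs-RO contrast on the faithful probe.
    """

    de_log2fc: dict[str, float]
    population_auroc: dict[str, float]
    batch_location: dict[str, np.ndarray]
    batch_scale: dict[str, np.ndarray]
    good_probe: dict[str, str]
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for batch, scale in self.batch_scale.items():
            if np.any(scale <= 0):
                raise ValueError(f"non-positive scale effect in batch {batch!r}")

    def contrast_log2fc(self, contrast: str) -> dict[str, float]:
        """Signed log2 FC per planted gene for a named contrast."""
        if contrast == "chRCC_vs_RO":
            return dict(self.de_log2fc)
        if contrast == "chRCC_vs_N":
            return {g: v / 2.0 for g, v in self.de_log2fc.items()}
        if contrast == "RO_vs_N":
            return {g: -v / 2.0 for g, v in self.de_log2fc.items()}
        raise KeyError(contrast)


class StudyBundle(NamedTuple):
    expression: ExpressionTable
    phenotype: PhenotypeTable
    annotation: dict[str, tuple[str, ...]]
    truth: SyntheticTruth


@dataclass(frozen=True)
class _Universe:
    gene_ids: tuple[str, ...]
    baseline: np.ndarray          # per gene, log2 scale
    de_log2fc: dict[str, float]
    probe_ids: tuple[str, ...]
    probe_gene_idx: np.ndarray    # primary gene index per probe
    probe_mode: tuple[str, ...]   # "faithful" or a degrade mode
    annotation: dict[str, tuple[str, ...]]
    good_probe: dict[str, str]


def _build_universe(design: StudyDesign, seed: int) -> _Universe:
    # Derived only from universe-shaping fields + seed: identical across
    # platforms/batch layouts generated from the same seed.
    rng = stage_rng(seed, "universe")
    n = design.n_genes
    gene_ids = tuple(f"G{i + 1:05d}" for i in range(n))
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n)

    n_de = int(round(design.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    fcs = rng.uniform(design.fc_range[0], design.fc_range[1], size=n_de)
    de_log2fc = {
        gene_ids[i]: float(s * np.log2(fc))
        for i, s, fc in zip(de_idx, signs, fcs)
    }

    plo, phi = design.probes_per_gene
    counts = rng.integers(plo, phi + 1, size=n)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    probe_mode: list[str] = []
    annotation: dict[str, tuple[str, ...]] = {}
    good_probe: dict[str, str] = {}
    for gi, k in enumerate(counts):
        faithful_slot = int(rng.integers(0, k))
        for slot in range(int(k)):
            pid = f"{gene_ids[gi]}_p{slot + 1}"
            probe_ids.append(pid)
            probe_gene_idx.append(gi)
            if slot == faithful_slot:
                probe_mode.append("faithful")
                annotation[pid] = (gene_ids[gi],)
                good_probe[gene_ids[gi]] = pid
            else:
                mode = _DEGRADE_MODES[int(rng.integers(0, len(_DEGRADE_MODES)))]
                probe_mode.append(mode)
                if mode == "cross_map":
                    other = int(rng.integers(0, n - 1))
                    if other >= gi:
                        other += 1
                    annotation[pid] = (gene_ids[gi], gene_ids[other])
                else:
                    annotation[pid] = (gene_ids[gi],)
    return _Universe(
        gene_ids=gene_ids,
        baseline=baseline,
        de_log2fc=de_log2fc,
        probe_ids=tuple(probe_ids),
        probe_gene_idx=np.asarray(probe_gene_idx),
        probe_mode=tuple(probe_mode),
        annotation=annotation,
        good_probe=good_probe,
    )


def _class_offsets(universe: _Universe, design: StudyDesign) -> dict[str, np.ndarray]:
    n = design.n_genes
    half = np.zeros(n)
    pos = {g: i for i, g in enumerate(universe.gene_ids)}
    for g, lfc in universe.de_log2fc.items():
        half[pos[g]] = lfc / 2.0
    return {"chRCC": half, "RO": -half, "N": np.zeros(n)}


def generate_study(design: StudyDesign, seed: int) -> StudyBundle:
    """Generate one multi-batch bundle from a design; deterministic in seed."""
    universe = _build_universe(design, seed)
    offsets = _class_offsets(universe, design)
    n_genes = design.n_genes

    sample_ids: list[str] = []
    histology: list[str] = []
    batch_col: list[str] = []
    gene_cols: list[np.ndarray] = []

    batch_location: dict[str, np.ndarray] = {}
    batch_scale: dict[str, np.ndarray] = {}
    rng_batches = stage_rng(seed, f"batch-effects:{design.platform}")
    rng_samples = stage_rng(seed, f"samples:{design.platform}")

    for batch_id, n_ch, n_ro, n_n in design.studies:
        loc = rng_batches.normal(0.0, design.batch_loc_sd, size=n_genes)
        # Inverse-gamma with mean 1: shape a, scale a - 1.
        a = design.batch_scale_shape
        scale_var = (a - 1.0) / rng_batches.gamma(a, 1.0, size=n_genes)
        batch_location[batch_id] = loc
        batch_scale[batch_id] = scale_var
        sd_mult = np.sqrt(scale_var)
        for hist, count in (("chRCC", n_ch), ("RO", n_ro), ("N", n_n)):
            for j in range(count):
                sid = f"{batch_id}_{hist}_{j + 1:02d}"
                resid = rng_samples.normal(0.0, design.noise_sd, size=n_genes)
                values = universe.baseline + offsets[hist] + loc + resid * sd_mult
                sample_ids.append(sid)
                histology.append(hist)
                batch_col.append(batch_id)
                gene_cols.append(values)

    gene_matrix = np.column_stack(gene_cols)  # genes x samples

    probe_matrix = _expand_probes(universe, design, gene_matrix, rng_samples)
    if design.platform == "rnaseq_logcpm":
        probe_matrix = _to_logcpm(probe_matrix, rng_samples)

    expr = ExpressionTable(
        pd.DataFrame(probe_matrix, index=list(universe.probe_ids), columns=sample_ids),
        scale="log2",
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"histology": histology, "batch": batch_col},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    pop_auroc = {
        g: float(_normal_cdf(abs(lfc) / (design.noise_sd * np.sqrt(2.0))))
        for g, lfc in universe.de_log2fc.items()
    }
    truth = SyntheticTruth(
        de_log2fc=dict(universe.de_log2fc),
        population_auroc=pop_auroc,
        batch_location=batch_location,
        batch_scale=batch_scale,
        good_probe=dict(universe.good_probe),
        gene_ids=universe.gene_ids,
    )
    return StudyBundle(expr, pheno, dict(universe.annotation), truth)


def _expand_probes(
    universe: _Universe,
    design: StudyDesign,
    gene_matrix: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Probe rows from gene rows; degraded probes get mode-specific damage."""
    n_samples = gene_matrix.shape[1]
    rows = np.empty((len(universe.probe_ids), n_samples))
    for pi, (gi, mode, pid) in enumerate(
        zip(universe.probe_gene_idx, universe.probe_mode, universe.probe_ids)
    ):
        signal = gene_matrix[gi]
        if mode == "faithful":
            rows[pi] = signal
        elif mode == "low_signal":
            rows[pi] = signal - 4.0 + rng.normal(0.0, design.noise_sd, size=n_samples)
        elif mode == "high_variance":
            rows[pi] = signal + rng.normal(0.0, 3.0 * design.noise_sd, size=n_samples)
        else:  # cross_map: mixes in the other annotated gene's signal
            other_gene = universe.annotation[pid][1]
            oi = universe.gene_ids.index(other_gene)
            rows[pi] = 0.6 * signal + 0.4 * gene_matrix[oi] + rng.normal(
                0.0, design.noise_sd, size=n_samples
            )
    return rows


def _to_logcpm(log2_matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw NB counts with mean 2^value, then log2-CPM transform."""
    mean = np.exp2(log2_matrix)
    r = 20.0  # NB size parameter; moderate overdispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(float)
    libsize = counts.sum(axis=0)
    libsize[libsize == 0] = 1.0
    return np.log2(counts / libsize * 1e6 + 1.0)


def _normal_cdf(x: float) -> float:
    from math import erf, sqrt

    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def generate_discovery_surrogate(seed: int, **overrides) -> StudyBundle:
    """Five array batches totalling 53 chRCC / 36 RO / 17 N (106 samples)."""
    design = StudyDesign(studies=DISCOVERY_STUDIES, **overrides)
    return generate_study(design, seed)


def generate_validation_surrogate(seed: int, **overrides) -> tuple[StudyBundle, StudyBundle]:
    """An array batch (9 chRCC, 9 RO) plus an RNA-seq batch (65 chRCC).

    Both bundles share the gene universe and planted effects of the
    discovery surrogate generated with the same seed.  One probe per gene,
    so probe ids double as gene-level handles downstream.
    """
    common = dict(probes_per_gene=(1, 1))
    common.update(overrides)
    array_design = StudyDesign(
        studies=(("val_array", 9, 9, 0),), platform="array_log2", **common
    )
    rnaseq_design = StudyDesign(
        studies=(("val_rnaseq", 65, 0, 0),), platform="rnaseq_logcpm", **common
    )
    return generate_study(array_design, seed), generate_study(rnaseq_design, seed)
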