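"""Tabular I/O for the pipeline: expression TSV, phenotype CSV, probe
annotation TSV, GMT gene sets, and JSON result files.

Expression tables are plain TSV (first column = feature ids, header row =
sample ids).  Lines starting with ``!`` are tolerated and skipped so that
series-matrix-style exports load directly.  Missing values are rejected, not
imputed: every downstream method assumes a complete matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "PhenotypeTable",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "write_json",
    "read_json",
]

HISTOLOGIES = ("chRCC", "RO", "N", "other")


@dataclass
class ExpressionTable:
    """A numeric feature-by-sample matrix with a scale flag.

    ``data`` rows are probes or genes, columns are samples.  ``scale`` is
    ``"log2"`` once values are on log scale, ``"raw"`` otherwise.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.issubdtype(np.asarray(self.data.values).dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ValueError(f"non-numeric value at row {bad[0]!r}, column {bad[1]!r}")
        if not np.isfinite(self.data.values).all():
            r, c = np.argwhere(~np.isfinite(self.data.values))[0]
            raise ValueError(
                f"non-finite value at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, ids: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(self.data.loc[list(ids)], scale=self.scale)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(self.data[list(ids)], scale=self.scale)


@dataclass
class PhenotypeTable:
    """Per-sample histology label and batch id.

    ``data`` is indexed by sample id with columns ``histology`` and ``batch``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"histology", "batch"} - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad = set(self.data["histology"]) - set(HISTOLOGIES)
        if bad:
            raise ValueError(f"unknown histology labels: {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def histology(self) -> pd.Series:
        return self.data["histology"]

    @property
    def batch(self) -> pd.Series:
        return self.data["batch"]

    def subset(self, ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(ids)])

    def check_covers(self, expr: ExpressionTable) -> None:
        """Every expression column must have a phenotype row."""
        missing = [s for s in expr.samples if s not in self.data.index]
        if missing:
            raise ValueError(f"samples without phenotype rows: {missing}")


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(col)
    return str(df.index[0]), str(df.columns[0])


def read_expression(
    path: str | Path,
    orientation: str = "features_by_samples",
    scale: str = "log2",
) -> ExpressionTable:
    """Read an expression TSV.

    ``orientation="samples_by_features"`` transposes after parsing so the
    returned table is always features x samples.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    if orientation == "samples_by_features":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[int(np.argmax(bad.values))]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r} in {path}")
    df = df.astype(float)
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}; imputation is not supported")
    return ExpressionTable(df, scale=scale)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    # %.17g preserves doubles exactly across the round trip
    expr.data.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, index_col=0, dtype=str)
    return PhenotypeTable(df)


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, index_label="sample_id")


def read_annotation(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a probe-to-gene annotation TSV (columns: probe_id, gene_ids).

    Multiple genes for one probe are comma-separated in the second column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["probe_id", "gene_ids"]:
        raise ValueError(
            f"annotation file {path} must have columns probe_id, gene_ids"
        )
    out: dict[str, tuple[str, ...]] = {}
    for probe, genes in zip(df["probe_id"], df["gene_ids"]):
        if probe in out:
            raise ValueError(f"duplicate probe id {probe!r} in annotation")
        out[probe] = tuple(g.strip() for g in genes.split(",") if g.strip())
    return out


def write_annotation(annotation: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_ids\n")
        for probe, genes in annotation.items():
            fh.write(f"{probe}\t{','.join(genes)}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated.

    Duplicate members within a set are dropped (first occurrence kept);
    duplicate set names and empty sets are errors.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            deduped = tuple(dict.fromkeys(m for m in members if m))
            if not deduped:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
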