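"""Shared data model, readers/writers, and validation.

The canonical on-disk format for all tabular inputs is TSV: one header row,
one label column.  Count tables are sample x taxon non-negative integer
matrices tagged with an organism domain; sample metadata lives in a
:class:`SampleTable`; pairwise sample distances in a :class:`DistanceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("archaea", "bacteria", "fungi", "grass")
GRASSLAND_TYPES = ("ASM", "AM", "AS", "TS")

#: canonical metadata column names; matching on read is case-insensitive
SAMPLE_COLUMNS = (
    "sample_id", "site_id", "grassland_type", "latitude", "longitude",
    "altitude", "MAT", "pH", "CEC", "OM", "TN", "TP", "TC", "SMC",
    "H", "CD", "S", "FB", "DB",
)
REQUIRED_SAMPLE_COLUMNS = ("sample_id", "latitude", "longitude")

SOIL_VARIABLES = ("pH", "CEC", "OM", "TN", "TP", "TC", "SMC")
GRASS_VARIABLES = ("H", "CD", "S", "FB", "DB")


class GraminetError(Exception):
    """Base class for all package errors."""


class ValidationError(GraminetError):
    pass


class SchemaError(GraminetError):
    pass


class AlignmentError(GraminetError):
    pass


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CountTable:
    """Sample x taxon count matrix with an organism-domain tag."""

    samples: list[str]
    taxa: list[str]
    counts: np.ndarray
    domain: str

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.taxa = [str(t) for t in self.taxa]
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")
        _check_unique(self.samples, "sample")
        _check_unique(self.taxa, "taxon")
        if len(self.samples) < 1 or len(self.taxa) < 1:
            raise ValidationError("count table needs >= 1 sample and >= 1 taxon")
        if self.counts.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(~np.isfinite(self.counts.astype(float))):
            raise ValidationError("counts must be finite")
        if np.any(self.counts.sum(axis=1) <= 0):
            empty = [s for s, tot in zip(self.samples, self.counts.sum(axis=1)) if tot <= 0]
            raise ValidationError(f"samples with zero total counts: {empty}")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.taxa)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts (each row sums to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        return self.counts / totals

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxa), self.counts[idx], self.domain)

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.counts.sum(axis=0) > 0
        if keep.all():
            return self
        taxa = [t for t, k in zip(self.taxa, keep) if k]
        return CountTable(list(self.samples), taxa, self.counts[:, keep], self.domain)

    def write(self, path: str | Path, orientation: str = "samples_rows") -> None:
        df = self.to_frame()
        if orientation == "taxa_rows":
            df = df.T
            df.index.name = "taxon_id"
        elif orientation == "samples_rows":
            df.index.name = "sample_id"
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        df.to_csv(path, sep="\t")


def read_count_table(path: str | Path, domain: str,
                     orientation: str = "samples_rows") -> CountTable:
    """Read a TSV count table, normalising orientation to samples x taxa."""
    if orientation not in ("samples_rows", "taxa_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate labels")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric cell") from exc
    if np.any(~np.isfinite(values)):
        raise SchemaError(f"{path}: missing or non-finite cell")
    if orientation == "taxa_rows":
        df = df.T
    return CountTable(list(df.index), list(df.columns), df.to_numpy(dtype=float), domain)


_RANGE_CHECKS = {
    "latitude": (-90.0, 90.0),
    "longitude": (-180.0, 180.0),
    "CD": (0.0, 100.0),
    "SMC": (0.0, 100.0),
}


@dataclass
class SampleTable:
    """Per-sample metadata (coordinates, soil and grass variables, type).

    Backed by a DataFrame indexed by sample_id with canonical column names.
    Optional columns that were absent from the source file are recorded in
    ``absent`` rather than filled with zeros.
    """

    data: pd.DataFrame
    absent: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_id in metadata")
        for col, (lo, hi) in _RANGE_CHECKS.items():
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if ((vals < lo) | (vals > hi)).any():
                    raise ValidationError(f"{col} outside [{lo}, {hi}]")
        if "S" in self.data.columns:
            s = self.data["S"].dropna()
            if (s < 0).any():
                raise ValidationError("S must be >= 0")
        if "grassland_type" in self.data.columns:
            bad = set(self.data["grassland_type"].dropna()) - set(GRASSLAND_TYPES)
            if bad:
                raise ValidationError(f"unknown grassland types: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def variables(self, names: Sequence[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"metadata columns not present: {missing}")
        return self.data[list(names)].astype(float)

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)].copy(), self.absent)

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def read_sample_frame(path: str | Path) -> SampleTable:
    """Read TSV sample metadata with case-insensitive column matching."""
    try:
        raw = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    canon = {c.lower(): c for c in SAMPLE_COLUMNS}
    rename = {}
    for col in raw.columns:
        if col.lower() in canon:
            rename[col] = canon[col.lower()]
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    raw["sample_id"] = raw["sample_id"].astype(str)
    data = raw.set_index("sample_id")
    absent = tuple(c for c in SAMPLE_COLUMNS[1:] if c not in data.columns)
    return SampleTable(data, absent)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise matrix over labelled samples."""

    labels: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        _check_unique(self.labels, "label")
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(self.values < -1e-12):
            raise ValidationError("distances must be non-negative")
        # enforce exact symmetry/zero diagonal after tolerance checks
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major (i<j) — scipy squareform order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def select(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(s) for s in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path, metric: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), metric)


@dataclass
class Bundle:
    """Count tables plus metadata restricted to a common, ordered sample set."""

    tables: dict[str, CountTable]
    frame: SampleTable
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return self.frame.samples


def align_bundle(tables: Iterable[CountTable], frame: SampleTable) -> Bundle:
    """Restrict tables and metadata to the intersection of sample ids.

    Sample ordering is lexicographic by sample_id so that repeated runs are
    deterministic.  Idempotent: aligning an aligned bundle changes nothing.
    """
    tables = list(tables)
    if not tables or len(frame) == 0:
        raise AlignmentError("empty inputs")
    common = set(frame.samples)
    for t in tables:
        common &= set(t.samples)
    if not common:
        raise AlignmentError("no samples shared by all tables and the metadata")
    order = sorted(common)
    dropped = {"frame": sorted(set(frame.samples) - common)}
    out_tables: dict[str, CountTable] = {}
    for t in tables:
        dropped[t.domain] = sorted(set(t.samples) - common)
        out_tables[t.domain] = t.select_samples(order)
    return Bundle(out_tables, frame.select_samples(order), dropped)


def align_pair(table: CountTable, frame: SampleTable) -> tuple[CountTable, SampleTable]:
    """Per-domain alignment of a single table to the metadata.

    Used when domains have unequal sample coverage (e.g. a fungal table with
    fewer sequenced samples than the prokaryote tables) — each domain keeps
    its own largest usable sample set.
    """
    b = align_bundle([table], frame)
    return b.tables[table.domain], b.frame
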