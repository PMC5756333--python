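"""Core containers and I/O for expression count data.

The central object is :class:`ExpressionMatrix`, a feature-by-sample numeric
matrix (raw counts or normalized values) with unique, ordered feature and
sample identifiers.  Companion types carry the experiment design, a
spike-in/biological feature partition and per-feature gene lengths.

Supported on-disk formats:

* delimited text (TSV/CSV): first column = feature IDs, header row = sample
  IDs; the delimiter is inferred from the extension (``.tsv`` → tab,
  ``.csv`` → comma) unless given explicitly;
* MatrixMarket coordinate triplets (Cell Ranger convention) with companion
  ``features`` / ``barcodes`` line-per-entry text files, 1-based
  coordinates, features file order = row order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "DesignTable",
    "SpikePartition",
    "GeneLengths",
    "read_counts",
    "write_counts",
    "read_design",
    "read_gene_list",
    "read_gene_lengths",
    "merge_matrices",
    "detect_spike_ins",
]

MatrixKind = Literal["counts", "normalized", "log_normalized"]
_KINDS = ("counts", "normalized", "log_normalized")


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """Feature-by-sample numeric matrix with identifier bookkeeping.

    Parameters
    ----------
    values
        DataFrame with features as the index and samples as columns.
    kind
        ``counts`` (non-negative raw or estimated counts), ``normalized``
        or ``log_normalized``.
    """

    values: pd.DataFrame
    kind: MatrixKind = "counts"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        dup = _first_duplicate(self.values.index)
        if dup is not None:
            raise ValueError(f"duplicate feature ID {dup!r}")
        dup = _first_duplicate(self.values.columns)
        if dup is not None:
            raise ValueError(f"duplicate sample ID {dup!r}")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        arr = self.values.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("matrix contains non-numeric cells")
            if not np.all(np.isfinite(arr)):
                raise ValueError("matrix contains non-finite cells")
            if self.kind == "counts" and (arr < 0).any():
                raise ValueError("count matrix contains negative values")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        feature_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return the sub-matrix restricted to the given IDs (order kept)."""
        df = self.values
        if feature_ids is not None:
            feature_ids = list(feature_ids)
            missing = [f for f in feature_ids if f not in df.index]
            if missing:
                raise KeyError(f"unknown feature ID {missing[0]!r}")
            df = df.loc[feature_ids]
        if sample_ids is not None:
            sample_ids = list(sample_ids)
            missing = [s for s in sample_ids if s not in df.columns]
            if missing:
                raise KeyError(f"unknown sample ID {missing[0]!r}")
            df = df[sample_ids]
        return ExpressionMatrix(df.copy(), kind=self.kind)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.kind == other.kind
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy())
        )


@dataclass
class DesignTable:
    """Per-sample experiment design: condition, optional batch, extras."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.table.index)
        if dup is not None:
            raise ValueError(f"duplicate sample row {dup!r} in design table")
        if "condition" not in self.table.columns:
            raise ValueError("design table is missing the 'condition' column")
        self.table.index = self.table.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> pd.Series:
        return self.table["condition"]

    def bind(self, matrix: ExpressionMatrix) -> "DesignTable":
        """Check the design covers every matrix sample exactly once."""
        for s in matrix.sample_ids:
            if s not in self.table.index:
                raise ValueError(f"design table has no row for sample {s!r}")
        return DesignTable(self.table.loc[matrix.sample_ids].copy())

    def groups(self, samples: Iterable[str] | None = None) -> dict[str, str]:
        t = self.table if samples is None else self.table.loc[list(samples)]
        return dict(t["condition"])


@dataclass
class SpikePartition:
    """Disjoint split of the feature set into spike-in and biological IDs."""

    spike_feature_ids: list[str]
    biological_feature_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.spike_feature_ids) & set(self.biological_feature_ids)
        if overlap:
            raise ValueError(f"feature {sorted(overlap)[0]!r} in both partitions")

    @property
    def all_feature_ids(self) -> list[str]:
        return list(self.spike_feature_ids) + list(self.biological_feature_ids)


@dataclass
class GeneLengths:
    """Mapping feature_id → length in bases (positive)."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths, dtype=float)
        self.lengths.index = self.lengths.index.astype(str)
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for feature {bad!r}")

    def for_features(self, feature_ids: Iterable[str]) -> np.ndarray:
        feature_ids = list(feature_ids)
        missing = [f for f in feature_ids if f not in self.lengths.index]
        if missing:
            raise ValueError(f"no length for feature {missing[0]!r}")
        return self.lengths.loc[feature_ids].to_numpy()


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = Path(path).suffix.lower()
    return "," if ext == ".csv" else "\t"


def read_counts(
    path: str | Path,
    format: Literal["delimited", "mtx_triplet"] = "delimited",
    *,
    delimiter: str | None = None,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    kind: MatrixKind = "counts",
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or MatrixMarket triplets.

    For ``mtx_triplet`` the companion ``features_path`` and ``barcodes_path``
    (one ID per line) are required; they default to ``features.tsv`` and
    ``barcodes.tsv`` next to the ``.mtx`` file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        sep = _infer_delimiter(path, delimiter)
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        except pd.errors.ParserError as exc:  # C parser reports the line number
            raise ValueError(f"ragged rows in {path}: {exc}") from exc
        if df.isna().to_numpy().any():
            row = df.index[df.isna().any(axis=1)][0]
            raise ValueError(
                f"missing or non-numeric cell in row {row!r} of {path} "
                "(ragged or malformed line)"
            )
        return ExpressionMatrix(df, kind=kind)
    if format == "mtx_triplet":
        features_path = Path(features_path or path.with_name("features.tsv"))
        barcodes_path = Path(barcodes_path or path.with_name("barcodes.tsv"))
        for p in (features_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(p)
        mat = scipy.io.mmread(os.fspath(path))
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        features = [ln.split("\t")[0] for ln in _read_lines(features_path)]
        barcodes = [ln.split("\t")[0] for ln in _read_lines(barcodes_path)]
        if dense.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match "
                f"{len(features)} features x {len(barcodes)} barcodes"
            )
        df = pd.DataFrame(dense, index=features, columns=barcodes)
        return ExpressionMatrix(df, kind=kind)
    raise ValueError(f"unknown format {format!r}")


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def write_counts(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: Literal["delimited", "mtx_triplet"] = "delimited",
    *,
    delimiter: str | None = None,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> None:
    """Write a matrix so that :func:`read_counts` recovers it exactly."""
    path = Path(path)
    if format == "delimited":
        sep = _infer_delimiter(path, delimiter)
        # 17 significant digits → exact float64 round trip
        matrix.values.to_csv(path, sep=sep, float_format="%.17g")
        return
    if format == "mtx_triplet":
        features_path = Path(features_path or path.with_name("features.tsv"))
        barcodes_path = Path(barcodes_path or path.with_name("barcodes.tsv"))
        coo = scipy.sparse.coo_matrix(matrix.values.to_numpy())
        scipy.io.mmwrite(os.fspath(path), coo, precision=17)
        features_path.write_text("".join(f"{f}\n" for f in matrix.feature_ids))
        barcodes_path.write_text("".join(f"{s}\n" for s in matrix.sample_ids))
        return
    raise ValueError(f"unknown format {format!r}")


def read_design(path: str | Path) -> DesignTable:
    """Read a design CSV with a ``sample`` column and a ``condition`` column."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols:
        raise ValueError("design CSV is missing the 'sample' column")
    df = df.set_index(cols["sample"])
    df.index.name = "sample"
    df = df.rename(columns={c: c.lower() for c in df.columns})
    return DesignTable(df)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one ID per line; blank lines skipped."""
    return _read_lines(Path(path))


def read_gene_lengths(path: str | Path) -> GeneLengths:
    """Two-column TSV (feature_id, length in bases), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("gene length table needs two columns: feature, length")
    series = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    return GeneLengths(series)


def merge_matrices(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    axis: Literal["samples", "features"] = "samples",
) -> ExpressionMatrix:
    """Concatenate two count matrices along samples or features.

    ``axis='samples'`` requires identical feature sets (A's order kept) and
    disjoint sample IDs; ``axis='features'`` is the transpose case.  ID
    collisions are rejected rather than silently suffixed.
    """
    if a.kind != "counts" or b.kind != "counts":
        raise ValueError("merge is defined on count matrices")
    if axis == "samples":
        if set(a.feature_ids) != set(b.feature_ids):
            diff = sorted(set(a.feature_ids) ^ set(b.feature_ids))
            raise ValueError(f"feature sets differ (e.g. {diff[0]!r})")
        overlap = set(a.sample_ids) & set(b.sample_ids)
        if overlap:
            raise ValueError(f"overlapping sample ID {sorted(overlap)[0]!r}")
        bv = b.values.loc[a.feature_ids] if a.n_features else b.values
        return ExpressionMatrix(pd.concat([a.values, bv], axis=1), kind="counts")
    if axis == "features":
        if set(a.sample_ids) != set(b.sample_ids):
            diff = sorted(set(a.sample_ids) ^ set(b.sample_ids))
            raise ValueError(f"sample sets differ (e.g. {diff[0]!r})")
        overlap = set(a.feature_ids) & set(b.feature_ids)
        if overlap:
            raise ValueError(f"overlapping feature ID {sorted(overlap)[0]!r}")
        bv = b.values[a.sample_ids] if a.n_samples else b.values
        return ExpressionMatrix(pd.concat([a.values, bv], axis=0), kind="counts")
    raise ValueError(f"unknown merge axis {axis!r}")


def detect_spike_ins(matrix: ExpressionMatrix, prefix: str = "ERCC-") -> SpikePartition:
    """Partition features into spike-ins (ID prefix match) and biological."""
    spikes = [f for f in matrix.feature_ids if f.startswith(prefix)]
    spike_set = set(spikes)
    bio = [f for f in matrix.feature_ids if f not in spike_set]
    return SpikePartition(spikes, bio)
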