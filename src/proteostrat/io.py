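"""Shared data model and TSV/GMT readers and writers.

All abundance matrices are features x samples on a log2 scale and are
assumed to be already normalized upstream (no normalization stage is
provided).  Missing values are encoded as ``NA`` in files and ``NaN`` in
memory.  Genomic coordinates are 1-based closed intervals in files and
0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "GeneSetCollection",
    "SchemaError",
    "load_matrix",
    "write_matrix",
    "load_gmt",
    "write_gmt",
    "subset_align",
]

META_COLUMNS = ["gene_symbol", "chromosome", "start", "end", "feature_class"]


class SchemaError(ValueError):
    """A file or table violates the expected schema."""


@dataclass
class OmicsMatrix:
    """Feature x sample matrix of log2 abundances with feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
        Entries are finite floats or NaN (missing).
    feature_meta
        Optional per-feature metadata indexed by feature id with columns
        ``gene_symbol, chromosome, start, end, feature_class``.  ``start``
        and ``end`` are 0-based half-open internally.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dup[:5]}")
        arr = self.values.to_numpy()
        if arr.dtype.kind not in "fiu":
            raise SchemaError("matrix values must be numeric")
        if np.isinf(arr).any():
            raise SchemaError("matrix contains non-finite (inf) values")
        if self.feature_meta is not None:
            missing = idx.difference(self.feature_meta.index)
            if len(missing):
                raise SchemaError(
                    f"features without metadata: {missing.tolist()[:5]}"
                )
            self.feature_meta = self.feature_meta.loc[idx]

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: list[str]) -> "OmicsMatrix":
        unknown = set(samples) - set(self.values.columns)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)[:5]}")
        return OmicsMatrix(self.values[list(samples)], self.feature_meta)

    def subset_features(self, features: list[str]) -> "OmicsMatrix":
        unknown = set(features) - set(self.values.index)
        if unknown:
            raise KeyError(f"unknown feature ids: {sorted(unknown)[:5]}")
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[list(features)]
        return OmicsMatrix(self.values.loc[list(features)], meta)


@dataclass
class GeneSetCollection:
    """Named feature sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise SchemaError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise SchemaError(f"gene set {name!r} has duplicate members")
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def load_matrix(path, meta_path=None) -> OmicsMatrix:
    """Read a ``feature_id<TAB>sample...`` TSV, optionally with metadata.

    ``NA`` cells become missing values.  Duplicate ids, ragged rows and
    non-numeric cells raise :class:`SchemaError` naming the offender.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"],
            keep_default_na=False, dtype=str,
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise SchemaError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicate feature_id {dup[:5]}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise SchemaError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}"
            )
        values[col] = converted
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if {"start", "end"}.issubset(meta.columns):
            # files carry 1-based closed intervals
            meta = meta.copy()
            meta["start"] = meta["start"].astype(int) - 1
            meta["end"] = meta["end"].astype(int)
    return OmicsMatrix(values, meta)


def write_matrix(matrix: OmicsMatrix, path, meta_path=None) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if meta_path is not None and matrix.feature_meta is not None:
        meta = matrix.feature_meta.copy()
        if {"start", "end"}.issubset(meta.columns):
            meta["start"] = meta["start"].astype(int) + 1
            meta["end"] = meta["end"].astype(int)
        meta.index.name = "feature_id"
        meta.to_csv(meta_path, sep="\t")


def load_gmt(path) -> GeneSetCollection:
    """Parse a standard GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise SchemaError(f"{path}:{lineno}: set {name!r} has no members")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} deduplicated"
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


def subset_align(samples: list[str], *objects):
    """Restrict matrices/tables to ``samples`` in that order.

    Accepts :class:`OmicsMatrix` (samples are columns) and DataFrames
    indexed by sample id.  Raises ``KeyError`` on an unknown sample.
    Idempotent: aligning already-aligned objects is the identity.
    """
    out = []
    for obj in objects:
        if isinstance(obj, OmicsMatrix):
            out.append(obj.subset_samples(samples))
        elif isinstance(obj, pd.DataFrame):
            unknown = set(samples) - set(obj.index)
            if unknown:
                raise KeyError(f"unknown sample ids: {sorted(unknown)[:5]}")
            out.append(obj.loc[list(samples)])
        else:
            raise TypeError(f"cannot align object of type {type(obj).__name__}")
    return tuple(out) if len(out) != 1 else out[0]
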