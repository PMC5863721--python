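"""Domain types and on-disk formats for OTU tables and sample metadata.

The canonical on-disk format is tab-separated UTF-8 text. An OTU table has a
header row whose first column is ``otu_id``; the remaining columns are PCR
replicate ids and the body holds non-negative integer read counts (OTUs in
rows, replicates in columns — transposed input is an error, never guessed at).
Sample metadata is one row per PCR replicate describing its position in the
nested field design (site / sampling event / bottle / replicate), the tide and
water-mass covariates, and its role (field sample or positive control).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "OTUTable",
    "SampleMetadata",
    "Dataset",
    "read_otu_table",
    "write_otu_table",
    "read_biom_table",
    "read_metadata",
    "write_metadata",
    "validate_dataset",
]

METADATA_COLUMNS = [
    "replicate_id",
    "bottle_id",
    "event_id",
    "site_id",
    "tide_direction",
    "tidal_height_m",
    "salinity_ppt",
    "temperature_c",
    "timestamp",
    "role",
]

TIDE_DIRECTIONS = frozenset({"incoming", "outgoing"})
ROLES = frozenset({"field", "positive_control"})


class ValidationError(ValueError):
    """A table or metadata file violates a domain invariant."""


class FormatError(ValueError):
    """A file is not in the expected on-disk layout."""


@dataclass(frozen=True)
class OTUTable:
    """Non-negative integer read counts, OTUs in rows x PCR replicates in columns.

    ``counts`` is a pandas DataFrame indexed by OTU id with replicate ids as
    columns; the constructor validates integrality, non-negativity, and id
    uniqueness.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate otu_id(s): {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate replicate id(s): {dupes}")
        arr = df.to_numpy()
        if not arr.size:
            if not all(np.issubdtype(d, np.integer) for d in df.dtypes):
                object.__setattr__(self, "counts", df.astype(np.int64))
            return
        if not np.issubdtype(arr.dtype, np.integer):
            # permit float input only if every cell is integral
            bad = ~np.isfinite(arr) | (arr != np.floor(arr))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count at otu {df.index[i]!r}, "
                    f"replicate {df.columns[j]!r}: {arr[i, j]!r}"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at otu {df.index[i]!r}, "
                f"replicate {df.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return [str(x) for x in self.counts.index]

    @property
    def replicate_ids(self) -> list[str]:
        return [str(x) for x in self.counts.columns]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-replicate read depth (column totals)."""
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def select_replicates(self, ids: Iterable[str]) -> "OTUTable":
        return OTUTable(self.counts.loc[:, list(ids)])

    def select_otus(self, ids: Iterable[str]) -> "OTUTable":
        return OTUTable(self.counts.loc[list(ids)])

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.counts.sum(axis=1) > 0
        return OTUTable(self.counts.loc[keep])

    def proportions(self) -> pd.DataFrame:
        """Column-relative proportions; zero-depth columns raise."""
        depths = self.depths()
        zero = depths[depths == 0]
        if len(zero):
            raise ValidationError(f"zero-depth replicate(s): {list(zero.index)}")
        return self.counts / depths

    def equals(self, other: "OTUTable") -> bool:
        return self.counts.equals(other.counts)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-PCR-replicate design labels and covariates.

    Backed by a DataFrame indexed by replicate_id. Temperature (and, for
    positive controls only, tide direction and the other water covariates) may
    be missing and is stored as NaN/NaT — never as zero.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in METADATA_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {missing}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate replicate_id(s): {dupes}")
        bad_role = set(df["role"]) - ROLES
        if bad_role:
            raise ValidationError(f"unknown role value(s): {sorted(bad_role)}")
        fld = df[df["role"] == "field"]
        bad_tide = set(fld["tide_direction"].dropna()) - TIDE_DIRECTIONS
        if bad_tide:
            raise ValidationError(f"unknown tide_direction(s): {sorted(bad_tide)}")
        if fld["tide_direction"].isna().any():
            raise ValidationError("field replicates must have a tide_direction")
        sal = pd.to_numeric(fld["salinity_ppt"], errors="coerce")
        if (sal.dropna() < 0).any():
            raise ValidationError("salinity must be >= 0")
        # nesting consistency: bottle -> one event, event -> one site
        for child, parent in [("bottle_id", "event_id"), ("event_id", "site_id")]:
            n_parents = df.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"inconsistent nesting: {child} {list(bad.index)} "
                    f"mapped to multiple {parent}s"
                )

    @property
    def replicate_ids(self) -> list[str]:
        return [str(x) for x in self.records.index]

    def field_replicates(self) -> list[str]:
        return list(self.records.index[self.records["role"] == "field"])

    def control_replicates(self) -> list[str]:
        return list(self.records.index[self.records["role"] == "positive_control"])

    def bottles(self) -> dict[str, list[str]]:
        """Field bottle_id -> ordered list of its replicate ids."""
        fld = self.records[self.records["role"] == "field"]
        return {
            str(b): list(grp.index)
            for b, grp in fld.groupby("bottle_id", sort=True)
        }

    def select(self, ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.records.loc[list(ids)])

    def equals(self, other: "SampleMetadata") -> bool:
        return self.records.equals(other.records)


@dataclass(frozen=True)
class Dataset:
    """A validated OTU table + metadata pair (same replicate id set)."""

    table: OTUTable
    metadata: SampleMetadata
    dropped_replicates: tuple[str, ...] = field(default=())

    def field_table(self) -> OTUTable:
        return self.table.select_replicates(self.metadata.field_replicates())

    def control_table(self) -> OTUTable:
        return self.table.select_replicates(self.metadata.control_replicates())


def read_otu_table(path: str | Path) -> OTUTable:
    """Read a canonical TSV OTU table (header row; first column ``otu_id``)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
    cols = header.rstrip("\n").split("\t")
    if not cols or cols[0] != "otu_id":
        raise FormatError(
            f"{path}: first header column must be 'otu_id', got {cols[:1]!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OTUTable(df)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_biom_table(path: str | Path) -> OTUTable:
    """Convenience reader for BIOM format 1.0 (JSON) tables.

    Only the JSON dialect is supported; rows are taken as OTUs and columns as
    replicates, matching the canonical orientation.
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        rep_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=np.int64)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from exc
    return OTUTable(pd.DataFrame(mat, index=otu_ids, columns=rep_ids))


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the canonical TSV metadata file (see module docstring)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    if df["replicate_id"].duplicated().any():
        dupes = df.loc[df["replicate_id"].duplicated(), "replicate_id"].tolist()
        raise ValidationError(f"{path}: duplicate replicate_id(s): {dupes}")
    df = df.set_index("replicate_id")
    df.index = df.index.astype(str)
    def parse_float(s):  # exact round-trip, unlike pandas' fast parser
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    for col in ("tidal_height_m", "salinity_ppt", "temperature_c"):
        df[col] = df[col].map(parse_float)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.records.copy()
    df.index.name = "replicate_id"
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(
        lambda t: t.isoformat() if pd.notna(t) else ""
    )
    out.to_csv(path, sep="\t", float_format="%.17g")


def validate_dataset(table: OTUTable, metadata: SampleMetadata) -> Dataset:
    """Pair a table with metadata, restricting to the shared replicate ids.

    Replicates present on only one side are dropped with a warning; an empty
    intersection is an error. Idempotent on its own output.
    """
    t_ids = set(table.replicate_ids)
    m_ids = set(metadata.replicate_ids)
    common = t_ids & m_ids
    if not common:
        raise ValidationError("table and metadata share no replicate ids")
    dropped = sorted((t_ids | m_ids) - common)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} replicate id(s) not shared by table "
            f"and metadata: {dropped}",
            stacklevel=2,
        )
    keep = [r for r in table.replicate_ids if r in common]
    return Dataset(
        table=table.select_replicates(keep),
        metadata=metadata.select(keep),
        dropped_replicates=tuple(dropped),
    )
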