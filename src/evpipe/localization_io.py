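"""Localization and cluster table I/O.

Coordinate convention: nanometres, origin top-left, y increasing downward
(imaging convention).  Channel 1 is CD81/AF647, channel 2 is CD9/AF488;
the two channels are acquired sequentially and are treated as independent
frame sequences throughout the pipeline.

The on-disk format is plain CSV with a header.  The default column dialect
(``frame, x, y, channel, photons``) mirrors common SMLM table exports; a
dialect mapping renames/rescales columns from other exports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class Channel(enum.IntEnum):
    """Fluorescence channel.  CH1 = CD81/AF647, CH2 = CD9/AF488."""

    CH1 = 1
    CH2 = 2


#: marker carried by each channel
CHANNEL_MARKER = {Channel.CH1: "CD81", Channel.CH2: "CD9"}

LOC_COLUMNS = ["id", "frame", "x", "y", "channel", "photons"]

CLUSTER_COLUMNS = [
    "cluster_id",
    "x",
    "y",
    "n_molecules_total",
    "n_ch1",
    "n_ch2",
    "n_localizations",
]


class FormatError(ValueError):
    """Raised when a required column is missing or a file is malformed."""


@dataclass
class Dialect:
    """Column-name mapping and unit scale for foreign localization tables.

    ``columns`` maps canonical names (frame, x, y, channel, photons) to the
    names used in the file; ``xy_scale`` multiplies coordinates into nm
    (e.g. 1000.0 for tables exported in µm).
    """

    columns: dict[str, str] = field(default_factory=dict)
    xy_scale: float = 1.0

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        """Load a dialect from a YAML (or plain ``key: value``) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scale = float(raw.pop("xy_scale", 1.0))
        return cls(columns={str(k): str(v) for k, v in raw.items()}, xy_scale=scale)


@dataclass
class AcquisitionMetadata:
    frames_per_channel: int = 1500
    exposure_ms: float = 30.0
    fov_extent_nm: float | None = None


@dataclass
class LocalizationTable:
    """Ordered table of localizations with acquisition metadata.

    ``df`` columns: id, frame, x, y, channel, photons (photons may be NaN).
    """

    df: pd.DataFrame
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)
    n_malformed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in LOC_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"localization table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if len(self.df) and self.df["id"].duplicated().any():
            raise ValueError("localization ids are not unique")
        if len(self.df):
            if not np.isfinite(self.df[["x", "y"]].to_numpy()).all():
                raise ValueError("non-finite coordinates")
            if (self.df["frame"] < 0).any():
                raise ValueError("negative frame index")
            if not self.df["channel"].isin([int(Channel.CH1), int(Channel.CH2)]).all():
                raise ValueError("channel outside {1, 2}")

    def __len__(self) -> int:
        return len(self.df)

    def channel(self, ch: Channel | int) -> pd.DataFrame:
        return self.df[self.df["channel"] == int(ch)]


def read_localizations(
    path: str | Path,
    dialect: Dialect | None = None,
    metadata: AcquisitionMetadata | None = None,
) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Rows with non-numeric coordinates or frames are dropped and counted in
    ``table.n_malformed``.  Coordinates are scaled into nm by
    ``dialect.xy_scale``.  Raises :class:`FormatError` if a mapped column is
    absent.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path)
    cols = {}
    for canonical in ("frame", "x", "y", "channel"):
        name = dialect.resolve(canonical)
        if name not in raw.columns:
            raise FormatError(f"required column {name!r} (for {canonical!r}) not in {path}")
        cols[canonical] = raw[name]
    photons_col = dialect.resolve("photons")
    cols["photons"] = raw[photons_col] if photons_col in raw.columns else np.nan

    df = pd.DataFrame(cols)
    for c in ("frame", "x", "y", "channel", "photons"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = df[["frame", "x", "y", "channel"]].notna().all(axis=1)
    n_malformed = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    df["frame"] = df["frame"].astype(np.int64)
    df["channel"] = df["channel"].astype(np.int64)
    df["x"] = df["x"].astype(float) * dialect.xy_scale
    df["y"] = df["y"].astype(float) * dialect.xy_scale
    df.insert(0, "id", np.arange(len(df), dtype=np.int64))
    return LocalizationTable(
        df=df[LOC_COLUMNS],
        metadata=metadata or AcquisitionMetadata(),
        n_malformed=n_malformed,
    )


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a localization table as canonical CSV (units: nm)."""
    table.df.to_csv(path, index=False)


def write_clusters(clusters: pd.DataFrame, path: str | Path) -> None:
    """Write a cluster table (one row per cluster) as CSV.

    Round-trips bit-exactly for integer columns and to full float repr for
    reals.  An empty table yields a header-only file.
    """
    missing = [c for c in CLUSTER_COLUMNS if c not in clusters.columns]
    if missing:
        raise FormatError(f"cluster table missing columns: {missing}")
    clusters.to_csv(path, index=False)


def read_clusters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cluster file missing columns: {missing}")
    for c in ("cluster_id", "n_molecules_total", "n_ch1", "n_ch2", "n_localizations"):
        df[c] = df[c].astype(np.int64)
    return df
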