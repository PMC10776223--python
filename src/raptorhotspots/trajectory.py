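"""Reading, validation, windowing and temporal thinning of GPS tracks.

All coordinates are kept in a projected metric CRS so that grid and distance
arithmetic downstream is plain Euclidean geometry. Geographic input
(longitude/latitude) is projected on read with a local equirectangular
approximation centred on the data, which is accurate to well under a metre
per kilometre at the landscape scales this package targets.

Timestamps are stored timezone-aware in UTC; calendar dates (for season
windows and revisit counting) are extracted in a configurable timezone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the fix table
FIX_COLUMNS = ["individual_id", "species", "timestamp", "x", "y"]

#: built-in column mapping for the Movebank CSV dialect
MOVEBANK_COLUMN_MAP = {
    "individual_id": "individual-local-identifier",
    "species": "individual-taxon-canonical-name",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}

_EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GpsFix:
    """One GPS position record for one tagged individual."""

    individual_id: str
    species: str
    timestamp: pd.Timestamp
    x: float
    y: float


@dataclass(frozen=True)
class ResampleSpec:
    """Thinning rule: keep fixes at least ``interval - tolerance`` apart.

    The tolerance admits fixes that arrive slightly early relative to the
    nominal interval (loggers rarely emit on an exact schedule).
    """

    interval: timedelta = timedelta(minutes=15)
    tolerance: timedelta = timedelta(minutes=2)

    def __post_init__(self) -> None:
        if not (timedelta(0) <= self.tolerance < self.interval):
            raise ValueError(
                f"require 0 <= tolerance < interval, got tolerance={self.tolerance}, "
                f"interval={self.interval}"
            )

    @property
    def min_gap(self) -> timedelta:
        return self.interval - self.tolerance


@dataclass(frozen=True)
class SeasonWindow:
    """An inclusive calendar-date window labelling one designation season."""

    label: str
    start_date: date
    end_date: date
    timezone_id: str = "UTC"

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"start_date {self.start_date} after end_date {self.end_date}"
            )

    def contains_dates(self, timestamps: pd.Series) -> np.ndarray:
        """Boolean mask of timestamps whose local calendar date is in window."""
        local = timestamps.dt.tz_convert(self.timezone_id)
        d = local.dt.date
        return ((d >= self.start_date) & (d <= self.end_date)).to_numpy()


@dataclass
class TrackSet:
    """Multi-individual fix table in a projected metric CRS.

    ``fixes`` has columns individual_id, species, timestamp (tz-aware UTC),
    x, y and is sorted by (individual_id, timestamp). Every individual maps
    to exactly one species.
    """

    fixes: pd.DataFrame
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        missing = [c for c in FIX_COLUMNS if c not in self.fixes.columns]
        if missing:
            raise ValueError(f"fix table missing required column(s): {missing}")
        df = self.fixes.loc[:, FIX_COLUMNS].copy()
        if len(df):
            if df["timestamp"].dt.tz is None:
                df["timestamp"] = df["timestamp"].dt.tz_localize("UTC")
            else:
                df["timestamp"] = df["timestamp"].dt.tz_convert("UTC")
            if not np.isfinite(df[["x", "y"]].to_numpy()).all():
                raise ValueError("non-finite coordinates in fix table")
            sp_per_ind = df.groupby("individual_id", sort=False)["species"].nunique()
            bad = sp_per_ind[sp_per_ind > 1]
            if len(bad):
                raise ValueError(
                    f"individual(s) mapped to more than one species: {list(bad.index)}"
                )
            df = df.sort_values(["individual_id", "timestamp"], kind="stable")
        self.fixes = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.fixes["individual_id"]))

    @property
    def species(self) -> list[str]:
        return list(pd.unique(self.fixes["species"]))

    def per_individual(self):
        """Iterate (individual_id, sub-table) in stable order."""
        return self.fixes.groupby("individual_id", sort=False)


def _project_lonlat(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection centred at (lon0, lat0), in metres."""
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y


def read_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    crs_id: str = "local-metric",
) -> TrackSet:
    """Read a fix table from CSV into a :class:`TrackSet`.

    ``column_map`` maps canonical names (individual_id, species, timestamp,
    x, y — or lon, lat for geographic input) to the file's column names.
    When omitted, the canonical names are tried first and then the Movebank
    dialect. Geographic coordinates are projected to local metres.

    Exact duplicate rows are dropped (count logged); rows sharing an
    individual and timestamp but differing in coordinates keep the first
    occurrence (logged).
    """
    raw = pd.read_csv(path)
    cmap = dict(column_map) if column_map is not None else None
    if cmap is None:
        if all(c in raw.columns for c in FIX_COLUMNS):
            cmap = {c: c for c in FIX_COLUMNS}
        elif MOVEBANK_COLUMN_MAP["lon"] in raw.columns:
            cmap = dict(MOVEBANK_COLUMN_MAP)
            if cmap["species"] not in raw.columns:
                # Movebank exports may omit the taxon column
                raise ValueError("missing required column: species")
        else:
            cmap = {c: c for c in FIX_COLUMNS}

    geographic = "lon" in cmap and "lat" in cmap
    wanted = ["individual_id", "species", "timestamp"] + (
        ["lon", "lat"] if geographic else ["x", "y"]
    )
    for name in wanted:
        src = cmap.get(name, name)
        if src not in raw.columns:
            raise ValueError(f"missing required column: {name} (looked for {src!r})")

    df = pd.DataFrame(
        {name: raw[cmap.get(name, name)] for name in wanted}
    )
    ts = pd.to_datetime(df["timestamp"], utc=True, format="mixed", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp at row {row}: {df['timestamp'].iloc[row]!r}"
        )
    df["timestamp"] = ts
    df["individual_id"] = df["individual_id"].astype(str)
    df["species"] = df["species"].astype(str)

    if geographic:
        lon = df.pop("lon").to_numpy(float)
        lat = df.pop("lat").to_numpy(float)
        lon0, lat0 = float(np.mean(lon)), float(np.mean(lat))
        df["x"], df["y"] = _project_lonlat(lon, lat, lon0, lat0)
        logger.info(
            "projected %d geographic fixes to local metres (centre %.5f, %.5f)",
            len(df), lon0, lat0,
        )

    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        logger.warning("dropped %d exact duplicate fix row(s)", n0 - len(df))
    n1 = len(df)
    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    df = df.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    if len(df) < n1:
        logger.warning(
            "dropped %d fix(es) with duplicate timestamps but differing "
            "coordinates (kept first)", n1 - len(df),
        )
    return TrackSet(fixes=df.reset_index(drop=True), crs_id=crs_id)


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    """Write a TrackSet back to the canonical CSV schema (ISO-8601 UTC)."""
    out = tracks.fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def resample_tracks(tracks: TrackSet, spec: ResampleSpec | None = None) -> TrackSet:
    """Thin each individual's track to fixes ≥ (interval − tolerance) apart.

    Greedy rule: the first fix is always kept; thereafter a fix is kept iff
    it is the first fix at least ``interval - tolerance`` after the
    previously kept fix. Equalizes sampling effort across individuals whose
    loggers recorded at different rates.
    """
    if spec is None:
        spec = ResampleSpec()
    min_gap = np.timedelta64(spec.min_gap)
    keep_parts: list[np.ndarray] = []
    for _, sub in tracks.per_individual():
        t = sub["timestamp"].to_numpy()
        keep = np.zeros(len(t), dtype=bool)
        last = None
        for i in range(len(t)):
            if last is None or t[i] - last >= min_gap:
                keep[i] = True
                last = t[i]
        keep_parts.append(sub.index.to_numpy()[keep])
    if keep_parts:
        idx = np.concatenate(keep_parts)
        out = tracks.fixes.loc[idx]
    else:
        out = tracks.fixes.iloc[0:0]
    return TrackSet(fixes=out.reset_index(drop=True), crs_id=tracks.crs_id)


def filter_window(
    tracks: TrackSet,
    window: SeasonWindow | None = None,
    bbox: Sequence[float] | None = None,
) -> TrackSet:
    """Restrict fixes to a season window and/or a bounding box.

    The date test is inclusive on both ends (local calendar dates in the
    window's timezone); the bbox test is half-open: x in [xmin, xmax),
    y in [ymin, ymax).
    """
    df = tracks.fixes
    mask = np.ones(len(df), dtype=bool)
    if window is not None and len(df):
        mask &= window.contains_dates(df["timestamp"])
    if bbox is not None and len(df):
        xmin, ymin, xmax, ymax = (float(v) for v in bbox)
        if not (xmin < xmax and ymin < ymax):
            raise ValueError(f"degenerate bbox {bbox!r}")
        x = df["x"].to_numpy()
        y = df["y"].to_numpy()
        mask &= (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    return TrackSet(fixes=df.loc[mask].reset_index(drop=True), crs_id=tracks.crs_id)
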