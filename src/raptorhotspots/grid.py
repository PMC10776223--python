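"""50 m analysis grid: construction, landcover masking and usage tallies.

Conventions used everywhere in the package: cells are indexed (row, col),
0-based, origin at the lower-left corner of the bounding box; cell (r, c)
covers the half-open square
``[origin_x + c*s, origin_x + (c+1)*s) x [origin_y + r*s, origin_y + (r+1)*s)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .trajectory import SeasonWindow, TrackSet

logger = logging.getLogger(__name__)

#: canonical landcover classes; the first two are "open" (retained), the
#: rest are subtracted before designation
LANDCOVER_CLASSES = ("farmland", "other_open", "forest", "water", "peatland")
OPEN_CLASSES = frozenset({"farmland", "other_open"})


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid in projected metres."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of points; half-open cell edges."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        row = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size)
        return row.astype(int), col.astype(int)

    def in_extent(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def centroid(self, row: int | np.ndarray, col: int | np.ndarray):
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0 = self.origin_x + col * self.cell_size
        y0 = self.origin_y + row * self.cell_size
        return (x0, y0, x0 + self.cell_size, y0 + self.cell_size)


def build_grid(bbox: Sequence[float], cell_size: float = 50.0) -> GridSpec:
    """Grid of ``cell_size`` squares covering bbox = (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = (float(v) for v in bbox)
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"bbox has zero or negative extent: {bbox!r}")
    n_cols = math.ceil((xmax - xmin) / cell_size)
    n_rows = math.ceil((ymax - ymin) / cell_size)
    return GridSpec(xmin, ymin, float(cell_size), n_rows, n_cols)


@dataclass
class LandcoverMask:
    """Per-cell eligibility flags derived from the landcover layer.

    ``eligible``: majority class of the cell is open (not forest/water/peat);
    ``farmland``: majority class is farmland (subset of eligible);
    ``perch_flag``: an isolated perch structure (tree, pylon) is in the cell —
    such cells attract raptors for perching rather than foraging and are
    excluded from designation.
    """

    eligible: np.ndarray
    farmland: np.ndarray
    perch_flag: np.ndarray

    def __post_init__(self) -> None:
        if not (self.eligible.shape == self.farmland.shape == self.perch_flag.shape):
            raise ValueError("mask layers must share one shape")
        if np.any(self.farmland & ~self.eligible):
            raise ValueError("farmland cells must be eligible")


@dataclass(frozen=True)
class CellUsage:
    """Per-cell raptor usage tallies in one period."""

    n_obs: int = 0
    n_individuals: int = 0
    n_species: int = 0
    n_days: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_species <= self.n_individuals <= self.n_obs):
            raise ValueError(
                f"require 0 <= n_species <= n_individuals <= n_obs, got {self}"
            )
        if not (0 <= self.n_days <= self.n_obs):
            raise ValueError(f"require 0 <= n_days <= n_obs, got {self}")


ZERO_USAGE = CellUsage()


@dataclass
class UsageTable:
    """Sparse per-cell usage for one period; zero-usage cells are implicit."""

    period: str
    grid: GridSpec
    usage: dict[tuple[int, int], CellUsage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (r, c) in self.usage:
            if not (0 <= r < self.grid.n_rows and 0 <= c < self.grid.n_cols):
                raise ValueError(f"cell {(r, c)} off the {self.grid.shape} grid")

    def get(self, cell: tuple[int, int]) -> CellUsage:
        return self.usage.get(cell, ZERO_USAGE)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.period, r, c, u.n_obs, u.n_individuals, u.n_species, u.n_days)
            for (r, c), u in sorted(self.usage.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["period", "row", "col", "n_obs", "n_individuals",
                     "n_species", "n_days"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: GridSpec, period: str) -> "UsageTable":
        usage = {
            (int(t.row), int(t.col)): CellUsage(
                int(t.n_obs), int(t.n_individuals), int(t.n_species), int(t.n_days)
            )
            for t in df.itertuples()
        }
        return cls(period=period, grid=grid, usage=usage)


def rasterize_landcover(
    grid: GridSpec,
    polygons: Iterable[tuple[BaseGeometry, str]],
    perch_points: Sequence[tuple[float, float]] = (),
    class_map: Mapping[str, str] | None = None,
) -> LandcoverMask:
    """Classify each grid cell by its largest-area landcover overlap.

    A cell is *eligible* iff the single class with the largest overlap area is
    open (farmland or other_open); any tie for the largest area — including a
    cell covered by no polygon at all — makes the cell ineligible
    (conservative). ``farmland`` is set iff the unique largest class is
    farmland. ``class_map`` translates input labels onto the canonical five
    classes; unknown labels raise.
    """
    cmap = dict(class_map) if class_map else {}
    geoms: list[BaseGeometry] = []
    classes: list[str] = []
    for geom, label in polygons:
        cls = cmap.get(label, label)
        if cls not in LANDCOVER_CLASSES:
            raise ValueError(
                f"unknown landcover class {label!r} (mapped to {cls!r}); "
                f"expected one of {LANDCOVER_CLASSES}"
            )
        # explode multi-part geometries for a tighter spatial index
        parts = geom.geoms if hasattr(geom, "geoms") else [geom]
        for part in parts:
            geoms.append(part)
            classes.append(cls)

    eligible = np.zeros(grid.shape, dtype=bool)
    farmland = np.zeros(grid.shape, dtype=bool)
    perch = np.zeros(grid.shape, dtype=bool)

    if geoms:
        tree = STRtree(geoms)
        class_idx = {c: i for i, c in enumerate(LANDCOVER_CLASSES)}
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                cell = box(*grid.cell_bounds(r, c))
                areas = np.zeros(len(LANDCOVER_CLASSES))
                for gi in tree.query(cell):
                    a = cell.intersection(geoms[gi]).area
                    if a > 0:
                        areas[class_idx[classes[gi]]] += a
                top = areas.max()
                if top <= 0:
                    continue  # uncovered cell: ineligible
                winners = np.flatnonzero(np.isclose(areas, top, rtol=1e-9, atol=1e-6))
                if len(winners) != 1:
                    continue  # tie: ineligible
                cls = LANDCOVER_CLASSES[winners[0]]
                if cls in OPEN_CLASSES:
                    eligible[r, c] = True
                    farmland[r, c] = cls == "farmland"

    if len(perch_points):
        px = np.array([p[0] for p in perch_points], float)
        py = np.array([p[1] for p in perch_points], float)
        rr, cc = grid.cell_of(px, py)
        ok = grid.in_extent(rr, cc)
        perch[rr[ok], cc[ok]] = True

    return LandcoverMask(eligible=eligible, farmland=farmland, perch_flag=perch)


def assign_fixes(tracks: TrackSet, grid: GridSpec) -> pd.DataFrame:
    """Fix table with (row, col) cell indices; out-of-extent fixes dropped.

    Cell assignment is floor((coord - origin)/cell_size) with half-open
    edges, so a fix exactly on a shared edge belongs to the higher cell.
    """
    df = tracks.fixes
    row, col = grid.cell_of(df["x"].to_numpy(), df["y"].to_numpy())
    inside = grid.in_extent(row, col)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("dropped %d fix(es) outside the grid extent", n_out)
    out = df.loc[inside].copy()
    out["row"] = row[inside]
    out["col"] = col[inside]
    return out.reset_index(drop=True)


def tally_usage(
    tracks: TrackSet,
    grid: GridSpec,
    window: SeasonWindow,
    resampled: bool = True,
) -> UsageTable:
    """Per-cell usage tallies over a season window.

    For every cell with at least one fix: number of fixes, distinct
    individuals, distinct species, and distinct local calendar dates
    (revisits). ``resampled`` asserts that the caller has already thinned the
    tracks to a common interval; tallying raw data would bias tallies toward
    the best-charging loggers.
    """
    if not resampled:
        logger.warning(
            "tallying un-resampled tracks; usage counts will over-weight "
            "individuals with higher fix rates"
        )
    windowed = tracks
    if len(tracks.fixes):
        keep = window.contains_dates(tracks.fixes["timestamp"])
        windowed = TrackSet(
            fixes=tracks.fixes.loc[keep].reset_index(drop=True),
            crs_id=tracks.crs_id,
        )
    df = assign_fixes(windowed, grid)
    usage: dict[tuple[int, int], CellUsage] = {}
    if len(df):
        local_date = df["timestamp"].dt.tz_convert(window.timezone_id).dt.date
        df = df.assign(_date=local_date)
        g = df.groupby(["row", "col"])
        agg = g.agg(
            n_obs=("individual_id", "size"),
            n_individuals=("individual_id", "nunique"),
            n_species=("species", "nunique"),
            n_days=("_date", "nunique"),
        )
        for (r, c), t in agg.iterrows():
            usage[(int(r), int(c))] = CellUsage(
                int(t.n_obs), int(t.n_individuals), int(t.n_species), int(t.n_days)
            )
    return UsageTable(period=window.label, grid=grid, usage=usage)
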