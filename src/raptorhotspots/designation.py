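"""Designation of raptor activity hotspots and matched control sites.

The procedure operates on a season's per-cell usage table over the 50 m
analysis grid:

1. *Qualification* — a cell is a hotspot candidate when it was used by at
   least three different individuals of at least two different species in the
   season, lies on open (non-forest/water/peat) land, and carries no isolated
   perch structure.
2. *Adjacency resolution* — touching candidate cells are collapsed to the one
   with the most species, then most individuals, then most observations.
3. *Spacing* — surviving cells are accepted greedily in that same rank order;
   a cell closer than 450 m to an already accepted hotspot is discarded.
4. *Control selection* — for each hotspot, the 500 m circle around its
   centroid is scanned clockwise from north; the first intersected cell that
   is farmland, held at most one raptor observation in the season, and lies
   at least 500 m from every other already designated site becomes the
   paired control.

Every step is deterministic: all ties end in lexicographic (row, col) order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import CellUsage, GridSpec, LandcoverMask, UsageTable

logger = logging.getLogger(__name__)

Cell = tuple[int, int]


@dataclass(frozen=True)
class HotspotCriteria:
    """Thresholds of the designation procedure (defaults follow the study design)."""

    min_individuals: int = 3
    min_species: int = 2
    min_hotspot_spacing: float = 450.0
    control_radius: float = 500.0
    min_control_spacing: float = 500.0
    max_control_obs: int = 1
    connectivity: int = 8

    def __post_init__(self) -> None:
        if min(self.min_individuals, self.min_species) < 1:
            raise ValueError("count thresholds must be positive")
        if self.min_species > self.min_individuals:
            raise ValueError("min_species cannot exceed min_individuals")
        if min(self.min_hotspot_spacing, self.control_radius,
               self.min_control_spacing) <= 0:
            raise ValueError("distances must be positive")
        if self.max_control_obs < 0:
            raise ValueError("max_control_obs must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Site:
    """A designated 50 m cell (hotspot or its control)."""

    cell: Cell
    centroid: tuple[float, float]
    kind: str  # "hotspot" | "control"
    season: str
    usage_at_designation: CellUsage


@dataclass(frozen=True)
class SitePair:
    """A hotspot and its control on the 500 m ring."""

    hotspot: Site
    control: Site
    azimuth_deg: float


@dataclass
class DesignationResult:
    pairs: list[SitePair] = field(default_factory=list)
    rejected_hotspots: list[tuple[Cell, str]] = field(default_factory=list)
    unpaired_hotspots: list[tuple[Cell, str]] = field(default_factory=list)


def _rank_key(usage: UsageTable, cell: Cell):
    u = usage.get(cell)
    return (-u.n_species, -u.n_individuals, -u.n_obs, cell[0], cell[1])


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def qualify_cells(
    usage: UsageTable, mask: LandcoverMask, crit: HotspotCriteria
) -> tuple[set[Cell], list[tuple[Cell, str]]]:
    """Hotspot candidate cells plus (cell, reason) rejections.

    A cell qualifies when eligible open land, no perch flag, and used by at
    least ``min_individuals`` individuals of at least ``min_species`` species.
    Cells meeting the usage rule but failing a mask test are reported with
    reasons ("perch", "ineligible landcover").
    """
    if mask.eligible.shape != usage.grid.shape:
        raise ValueError("usage table and landcover mask use different grids")
    candidates: set[Cell] = set()
    rejected: list[tuple[Cell, str]] = []
    for cell, u in usage.usage.items():
        if u.n_individuals < crit.min_individuals or u.n_species < crit.min_species:
            continue
        if not mask.eligible[cell]:
            rejected.append((cell, "ineligible landcover"))
        elif mask.perch_flag[cell]:
            rejected.append((cell, "perch"))
        else:
            candidates.add(cell)
    return candidates, sorted(rejected)


def resolve_adjacent(
    candidates: set[Cell], usage: UsageTable, crit: HotspotCriteria
) -> list[Cell]:
    """One representative per connected component of candidate cells.

    Components use 4- or 8-connectivity per ``crit``. The representative is
    the component cell with the most species, breaking ties by individuals,
    then observations, then the lexicographically smallest (row, col).
    Returned sorted by that same descending rank (the designation order).
    """
    if not candidates:
        return []
    arr = np.zeros(usage.grid.shape, dtype=bool)
    for cell in candidates:
        arr[cell] = True
    structure = (
        np.ones((3, 3), dtype=bool)
        if crit.connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n = ndimage.label(arr, structure=structure)
    reps: list[Cell] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        members = [(int(r), int(c)) for r, c in zip(rows, cols)]
        reps.append(min(members, key=lambda cell: _rank_key(usage, cell)))
    reps.sort(key=lambda cell: _rank_key(usage, cell))
    return reps


def enforce_spacing(
    reps: list[Cell], usage: UsageTable, crit: HotspotCriteria
) -> tuple[list[Site], list[tuple[Cell, str]]]:
    """Greedy minimum-spacing filter over ranked representatives.

    Representatives are accepted in rank order; one strictly closer than
    ``min_hotspot_spacing`` (centroid to centroid) to an already accepted
    hotspot is discarded ("closer than" is a strict inequality, so two cells
    exactly 450 m apart may both stand).
    """
    grid = usage.grid
    accepted: list[Site] = []
    discarded: list[tuple[Cell, str]] = []
    for cell in sorted(reps, key=lambda cl: _rank_key(usage, cl)):
        x, y = grid.centroid(*cell)
        centroid = (float(x), float(y))
        too_close = any(
            _dist(centroid, s.centroid) < crit.min_hotspot_spacing for s in accepted
        )
        if too_close:
            discarded.append((cell, "within hotspot spacing"))
        else:
            accepted.append(
                Site(cell=cell, centroid=centroid, kind="hotspot",
                     season=usage.period, usage_at_designation=usage.get(cell))
            )
    return accepted, discarded


def ring_cells(
    centroid: tuple[float, float], grid: GridSpec, radius: float
) -> list[tuple[Cell, float]]:
    """Grid cells intersected by the circle of ``radius`` around ``centroid``.

    Returned as (cell, azimuth_deg) ordered by the azimuth of the cell centre,
    clockwise from north starting at 0°; azimuth ties are broken by nearer
    centroid first, then lexicographic index. Cells off the grid are simply
    absent (the ring is truncated at the grid edge).
    """
    if radius <= grid.cell_size:
        raise ValueError("radius must exceed the cell size")
    cx, cy = centroid
    s = grid.cell_size
    # candidate index window covering the circle
    row_min = max(0, math.floor((cy - radius - grid.origin_y) / s) - 1)
    row_max = min(grid.n_rows - 1, math.ceil((cy + radius - grid.origin_y) / s) + 1)
    col_min = max(0, math.floor((cx - radius - grid.origin_x) / s) - 1)
    col_max = min(grid.n_cols - 1, math.ceil((cx + radius - grid.origin_x) / s) + 1)
    out: list[tuple[float, float, int, int, float]] = []
    for r in range(row_min, row_max + 1):
        by0 = grid.origin_y + r * s
        for c in range(col_min, col_max + 1):
            bx0 = grid.origin_x + c * s
            bx1, by1 = bx0 + s, by0 + s
            # circle intersects square iff min dist to square <= radius <= max dist
            dx = max(bx0 - cx, 0.0, cx - bx1)
            dy = max(by0 - cy, 0.0, cy - by1)
            dmin = math.hypot(dx, dy)
            fx = max(cx - bx0, bx1 - cx)
            fy = max(cy - by0, by1 - cy)
            dmax = math.hypot(fx, fy)
            if dmin <= radius <= dmax:
                mx, my = bx0 + s / 2, by0 + s / 2
                az = math.degrees(math.atan2(mx - cx, my - cy)) % 360.0
                dcent = math.hypot(mx - cx, my - cy)
                out.append((az, dcent, r, c, az))
    out.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return [((r, c), az) for _, _, r, c, az in out]


def select_control(
    hotspot: Site,
    usage: UsageTable,
    mask: LandcoverMask,
    taken: list[Site],
    crit: HotspotCriteria,
) -> tuple[Site, float] | None:
    """First acceptable control cell on the hotspot's 500 m ring, or None.

    Scanning clockwise from due north, a ring cell is accepted iff it is
    farmland without a perch flag, held at most ``max_control_obs``
    observations of tracked raptors in the season, and its centroid lies at
    least ``min_control_spacing`` from every already designated site other
    than the paired hotspot itself (which sits at exactly the ring radius by
    construction). Returns (control site, azimuth) or None when the ring is
    exhausted.
    """
    grid = usage.grid
    for cell, az in ring_cells(hotspot.centroid, grid, crit.control_radius):
        if not mask.farmland[cell] or mask.perch_flag[cell]:
            continue
        if usage.get(cell).n_obs > crit.max_control_obs:
            continue
        x, y = grid.centroid(*cell)
        centroid = (float(x), float(y))
        conflict = any(
            s.cell != hotspot.cell
            and _dist(centroid, s.centroid) < crit.min_control_spacing
            for s in taken
        )
        if conflict:
            continue
        site = Site(cell=cell, centroid=centroid, kind="control",
                    season=usage.period, usage_at_designation=usage.get(cell))
        return site, az
    return None


def designate_sites(
    usage: UsageTable,
    mask: LandcoverMask,
    crit: HotspotCriteria | None = None,
) -> DesignationResult:
    """Run the full designation procedure for one season.

    qualify → resolve adjacency → enforce spacing → pair each hotspot with a
    control, scanning rings in hotspot rank order while the set of taken
    sites grows. Deterministic for fixed inputs. Hotspots whose ring offers
    no acceptable control are reported in ``unpaired_hotspots`` and dropped
    from pairing.
    """
    if crit is None:
        crit = HotspotCriteria()
    result = DesignationResult()
    candidates, rejected = qualify_cells(usage, mask, crit)
    result.rejected_hotspots.extend(rejected)
    if not candidates:
        logger.info("season %s: no cells qualify as hotspots", usage.period)
        return result
    reps = resolve_adjacent(candidates, usage, crit)
    losers = sorted(candidates - set(reps))
    result.rejected_hotspots.extend((cell, "adjacent to stronger cell") for cell in losers)
    hotspots, discarded = enforce_spacing(reps, usage, crit)
    result.rejected_hotspots.extend(discarded)

    taken: list[Site] = list(hotspots)
    for hs in hotspots:
        found = select_control(hs, usage, mask, taken, crit)
        if found is None:
            result.unpaired_hotspots.append((hs.cell, "control ring exhausted"))
            continue
        control, az = found
        taken.append(control)
        result.pairs.append(SitePair(hotspot=hs, control=control, azimuth_deg=az))
    logger.info(
        "season %s: %d pair(s), %d rejection(s), %d unpaired hotspot(s)",
        usage.period, len(result.pairs), len(result.rejected_hotspots),
        len(result.unpaired_hotspots),
    )
    return result
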