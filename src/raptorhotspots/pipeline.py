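"""End-to-end orchestration: simulate, designate, survey statistics, reports.

Everything is driven by one YAML config (see :class:`RunConfig`); each run
writes the resolved configuration next to its outputs so any result can be
regenerated byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from shapely.geometry import Point

from . import geojson_io
from .designation import (
    DesignationResult,
    HotspotCriteria,
    SitePair,
    designate_sites,
)
from .grid import build_grid, rasterize_landcover, tally_usage, UsageTable
from .persistence import persistence_analysis
from .simulate import (
    Landscape,
    LandscapeConfig,
    MovementConfig,
    SurveyEffectConfig,
    generate_landscape,
    generate_surveys,
    generate_tracks,
    ground_truth,
)
from .surveys import SurveyPlot, aggregate_surveys, run_table1, table1_frame
from .trajectory import (
    ResampleSpec,
    SeasonWindow,
    filter_window,
    read_tracks,
    resample_tracks,
    write_tracks,
)

logger = logging.getLogger(__name__)

SURVEY_SCHEMAS = {
    "birds": ["plot_id", "site_class", "year", "visit", "species", "count"],
    "small_mammals": ["plot_id", "site_class", "year", "station", "species", "count"],
    "amphibians": ["plot_id", "site_class", "year", "transect", "species", "count"],
    "plants": ["plot_id", "site_class", "year", "quadrat", "species"],
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    tracks: str = "tracks.csv"
    landcover: str = "landcover.geojson"
    perches: str | None = None
    surveys_dir: str | None = None
    out_dir: str = "out"
    cell_size: float = 50.0
    bbox: tuple[float, float, float, float] | None = None
    season: dict = field(default_factory=lambda: {
        "label": "spring2020",
        "start_date": "2020-04-01",
        "end_date": "2020-05-31",
        "timezone_id": "UTC",
    })
    resample_interval_min: float = 15.0
    resample_tolerance_min: float = 2.0
    criteria: dict = field(default_factory=dict)
    standardize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def season_window(self) -> SeasonWindow:
        s = self.season
        return SeasonWindow(
            label=s["label"],
            start_date=date.fromisoformat(str(s["start_date"])),
            end_date=date.fromisoformat(str(s["end_date"])),
            timezone_id=s.get("timezone_id", "UTC"),
        )

    def hotspot_criteria(self) -> HotspotCriteria:
        return HotspotCriteria(**self.criteria)

    def resample_spec(self) -> ResampleSpec:
        return ResampleSpec(
            interval=timedelta(minutes=self.resample_interval_min),
            tolerance=timedelta(minutes=self.resample_tolerance_min),
        )


def pairs_frame(pairs: Sequence[SitePair]) -> pd.DataFrame:
    """Site pairs as a flat table (one row per site)."""
    rows = []
    for i, pair in enumerate(pairs):
        for site in (pair.hotspot, pair.control):
            u = site.usage_at_designation
            rows.append(
                {
                    "pair_id": i,
                    "kind": site.kind,
                    "row": site.cell[0],
                    "col": site.cell[1],
                    "x": site.centroid[0],
                    "y": site.centroid[1],
                    "season": site.season,
                    "azimuth_deg": pair.azimuth_deg,
                    "n_obs": u.n_obs,
                    "n_individuals": u.n_individuals,
                    "n_species": u.n_species,
                    "n_days": u.n_days,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "kind", "row", "col", "x", "y", "season",
                 "azimuth_deg", "n_obs", "n_individuals", "n_species", "n_days"],
    )


def write_pairs_geojson(pairs: Sequence[SitePair], path: str | Path) -> None:
    feats = []
    for i, pair in enumerate(pairs):
        for site in (pair.hotspot, pair.control):
            u = site.usage_at_designation
            feats.append(
                (
                    Point(*site.centroid),
                    {
                        "pair_id": i,
                        "kind": site.kind,
                        "season": site.season,
                        "row": site.cell[0],
                        "col": site.cell[1],
                        "n_obs": u.n_obs,
                        "n_individuals": u.n_individuals,
                        "n_species": u.n_species,
                        "n_days": u.n_days,
                    },
                )
            )
    geojson_io.write_features(feats, path)


def run_designation(config: RunConfig) -> DesignationResult:
    """read → resample → window → grid → tally → designate, with artifacts.

    Writes resampled tracks, the usage table, site pairs (CSV + GeoJSON),
    the rejection/unpaired logs and the resolved config into ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "tracks"
    try:
        tracks = read_tracks(config.tracks)
        logger.info("read %d fixes, %d individuals", len(tracks), len(tracks.individuals))
        stage = "resample"
        tracks = resample_tracks(tracks, config.resample_spec())
        logger.info("resampled to %d fixes", len(tracks))
        stage = "window"
        window = config.season_window()
        tracks = filter_window(tracks, window=window, bbox=config.bbox)
        logger.info("windowed to %d fixes in %s", len(tracks), window.label)
        stage = "landcover"
        polygons = geojson_io.read_landcover(config.landcover)
        if config.bbox is not None:
            bbox = config.bbox
        else:
            xs = [g.bounds for g, _ in polygons]
            bbox = (
                min(b[0] for b in xs), min(b[1] for b in xs),
                max(b[2] for b in xs), max(b[3] for b in xs),
            )
        grid = build_grid(bbox, config.cell_size)
        perches = geojson_io.read_points(config.perches) if config.perches else ()
        mask = rasterize_landcover(grid, polygons, perch_points=perches)
        stage = "tally"
        usage = tally_usage(tracks, grid, window)
        stage = "designate"
        result = designate_sites(usage, mask, config.hotspot_criteria())
    except FileNotFoundError as err:
        raise RuntimeError(f"stage {stage!r} failed: missing input {err.filename}") from err
    except ValueError as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    write_tracks(tracks, out / "tracks_resampled.csv")
    usage.to_frame().to_csv(out / "usage.csv", index=False)
    pairs_frame(result.pairs).to_csv(out / "sites.csv", index=False)
    write_pairs_geojson(result.pairs, out / "sites.geojson")
    pd.DataFrame(
        [(r, c, reason) for (r, c), reason in result.rejected_hotspots],
        columns=["row", "col", "reason"],
    ).to_csv(out / "rejected.csv", index=False)
    pd.DataFrame(
        [(r, c, reason) for (r, c), reason in result.unpaired_hotspots],
        columns=["row", "col", "reason"],
    ).to_csv(out / "unpaired.csv", index=False)
    config.to_yaml(out / "config_resolved.yaml")
    return result


def read_survey_csv(path: str | Path, taxon_group: str) -> list[SurveyPlot]:
    """Read one taxon group's survey table into per-plot records."""
    schema = SURVEY_SCHEMAS[taxon_group]
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    plots = []
    rec_cols = [c for c in schema if c not in ("plot_id", "site_class", "year")]
    for (pid, cls, yr), sub in df.groupby(["plot_id", "site_class", "year"]):
        plots.append(
            SurveyPlot(
                plot_id=str(pid),
                site_class=int(cls),
                taxon_group=taxon_group,
                year=int(yr),
                records=sub[rec_cols].reset_index(drop=True),
            )
        )
    return plots


def write_survey_csv(plots: Sequence[SurveyPlot], path: str | Path) -> None:
    """Write survey plots of one taxon group to its CSV schema."""
    groups = {p.taxon_group for p in plots}
    if len(groups) != 1:
        raise ValueError(f"expected one taxon group per file, got {sorted(groups)}")
    group = groups.pop()
    frames = []
    for p in plots:
        rec = p.records.copy()
        rec.insert(0, "plot_id", p.plot_id)
        rec.insert(1, "site_class", p.site_class)
        rec.insert(2, "year", p.year)
        frames.append(rec)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_surveys(surveys_dir: str | Path) -> list[SurveyPlot]:
    """Read all present taxon-group CSVs (birds.csv, small_mammals.csv, ...)."""
    plots: list[SurveyPlot] = []
    for group in SURVEY_SCHEMAS:
        path = Path(surveys_dir) / f"{group}.csv"
        if path.exists():
            plots.extend(read_survey_csv(path, group))
        else:
            logger.info("no %s survey file; skipped", group)
    return plots


def run_full_study(
    config: RunConfig,
    usage_by_year: Mapping[int, UsageTable] | None = None,
    pairs_by_year: Mapping[int, Sequence[SitePair]] | None = None,
) -> dict:
    """Designation plus survey GLMs (and persistence when multi-year usage given).

    Writes ``table1.csv`` (one logistic model per survey predictor),
    ``table2.csv`` (Wilcoxon persistence tests, when usage tables for later
    years are supplied) and a plain-text summary into ``out_dir``.
    """
    out = Path(config.out_dir)
    result = run_designation(config)
    report: dict = {"designation": result}
    lines = [f"designated pairs: {len(result.pairs)}",
             f"rejected cells: {len(result.rejected_hotspots)}",
             f"unpaired hotspots: {len(result.unpaired_hotspots)}"]

    if config.surveys_dir:
        plots = load_surveys(config.surveys_dir)
        if plots:
            table = aggregate_surveys(plots)
            glms = run_table1(table, standardize=config.standardize)
            t1 = table1_frame(glms)
            t1.to_csv(out / "table1.csv", index=False)
            report["table1"] = t1
            lines.append(f"glm rows: {len(t1)}")
    if usage_by_year and pairs_by_year:
        t2 = persistence_analysis(pairs_by_year, usage_by_year)
        t2.to_csv(out / "table2.csv", index=False)
        report["table2"] = t2
        lines.append(f"persistence rows: {len(t2)}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    landscape_cfg: LandscapeConfig | None = None,
    movement_cfg: MovementConfig | None = None,
    survey_cfg: SurveyEffectConfig | None = None,
    criteria: HotspotCriteria | None = None,
) -> dict:
    """Generate a full synthetic study on disk: tracks, landcover, surveys, truth.

    Sites for the surveys are obtained by actually running designation on the
    simulated season, so the written survey tables refer to real designated
    plots. Returns the in-memory objects for further use.
    """
    import numpy as np

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "surveys").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    landscape = generate_landscape(landscape_cfg, seed=rng)
    mcfg = movement_cfg or MovementConfig()
    tracks = generate_tracks(landscape, mcfg, seed=rng)
    write_tracks(tracks, out / "tracks.csv")
    geojson_io.write_features(
        [(g, {"class": c}) for g, c in landscape.landcover_polygons()],
        out / "landcover.geojson",
    )
    geojson_io.write_features([], out / "perches.geojson")
    ground_truth(landscape).to_csv(out / "truth.csv", index=False)

    window = SeasonWindow(
        label="sim_season",
        start_date=mcfg.season_start,
        end_date=mcfg.season_start + timedelta(days=mcfg.season_days),
    )
    grid = build_grid(landscape.bbox, 50.0)
    mask = landscape.mask_for(grid)
    resampled = resample_tracks(tracks)
    usage = tally_usage(resampled, grid, window)
    result = designate_sites(usage, mask, criteria or HotspotCriteria())
    sites = [s for p in result.pairs for s in (p.hotspot, p.control)]
    plots = generate_surveys(
        landscape, sites, survey_cfg, seed=rng, year=mcfg.season_start.year
    )
    for group in SURVEY_SCHEMAS:
        sub = [p for p in plots if p.taxon_group == group]
        if sub:
            write_survey_csv(sub, out / "surveys" / f"{group}.csv")
    return {
        "landscape": landscape,
        "tracks": tracks,
        "usage": usage,
        "designation": result,
        "plots": plots,
    }
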