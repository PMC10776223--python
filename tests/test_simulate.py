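"""Synthetic landscape, movement and survey generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from raptorhotspots import (
    LandscapeConfig,
    MovementConfig,
    PreyPatch,
    Site,
    SurveyEffectConfig,
    aggregate_surveys,
    build_grid,
    generate_landscape,
    generate_surveys,
    generate_tracks,
    ground_truth,
    mean_pairwise_jaccard,
    rasterize_landcover,
)
from raptorhotspots.grid import CellUsage


SMALL = LandscapeConfig(bbox=(0, 0, 2000, 2000), n_patches=2,
                        min_patch_separation=600.0)


class TestGenerateLandscape:
    def test_seed_determinism(self):
        a = generate_landscape(SMALL, seed=1)
        b = generate_landscape(SMALL, seed=1)
        assert np.array_equal(a.parcel_class, b.parcel_class)
        assert a.patches == b.patches

    def test_seed_changes_output(self):
        a = generate_landscape(SMALL, seed=1)
        b = generate_landscape(SMALL, seed=2)
        assert not np.array_equal(a.parcel_class, b.parcel_class)

    def test_farmland_fraction_near_target(self):
        ls = generate_landscape(seed=3)
        assert 0.41 <= ls.realized_fractions["farmland"] <= 0.51

    def test_null_world_has_no_patches(self):
        cfg = LandscapeConfig(n_patches=0)
        assert generate_landscape(cfg, seed=1).patches == []

    def test_patch_separation_and_farmland_placement(self):
        ls = generate_landscape(seed=4)
        pts = [p.centre for p in ls.patches]
        for i, a in enumerate(pts):
            for b in pts[i + 1:]:
                assert np.hypot(a[0] - b[0], a[1] - b[1]) >= 1000.0
        codes = ls.class_at(
            np.array([p[0] for p in pts]), np.array([p[1] for p in pts])
        )
        assert all(c == 0 for c in codes)  # farmland code

    def test_mask_fast_path_equals_polygon_rasterization(self):
        ls = generate_landscape(SMALL, seed=5)
        grid = build_grid(ls.bbox, 50.0)
        fast = ls.mask_for(grid)
        slow = rasterize_landcover(grid, ls.landcover_polygons())
        assert np.array_equal(fast.eligible, slow.eligible)
        assert np.array_equal(fast.farmland, slow.farmland)


class TestGroundTruth:
    def test_one_row_per_patch_and_csv_round_trip(self, tmp_path):
        ls = generate_landscape(SMALL, seed=1)
        gt = ground_truth(ls)
        assert len(gt) == len(ls.patches)
        p = tmp_path / "truth.csv"
        gt.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, gt)

    def test_empty_for_null_world(self):
        ls = generate_landscape(LandscapeConfig(n_patches=0), seed=1)
        assert len(ground_truth(ls)) == 0


class TestGenerateTracks:
    def test_seed_determinism(self):
        ls = generate_landscape(SMALL, seed=1)
        cfg = MovementConfig(season_days=2)
        a = generate_tracks(ls, cfg, seed=7)
        b = generate_tracks(ls, cfg, seed=7)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="attraction"):
            MovementConfig(attraction_exponent=-1.0)

    def test_one_species_per_individual_and_intervals(self):
        ls = generate_landscape(SMALL, seed=1)
        tracks = generate_tracks(ls, MovementConfig(season_days=1), seed=0)
        sp = tracks.fixes.groupby("individual_id")["species"].nunique()
        assert (sp == 1).all()
        assert len(tracks.individuals) == MovementConfig().n_individuals

    def test_fix_count_tracks_interval_arithmetic(self):
        """High-rate species log roughly active-time/interval fixes per day."""
        ls = generate_landscape(SMALL, seed=1)
        cfg = MovementConfig(
            species={"eagle": {"n": 1, "interval_min": (10.0, 10.0)}},
            season_days=1,
        )
        tracks = generate_tracks(ls, cfg, seed=3)
        active_min = (cfg.day_end_h - cfg.day_start_h) * 60
        expected = active_min / 10.0
        assert abs(len(tracks) - expected) <= 0.15 * expected + 2

    def test_alpha_zero_visits_patches_in_proportion_to_area(self):
        """Without attraction, destinations hit patches at their area share."""
        cfg = LandscapeConfig(n_patches=3, min_patch_separation=900.0,
                              bbox=(0, 0, 4000, 4000))
        rng = np.random.default_rng(21)
        fracs, shares = [], []
        for rep in range(15):
            ls = generate_landscape(cfg, seed=rng)
            _, trips = generate_tracks(
                ls, MovementConfig(attraction_exponent=0.0, season_days=3),
                seed=rng, return_details=True,
            )
            fracs.append(trips["in_patch"].mean())
            # area share of patches among farmland destination cells
            grid = build_grid(ls.bbox, 50.0)
            mask = ls.mask_for(grid)
            cols, rows = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
            cx, cy = grid.centroid(rows, cols)
            in_patch = np.zeros(grid.shape, bool)
            for p in ls.patches:
                in_patch |= (cx - p.centre[0]) ** 2 + (cy - p.centre[1]) ** 2 <= p.radius ** 2
            shares.append((in_patch & mask.farmland).sum() / mask.farmland.sum())
        diff = np.array(fracs) - np.array(shares)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se + 1e-3

    def test_high_alpha_concentrates_in_patches(self):
        ls = generate_landscape(seed=2)
        _, trips = generate_tracks(
            ls, MovementConfig(attraction_exponent=4.0), seed=2,
            return_details=True,
        )
        assert trips["in_patch"].mean() > 0.5


def _sites(ls, n_in, n_out, grid):
    """Synthetic designated sites: n_in hotspot plots inside patches,
    n_out controls on farmland outside any patch."""
    mask = ls.mask_for(grid)
    cols, rows = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
    cx, cy = grid.centroid(rows, cols)
    in_patch = np.zeros(grid.shape, bool)
    for p in ls.patches:
        in_patch |= (cx - p.centre[0]) ** 2 + (cy - p.centre[1]) ** 2 <= p.radius ** 2
    sites = []
    for kind, want, sel in (("hotspot", n_in, in_patch & mask.farmland),
                            ("control", n_out, ~in_patch & mask.farmland)):
        if want == 0:
            continue
        rr, cc = np.nonzero(sel)
        step = max(1, len(rr) // want)
        for k in range(want):
            r, c = int(rr[(k * step) % len(rr)]), int(cc[(k * step) % len(rr)])
            x, y = grid.centroid(r, c)
            sites.append(Site(cell=(r, c), centroid=(float(x), float(y)),
                              kind=kind, season="s",
                              usage_at_designation=CellUsage()))
    return sites


class TestGenerateSurveys:
    def test_seed_determinism(self):
        ls = generate_landscape(seed=1)
        grid = build_grid(ls.bbox, 50.0)
        sites = _sites(ls, 3, 3, grid)
        a = generate_surveys(ls, sites, seed=11)
        b = generate_surveys(ls, sites, seed=11)
        assert len(a) == len(b) == len(sites) * 4
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa.records, pb.records)

    def test_delta_one_is_null(self):
        """Without an effect, in-patch and out-of-patch means agree closely."""
        ls = generate_landscape(seed=1)
        grid = build_grid(ls.bbox, 50.0)
        sites = _sites(ls, 40, 40, grid)
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(20):
            plots = generate_surveys(
                ls, sites, SurveyEffectConfig(effect_multiplier=1.0), seed=rng
            )
            tab = aggregate_surveys(plots)
            sub = tab[tab["predictor"] == "mammal_abundance"]
            diffs.append(sub[sub["site_class"] == 1]["value"].mean()
                         - sub[sub["site_class"] == 0]["value"].mean())
        diffs = np.array(diffs)
        assert abs(diffs.mean()) <= 3 * diffs.std(ddof=1) / np.sqrt(len(diffs)) + 0.05

    def test_delta_raises_fauna_means_in_patches(self):
        ls = generate_landscape(seed=1)
        grid = build_grid(ls.bbox, 50.0)
        sites = _sites(ls, 40, 40, grid)
        plots = generate_surveys(
            ls, sites, SurveyEffectConfig(effect_multiplier=3.0), seed=5
        )
        tab = aggregate_surveys(plots)
        for pred in ("bird_abundance", "mammal_abundance", "amphibian_abundance"):
            sub = tab[tab["predictor"] == pred]
            assert (sub[sub["site_class"] == 1]["value"].mean()
                    > sub[sub["site_class"] == 0]["value"].mean())

    def test_turnover_parameter_lowers_similarity_monotonically(self):
        ls = generate_landscape(LandscapeConfig(n_patches=0), seed=1)
        grid = build_grid(ls.bbox, 50.0)
        sites = _sites(ls, 0, 60, grid)
        means = []
        rng = np.random.default_rng(8)
        for turnover in (0.2, 0.45, 0.7):
            cfg = SurveyEffectConfig(effect_multiplier=1.0, plant_turnover=turnover)
            plots = generate_surveys(ls, sites, cfg, seed=rng)
            tab = aggregate_surveys(plots)
            means.append(tab[tab["predictor"] == "plant_similarity"]["value"].mean())
        assert means[0] > means[1] > means[2]

    def test_delta_below_one_rejected(self):
        with pytest.raises(ValueError):
            SurveyEffectConfig(effect_multiplier=0.5)
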