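"""Shared fixtures: randomized small worlds and tiny deterministic inputs."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from raptorhotspots import (
    CellUsage,
    GridSpec,
    LandcoverMask,
    SeasonWindow,
    TrackSet,
    UsageTable,
)


@pytest.fixture
def season() -> SeasonWindow:
    return SeasonWindow("spring2020", date(2020, 4, 1), date(2020, 5, 31))


def make_tracks(rows) -> TrackSet:
    """TrackSet from (individual, species, iso-timestamp, x, y) tuples."""
    df = pd.DataFrame(
        rows, columns=["individual_id", "species", "timestamp", "x", "y"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return TrackSet(fixes=df)


def random_world(rng: np.random.Generator, max_side: int = 24):
    """A randomized small usage table + landcover mask for oracle checks.

    Grids up to ``max_side`` cells a side (50 m cells), at most 8 individuals
    of at most 3 species, sparse usage, random eligibility/farmland/perch
    layers.
    """
    n_rows = int(rng.integers(10, max_side + 1))
    n_cols = int(rng.integers(10, max_side + 1))
    grid = GridSpec(0.0, 0.0, 50.0, n_rows, n_cols)
    individuals = [f"i{k}" for k in range(8)]
    species_of = {ind: f"s{k % 3}" for k, ind in enumerate(individuals)}

    usage: dict[tuple[int, int], CellUsage] = {}
    n_used = int(rng.integers(5, max(6, n_rows * n_cols // 6)))
    cells = rng.choice(n_rows * n_cols, size=n_used, replace=False)
    for flat in cells:
        cell = (int(flat) // n_cols, int(flat) % n_cols)
        n_ind = int(rng.integers(1, 9))
        chosen = rng.choice(individuals, size=n_ind, replace=False)
        n_sp = len({species_of[i] for i in chosen})
        n_obs = n_ind + int(rng.integers(0, 10))
        n_days = int(rng.integers(1, n_obs + 1))
        usage[cell] = CellUsage(n_obs, n_ind, n_sp, n_days)
    table = UsageTable(period="rnd", grid=grid, usage=usage)

    eligible = rng.random((n_rows, n_cols)) < 0.85
    farmland = eligible & (rng.random((n_rows, n_cols)) < 0.85)
    perch = rng.random((n_rows, n_cols)) < 0.05
    mask = LandcoverMask(eligible=eligible, farmland=farmland, perch_flag=perch)
    return table, mask
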