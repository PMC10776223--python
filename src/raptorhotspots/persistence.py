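"""Hotspot persistence: do designated cells keep attracting raptors?

Sites designated from one season's movement data are re-measured on the same
50 m cells in later years (observations, individuals, species, revisits) and
hotspots are compared with controls by a two-sided Wilcoxon rank-sum test,
one and two years after designation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .designation import Site, SitePair
from .grid import UsageTable

logger = logging.getLogger(__name__)

#: usage metrics compared between hotspots and controls
USAGE_METRICS = ("n_obs", "n_individuals", "n_species", "n_revisits")


@dataclass(frozen=True)
class SiteUsageMetrics:
    """Usage of one designated site in one comparison year."""

    site: Site
    year: int
    n_obs: int
    n_individuals: int
    n_species: int
    n_revisits: int


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum comparison of one usage metric."""

    variable: str
    statistic_w: float
    p_value: float
    n_hotspot: int
    n_control: int


def usage_at_sites(
    pairs: Sequence[SitePair], usage: UsageTable, year: int | None = None
) -> pd.DataFrame:
    """Usage metrics of every designated site under a later usage table.

    Returns one row per site (kind, row, col, n_obs, n_individuals,
    n_species, n_revisits); sites unused in the comparison period get zeros.
    ``year`` is carried through for bookkeeping (defaults to the usage
    table's period label).
    """
    rows = []
    for pair in pairs:
        for site in (pair.hotspot, pair.control):
            u = usage.get(site.cell)
            rows.append(
                {
                    "kind": site.kind,
                    "row": site.cell[0],
                    "col": site.cell[1],
                    "season": site.season,
                    "period": year if year is not None else usage.period,
                    "n_obs": u.n_obs,
                    "n_individuals": u.n_individuals,
                    "n_species": u.n_species,
                    "n_revisits": u.n_days,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["kind", "row", "col", "season", "period",
                 "n_obs", "n_individuals", "n_species", "n_revisits"],
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 10
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test; W is the rank sum of ``x``.

    Uses the exact null distribution when min(len(x), len(y)) is at most
    ``exact_threshold`` and the pooled sample is tie-free; otherwise the
    normal approximation with midranks, tie correction and continuity
    correction. W relates to the Mann-Whitney U of ``x`` by
    W = U + n_x(n_x+1)/2.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) <= exact_threshold and not has_ties
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return WilcoxonResult(
        variable="",
        statistic_w=w,
        p_value=float(res.pvalue),
        n_hotspot=len(x),
        n_control=len(y),
    )


def persistence_analysis(
    pairs_by_year: Mapping[int, Sequence[SitePair]],
    usage_by_year: Mapping[int, UsageTable],
    lags: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Wilcoxon comparisons of hotspot vs control usage at later years.

    For every designation year Y with site pairs and every lag with a usage
    table for year Y+lag, each of the four usage metrics is compared between
    the hotspot and control groups. Missing comparison years are skipped with
    a notice. Returns a table with one row per (designation year, comparison
    year, variable).
    """
    rows = []
    for year, pairs in sorted(pairs_by_year.items()):
        if not pairs:
            continue
        for lag in lags:
            target = year + lag
            if target not in usage_by_year:
                logger.info(
                    "no usage table for %d (lag %d from %d); skipped",
                    target, lag, year,
                )
                continue
            metrics = usage_at_sites(pairs, usage_by_year[target], year=target)
            hot = metrics.loc[metrics["kind"] == "hotspot"]
            ctl = metrics.loc[metrics["kind"] == "control"]
            for var in USAGE_METRICS:
                col = "n_revisits" if var == "n_revisits" else var
                res = wilcoxon_rank_sum(hot[col].to_numpy(), ctl[col].to_numpy())
                rows.append(
                    {
                        "designation_year": year,
                        "comparison_year": target,
                        "variable": var,
                        "W": res.statistic_w,
                        "p": res.p_value,
                        "n_hotspot": res.n_hotspot,
                        "n_control": res.n_control,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["designation_year", "comparison_year", "variable",
                 "W", "p", "n_hotspot", "n_control"],
    )
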