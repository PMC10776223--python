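"""Survey aggregation and hotspot-vs-control binomial GLMs.

Survey plots carry the site class as the response (hotspot = 1, control = 0);
each biodiversity metric is fitted as the single predictor of a logistic
regression, so the slope describes how well that metric discriminates raptor
activity hotspots from matched controls. Eight canonical predictors are
reported: abundance and richness for birds, small mammals and amphibians,
plus plant richness and mean within-plot Jaccard similarity.

Predictors are z-scored before fitting by default, which puts the eight
slopes on a comparable scale.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

TAXON_GROUPS = ("birds", "small_mammals", "amphibians", "plants")

PREDICTORS = (
    "bird_abundance",
    "bird_richness",
    "mammal_abundance",
    "mammal_richness",
    "amphibian_abundance",
    "amphibian_richness",
    "plant_similarity",
    "plant_richness",
)


@dataclass
class QuadratSample:
    """One 1 m² vegetation quadrat within a 50 m plot."""

    plot_id: str
    quadrat_index: int
    species_list: frozenset[str]


@dataclass
class SurveyPlot:
    """Raw survey records of one taxon group on one 50 m plot.

    ``records`` schema by taxon group (long format, one row per species
    observation):

    - birds: visit (1..2), species, count
    - small_mammals: station (1..5), species, count  (captures over 2 nights)
    - amphibians: transect (1..5), species, count
    - plants: quadrat (1..5), species
    """

    plot_id: str
    site_class: int
    taxon_group: str
    year: int
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.site_class not in (0, 1):
            raise ValueError(f"site_class must be 0 or 1, got {self.site_class}")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}")


@dataclass(frozen=True)
class GlmResult:
    """One row of the hotspot-vs-control logistic regression table."""

    predictor: str
    beta: float
    beta0: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    mcfadden_r2: float
    nagelkerke_r2: float
    aic: float
    loglik: float
    loglik_null: float
    converged: bool = True


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard similarity |a∩b| / |a∪b|; two empty sets count as identical (1)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def mean_pairwise_jaccard(quadrats: Sequence[Iterable[str]]) -> float:
    """Mean Jaccard similarity over all unordered quadrat pairs.

    Lower values mean higher compositional turnover between quadrats, i.e.
    a more heterogeneous plot.
    """
    sets = [set(q) for q in quadrats]
    if len(sets) < 2:
        raise ValueError("need at least 2 quadrats to compare in pairs")
    vals = [jaccard(a, b) for a, b in itertools.combinations(sets, 2)]
    # fsum: exactly-rounded, so the result is invariant to quadrat order
    return math.fsum(sorted(vals)) / len(vals)


def plot_richness(quadrats: Sequence[Iterable[str]]) -> int:
    """Species richness of a plot: size of the union over its quadrats."""
    u: set[str] = set()
    for q in quadrats:
        u |= set(q)
    return len(u)


def _aggregate_plot(plot: SurveyPlot) -> list[tuple[str, float]]:
    rec = plot.records
    if plot.taxon_group == "birds":
        visits = sorted(rec["visit"].unique()) if len(rec) else []
        if len(visits) != 2:
            logger.warning(
                "plot %s: expected 2 bird visits, found %d; using available visits",
                plot.plot_id, len(visits),
            )
        if not visits:
            return [("bird_abundance", 0.0), ("bird_richness", 0.0)]
        abund = [rec.loc[rec["visit"] == v, "count"].sum() for v in visits]
        rich = [
            rec.loc[(rec["visit"] == v) & (rec["count"] > 0), "species"].nunique()
            for v in visits
        ]
        return [
            ("bird_abundance", float(np.mean(abund))),
            ("bird_richness", float(np.mean(rich))),
        ]
    if plot.taxon_group == "small_mammals":
        return [
            ("mammal_abundance", float(rec["count"].sum()) if len(rec) else 0.0),
            ("mammal_richness", float(rec.loc[rec["count"] > 0, "species"].nunique())
             if len(rec) else 0.0),
        ]
    if plot.taxon_group == "amphibians":
        return [
            ("amphibian_abundance", float(rec["count"].sum()) if len(rec) else 0.0),
            ("amphibian_richness", float(rec.loc[rec["count"] > 0, "species"].nunique())
             if len(rec) else 0.0),
        ]
    # plants
    idx = sorted(rec["quadrat"].unique()) if len(rec) else []
    quadrats = [set(rec.loc[rec["quadrat"] == q, "species"]) for q in idx]
    if len(quadrats) < 2:
        raise ValueError(
            f"plot {plot.plot_id}: need >= 2 plant quadrats, found {len(quadrats)}"
        )
    return [
        ("plant_similarity", mean_pairwise_jaccard(quadrats)),
        ("plant_richness", float(plot_richness(quadrats))),
    ]


def aggregate_surveys(plots: Iterable[SurveyPlot]) -> pd.DataFrame:
    """Collapse raw survey records into the per-plot predictor table.

    Returns a long table (plot_id, site_class, year, predictor, value):
    birds averaged over the two seasonal visits, small-mammal captures and
    amphibian transect counts totalled, plant richness as the union of the
    five quadrats and plant similarity as the mean pairwise Jaccard index.
    Plots whose records cannot be aggregated are dropped with a logged id.
    """
    rows = []
    for plot in plots:
        try:
            for predictor, value in _aggregate_plot(plot):
                rows.append((plot.plot_id, plot.site_class, plot.year,
                             predictor, value))
        except ValueError as err:
            logger.warning("dropping plot %s: %s", plot.plot_id, err)
    df = pd.DataFrame(
        rows, columns=["plot_id", "site_class", "year", "predictor", "value"]
    )
    dup = df.duplicated(subset=["plot_id", "predictor"])
    if dup.any():
        raise ValueError(
            f"duplicate predictor values for plot(s) "
            f"{sorted(df.loc[dup, 'plot_id'].unique())}"
        )
    return df


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden's R² = 1 − lnL(model)/lnL(null)."""
    if loglik_null == 0:
        raise ValueError("null log-likelihood is 0 (degenerate outcome)")
    return 1.0 - loglik_model / loglik_null

def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R²: Cox–Snell rescaled to a [0, 1] range."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_null == 0:
        raise ValueError("null log-likelihood is 0 (degenerate outcome)")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    ceiling = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(cox_snell / ceiling)


def fit_binomial_glm(
    table: pd.DataFrame, predictor_name: str, standardize: bool = True
) -> GlmResult:
    """Logistic regression of site class on one survey predictor.

    Fits ``site_class ~ value`` by IRLS (relative log-likelihood tolerance
    1e-10) on the plots where the predictor is available. With
    ``standardize`` (default) the predictor is z-scored first so slopes are
    comparable across predictors. The confidence interval and p-value are
    Wald-based. Perfect separation yields a result flagged ``converged=False``
    with a warning rather than an exception.
    """
    sub = table.loc[table["predictor"] == predictor_name]
    if not len(sub):
        raise ValueError(f"no rows for predictor {predictor_name!r}")
    y = sub["site_class"].to_numpy(float)
    x = sub["value"].to_numpy(float)
    n = len(y)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 plots in each site class")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate predictor {predictor_name!r} (constant)")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)

    X = sm.add_constant(x)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                tol=1e-10, maxiter=200
            )
        except Exception:  # perfect separation aborts IRLS in some versions
            converged = False
            fit = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
        beta0, beta = (float(v) for v in fit.params)
        se = float(fit.bse[1])
        loglik = float(fit.llf)
        null_fit = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit(
            tol=1e-10, maxiter=200
        )
        loglik_null = float(null_fit.llf)
        if any("separation" in str(w.message).lower() for w in caught):
            converged = False
        if getattr(fit, "converged", True) is False:
            converged = False
    if not converged:
        logger.warning(
            "predictor %s: separation or non-convergence, estimates unreliable",
            predictor_name,
        )
    z = stats.norm.ppf(0.975)
    return GlmResult(
        predictor=predictor_name,
        beta=beta,
        beta0=beta0,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        p_value=float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan"),
        n=n,
        mcfadden_r2=mcfadden_r2(loglik, loglik_null),
        nagelkerke_r2=nagelkerke_r2(loglik, loglik_null, n),
        aic=2 * 2 - 2 * loglik,
        loglik=loglik,
        loglik_null=loglik_null,
        converged=converged,
    )


def run_table1(
    table: pd.DataFrame, standardize: bool = True
) -> list[GlmResult]:
    """One single-predictor logistic model per available canonical predictor.

    Plot counts differ between predictors (surveys of different taxa cover
    different plot subsets); each model uses the plots where its predictor is
    present. Missing predictors are logged and skipped.
    """
    results = []
    present = set(table["predictor"].unique())
    for name in PREDICTORS:
        if name not in present:
            logger.info("predictor %s absent from table; skipped", name)
            continue
        results.append(fit_binomial_glm(table, name, standardize=standardize))
    return results


def table1_frame(results: Sequence[GlmResult]) -> pd.DataFrame:
    """GLM results as a flat table mirroring the reporting layout."""
    return pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "beta": r.beta,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "n": r.n,
                "mcfadden_r2": r.mcfadden_r2,
                "nagelkerke_r2": r.nagelkerke_r2,
                "aic": r.aic,
                "converged": r.converged,
            }
            for r in results
        ]
    )
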