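"""Jaccard measures, survey aggregation and the binomial GLM layer."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from raptorhotspots import (
    SurveyPlot,
    aggregate_surveys,
    fit_binomial_glm,
    jaccard,
    mcfadden_r2,
    mean_pairwise_jaccard,
    nagelkerke_r2,
    plot_richness,
    run_table1,
)
from oracles import grid_search_logistic, null_loglik


class TestJaccard:
    def test_one_shared_of_three(self):
        assert jaccard({"x", "y"}, {"y", "z"}) == pytest.approx(1 / 3)

    def test_identical_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_both_empty_is_one(self):
        assert jaccard(set(), set()) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.sets(st.sampled_from("abcdefgh")),
        b=st.sets(st.sampled_from("abcdefgh")),
    )
    def test_symmetry_and_bounds(self, a, b):
        assert jaccard(a, b) == jaccard(b, a)
        assert 0.0 <= jaccard(a, b) <= 1.0


class TestMeanPairwiseJaccard:
    def test_identical_quadrats(self):
        assert mean_pairwise_jaccard([{"a", "b"}] * 5) == 1.0

    def test_disjoint_quadrats(self):
        quads = [{f"s{i}"} for i in range(5)]
        assert mean_pairwise_jaccard(quads) == 0.0

    def test_hand_enumerated_example(self):
        quads = [{"a", "b"}, {"b", "c"}, {"c"}, {"a", "b", "c"}, {"b"}]
        expected = np.mean(
            [jaccard(p, q) for p, q in itertools.combinations(quads, 2)]
        )
        # frozen value from enumerating the ten pairs by hand:
        # AB 1/3, AC 0, AD 2/3, AE 1/2, BC 1/2, BD 2/3, BE 1/2, CD 1/3,
        # CE 0, DE 1/3
        assert expected == pytest.approx((1/3 + 0 + 2/3 + 1/2 + 1/2 + 2/3 + 1/2
                                          + 1/3 + 0 + 1/3) / 10)
        assert mean_pairwise_jaccard(quads) == pytest.approx(expected)

    def test_order_invariance(self):
        quads = [{"a", "b"}, {"b", "c"}, {"c"}, {"a"}, {"b"}]
        assert mean_pairwise_jaccard(quads) == mean_pairwise_jaccard(quads[::-1])

    def test_single_quadrat_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_jaccard([{"a"}])


class TestPlotRichness:
    @pytest.mark.parametrize(
        "quads,expected",
        [([{"a", "b"}, {"b", "c"}], 3), ([set(), set()], 0), ([{"a"}], 1)],
    )
    def test_union_cardinality(self, quads, expected):
        assert plot_richness(quads) == expected


def _plot(group, records, plot_id="p1", site_class=1):
    return SurveyPlot(
        plot_id=plot_id, site_class=site_class, taxon_group=group,
        year=2020, records=pd.DataFrame(records),
    )


class TestAggregateSurveys:
    def test_bird_visits_averaged(self):
        plot = _plot(
            "birds",
            [
                {"visit": 1, "species": "b1", "count": 4},
                {"visit": 2, "species": "b1", "count": 2},
                {"visit": 2, "species": "b2", "count": 4},
            ],
        )
        tab = aggregate_surveys([plot]).set_index("predictor")["value"]
        assert tab["bird_abundance"] == pytest.approx(5.0)
        assert tab["bird_richness"] == pytest.approx(1.5)

    def test_mammal_totals(self):
        plot = _plot(
            "small_mammals",
            [
                {"station": 1, "species": "v", "count": 2},
                {"station": 3, "species": "v", "count": 0},
                {"station": 3, "species": "s", "count": 1},
            ],
        )
        tab = aggregate_surveys([plot]).set_index("predictor")["value"]
        assert tab["mammal_abundance"] == 3
        assert tab["mammal_richness"] == 2  # zero-count row is not a record of presence

    def test_plants_identical_quadrats(self):
        rows = [
            {"quadrat": q, "species": f"s{i}"}
            for q in range(1, 6) for i in range(7)
        ]
        tab = aggregate_surveys([_plot("plants", rows)]).set_index("predictor")["value"]
        assert tab["plant_richness"] == 7
        assert tab["plant_similarity"] == 1.0

    def test_single_quadrat_plot_dropped_and_logged(self, caplog):
        bad = _plot("plants", [{"quadrat": 1, "species": "a"}])
        with caplog.at_level("WARNING"):
            tab = aggregate_surveys([bad])
        assert len(tab) == 0
        assert "p1" in caplog.text


def toy_table():
    """8 plots, 4 per class, moderately separated predictor values."""
    vals = [1.0, 3.0, 2.0, 4.0, 2.0, 4.0, 5.0, 6.0]
    cls = [0, 0, 0, 0, 1, 1, 1, 1]
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(8)],
            "site_class": cls,
            "year": 2020,
            "predictor": "bird_abundance",
            "value": vals,
        }
    )


class TestBinomialGlm:
    def test_matches_grid_search_ml_oracle(self):
        tab = toy_table()
        res = fit_binomial_glm(tab, "bird_abundance", standardize=False)
        x = tab["value"].to_numpy()
        y = tab["site_class"].to_numpy()
        b0, b1, ll = grid_search_logistic(x, y)
        assert res.beta == pytest.approx(b1, abs=1e-4)
        assert res.beta0 == pytest.approx(b0, abs=1e-4)
        assert res.loglik == pytest.approx(ll, abs=1e-6)

    def test_r2_match_oracle_logliks(self):
        tab = toy_table()
        res = fit_binomial_glm(tab, "bird_abundance", standardize=False)
        x = tab["value"].to_numpy()
        y = tab["site_class"].to_numpy()
        _, _, ll = grid_search_logistic(x, y)
        ll0 = null_loglik(y)
        assert res.loglik_null == pytest.approx(ll0, abs=1e-8)
        assert res.mcfadden_r2 == pytest.approx(1 - ll / ll0, abs=1e-5)
        n = len(y)
        nag = (1 - np.exp(2 * (ll0 - ll) / n)) / (1 - np.exp(2 * ll0 / n))
        assert res.nagelkerke_r2 == pytest.approx(nag, abs=1e-5)

    def test_label_flip_negates_beta(self):
        tab = toy_table()
        res = fit_binomial_glm(tab, "bird_abundance")
        flipped = tab.assign(site_class=1 - tab["site_class"])
        res_f = fit_binomial_glm(flipped, "bird_abundance")
        assert res_f.beta == pytest.approx(-res.beta, rel=1e-6)
        assert res_f.aic == pytest.approx(res.aic, rel=1e-9)
        assert res_f.mcfadden_r2 == pytest.approx(res.mcfadden_r2, rel=1e-6)

    def test_uninformative_predictor_near_zero(self):
        # same values in both classes: perfectly symmetric
        tab = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(8)],
                "site_class": [0, 0, 0, 0, 1, 1, 1, 1],
                "year": 2020,
                "predictor": "q",
                "value": [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
            }
        )
        res = fit_binomial_glm(tab, "q")
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert res.mcfadden_r2 == pytest.approx(0.0, abs=1e-9)
        assert res.nagelkerke_r2 == pytest.approx(0.0, abs=1e-9)

    def test_constant_predictor_rejected(self):
        tab = toy_table().assign(value=2.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_binomial_glm(tab, "bird_abundance")

    def test_perfect_separation_flagged(self):
        tab = toy_table().assign(value=[1, 2, 3, 4, 10, 11, 12, 13])
        res = fit_binomial_glm(tab, "bird_abundance")
        assert not res.converged

    def test_r2_grow_with_separation(self):
        """Both pseudo-R² rise monotonically along a separation family."""
        mcf, nag = [], []
        for shift in (0.0, 1.0, 2.5):
            vals = np.array([1.0, 2.0, 3.0, 4.0] * 2)
            vals[4:] += shift
            tab = pd.DataFrame(
                {
                    "plot_id": [f"p{i}" for i in range(8)],
                    "site_class": [0] * 4 + [1] * 4,
                    "year": 2020,
                    "predictor": "q",
                    "value": vals,
                }
            )
            res = fit_binomial_glm(tab, "q")
            mcf.append(res.mcfadden_r2)
            nag.append(res.nagelkerke_r2)
        assert mcf[0] < mcf[1] < mcf[2]
        assert nag[0] < nag[1] < nag[2]


class TestR2Functions:
    def test_equal_logliks_give_zero(self):
        assert mcfadden_r2(-5.0, -5.0) == 0.0
        assert nagelkerke_r2(-5.0, -5.0, 10) == 0.0

    def test_mcfadden_arithmetic(self):
        assert mcfadden_r2(-2.5, -5.0) == pytest.approx(0.5)

    def test_nagelkerke_reaches_one_for_perfect_fit(self):
        # balanced outcome, model loglik -> 0
        n = 20
        ll0 = n * np.log(0.5)
        assert nagelkerke_r2(0.0, ll0, n) == pytest.approx(1.0)

    def test_zero_null_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_r2(0.0, 0.0)


class TestRunTable1:
    def _full_table(self, rng, n=20):
        rows = []
        for i in range(n):
            cls = i % 2
            for pred in (
                "bird_abundance", "bird_richness", "mammal_abundance",
                "mammal_richness", "amphibian_abundance", "amphibian_richness",
                "plant_similarity", "plant_richness",
            ):
                rows.append((f"p{i}", cls, 2020, pred, rng.normal() + 0.5 * cls))
        return pd.DataFrame(
            rows, columns=["plot_id", "site_class", "year", "predictor", "value"]
        )

    def test_eight_models_from_full_table(self):
        tab = self._full_table(np.random.default_rng(0))
        assert len(run_table1(tab)) == 8

    def test_missing_group_yields_fewer_models(self):
        tab = self._full_table(np.random.default_rng(0))
        tab = tab[~tab["predictor"].str.startswith("plant")]
        assert len(run_table1(tab)) == 6
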