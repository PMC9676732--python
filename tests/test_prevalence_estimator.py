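"""Prevalence estimator: trend multipliers, historic death reconstruction,
scenario ordering and the cross-estimator consistency identity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cancer_orphans import (
    PopulationTable,
    ScenarioConfig,
    SyntheticConfig,
    ValidationError,
    estimate_new_orphans,
    estimate_prevalent_orphans,
    historic_deaths,
    make_world,
    sensitivity_grid,
    trend_multiplier,
)


class TestTrendMultiplier:
    @pytest.mark.parametrize(
        "trend,yd,cat,expected",
        [
            ("S1", 2005, None, 1.0),
            ("S1", 2019, "low", 1.0),
            ("S2", 2018, None, 0.9801),
            ("S2", 2010, None, 0.99**10),
            ("S3", 2018, None, 1.01**2),
            ("S4", 2010, "very_high", 1.01**10),
            ("S4", 2010, "high", 1.01**10),
            ("S4", 2010, "low", 0.99**10),
            ("S4", 2010, "medium", 0.99**10),
        ],
    )
    def test_scenario_formulas(self, trend, yd, cat, expected):
        assert trend_multiplier(trend, yd, cat) == pytest.approx(expected, rel=1e-12)

    def test_s4_without_hdi_is_error(self):
        with pytest.raises(ValidationError, match="HDI"):
            trend_multiplier("S4", 2010, "missing")


class TestHistoricDeaths:
    def test_constant_population_s1_reproduces_reference_deaths(self, world):
        hist = historic_deaths(world, "S1", 2010)
        merged = hist.data.merge(world.deaths.data, on=["country", "site", "age_group"])
        assert np.allclose(merged["deaths_x"], merged["deaths_y"], rtol=1e-12)

    def test_halved_population_halves_deaths(self, world):
        pop = world.population.data.copy()
        mask = (pop["year"] == 2010) & (pop["sex"] == "female")
        pop.loc[mask, "count"] = pop.loc[mask, "count"] / 2
        shrunk = dataclasses.replace(world, population=PopulationTable(pop))
        hist = historic_deaths(shrunk, "S1", 2010)
        merged = hist.data.merge(world.deaths.data, on=["country", "site", "age_group"])
        assert np.allclose(merged["deaths_x"], merged["deaths_y"] / 2, rtol=1e-12)

    def test_s2_single_factor(self, world):
        hist = historic_deaths(world, "S2", 2019)
        merged = hist.data.merge(world.deaths.data, on=["country", "site", "age_group"])
        assert np.allclose(merged["deaths_x"], 0.99 * merged["deaths_y"], rtol=1e-12)


class TestPrevalence:
    def test_zero_deaths_zero_prevalence(self):
        bundle = make_world(SyntheticConfig(site_peak_rate=(0.0, 0.0, 0.0, 0.0)))
        assert estimate_prevalent_orphans(bundle).total() == 0.0

    def test_scenario_ordering_per_country(self, world):
        """Higher historic mortality rates (S3) imply more prevalent orphans
        than stable (S1), which beats declining-into-the-past (S2)."""
        totals = {
            t: estimate_prevalent_orphans(world, ScenarioConfig(trend=t)).totals_by_country()
            for t in ("S1", "S2", "S3")
        }
        assert (totals["S3"] > totals["S1"]).all()
        assert (totals["S1"] > totals["S2"]).all()

    def test_monotone_nonincreasing_in_mrr(self, world):
        by_mrr = [
            estimate_prevalent_orphans(world, ScenarioConfig(mrr_label=lab)).total()
            for lab in ("e", "a", "b", "c", "d")  # 1.0, 1.25, 1.5, 2.0, 2.6
        ]
        assert all(x > y for x, y in zip(by_mrr, by_mrr[1:]))

    def test_mrr_acts_only_through_child_hazards(self):
        bundle = make_world(SyntheticConfig(infant_hazard=(0.0, 0.0, 0.0)))
        d = estimate_prevalent_orphans(bundle, ScenarioConfig(mrr_label="d")).total()
        e = estimate_prevalent_orphans(bundle, ScenarioConfig(mrr_label="e")).total()
        assert d == pytest.approx(e, rel=1e-12)

    def test_children_aged_out_contribute_zero(self, world):
        res = estimate_prevalent_orphans(world)
        assert res.data["birth_year"].min() >= 2003

    def test_s4_excludes_countries_without_hdi(self):
        cfg = SyntheticConfig(hdi=(0.47, None, 0.86))
        bundle = make_world(cfg)
        with pytest.warns(UserWarning, match="no HDI"):
            res = estimate_prevalent_orphans(bundle, ScenarioConfig(trend="S4"))
        assert res.excluded_countries == ["C02"]
        assert set(res.data["country"]) == {"C01", "C03"}

    def test_cross_estimator_identity(self):
        """With stable rates, constant population, no child mortality and
        mrr=1, prevalence equals the sum over death years of the per-year
        new-orphan totals restricted to children still under 18 at the
        reference — computed through both estimators independently."""
        cfg = SyntheticConfig(
            infant_hazard=(0.0, 0.0, 0.0),
            fertility_start_year=1985,
            mortality_start_year=1985,
        )
        bundle = make_world(cfg)
        pmc = estimate_prevalent_orphans(bundle, ScenarioConfig(trend="S1", mrr_label="e")).total()
        total = 0.0
        for yd in range(2003, 2020):
            arr = estimate_new_orphans(bundle, ref_year=yd, include_ref_year_births=True)
            still_minor = arr.data[arr.data["birth_year"] >= 2003]
            total += float(still_minor["orphans"].sum())
        assert pmc == pytest.approx(total, rel=1e-9)


class TestSensitivityGrid:
    def test_single_combination_degenerate_grid(self, world):
        df = sensitivity_grid(world, trends=("S1",), mrr_labels=("a",))
        assert len(df) == 1 and df["trend"].iloc[0] == "S1"

    def test_extremes_at_expected_corners(self, world):
        df = sensitivity_grid(world, trends=("S1", "S2", "S3"), mrr_labels=("a", "d", "e"))
        imax = df["total"].idxmax()
        imin = df["total"].idxmin()
        assert (df.loc[imax, "trend"], df.loc[imax, "mrr_label"]) == ("S3", "e")
        assert (df.loc[imin, "trend"], df.loc[imin, "mrr_label"]) == ("S2", "d")
        assert df.attrs["max"] >= df.attrs["min"]
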