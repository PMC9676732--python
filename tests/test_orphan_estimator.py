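"""New-orphan estimator: single-age splitting, the per-woman convolution and
the country x site x age accounting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cancer_orphans import (
    DEFAULT_PARITY_RR,
    UNIT_PARITY_RR,
    ChildMortalityTable,
    DeathTable,
    FertilitySchedule,
    ParityRRTable,
    ParityRule,
    SyntheticConfig,
    WorldBundle,
    estimate_new_orphans,
    expected_minor_children,
    make_world,
    split_deaths_single_age,
)


def one_band_deaths(deaths=500.0, band="40-44", site="Breast", country="A"):
    return DeathTable(
        pd.DataFrame([(country, site, band, deaths)], columns=["country", "site", "age_group", "deaths"]),
        year=2020,
    )


class TestSplit:
    def test_uniform_split(self):
        single = split_deaths_single_age(one_band_deaths(500.0)).data
        assert sorted(single["md"]) == [40, 41, 42, 43, 44]
        assert (single["deaths"] == 100.0).all()
        assert single["contributing"].all()

    def test_zero_band(self):
        single = split_deaths_single_age(one_band_deaths(0.0)).data
        assert len(single) == 5 and (single["deaths"] == 0.0).all()

    def test_open_band_retained_but_non_contributing(self):
        single = split_deaths_single_age(one_band_deaths(1000.0, band="85+")).data
        assert len(single) == 5
        assert single["deaths"].sum() == pytest.approx(1000.0)
        assert not single["contributing"].any()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(deaths=st.lists(st.floats(0, 1e6), min_size=18, max_size=18))
    def test_band_totals_conserved(self, deaths):
        from cancer_orphans.ages import BAND_LABELS

        dt = DeathTable(
            pd.DataFrame(
                [("A", "Breast", b, d) for b, d in zip(BAND_LABELS, deaths)],
                columns=["country", "site", "age_group", "deaths"],
            ),
            year=2020,
        )
        single = split_deaths_single_age(dt).data
        by_band = single.groupby(single["md"] // 5)["deaths"].sum()
        assert np.allclose(sorted(by_band.to_numpy()), sorted(deaths), rtol=1e-12)


class TestExpectedChildren:
    def test_md_70_yields_nothing(self, quiet_world):
        vec = expected_minor_children(quiet_world, "C01", 70, "Breast")
        assert (vec == 0).all()

    def test_zero_fertility_world(self):
        bundle = make_world(SyntheticConfig(tfr=(0.0, 0.0, 0.0), jitter=0.0))
        vec = expected_minor_children(bundle, "C01", 40, "Breast")
        assert (vec == 0).all()

    def test_constant_fertility_hand_enumeration(self):
        """Constant 0.10 births/woman-year over 15-49, no child mortality,
        death at 40: the mother was 22-39 in the 18 birth years, so every
        component is 0.10 and the vector sums to 1.8 children."""
        bundle = _flat_world()
        vec = expected_minor_children(bundle, "A", 40, "Stomach")
        assert (vec.to_numpy() == pytest.approx(0.10)) and len(vec) == 18
        assert vec.sum() == pytest.approx(1.8)


def _flat_world(rate=0.10, deaths_band="40-44", deaths=500.0):
    """Single-country world: constant fertility, zero child mortality."""
    from test_demography import constant_schedule, mortality_table

    fert = constant_schedule(rate, countries=("A",))
    mort = mortality_table(0.0, country="A")
    pop_rows = [("A", "female", f"{lo}-{lo + 4}" if lo < 85 else "85+", y, 1e5)
                for lo in range(0, 90, 5) for y in range(2002, 2021)]
    pop_rows.append(("A", "both", "0-17", 2020, 1e6))
    from cancer_orphans import CountryMeta, PopulationTable, assemble_bundle

    pop = PopulationTable(pd.DataFrame(pop_rows, columns=["country", "sex", "age_group", "year", "count"]))
    meta = CountryMeta(pd.DataFrame([("A", "Aland", "R", "S", 0.7)],
                                    columns=["country", "name", "region", "subregion", "hdi"]))
    return assemble_bundle(one_band_deaths(deaths, band=deaths_band, site="Stomach"), fert, mort, pop, meta)


class TestEstimate:
    def test_zero_deaths_zero_orphans(self):
        bundle = _flat_world(deaths=0.0)
        assert estimate_new_orphans(bundle).total() == 0.0

    def test_scalar_multiple_of_per_woman_vector(self):
        """500 deaths in band 40-44 -> 100 at each single age, each with 1.8
        expected minor children -> 900 new orphans."""
        bundle = _flat_world(deaths=500.0)
        assert estimate_new_orphans(bundle).total() == pytest.approx(900.0)

    def test_linearity_in_deaths(self, world):
        base = estimate_new_orphans(world)
        doubled_deaths = DeathTable(world.deaths.data.assign(deaths=world.deaths.data["deaths"] * 2), year=2020)
        doubled = estimate_new_orphans(dataclasses.replace(world, deaths=doubled_deaths))
        merged = base.data.merge(doubled.data, on=["country", "site", "md", "birth_year"])
        assert np.allclose(2 * merged["orphans_x"], merged["orphans_y"], rtol=1e-12)

    def test_support_limits(self, world):
        arr = estimate_new_orphans(world)
        assert arr.data["md"].between(15, 67).all()
        assert arr.data["birth_year"].between(2002, 2019).all()

    def test_additivity_over_sites_and_groups(self, world):
        arr = estimate_new_orphans(world)
        by_site = arr.totals_by_site()
        groups = world.site_groups
        by_group = by_site.groupby([groups.group_of(s) for s in by_site.index]).sum()
        assert by_group.sum() == pytest.approx(by_site.sum(), rel=1e-9)
        assert arr.totals_by_country().sum() == pytest.approx(arr.total(), rel=1e-9)

    def test_monotone_in_fertility_and_child_mortality(self, world):
        base = estimate_new_orphans(world, rr_table=UNIT_PARITY_RR).total()
        more_fert = FertilitySchedule(world.fertility.data.assign(rate=world.fertility.data["rate"] * 1.2))
        up = estimate_new_orphans(dataclasses.replace(world, fertility=more_fert), rr_table=UNIT_PARITY_RR).total()
        assert up > base
        more_mort = ChildMortalityTable(world.child_mortality.data.assign(rate=world.child_mortality.data["rate"] + 0.01))
        down = estimate_new_orphans(dataclasses.replace(world, child_mortality=more_mort), rr_table=UNIT_PARITY_RR).total()
        assert down < base

    def test_rr_scales_site_orphans_exactly(self, world):
        """Switching a site's parity RR from 1.0 to 1.1 scales that site's
        orphans by exactly 1.1 and leaves every other site untouched."""
        plain = estimate_new_orphans(world, rr_table=UNIT_PARITY_RR).totals_by_site()
        cervix_only = ParityRRTable(rules=(ParityRule("Cervix uteri", 1.1),))
        adjusted = estimate_new_orphans(world, rr_table=cervix_only).totals_by_site()
        assert adjusted["Cervix uteri"] == pytest.approx(1.1 * plain["Cervix uteri"], rel=1e-12)
        others = [s for s in plain.index if s != "Cervix uteri"]
        assert np.allclose(adjusted[others], plain[others], rtol=1e-12)
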