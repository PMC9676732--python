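"""Reading, validation and assembly of the five input tables."""

import numpy as np
import pandas as pd
import pytest

from cancer_orphans import (
    FormatError,
    SiteGroupMap,
    ValidationError,
    assemble_bundle,
    hdi_category,
    load_site_groups,
    read_child_mortality,
    read_death_table,
    read_fertility_table,
    read_population,
    write_death_table,
    write_fertility_table,
)
from cancer_orphans.sites import GROUPS, SITES


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestDeathTable:
    def test_two_row_parse(self, tmp_path):
        p = _write(
            tmp_path,
            "d.csv",
            "country,site,age_group,deaths\nA,Breast,40-44,500\nA,Breast,45-49,300\n",
        )
        dt = read_death_table(p, year=2020)
        assert len(dt.data) == 2
        assert dt.total_deaths() == 800

    def test_missing_deaths_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "d.csv", "country,site,age_group\nA,Breast,40-44\n")
        with pytest.raises(FormatError, match="deaths"):
            read_death_table(p, year=2020)

    def test_negative_deaths_rejected(self, tmp_path):
        p = _write(tmp_path, "d.csv", "country,site,age_group,deaths\nA,Breast,40-44,-1\n")
        with pytest.raises(ValidationError, match="negative"):
            read_death_table(p, year=2020)

    def test_unknown_site_named_in_error(self, tmp_path):
        p = _write(tmp_path, "d.csv", "country,site,age_group,deaths\nA,Gallstones,40-44,1\n")
        with pytest.raises(ValidationError, match="Gallstones"):
            read_death_table(p, year=2020)

    def test_band_labels_canonicalized(self, tmp_path):
        p = _write(
            tmp_path,
            "d.csv",
            "country,site,age_group,deaths\nA,Breast,40–44,5\nA,Breast,85 +,3\n",
        )
        dt = read_death_table(p, year=2020)
        assert sorted(dt.data["age_group"]) == ["40-44", "85+"]

    def test_generator_fixture_covers_full_grid(self, world_dir):
        dt = read_death_table(world_dir / "deaths.csv", year=2020)
        assert len(dt.data) == 35 * 18 * 3

    def test_round_trip_bit_exact(self, world_dir, tmp_path):
        dt = read_death_table(world_dir / "deaths.csv", year=2020)
        write_death_table(dt, tmp_path / "d2.csv")
        dt2 = read_death_table(tmp_path / "d2.csv", year=2020)
        assert (dt.data["deaths"].to_numpy() == dt2.data["deaths"].to_numpy()).all()


class TestFertility:
    def test_per_1000_conversion(self, tmp_path):
        p = _write(tmp_path, "f.csv", "country,age_group,period,rate\nA,20-24,2010-2014,120\n")
        sched = read_fertility_table(p)
        assert sched.data["rate"].iloc[0] == pytest.approx(0.12)

    def test_negative_rate_rejected(self, tmp_path):
        p = _write(tmp_path, "f.csv", "country,age_group,period,rate\nA,20-24,2010-2014,-5\n")
        with pytest.raises(ValidationError, match="negative"):
            read_fertility_table(p)

    def test_band_outside_15_49_rejected(self, tmp_path):
        p = _write(tmp_path, "f.csv", "country,age_group,period,rate\nA,50-54,2010-2014,10\n")
        with pytest.raises(ValidationError, match="15-49"):
            read_fertility_table(p)

    def test_full_grid_row_count(self, tmp_path):
        rows = ["country,age_group,period,rate"]
        for c in "AB":
            for lo in range(15, 50, 5):
                for start in range(2000, 2019, 5):
                    rows.append(f"{c},{lo}-{lo + 4},{start}-{start + 4},100")
        sched = read_fertility_table(_write(tmp_path, "f.csv", "\n".join(rows)))
        assert len(sched.data) == 7 * 4 * 2 == 56

    def test_round_trip_recovers_per_1000_values(self, world_dir, tmp_path):
        sched = read_fertility_table(world_dir / "fertility.csv")
        write_fertility_table(sched, tmp_path / "f2.csv")
        a = pd.read_csv(world_dir / "fertility.csv")["rate"].to_numpy()
        b = pd.read_csv(tmp_path / "f2.csv")["rate"].to_numpy()
        assert np.array_equal(a, b)


class TestChildMortalityAndMeta:
    def test_grid_gap_names_missing_year(self, tmp_path):
        rows = ["country,age,year,rate"]
        for year in range(2006, 2010):
            if year == 2007:
                continue
            rows.extend(f"A,{a},{year},0.01" for a in range(18))
        with pytest.raises(ValidationError, match="2007"):
            read_child_mortality(_write(tmp_path, "m.csv", "\n".join(rows)))

    def test_banded_hazards_expanded_by_repetition(self, tmp_path):
        rows = ["country,age,year,rate", "A,0-4,2010,0.02", "A,5-9,2010,0.01",
                "A,10-14,2010,0.005", "A,15-19,2010,0.004"]
        mort = read_child_mortality(_write(tmp_path, "m.csv", "\n".join(rows)))
        assert len(mort.data) == 18  # clipped to ages 0-17
        grid, y0, _ = mort.hazard_grid("A")
        assert grid[3, 2010 - y0] == 0.02 and grid[17, 2010 - y0] == 0.004

    @pytest.mark.parametrize(
        "hdi,expected",
        [
            (0.39, "low"),
            (0.549, "low"),
            (0.55, "medium"),
            (0.69, "medium"),
            (0.70, "high"),
            (0.79, "high"),
            (0.80, "very_high"),
            (0.96, "very_high"),
            (None, "missing"),
        ],
    )
    def test_hdi_categories(self, hdi, expected):
        assert hdi_category(hdi) == expected


class TestSiteGroups:
    def test_vocabulary_and_groups_sizes(self):
        assert len(SITES) == 35
        assert len(GROUPS) == 14

    def test_missing_site_is_validation_error(self):
        partial = {s: "Other" for s in SITES if s != "Thyroid"}
        with pytest.raises(ValidationError, match="Thyroid"):
            SiteGroupMap(partial)

    def test_group_totality_preserves_sums(self, world):
        """Summing any site-level quantity over the 14 groups equals summing
        over the 35 sites."""
        groups = load_site_groups()
        by_site = world.deaths.data.groupby("site")["deaths"].sum()
        by_group = by_site.groupby([groups.group_of(s) for s in by_site.index]).sum()
        assert by_group.sum() == pytest.approx(by_site.sum(), rel=1e-12)


class TestAssemble:
    def test_intersection_drops_reported(self, world):
        deaths = world.deaths
        fert_ab = type(world.fertility)(
            world.fertility.data[world.fertility.data["country"] != "C03"]
        )
        bundle = assemble_bundle(
            deaths, fert_ab, world.child_mortality, world.population, world.country_meta
        )
        assert bundle.countries == ["C01", "C02"]
        assert bundle.report["dropped"]["deaths"] == ["C03"]

    def test_identical_sets_no_drops(self, world):
        assert world.report["dropped"] == {}

    def test_empty_intersection_fatal(self, world):
        lonely = type(world.fertility)(
            world.fertility.data.assign(country="ZZ")
        )
        with pytest.raises(ValidationError, match="no common countries"):
            assemble_bundle(
                world.deaths, lonely, world.child_mortality, world.population, world.country_meta
            )
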