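"""Read, validate and normalize the five input tables into a WorldBundle.

Inputs are UTF-8, comma-delimited CSV with a header row:

==================  =============================================================
table               columns
==================  =============================================================
deaths              country, site, age_group, deaths [, year]
fertility           country, age_group, period, rate   (births per 1,000 women/yr)
child mortality     country, age, year, rate           (deaths per person-year)
population          country, sex, age_group, year, count
country metadata    country, name, region, subregion, hdi  (hdi may be blank)
==================  =============================================================

Readers hard-error only on structural problems (missing columns) and the
semantic violations called out per table (negative counts/rates, unknown site
labels, fertility outside ages 15-49, gaps in the child-mortality grid).
Completeness of age bands and calendar periods is reported, not fatal, at read
time; :func:`assemble_bundle` attaches a validation report covering it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ages import (
    BAND_LABELS,
    FERTILE_MAX,
    FERTILE_MIN,
    band_bounds,
    canonical_band,
    parse_period,
)
from .errors import FormatError, ValidationError
from .sites import SITES, SiteGroupMap, load_site_groups, normalize_site

#: HDI category cut points: low < 0.55 <= medium < 0.70 <= high < 0.80 <= very_high.
HDI_CUTS = (0.55, 0.70, 0.80)
HDI_CATEGORIES = ("low", "medium", "high", "very_high", "missing")


def hdi_category(hdi: float | None) -> str:
    """Categorize an HDI value with the standard cut points."""
    if hdi is None or (isinstance(hdi, float) and math.isnan(hdi)):
        return "missing"
    if not 0.0 <= hdi <= 1.0:
        raise ValidationError(f"HDI outside [0,1]: {hdi}")
    if hdi < HDI_CUTS[0]:
        return "low"
    if hdi < HDI_CUTS[1]:
        return "medium"
    if hdi < HDI_CUTS[2]:
        return "high"
    return "very_high"


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------


@dataclass
class DeathTable:
    """Female cancer deaths by country x site x 5-year age band, for one year."""

    data: pd.DataFrame  # columns: country, site, age_group, deaths
    year: int

    def __post_init__(self) -> None:
        _require_columns(self.data, ["country", "site", "age_group", "deaths"], "death table")
        if (self.data["deaths"] < 0).any():
            bad = self.data.loc[self.data["deaths"] < 0].iloc[0]
            raise ValidationError(
                f"negative deaths for {bad['country']}/{bad['site']}/{bad['age_group']}"
            )
        dup = self.data.duplicated(["country", "site", "age_group"])
        if dup.any():
            raise ValidationError(
                f"duplicate (country, site, age band) rows: {self.data.loc[dup].head().to_dict('records')}"
            )

    @property
    def countries(self) -> set[str]:
        return set(self.data["country"].unique())

    def total_deaths(self, country: str | None = None) -> float:
        df = self.data if country is None else self.data[self.data["country"] == country]
        return float(df["deaths"].sum())

    def band_matrix(self, country: str) -> pd.DataFrame:
        """site x band matrix of deaths for one country (absent cells are 0)."""
        sub = self.data[self.data["country"] == country]
        mat = sub.pivot_table(index="site", columns="age_group", values="deaths", aggfunc="sum")
        return mat.reindex(columns=BAND_LABELS, fill_value=0.0).fillna(0.0)


@dataclass
class FertilitySchedule:
    """Per-woman annual birth rates on a 5-year age x 5-year period grid.

    Rates are stored per woman (converted from per-1,000 on read) and defined
    for age bands within 15-49; fertility is implicitly zero elsewhere.
    """

    data: pd.DataFrame  # columns: country, age_group, period, rate (per woman)

    def __post_init__(self) -> None:
        _require_columns(self.data, ["country", "age_group", "period", "rate"], "fertility table")
        if (self.data["rate"] < 0).any():
            bad = self.data.loc[self.data["rate"] < 0].iloc[0]
            raise ValidationError(
                f"negative fertility rate for {bad['country']}/{bad['age_group']}/{bad['period']}"
            )
        for band in self.data["age_group"].unique():
            lo, hi = band_bounds(band)
            if hi is None or lo < FERTILE_MIN or hi > FERTILE_MAX:
                raise ValidationError(f"fertility age band outside 15-49: {band!r}")
        self._grid_cache: dict[str, tuple[np.ndarray, int, int]] = {}

    @property
    def countries(self) -> set[str]:
        return set(self.data["country"].unique())

    def year_range(self, country: str) -> tuple[int, int]:
        """(first, last) calendar year covered by this country's periods."""
        periods = self.data.loc[self.data["country"] == country, "period"].unique()
        if len(periods) == 0:
            raise ValidationError(f"no fertility periods for country {country!r}")
        bounds = [parse_period(p) for p in periods]
        return min(b[0] for b in bounds), max(b[1] for b in bounds)

    def single_age_grid(self, country: str) -> tuple[np.ndarray, int, int]:
        """Step-function expansion: array[age 15..49, year y0..y1] of per-woman rates.

        Returns (grid, y0, y1); grid cells not present in the table are zero.
        Cached per country.
        """
        if country in self._grid_cache:
            return self._grid_cache[country]
        y0, y1 = self.year_range(country)
        grid = np.zeros((FERTILE_MAX - FERTILE_MIN + 1, y1 - y0 + 1))
        sub = self.data[self.data["country"] == country]
        for _, row in sub.iterrows():
            lo, hi = band_bounds(row["age_group"])
            p0, p1 = parse_period(row["period"])
            grid[lo - FERTILE_MIN : hi - FERTILE_MIN + 1, p0 - y0 : p1 - y0 + 1] = row["rate"]
        self._grid_cache[country] = (grid, y0, y1)
        return grid, y0, y1


@dataclass
class ChildMortalityTable:
    """Single-age annual child mortality hazards (deaths per person-year),
    ages 0-17 x calendar years, complete per country."""

    data: pd.DataFrame  # columns: country, age, year, rate

    def __post_init__(self) -> None:
        _require_columns(self.data, ["country", "age", "year", "rate"], "child mortality table")
        if (self.data["rate"] < 0).any():
            raise ValidationError("negative child mortality hazard")
        if not self.data["age"].between(0, 17).all():
            bad = sorted(self.data.loc[~self.data["age"].between(0, 17), "age"].unique())
            raise ValidationError(f"child mortality ages outside 0-17: {bad}")
        # completeness: per country, full (age 0-17) x (min..max year) grid
        for country, sub in self.data.groupby("country"):
            years = range(int(sub["year"].min()), int(sub["year"].max()) + 1)
            have = set(zip(sub["age"].astype(int), sub["year"].astype(int)))
            missing = [(a, y) for y in years for a in range(18) if (a, y) not in have]
            if missing:
                raise ValidationError(
                    f"child mortality grid for {country!r} has gaps; missing (age, year) "
                    f"cells include {missing[:10]}"
                )
        self._grid_cache: dict[str, tuple[np.ndarray, int, int]] = {}

    @property
    def countries(self) -> set[str]:
        return set(self.data["country"].unique())

    def hazard_grid(self, country: str) -> tuple[np.ndarray, int, int]:
        """array[age 0..17, year y0..y1] of hazards, with (grid, y0, y1)."""
        if country in self._grid_cache:
            return self._grid_cache[country]
        sub = self.data[self.data["country"] == country]
        if sub.empty:
            raise ValidationError(f"no child mortality data for country {country!r}")
        y0, y1 = int(sub["year"].min()), int(sub["year"].max())
        grid = np.zeros((18, y1 - y0 + 1))
        grid[sub["age"].to_numpy(int), sub["year"].to_numpy(int) - y0] = sub["rate"].to_numpy()
        self._grid_cache[country] = (grid, y0, y1)
        return grid, y0, y1


@dataclass
class PopulationTable:
    """Population counts by country x sex x age band x year.

    Female counts by the death table's 5-year bands across the historic years;
    both-sex counts for ages 0-17 (band label ``"0-17"``) at mid-reference-year.
    """

    data: pd.DataFrame  # columns: country, sex, age_group, year, count

    def __post_init__(self) -> None:
        _require_columns(self.data, ["country", "sex", "age_group", "year", "count"], "population table")
        if (self.data["count"] < 0).any():
            raise ValidationError("negative population count")
        bad_sex = set(self.data["sex"].unique()) - {"female", "both"}
        if bad_sex:
            raise ValidationError(f"unknown sex values: {sorted(bad_sex)}")

    @property
    def countries(self) -> set[str]:
        return set(self.data["country"].unique())

    def female_bands(self, country: str, year: int) -> pd.Series:
        sub = self.data[
            (self.data["country"] == country)
            & (self.data["sex"] == "female")
            & (self.data["year"] == year)
        ]
        if sub.empty:
            raise ValidationError(f"no female population for {country!r} in {year}")
        return sub.set_index("age_group")["count"].reindex(BAND_LABELS, fill_value=0.0)

    def children_0_17(self, country: str, year: int) -> float:
        sub = self.data[
            (self.data["country"] == country)
            & (self.data["sex"] == "both")
            & (self.data["age_group"] == "0-17")
            & (self.data["year"] == year)
        ]
        if sub.empty:
            raise ValidationError(f"no both-sex 0-17 population for {country!r} in {year}")
        return float(sub["count"].iloc[0])


@dataclass
class CountryMeta:
    """Region hierarchy and HDI per country; hdi_category recomputed from hdi."""

    data: pd.DataFrame  # columns: country, name, region, subregion, hdi, hdi_category

    def __post_init__(self) -> None:
        _require_columns(self.data, ["country", "name", "region", "subregion", "hdi"], "country metadata")
        if (self.data["region"].astype(str).str.strip() == "").any():
            raise ValidationError("empty region in country metadata")
        self.data = self.data.copy()
        self.data["hdi"] = pd.to_numeric(self.data["hdi"], errors="coerce")
        self.data["hdi_category"] = [
            hdi_category(None if pd.isna(v) else float(v)) for v in self.data["hdi"]
        ]

    @property
    def countries(self) -> set[str]:
        return set(self.data["country"].unique())

    def category_of(self, country: str) -> str:
        sub = self.data[self.data["country"] == country]
        if sub.empty:
            raise ValidationError(f"no metadata for country {country!r}")
        return str(sub["hdi_category"].iloc[0])


@dataclass
class WorldBundle:
    """All five tables plus the site-group map, restricted to a common country set."""

    deaths: DeathTable
    fertility: FertilitySchedule
    child_mortality: ChildMortalityTable
    population: PopulationTable
    country_meta: CountryMeta
    site_groups: SiteGroupMap = field(default_factory=SiteGroupMap)
    report: dict = field(default_factory=dict)

    @property
    def countries(self) -> list[str]:
        return sorted(self.deaths.countries)

    @property
    def ref_year(self) -> int:
        return self.deaths.year


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    try:
        # round_trip float parsing so write->read reproduces values bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{what}: cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_death_table(path: str | Path, year: int) -> DeathTable:
    """Read a deaths CSV (country, site, age_group, deaths) for a reference year.

    Site labels are checked against the 35-site vocabulary; age-band labels are
    canonicalized.
    """
    df = _read_csv(path, "death table")
    _require_columns(df, ["country", "site", "age_group", "deaths"], "death table")
    df = df[["country", "site", "age_group", "deaths"]].copy()
    df["country"] = df["country"].astype(str)
    df["site"] = [normalize_site(s) for s in df["site"]]
    df["age_group"] = [canonical_band(b) for b in df["age_group"]]
    df["deaths"] = pd.to_numeric(df["deaths"], errors="raise").astype(float)
    return DeathTable(df, year=int(year))


def write_death_table(dt: DeathTable, path: str | Path) -> None:
    """Write a DeathTable back to CSV (round-trips deaths bit-exactly)."""
    out = dt.data.copy()
    out["year"] = dt.year
    out.to_csv(path, index=False, float_format="%.17g")


def read_fertility_table(path: str | Path) -> FertilitySchedule:
    """Read fertility rates (per 1,000 women per year) on the 5x5 grid;
    stored per woman (divided by 1,000)."""
    df = _read_csv(path, "fertility table")
    _require_columns(df, ["country", "age_group", "period", "rate"], "fertility table")
    df = df[["country", "age_group", "period", "rate"]].copy()
    df["country"] = df["country"].astype(str)
    df["age_group"] = [canonical_band(b) for b in df["age_group"]]
    df["period"] = ["{}-{}".format(*parse_period(p)) for p in df["period"]]
    per_1000 = pd.to_numeric(df["rate"], errors="raise").astype(float)
    df["rate"] = per_1000 / 1000.0
    # keep the source values so re-expressing per 1,000 is bit-exact
    df["rate_per_1000"] = per_1000
    return FertilitySchedule(df)


def write_fertility_table(sched: FertilitySchedule, path: str | Path) -> None:
    """Write fertility back out per 1,000 women (exact inverse of the read conversion)."""
    out = sched.data.copy()
    if "rate_per_1000" in out.columns:
        out["rate"] = out.pop("rate_per_1000")
    else:
        out["rate"] = out["rate"] * 1000.0
    out.to_csv(path, index=False, float_format="%.17g")


def read_child_mortality(path: str | Path) -> ChildMortalityTable:
    """Read single-age child mortality hazards; 5-year-band input is expanded
    by constant repetition within each band (clipped to ages 0-17)."""
    df = _read_csv(path, "child mortality table")
    _require_columns(df, ["country", "age", "year", "rate"], "child mortality table")
    df = df[["country", "age", "year", "rate"]].copy()
    df["country"] = df["country"].astype(str)
    try:
        df["age"] = df["age"].astype(int)
    except (ValueError, TypeError):
        # banded input: expand each band to its single ages by repetition
        rows = []
        for _, row in df.iterrows():
            lo, hi = band_bounds(row["age"])
            for a in range(lo, min(hi if hi is not None else 17, 17) + 1):
                rows.append((row["country"], a, row["year"], row["rate"]))
        df = pd.DataFrame(rows, columns=["country", "age", "year", "rate"])
    df["year"] = df["year"].astype(int)
    df["rate"] = pd.to_numeric(df["rate"], errors="raise").astype(float)
    return ChildMortalityTable(df)


def read_population(path: str | Path) -> PopulationTable:
    df = _read_csv(path, "population table")
    _require_columns(df, ["country", "sex", "age_group", "year", "count"], "population table")
    df = df[["country", "sex", "age_group", "year", "count"]].copy()
    df["country"] = df["country"].astype(str)
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    df["age_group"] = [
        "0-17" if str(b).strip() in ("0-17", "0–17") else canonical_band(b) for b in df["age_group"]
    ]
    df["year"] = df["year"].astype(int)
    df["count"] = pd.to_numeric(df["count"], errors="raise").astype(float)
    return PopulationTable(df)


def read_country_meta(path: str | Path) -> CountryMeta:
    df = _read_csv(path, "country metadata")
    _require_columns(df, ["country", "name", "region", "subregion", "hdi"], "country metadata")
    df = df[["country", "name", "region", "subregion", "hdi"]].copy()
    df["country"] = df["country"].astype(str)
    return CountryMeta(df)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------


def assemble_bundle(
    deaths: DeathTable,
    fertility: FertilitySchedule,
    child_mortality: ChildMortalityTable,
    population: PopulationTable,
    country_meta: CountryMeta,
    site_groups: SiteGroupMap | None = None,
) -> WorldBundle:
    """Intersect country sets, attach the site-group map and a validation report.

    Raises :class:`ValidationError` if the intersection is empty or the
    site-group map does not cover the vocabulary.
    """
    if site_groups is None:
        site_groups = load_site_groups()
    sets = {
        "deaths": deaths.countries,
        "fertility": fertility.countries,
        "child_mortality": child_mortality.countries,
        "population": population.countries,
        "country_meta": country_meta.countries,
    }
    common = set.intersection(*sets.values())
    if not common:
        raise ValidationError("no common countries across the input tables")
    dropped = {name: sorted(s - common) for name, s in sets.items() if s - common}

    warnings: list[str] = []
    for country in sorted(common):
        try:
            y0, y1 = fertility.year_range(country)
            if y0 > 2000 or y1 < 2019:
                warnings.append(f"fertility periods for {country} cover {y0}-{y1}, not 2000-2019")
            periods = sorted(
                parse_period(p)
                for p in fertility.data.loc[fertility.data["country"] == country, "period"].unique()
            )
            for (a0, a1), (b0, _) in zip(periods, periods[1:]):
                if b0 != a1 + 1:
                    warnings.append(f"fertility periods for {country} have a gap after {a0}-{a1}")
        except ValidationError as exc:
            warnings.append(str(exc))
        mat = deaths.band_matrix(country)
        present = deaths.data.loc[deaths.data["country"] == country, "age_group"].unique()
        if set(present) != set(BAND_LABELS):
            warnings.append(
                f"death table for {country} lacks bands {sorted(set(BAND_LABELS) - set(present))}"
            )
        if len(mat.index) != len(SITES):
            warnings.append(f"death table for {country} covers {len(mat.index)}/35 sites")

    report = {
        "countries": sorted(common),
        "n_countries": len(common),
        "dropped": dropped,
        "warnings": warnings,
    }
    restrict = lambda df: df[df["country"].isin(common)].reset_index(drop=True)  # noqa: E731
    return WorldBundle(
        deaths=DeathTable(restrict(deaths.data), year=deaths.year),
        fertility=FertilitySchedule(restrict(fertility.data)),
        child_mortality=ChildMortalityTable(restrict(child_mortality.data)),
        population=PopulationTable(restrict(population.data)),
        country_meta=CountryMeta(restrict(country_meta.data)),
        site_groups=site_groups,
        report=report,
    )


def read_bundle(
    deaths_path: str | Path,
    fertility_path: str | Path,
    child_mortality_path: str | Path,
    population_path: str | Path,
    meta_path: str | Path,
    year: int = 2020,
    site_groups_path: str | Path | None = None,
) -> WorldBundle:
    """Convenience reader: all five tables -> assembled WorldBundle."""
    return assemble_bundle(
        read_death_table(deaths_path, year=year),
        read_fertility_table(fertility_path),
        read_child_mortality(child_mortality_path),
        read_population(population_path),
        read_country_meta(meta_path),
        load_site_groups(site_groups_path),
    )


def write_validation_report(bundle: WorldBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(bundle.report, fh, indent=2)
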