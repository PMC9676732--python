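"""Prevalent maternal orphans due to cancer at mid-reference-year.

Historic female cancer deaths (reference-17 .. reference-1) are reconstructed
by applying trend multipliers to the reference year's age-specific mortality
rates and the historic female population:

    D(yd, c, t, band) = lambda(yd) * [D(ref, c, t, band) / N_f(ref, c, band)]
                                   * N_f(yd, c, band)

with lambda given by four scenarios: S1 stable (lambda = 1), S2 rates rising
1%/yr (lambda = 0.99^(ref-yd), so past rates were lower), S3 rates falling
1%/yr (lambda = 1.01^(ref-yd)), and S4 applying the S2 rule to low/medium-HDI
countries and the S3 rule to high/very-high-HDI countries.

Each death cohort's surviving, still-minor children at the reference are then
accumulated with the bereavement-adjusted survival ``P(U18 | y, yd)`` from
:mod:`.demography`, under a bereavement mortality-rate-ratio MRR labelled
a=1.25, b=1.5, c=2.0, d=2.6, e=1.0.  The headline configuration is S1a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import MAX_ORPHANING_AGE
from .demography import DEFAULT_PARITY_RR, CountryGrids, ParityRRTable
from .errors import ValidationError
from .orphan_estimator import MIN_ORPHANING_AGE, _rr_vector, estimate_new_orphans
from .tables_io import DeathTable, WorldBundle

TRENDS = ("S1", "S2", "S3", "S4")

#: Bereavement mortality-rate-ratio labels and values.
MRR_VALUES: dict[str, float] = {"a": 1.25, "b": 1.5, "c": 2.0, "d": 2.6, "e": 1.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """A trend scenario x bereavement-MRR combination (default S1a)."""

    trend: str = "S1"
    mrr_label: str = "a"
    include_ref_year_half: bool = False

    def __post_init__(self) -> None:
        if self.trend not in TRENDS:
            raise ValidationError(f"unknown trend scenario {self.trend!r}; expected one of {TRENDS}")
        if self.mrr_label not in MRR_VALUES:
            raise ValidationError(
                f"unknown MRR label {self.mrr_label!r}; expected one of {sorted(MRR_VALUES)}"
            )

    @property
    def mrr_value(self) -> float:
        return MRR_VALUES[self.mrr_label]

    @property
    def name(self) -> str:
        return f"{self.trend}{self.mrr_label}"


def trend_multiplier(trend: str, yd: int, hdi_category: str | None = None, ref_year: int = 2020) -> float:
    """Multiplier on reference-year mortality rates for historic year ``yd``."""
    if trend not in TRENDS:
        raise ValidationError(f"unknown trend scenario {trend!r}")
    if not ref_year - 18 <= yd <= ref_year:
        raise ValidationError(f"death year {yd} outside {ref_year - 18}-{ref_year}")
    k = ref_year - yd
    if trend == "S1":
        return 1.0
    if trend == "S2":
        return 0.99**k
    if trend == "S3":
        return 1.01**k
    # S4: direction depends on the country's HDI category at the reference year
    if hdi_category in ("low", "medium"):
        return 0.99**k
    if hdi_category in ("high", "very_high"):
        return 1.01**k
    raise ValidationError(f"S4 requires an HDI category; got {hdi_category!r}")


def historic_deaths(bundle: WorldBundle, trend: str, yd: int, ref_year: int | None = None) -> DeathTable:
    """Reconstructed female cancer deaths for historic year ``yd``.

    Countries lacking an HDI category are excluded (with a warning) under S4.
    Raises :class:`ValidationError` if a band has reference-year deaths but
    zero reference-year female population.
    """
    ref_year = bundle.ref_year if ref_year is None else ref_year
    frames = []
    for country in bundle.countries:
        cat = bundle.country_meta.category_of(country)
        if trend == "S4" and cat == "missing":
            warnings.warn(f"country {country} has no HDI; excluded from S4 rates", stacklevel=2)
            continue
        mult = trend_multiplier(trend, yd, cat, ref_year)
        pop_ref = bundle.population.female_bands(country, ref_year)
        pop_yd = bundle.population.female_bands(country, yd)
        mat = bundle.deaths.band_matrix(country)
        zero_pop = (pop_ref.to_numpy() == 0) & (mat.to_numpy().sum(axis=0) > 0)
        if zero_pop.any():
            bad = [b for b, z in zip(mat.columns, zero_pop) if z]
            raise ValidationError(
                f"zero {ref_year} female population with nonzero deaths for {country}, bands {bad}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(pop_ref.to_numpy() > 0, mat.to_numpy() / pop_ref.to_numpy(), 0.0)
        d = mult * rates * pop_yd.to_numpy()
        long = pd.DataFrame(d, index=mat.index, columns=mat.columns).stack().reset_index()
        long.columns = ["site", "age_group", "deaths"]
        long.insert(0, "country", country)
        frames.append(long)
    if not frames:
        raise ValidationError(f"no countries usable for trend {trend} in year {yd}")
    return DeathTable(pd.concat(frames, ignore_index=True), year=yd)


@dataclass
class PrevalenceResult:
    """Prevalent orphans by country x site x child birth year at mid-reference."""

    data: pd.DataFrame  # columns: country, site, birth_year, orphans
    ref_year: int
    scenario: ScenarioConfig
    excluded_countries: list[str] = field(default_factory=list)

    def total(self) -> float:
        return float(self.data["orphans"].sum())

    def totals_by_country(self) -> pd.Series:
        return self.data.groupby("country")["orphans"].sum()

    def totals_by_site(self) -> pd.Series:
        return self.data.groupby("site")["orphans"].sum()

    def by_birth_year(self) -> pd.Series:
        return self.data.groupby("birth_year")["orphans"].sum()

    def to_long_csv(self, path) -> None:
        out = self.data.copy()
        out["ref_year"] = self.ref_year
        out["child_age_at_ref"] = self.ref_year - out["birth_year"] - 0.5
        out["scenario"] = self.scenario.name
        out.to_csv(path, index=False)


def estimate_prevalent_orphans(
    bundle: WorldBundle,
    scenario: ScenarioConfig = ScenarioConfig(),
    ref_year: int | None = None,
    rr_table: ParityRRTable = DEFAULT_PARITY_RR,
) -> PrevalenceResult:
    """Accumulate surviving, still-minor orphans from death years ref-17..ref-1.

    For each death year ``yd`` and maternal age ``md`` (15..67), historic
    single-age deaths are multiplied by the inner fertility x survival sum over
    child birth years ``y`` up to and including ``yd`` (mother's age at birth
    ``md - (yd - y)``), with the bereavement-adjusted probability the child is
    alive and under 18 at mid-reference.  Children born 18+ years before the
    reference contribute zero.

    ``include_ref_year_half`` additionally counts half of the reference year's
    own new orphans (deaths up to mid-reference).
    """
    ref_year = bundle.ref_year if ref_year is None else ref_year
    mrr = scenario.mrr_value
    mds = np.arange(MIN_ORPHANING_AGE, MAX_ORPHANING_AGE + 1)  # 15..67
    yds = np.arange(ref_year - 17, ref_year)  # ref-17 .. ref-1
    ys = np.arange(ref_year - 18, ref_year)  # child birth years

    # historic death tables once per yd (site x band matrices per country inside)
    excluded: list[str] = []
    hist: dict[int, DeathTable] = {}
    for yd in yds:
        hist[int(yd)] = historic_deaths(bundle, scenario.trend, int(yd), ref_year)
    band_idx = np.minimum(mds // 5, 17)

    frames = []
    for country in bundle.countries:
        if scenario.trend == "S4" and bundle.country_meta.category_of(country) == "missing":
            excluded.append(country)
            continue
        grids = CountryGrids.build(bundle.fertility, bundle.child_mortality, country)
        u = grids.under18_matrix(mrr, ref_year)  # [y, yd]

        # FR[md, yd, y]: mother's age at birth = md - (yd - y), zero outside 15-49
        ma = mds[:, None, None] - (yds[None, :, None] - ys[None, None, :])
        valid = ys[None, None, :] <= yds[None, :, None]
        fr = grids.fert_at(ma, np.broadcast_to(ys[None, None, :], ma.shape)) * valid

        inner = np.einsum("mdy,yd->mdy", fr, u)  # keep the birth-year decomposition
        # single-age historic deaths [site, md, yd]
        site_index = None
        d_single = None
        for j, yd in enumerate(yds):
            mat = hist[int(yd)].band_matrix(country)
            if d_single is None:
                site_index = mat.index
                d_single = np.zeros((len(site_index), mds.size, yds.size))
            d_single[:, :, j] = mat.to_numpy()[:, band_idx] / 5.0
        rr = np.stack([_rr_vector(rr_table, site, mds) for site in site_index])  # [site, md]
        orphans_sy = np.einsum("sm,smd,mdy->sy", rr, d_single, inner)

        nz_s, nz_y = np.nonzero(orphans_sy)
        if nz_s.size:
            frames.append(
                pd.DataFrame(
                    {
                        "country": country,
                        "site": np.asarray(site_index)[nz_s],
                        "birth_year": ys[nz_y],
                        "orphans": orphans_sy[nz_s, nz_y],
                    }
                )
            )

    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(columns=["country", "site", "birth_year", "orphans"])

    if scenario.include_ref_year_half:
        new = estimate_new_orphans(bundle, ref_year=ref_year, rr_table=rr_table)
        half = (
            new.data.groupby(["country", "site", "birth_year"], as_index=False)["orphans"].sum()
        )
        half["orphans"] *= 0.5
        data = (
            pd.concat([data, half], ignore_index=True)
            .groupby(["country", "site", "birth_year"], as_index=False)["orphans"]
            .sum()
        )

    return PrevalenceResult(data=data, ref_year=ref_year, scenario=scenario, excluded_countries=excluded)


def sensitivity_grid(
    bundle: WorldBundle,
    trends: tuple[str, ...] = TRENDS,
    mrr_labels: tuple[str, ...] = ("a", "b", "c", "d", "e"),
    ref_year: int | None = None,
    rr_table: ParityRRTable = DEFAULT_PARITY_RR,
) -> pd.DataFrame:
    """Global prevalent-orphan total for each (trend, MRR) combination.

    Returns a DataFrame with columns trend, mrr_label, mrr_value, total and
    pct_dev_from_S1a (percent deviation from the S1a total when S1a is in the
    grid, else from the first combination).
    """
    rows = []
    for trend in trends:
        for label in mrr_labels:
            sc = ScenarioConfig(trend=trend, mrr_label=label)
            total = estimate_prevalent_orphans(bundle, sc, ref_year, rr_table).total()
            rows.append({"trend": trend, "mrr_label": label, "mrr_value": sc.mrr_value, "total": total})
    df = pd.DataFrame(rows)
    base_rows = df[(df["trend"] == "S1") & (df["mrr_label"] == "a")]
    base = float(base_rows["total"].iloc[0]) if len(base_rows) else float(df["total"].iloc[0])
    df["pct_dev_from_S1a"] = 100.0 * (df["total"] - base) / base if base else np.nan
    df.attrs["min"] = float(df["total"].min())
    df.attrs["max"] = float(df["total"].max())
    return df
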