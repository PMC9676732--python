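"""Synthetic world bundles and a microsimulation oracle.

The generator emulates the structure of the real inputs — GLOBOCAN-style
female cancer deaths on 5-year bands for 35 sites, UN-WPP-style cohort
fertility on the 5x5 grid, single-age child lifetable hazards, female and
child populations, and an HDI hierarchy — without imitating any real
country's magnitudes.  Its defaults describe a small three-country world
spanning the global range of the quantities that drive orphanhood: total
fertility from 1.6 to 5.0 births per woman, infant mortality from 4 to 40
per 1,000, and log-normal cancer mortality age curves peaking at ages 55-68
for four active sites (breast, cervix, ovary, lung).

The microsimulation draws individual women by birth cohort, realizes their
births as Bernoulli woman-year events with probability equal to the fertility
rate, their cancer death from the configured age-specific rates, and their
children's survival from the annual hazards (times the bereavement MRR after
a maternal death).  It is the independent oracle the analytic estimators are
validated against: under the generator's independence assumptions the two
must agree within Monte-Carlo error.

An optional parity-dependence mechanism makes a site's death hazard depend on
the woman's realized number of births (a per-birth multiplicative factor,
calibrated so the fertility of decedents is a chosen multiple of their
cohort's); this reproduces the bias the analytic RR_t correction removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ages import BAND_LABELS, FERTILE_MIN, band_bounds, period_label
from .demography import CountryGrids
from .errors import ValidationError
from .prevalence_estimator import trend_multiplier
from .sites import SITES
from .tables_io import (
    ChildMortalityTable,
    CountryMeta,
    DeathTable,
    FertilitySchedule,
    PopulationTable,
    WorldBundle,
    assemble_bundle,
    write_death_table,
    write_fertility_table,
)

_FERT_BANDS = [f"{lo}-{lo + 4}" for lo in range(15, 50, 5)]

#: Child-mortality age profile relative to the infant hazard.
_CHILD_PROFILE = np.array([1.0] + [0.15] * 4 + [0.05] * 5 + [0.04] * 5 + [0.06] * 3)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic world (all rates per woman per year).

    Per-country parameters are cycled from the tuples below across
    ``n_countries``; a seeded multiplicative log-normal jitter of relative
    width ``jitter`` individualizes countries drawn beyond the tuples.
    """

    n_countries: int = 3
    ref_year: int = 2020
    seed: int = 0
    # fertility: total fertility rate and a Gaussian age pattern (peak, spread)
    tfr: tuple[float, ...] = (5.0, 2.4, 1.6)
    fert_peak: tuple[float, ...] = (26.0, 29.0, 31.0)
    fert_spread: tuple[float, ...] = (7.0, 6.0, 5.5)
    # cancer mortality: active sites with peak-age rate (per woman-year),
    # log-normal age curve peak and log-sd
    active_sites: tuple[str, ...] = ("Breast", "Cervix uteri", "Ovary", "Trachea, bronchus and lung")
    site_peak_rate: tuple[float, ...] = (6e-4, 3.5e-4, 1.5e-4, 4e-4)
    site_peak_age: tuple[float, ...] = (62.0, 55.0, 65.0, 68.0)
    site_log_sd: float = 0.35
    # child mortality: infant hazard per country (profile above scales ages 1-17)
    infant_hazard: tuple[float, ...] = (0.040, 0.012, 0.004)
    # female population per 5-year band at age 0, with exponential decline in age
    women_per_band: tuple[float, ...] = (400_000.0, 300_000.0, 200_000.0)
    pop_age_slope: float = 0.012
    growth_rate: float = 0.0
    hdi: tuple[float | None, ...] = (0.47, 0.66, 0.86)
    jitter: float = 0.10
    # parity-cancer dependence: per-birth multiplicative death-hazard mechanism
    parity_site: str | None = None
    parity_rr_target: float | None = None
    # grid extents (fertility periods start / child-mortality years start)
    fertility_start_year: int = 2000
    mortality_start_year: int = 2002
    rate_cap: float = 0.5

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValidationError("n_countries must be >= 1")
        for name in ("tfr", "site_peak_rate", "infant_hazard", "women_per_band"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValidationError(f"negative values in {name}")
        unknown = set(self.active_sites) - set(SITES)
        if unknown:
            raise ValidationError(f"active sites outside the vocabulary: {sorted(unknown)}")
        if (self.parity_site is None) != (self.parity_rr_target is None):
            raise ValidationError("parity_site and parity_rr_target must be set together")
        if self.parity_site is not None and self.parity_site not in self.active_sites:
            raise ValidationError("parity_site must be one of the active sites")

    def country_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_countries)]


def _cycle(values: tuple, i: int):
    return values[i % len(values)]


def _country_params(config: SyntheticConfig, seed: int) -> dict[str, dict]:
    """Realized per-country parameters (cycled defaults x seeded jitter)."""
    rng = np.random.default_rng(seed)
    params: dict[str, dict] = {}
    for i, cid in enumerate(config.country_ids()):
        j = math.exp(rng.normal(0.0, config.jitter)) if config.jitter > 0 else 1.0
        jm = math.exp(rng.normal(0.0, config.jitter)) if config.jitter > 0 else 1.0
        params[cid] = {
            "tfr": _cycle(config.tfr, i) * j,
            "fert_peak": _cycle(config.fert_peak, i),
            "fert_spread": _cycle(config.fert_spread, i),
            "site_scale": jm,
            "infant_hazard": _cycle(config.infant_hazard, i),
            "women_per_band": _cycle(config.women_per_band, i),
            "hdi": _cycle(config.hdi, i),
        }
    return params


def make_world(
    config: SyntheticConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> WorldBundle:
    """Build a synthetic WorldBundle; optionally write the five CSV fixtures.

    The realized per-country parameters are recorded in
    ``bundle.report["synthetic_params"]``.  With a fixed seed the bundle and
    the files are bit-identical across calls.
    """
    seed = config.seed if seed is None else seed
    params = _country_params(config, seed)
    ref = config.ref_year
    countries = config.country_ids()

    # --- population ----------------------------------------------------------
    years = list(range(config.mortality_start_year, ref + 1))
    pop_rows = []
    child_pop: dict[str, float] = {}
    for cid in countries:
        p = params[cid]
        base = {
            band: p["women_per_band"] * math.exp(-config.pop_age_slope * (band_bounds(band)[0] + 2.5))
            for band in BAND_LABELS
        }
        for year in years:
            g = (1.0 + config.growth_rate) ** (year - ref)
            for band in BAND_LABELS:
                pop_rows.append((cid, "female", band, year, base[band] * g))
        child_pop[cid] = 2.0 * (base["0-4"] + base["5-9"] + base["10-14"] + 0.6 * base["15-19"])
        pop_rows.append((cid, "both", "0-17", ref, child_pop[cid]))
    population = PopulationTable(
        pd.DataFrame(pop_rows, columns=["country", "sex", "age_group", "year", "count"])
    )

    # --- fertility (stationary across periods) -------------------------------
    fert_rows = []
    period_starts = list(range(config.fertility_start_year, 2019, 5))
    for cid in countries:
        p = params[cid]
        mids = np.array([band_bounds(b)[0] + 2.0 for b in _FERT_BANDS])
        shape = np.exp(-((mids - p["fert_peak"]) ** 2) / (2.0 * p["fert_spread"] ** 2))
        denom = 5.0 * shape.sum()
        rates = p["tfr"] * shape / denom if denom > 0 else np.zeros_like(shape)
        rates = np.minimum(rates, config.rate_cap)
        for start in period_starts:
            for band, rate in zip(_FERT_BANDS, rates):
                fert_rows.append((cid, band, period_label(start), rate))
    fertility = FertilitySchedule(
        pd.DataFrame(fert_rows, columns=["country", "age_group", "period", "rate"])
    )

    # --- cancer deaths (reference year, all 35 sites, 18 bands) --------------
    death_rows = []
    site_curves = {
        site: (rate, peak)
        for site, rate, peak in zip(config.active_sites, config.site_peak_rate, config.site_peak_age)
    }
    for cid in countries:
        p = params[cid]
        fem = population.female_bands(cid, ref)
        for site in SITES:
            for band in BAND_LABELS:
                lo, hi = band_bounds(band)
                mid = lo + 2.5 if hi is not None else 87.5
                if site in site_curves:
                    level, peak = site_curves[site]
                    rate = (
                        level
                        * p["site_scale"]
                        * math.exp(-(math.log(mid / peak) ** 2) / (2.0 * config.site_log_sd**2))
                    )
                else:
                    rate = 0.0
                death_rows.append((cid, site, band, rate * fem[band]))
    deaths = DeathTable(
        pd.DataFrame(death_rows, columns=["country", "site", "age_group", "deaths"]), year=ref
    )

    # --- child mortality ------------------------------------------------------
    cm_rows = []
    for cid in countries:
        hz = params[cid]["infant_hazard"] * _CHILD_PROFILE
        for year in range(config.mortality_start_year, ref + 1):
            for age in range(18):
                cm_rows.append((cid, age, year, hz[age]))
    child_mortality = ChildMortalityTable(
        pd.DataFrame(cm_rows, columns=["country", "age", "year", "rate"])
    )

    # --- metadata -------------------------------------------------------------
    meta_rows = []
    for i, cid in enumerate(countries):
        region = f"Region {chr(ord('A') + i % 2)}"
        meta_rows.append(
            (cid, f"Country {i + 1}", region, f"Subregion {region[-1]}{i // 2 + 1}", params[cid]["hdi"])
        )
    meta = CountryMeta(
        pd.DataFrame(meta_rows, columns=["country", "name", "region", "subregion", "hdi"])
    )

    bundle = assemble_bundle(deaths, fertility, child_mortality, population, meta)
    bundle.report["synthetic_params"] = params
    bundle.report["seed"] = seed

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_death_table(deaths, out / "deaths.csv")
        write_fertility_table(fertility, out / "fertility.csv")
        child_mortality.data.to_csv(out / "child_mortality.csv", index=False, float_format="%.17g")
        population.data.to_csv(out / "population.csv", index=False, float_format="%.17g")
        meta.data[["country", "name", "region", "subregion", "hdi"]].to_csv(
            out / "country_meta.csv", index=False, float_format="%.17g"
        )
    return bundle


# ---------------------------------------------------------------------------
# parity-dependence calibration
# ---------------------------------------------------------------------------


def calibrate_parity_factor(birth_probs: np.ndarray, rr_target: float) -> tuple[float, float]:
    """Per-birth death-hazard factor phi reproducing a decedent fertility ratio.

    With independent Bernoulli births at probabilities ``p_i`` and a death
    hazard proportional to ``phi**K`` (K = number of births), decedents'
    expected births are ``sum_i phi p_i / (1 - p_i + phi p_i)`` against a
    cohort mean of ``sum_i p_i``; phi solves ratio = ``rr_target``.  Returns
    ``(phi, achieved_ratio)`` — the achieved ratio is reported, not assumed.
    """
    p = np.asarray(birth_probs, dtype=float)
    total = p.sum()
    if total <= 0:
        return 1.0, 1.0

    def ratio(phi: float) -> float:
        return float((phi * p / (1.0 - p + phi * p)).sum() / total)

    if abs(rr_target - 1.0) < 1e-12:
        return 1.0, 1.0
    phi = brentq(lambda f: ratio(f) - rr_target, 1e-4, 1e4, xtol=1e-12)
    return float(phi), ratio(float(phi))


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """A microsimulation estimate with its Monte-Carlo standard error."""

    count: float
    se: float
    n_women: int
    by_age_bin: dict[str, float] = field(default_factory=dict)
    block_estimates: np.ndarray | None = None

    def z_against(self, analytic: float) -> float:
        """Standardized deviation of an analytic estimate from the oracle."""
        return (analytic - self.count) / self.se if self.se > 0 else float("inf")


def _bin_label(child_age: float) -> str:
    if child_age < 5:
        return "u5"
    if child_age < 10:
        return "5_9"
    return "10_17"


def _site_rates(bundle: WorldBundle, country: str) -> tuple[pd.Index, np.ndarray]:
    """Per-woman single-age death rates [site, md 15..67] at the reference year."""
    mat = bundle.deaths.band_matrix(country)
    fem = bundle.population.female_bands(country, bundle.ref_year).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        band_rates = np.where(fem > 0, mat.to_numpy() / fem, 0.0)
    mds = np.arange(15, 68)
    return mat.index, band_rates[:, np.minimum(mds // 5, 17)]


def _fem_single(bundle: WorldBundle, country: str, year: int) -> np.ndarray:
    """Female population per single age md 15..67 (band/5)."""
    fem = bundle.population.female_bands(country, year).to_numpy()
    mds = np.arange(15, 68)
    return fem[np.minimum(mds // 5, 17)] / 5.0


def microsim_new_orphans(
    config: SyntheticConfig,
    n_women: int = 200_000,
    seed: int = 0,
    bundle: WorldBundle | None = None,
    n_blocks: int = 10,
) -> MicrosimResult:
    """Individual-level oracle for the new-orphan estimator.

    Per country, women are simulated in equal numbers for each birth cohort
    that reaches ages 15-67 in the reference year, weighted by the cohort's
    female population; births over the 18 preceding years are Bernoulli
    woman-year events, children survive with the lifetable hazards, and the
    mother dies in the reference year with the configured age-specific rates.
    Children under 18 at the death are counted and scaled to the population.
    Standard errors come from ``n_blocks`` independent replicate blocks.
    """
    if bundle is None:
        bundle = make_world(config)
    ref = bundle.ref_year
    rng = np.random.default_rng(seed)
    mds = np.arange(15, 68)
    years = np.arange(ref - 18, ref)
    n_b = max(n_blocks, (n_women // mds.size // n_blocks) * n_blocks)
    block_tot = np.zeros(n_blocks)
    bins = {b: 0.0 for b in ("u5", "5_9", "10_17")}
    total_women = 0

    phi_target = None
    if config.parity_site is not None:
        phi_target = config.parity_rr_target

    for country in bundle.countries:
        grids = CountryGrids.build(bundle.fertility, bundle.child_mortality, country)
        site_index, rates = _site_rates(bundle, country)  # [site, md]
        fem_single = _fem_single(bundle, country, ref)
        surv = grids.survival_vector(ref)  # per birth year
        # birth probabilities per cohort [md, y]
        ma = mds[:, None] - (ref - years[None, :])
        p_mat = np.minimum(grids.fert_at(ma, np.broadcast_to(years[None, :], ma.shape)), config.rate_cap)

        ps_idx = None
        if config.parity_site is not None and config.parity_site in site_index:
            ps_idx = list(site_index).index(config.parity_site)

        for m, md in enumerate(mds):
            p = p_mat[m]
            births = rng.random((n_b, years.size)) < p[None, :]
            total_women += n_b
            d_other = rates[:, m].sum() - (rates[ps_idx, m] if ps_idx is not None else 0.0)
            if ps_idx is not None and rates[ps_idx, m] > 0:
                phi, _ = calibrate_parity_factor(p, phi_target)
                z_norm = float(np.prod(1.0 - p + phi * p))
                k = births.sum(axis=1)
                d = d_other + rates[ps_idx, m] * phi**k / z_norm
            else:
                d = np.full(n_b, d_other + (rates[ps_idx, m] if ps_idx is not None else 0.0))
            dead = rng.random(n_b) < d
            idx = np.nonzero(dead)[0]
            if idx.size == 0:
                continue
            alive = births[idx] & (rng.random((idx.size, years.size)) < surv[None, :])
            w = fem_single[m] / n_b
            per_year = alive.sum(axis=0) * w
            for y, v in zip(years, per_year):
                bins[_bin_label(ref - y - 0.5)] += float(v)
            np.add.at(block_tot, idx % n_blocks, alive.sum(axis=1) * w)

    est = n_blocks * block_tot
    return MicrosimResult(
        count=float(est.mean()),
        se=float(est.std(ddof=1) / math.sqrt(n_blocks)),
        n_women=total_women,
        by_age_bin=bins,
        block_estimates=est,
    )


def microsim_prevalent(
    config: SyntheticConfig,
    n_women: int = 200_000,
    seed: int = 0,
    mrr: float = 1.25,
    trend: str = "S1",
    bundle: WorldBundle | None = None,
    n_blocks: int = 10,
) -> MicrosimResult:
    """Individual-level oracle for the prevalent-orphan estimator.

    Maternal deaths are drawn independently for each historic year with the
    trend-scaled age-specific rates; children alive and still under 18 at the
    mid-reference are counted, with hazards multiplied by ``mrr`` after the
    maternal death.
    """
    if bundle is None:
        bundle = make_world(config)
    ref = bundle.ref_year
    rng = np.random.default_rng(seed)
    yds = np.arange(ref - 17, ref)
    ys = np.arange(ref - 18, ref)
    cohorts = np.arange(yds.min() - 67, yds.max() - 15 + 1)  # reach 15-67 in some yd
    n_b = max(n_blocks, (n_women // cohorts.size // n_blocks) * n_blocks)
    block_tot = np.zeros(n_blocks)
    bins = {b: 0.0 for b in ("u5", "5_9", "10_17")}
    total_women = 0

    for country in bundle.countries:
        cat = bundle.country_meta.category_of(country)
        if trend == "S4" and cat == "missing":
            continue
        grids = CountryGrids.build(bundle.fertility, bundle.child_mortality, country)
        site_index, rates = _site_rates(bundle, country)  # [site, md 15..67]
        rate_total = rates.sum(axis=0)
        u = grids.under18_matrix(mrr, ref)  # [y (ref-18..ref-1), yd (ref-17..ref-1)]

        ps_idx = None
        if config.parity_site is not None and config.parity_site in site_index:
            ps_idx = list(site_index).index(config.parity_site)

        for b in cohorts:
            ages = ys - b
            with np.errstate(invalid="ignore"):
                p = np.where(
                    (ages >= FERTILE_MIN) & (ages <= 49),
                    grids.fert_at(np.clip(ages, FERTILE_MIN, 49), ys),
                    0.0,
                )
            p = np.minimum(p, config.rate_cap)
            births = rng.random((n_b, ys.size)) < p[None, :]
            total_women += n_b
            phi = z_norm = None
            if ps_idx is not None:
                phi, _ = calibrate_parity_factor(p, config.parity_rr_target)
                z_norm = float(np.prod(1.0 - p + phi * p))
                k = births.sum(axis=1)
            for j, yd in enumerate(yds):
                md = yd - b
                if not 15 <= md <= 67:
                    continue
                mult = trend_multiplier(trend, int(yd), cat, ref)
                base = rate_total[md - 15]
                if ps_idx is not None and rates[ps_idx, md - 15] > 0 and phi is not None:
                    base = base - rates[ps_idx, md - 15] + rates[ps_idx, md - 15] * phi**k / z_norm
                dead = rng.random(n_b) < mult * base
                idx = np.nonzero(dead)[0]
                if idx.size == 0:
                    continue
                uy = u[:, j]  # P(alive & U18 | born y, died yd)
                eligible = births[idx] & (ys[None, :] <= yd)
                alive = eligible & (rng.random((idx.size, ys.size)) < uy[None, :])
                fem = _fem_single(bundle, country, int(yd))
                w = fem[md - 15] / n_b
                per_year = alive.sum(axis=0) * w
                for y, v in zip(ys, per_year):
                    bins[_bin_label(ref - y - 0.5)] += float(v)
                np.add.at(block_tot, idx % n_blocks, alive.sum(axis=1) * w)

    est = n_blocks * block_tot
    return MicrosimResult(
        count=float(est.mean()),
        se=float(est.std(ddof=1) / math.sqrt(n_blocks)),
        n_women=total_women,
        by_age_bin=bins,
        block_estimates=est,
    )
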