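"""New maternal orphans due to cancer in the reference year.

For each country ``c``, site ``t`` and single maternal age at death ``md`` the
expected number of newly orphaned (minor) children is

    NMC(c, t, md) = D(c, t, md) * A(c, md, t)

where ``D`` is the single-age death count (5-year band totals split uniformly)
and ``A`` is the per-woman expected number of living children under 18 at the
mother's death, convolving the cohort's fertility history over the 18 birth
years preceding the reference year with child survival:

    A(c, md, t) = sum_{y = ref-18}^{ref-1} RR_t * FR(c, y, md - (ref - y))
                                         * P(alive at mid ref | born y).

Deaths at ages 68+ cannot leave minor children (fertility ends at 49), so the
estimator runs over ``md`` 15..67 only.  The result retains the child-birth-
year decomposition: the child's age at orphaning is ``ref - y - 0.5`` under
the mid-period birth convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import FERTILE_MAX, FERTILE_MIN, MAX_ORPHANING_AGE, band_ages
from .demography import DEFAULT_PARITY_RR, CountryGrids, ParityRRTable
from .tables_io import DeathTable, WorldBundle

MIN_ORPHANING_AGE = 15


@dataclass
class SingleAgeDeaths:
    """Deaths spread uniformly over the five single ages of each band.

    ``contributing`` flags ages that can give rise to maternal orphans
    (15 <= md <= 67); the 85+ band is represented as ages 85-89, all
    non-contributing.
    """

    data: pd.DataFrame  # columns: country, site, md, deaths, contributing


def split_deaths_single_age(dt: DeathTable) -> SingleAgeDeaths:
    """Uniform within-band split: each band's deaths divided by five.

    Band totals are conserved exactly (each single age gets deaths/5).
    """
    rows = {"country": [], "site": [], "md": [], "deaths": []}
    for _, r in dt.data.iterrows():
        for a in band_ages(r["age_group"]):
            rows["country"].append(r["country"])
            rows["site"].append(r["site"])
            rows["md"].append(a)
            rows["deaths"].append(r["deaths"] / 5.0)
    df = pd.DataFrame(rows)
    df["contributing"] = df["md"].between(MIN_ORPHANING_AGE, MAX_ORPHANING_AGE)
    return SingleAgeDeaths(df)


@dataclass
class OrphanArray:
    """Expected new orphans by country x site x maternal age at death x child
    birth year, for one reference year."""

    data: pd.DataFrame  # columns: country, site, md, birth_year, orphans
    ref_year: int
    rr_table: ParityRRTable = field(default=DEFAULT_PARITY_RR, repr=False)

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
        out.to_csv(path, index=False)


def _rr_vector(rr_table: ParityRRTable, site: str, mds: np.ndarray) -> np.ndarray:
    return np.array([rr_table.factor(site, int(md)) for md in mds])


def expected_minor_children(
    bundle: WorldBundle,
    country: str,
    md: int,
    site: str,
    ref_year: int = 2020,
    rr_table: ParityRRTable = DEFAULT_PARITY_RR,
) -> pd.Series:
    """Per-woman expected surviving minor children, decomposed by birth year.

    Returns a Series indexed by child birth year (ref-18 .. ref-1); all-zero
    when the maternal age at death is outside 15..67 or the mother's age at a
    birth year falls outside 15-49.
    """
    years = np.arange(ref_year - 18, ref_year)
    if not MIN_ORPHANING_AGE <= md <= MAX_ORPHANING_AGE:
        return pd.Series(0.0, index=years, name="expected_children")
    grids = CountryGrids.build(bundle.fertility, bundle.child_mortality, country)
    ma = md - (ref_year - years)  # mother's age in each birth year
    fr = grids.fert_at(ma, years)
    surv = grids.survival_vector(ref_year)
    rr = rr_table.factor(site, md)
    return pd.Series(rr * fr * surv, index=years, name="expected_children")


def estimate_new_orphans(
    bundle: WorldBundle,
    ref_year: int = 2020,
    rr_table: ParityRRTable = DEFAULT_PARITY_RR,
    include_ref_year_births: bool = False,
) -> OrphanArray:
    """Expected new maternal orphans for the reference year.

    ``include_ref_year_births`` extends the birth-year sum to the reference
    year itself (a child born in the year of the mother's death, counted with
    survival 1); off by default — the standard accounting ends the cohort's
    fertility history the year before the reference year.  The option exists
    so prevalence accounting, which does include death-year births, can be
    cross-checked against sums of per-year new-orphan runs.
    """
    mds = np.arange(MIN_ORPHANING_AGE, MAX_ORPHANING_AGE + 1)  # 15..67
    years = np.arange(ref_year - 18, ref_year + (1 if include_ref_year_births else 0))
    frames = []
    for country in bundle.countries:
        grids = CountryGrids.build(bundle.fertility, bundle.child_mortality, country)
        ma = mds[:, None] - (ref_year - years[None, :])  # [md, y]
        fr = grids.fert_at(ma, np.broadcast_to(years[None, :], ma.shape))
        surv18 = grids.survival_vector(ref_year)
        surv = np.concatenate([surv18, [1.0]]) if include_ref_year_births else surv18
        base = fr * surv[None, :]  # [md, y] per-woman children, before RR

        mat = bundle.deaths.band_matrix(country)  # site x 18 bands
        # single-age deaths for md 15..67: band index of each md, divided by 5
        band_idx = np.minimum(mds // 5, 17)
        d_single = mat.to_numpy()[:, band_idx] / 5.0  # [site, md]
        for s_i, site in enumerate(mat.index):
            rr = _rr_vector(rr_table, site, mds)
            orphans = (d_single[s_i] * rr)[:, None] * base  # [md, y]
            nz_md, nz_y = np.nonzero(orphans)
            if nz_md.size == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "country": country,
                        "site": site,
                        "md": mds[nz_md],
                        "birth_year": years[nz_y],
                        "orphans": orphans[nz_md, nz_y],
                    }
                )
            )
    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(columns=["country", "site", "md", "birth_year", "orphans"])
    return OrphanArray(data=data, ref_year=ref_year, rr_table=rr_table)
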