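"""Primitive demographic rates and survival probabilities.

Conventions shared by both orphan estimators:

* Fertility is a step function on the 5-year age x 5-year period grid; zero
  outside ages 15-49 inclusive.  No interpolation, no extrapolation beyond the
  period grid.
* Child mortality hazards ``Mx`` are annual cumulative-hazard increments: the
  probability a child born in year ``y`` is alive at mid reference year ``R``
  is ``exp(-sum_{x=0}^{R-1-y} Mx(age=x, year=y+x))`` — the hazard at age ``x``
  is read in calendar year ``y + x``, and exposure stops with the year before
  the reference year (mid-year birth cohorts).  No actuarial a(x) correction.
* After a maternal death in year ``yd``, a child's remaining hazards are
  multiplied by a bereavement mortality rate ratio ``mrr`` (>= 1): ages
  ``0..yd-y`` carry the baseline hazard, ages ``yd-y+1 .. R-1-y`` carry
  ``mrr * Mx``.  With ``mrr = 1`` this collapses onto the plain survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ages import FERTILE_MAX, FERTILE_MIN
from .errors import ValidationError
from .sites import normalize_site
from .tables_io import ChildMortalityTable, FertilitySchedule

# ---------------------------------------------------------------------------
# parity-cancer-risk corrections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParityRule:
    """Multiplicative fertility correction for one site.

    ``min_age_exclusive`` restricts the rule to maternal ages at death strictly
    above that age (the postmenopausal breast-cancer correction).
    """

    site: str
    factor: float
    min_age_exclusive: int | None = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValidationError(f"parity RR must be positive, got {self.factor}")


@dataclass(frozen=True)
class ParityRRTable:
    """Site-specific relative risks of parity; factor 1 for unlisted sites.

    Defaults encode the established parity-risk associations: cervical cancer
    RR 1.1, ovarian cancer RR 0.80, and breast cancer RR 0.93 applied only to
    deaths over age 50 (parity is at most weakly protective premenopausally).
    """

    rules: tuple[ParityRule, ...] = (
        ParityRule("Cervix uteri", 1.1),
        ParityRule("Ovary", 0.80),
        ParityRule("Breast", 0.93, min_age_exclusive=50),
    )

    def factor(self, site: str, maternal_age_at_death: int) -> float:
        site = normalize_site(site)
        for rule in self.rules:
            if rule.site == site:
                if rule.min_age_exclusive is not None and maternal_age_at_death <= rule.min_age_exclusive:
                    return 1.0
                return rule.factor
        return 1.0


DEFAULT_PARITY_RR = ParityRRTable()

#: Table with every factor 1 (no parity correction).
UNIT_PARITY_RR = ParityRRTable(rules=())


def parity_rr(table: ParityRRTable, site: str, maternal_age_at_death: int) -> float:
    """Fertility correction factor RR_t for a site and maternal age at death."""
    return table.factor(site, maternal_age_at_death)


# ---------------------------------------------------------------------------
# rate lookups
# ---------------------------------------------------------------------------


def fertility_rate(sched: FertilitySchedule, country: str, year: int, age: int) -> float:
    """Per-woman annual fertility rate at a single age and calendar year.

    Returns 0 outside ages 15-49; raises :class:`ValidationError` for years
    outside the schedule's period grid (no extrapolation).
    """
    if age < FERTILE_MIN or age > FERTILE_MAX:
        return 0.0
    grid, y0, y1 = sched.single_age_grid(country)
    if not y0 <= year <= y1:
        raise ValidationError(
            f"year {year} outside fertility grid {y0}-{y1} for country {country!r}"
        )
    return float(grid[age - FERTILE_MIN, year - y0])


def _hazard(mort: ChildMortalityTable, country: str, age: int, year: int) -> float:
    grid, y0, y1 = mort.hazard_grid(country)
    if not (0 <= age <= 17):
        raise ValidationError(f"child hazard requested at age {age} (outside 0-17)")
    if not y0 <= year <= y1:
        raise ValidationError(
            f"child mortality year {year} outside grid {y0}-{y1} for country {country!r}"
        )
    return float(grid[age, year - y0])


def survival_to_reference(
    mort: ChildMortalityTable, country: str, birth_year: int, ref_year: int
) -> float:
    """P(child born in ``birth_year`` is alive at mid ``ref_year``).

    ``exp(-sum_{x=0}^{ref_year-1-birth_year} Mx(age=x, year=birth_year+x))``.
    """
    if birth_year > ref_year - 1:
        raise ValidationError(f"birth year {birth_year} not before reference year {ref_year}")
    cum = 0.0
    for x in range(0, ref_year - birth_year):
        cum += _hazard(mort, country, x, birth_year + x)
    return math.exp(-cum)


def prob_under18_at_ref(
    mort: ChildMortalityTable,
    country: str,
    birth_year: int,
    death_year: int,
    mrr: float,
    ref_year: int = 2020,
) -> float:
    """P(child born in ``birth_year``, whose mother died in ``death_year``, is
    alive *and under 18* at mid ``ref_year``).

    Zero when ``ref_year - birth_year >= 18``.  Otherwise the child carries the
    baseline hazard through the year of the maternal death (ages ``0..yd-y``)
    and ``mrr`` times the baseline thereafter (ages ``yd-y+1 .. ref-1-y``).
    """
    if birth_year > death_year:
        raise ValidationError(f"birth year {birth_year} after maternal death year {death_year}")
    if ref_year - birth_year >= 18:
        return 0.0
    split = death_year - birth_year  # child's age in the year of maternal death
    cum = 0.0
    for x in range(0, ref_year - birth_year):
        h = _hazard(mort, country, x, birth_year + x)
        cum += h if x <= split else mrr * h
    return math.exp(-cum)


# ---------------------------------------------------------------------------
# vectorized per-country grids used by the estimators
# ---------------------------------------------------------------------------


@dataclass
class CountryGrids:
    """Precomputed numpy grids for one country (internal estimator plumbing)."""

    fert: np.ndarray  # [age 15..49, year fy0..fy1], per-woman rates
    fy0: int
    fy1: int
    haz: np.ndarray  # [age 0..17, year my0..my1]
    my0: int
    my1: int
    _surv_cache: dict[int, np.ndarray] = field(default_factory=dict)

    @classmethod
    def build(
        cls, fertility: FertilitySchedule, mortality: ChildMortalityTable, country: str
    ) -> "CountryGrids":
        fert, fy0, fy1 = fertility.single_age_grid(country)
        haz, my0, my1 = mortality.hazard_grid(country)
        return cls(fert=fert, fy0=fy0, fy1=fy1, haz=haz, my0=my0, my1=my1)

    def fert_at(self, ages: np.ndarray, years: np.ndarray) -> np.ndarray:
        """Vectorized fertility lookup; zero outside 15-49, error outside the grid."""
        ages = np.asarray(ages)
        years = np.asarray(years)
        inside = (ages >= FERTILE_MIN) & (ages <= FERTILE_MAX)
        if np.any(inside & ((years < self.fy0) | (years > self.fy1))):
            raise ValidationError(
                f"fertility lookup outside the period grid {self.fy0}-{self.fy1}"
            )
        out = np.zeros(np.broadcast(ages, years).shape)
        a = np.where(inside, ages - FERTILE_MIN, 0)
        y = np.where(inside, np.clip(years - self.fy0, 0, self.fy1 - self.fy0), 0)
        out[...] = np.where(inside, self.fert[a, y], 0.0)
        return out

    def survival_vector(self, ref_year: int) -> np.ndarray:
        """P(alive at mid ref) for birth years ref-18 .. ref-1 (length 18)."""
        if ref_year in self._surv_cache:
            return self._surv_cache[ref_year]
        births = np.arange(ref_year - 18, ref_year)
        out = np.empty(18)
        for i, y in enumerate(births):
            ages = np.arange(0, ref_year - y)
            years = y + ages
            if years.size and (years.min() < self.my0 or years.max() > self.my1):
                raise ValidationError(
                    f"child mortality years {years.min()}-{years.max()} outside grid "
                    f"{self.my0}-{self.my1}"
                )
            out[i] = math.exp(-self.haz[ages, years - self.my0].sum())
        self._surv_cache[ref_year] = out
        return out

    def under18_matrix(self, mrr: float, ref_year: int = 2020) -> np.ndarray:
        """u[y_idx, yd_idx]: P(alive and under 18 at mid ref | born y, mother died yd)
        for y in ref-18..ref-1 and yd in ref-17..ref-1; zero where y > yd or the
        child is 18+ at the reference."""
        births = np.arange(ref_year - 18, ref_year)
        deaths = np.arange(ref_year - 17, ref_year)
        u = np.zeros((births.size, deaths.size))
        for i, y in enumerate(births):
            if ref_year - y >= 18:
                continue
            ages = np.arange(0, ref_year - y)
            h = self.haz[ages, y + ages - self.my0]
            for j, yd in enumerate(deaths):
                if y > yd:
                    continue
                split = yd - y
                w = np.where(ages <= split, 1.0, mrr)
                u[i, j] = math.exp(-(w * h).sum())
        return u
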