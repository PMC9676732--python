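# Methods

## Estimand and model structure

A maternal orphan is a child under 18 whose mother has died; here the cause
of death is any malignancy, resolved into 35 exhaustive and mutually
exclusive topographic sites (collapsed to 14 groups for reporting).  Two
estimands are computed per country and site:

* **New orphans** in a reference year *R*: expected number of children under
  18 at their mother's cancer death during *R*.
* **Prevalent orphans** at mid-*R*: children still alive and under 18 at
  mid-*R* whose mother died of cancer in any year *R−17 … R−1*.

Both are expectation calculations on aggregate inputs, not simulations: death
counts × the per-woman expected number of surviving minor children, built
from the mother's birth-cohort fertility history and lifetable child
survival.  Everything is deterministic and linear in the death counts.

## Conventions and numerical choices

* **Single ages from 5-year bands.**  Deaths on bands (0–4 … 85+) are split
  uniformly (band/5) with no graduation; band totals are conserved exactly.
  The open 85+ band is carried as ages 85–89 but flagged non-contributing —
  no maternal age at death above 67 can leave a minor child, because
  fertility ends at 49.
* **Fertility** is a step function on the 5-year age × 5-year period grid
  (no interpolation; none of the standard demographic smoothing rules is
  obviously superior on a 5×5 grid, and a step function keeps the estimator
  exactly linear in the published cells).  Rates are per woman per year,
  zero outside ages 15–49 inclusive; lookups outside the period grid raise
  rather than extrapolate.
* **Child survival** treats the lifetable rates as annual cumulative-hazard
  increments: `P(alive at R | born y) = exp(−Σ_{x=0}^{R-1-y} Mx(x, y+x))`,
  the hazard at age *x* read in calendar year *y+x*.  No actuarial a(x)
  correction is applied, and exposure ends with the year before the
  reference (mid-year cohorts); the death-year boundary is therefore
  half-open by convention, not by data.
* **Bereavement survival.**  After a maternal death in year *yd*, the
  child's remaining hazards (ages *yd−y+1 … R−1−y*) are multiplied by an
  excess-mortality ratio MRR; ages up to *yd−y* carry the baseline hazard.
  The post-death sum's upper limit is *R−1−y*, the unique choice under which
  MRR = 1 collapses exactly onto the plain survival probability.  Children
  with *R − y ≥ 18* contribute zero to prevalence.
* **Parity corrections RR_t** multiply cohort fertility for sites with
  established parity-risk associations: cervix 1.1, ovary 0.80, breast 0.93
  restricted to deaths over age 50 (premenopausal breast risk is at most
  weakly parity-associated).  All other sites use 1.
* **Age at orphaning** uses the mid-period convention: a child born in year
  *y* is *R − y − 0.5* years old at mid-*R*; reporting bins <5 / 5–9 / 10–17
  correspond to birth years *y ≥ R−5*, *R−10 ≤ y ≤ R−6* and
  *R−18 ≤ y ≤ R−11*.  This keeps the oldest birth cohort (*y = R−18*,
  age 17.5) inside the new-orphan accounting.
* **Boundary asymmetry between the estimators.**  New-orphan accounting ends
  the fertility history at *y = R−1*; prevalence counts births up to and
  including the death year (*y = yd*).  The asymmetry is preserved rather
  than harmonized; `estimate_new_orphans(..., include_ref_year_births=True)`
  exists solely so the cross-estimator identity (below) can be tested with
  matching conventions.
* **Historic deaths** for prevalence are reconstructed as reference-year
  age-specific rates × trend multiplier × historic female population, with
  the S4 scenario split on the country's HDI category at the reference
  (historic HDI is not modelled; countries without an HDI are excluded from
  S4 with a warning).  The trend multiplier applies uniformly across sites.
* **Aggregation** (region, subregion, HDI category, world, site group) sums
  counts and recomputes every ratio from aggregated numerators and
  denominators — never averages of member ratios.  Display rounding
  (integers for per-100/per-100k ratios, optional rounding of counts to the
  nearest thousand) is isolated in a formatting layer; stored values are
  full precision.

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| reference year | 2020 | year of the death table |
| maternal ages | 15–67 | single ages at death that can leave minors |
| parity RR (cervix, ovary, breast>50) | 1.1, 0.80, 0.93 | fertility multipliers |
| trend scenarios S1–S4 | S1 | multiplier on reference rates, per year back |
| MRR labels a–e | a | 1.25, 1.5, 2.0, 2.6, 1.0 × child hazard post-bereavement |
| `include_ref_year_half` | off | adds ½ of the reference year's new orphans to prevalence |

## The synthetic world and what passing tests show

The generator produces a three-country world whose parameters span the
global range of the drivers of orphanhood: total fertility 5.0 / 2.4 / 1.6
births per woman (Gaussian age pattern peaking at 26–31), infant hazards
40 / 12 / 4 per 1,000 (declining age profile to 17), stationary fertility
and constant population by default, and log-normal cancer-mortality age
curves for four active sites (breast, cervix, ovary, lung) peaking at ages
55–68 with peak rates 1.5–6 × 10⁻⁴ per woman-year; the remaining 31 sites
are present with zero deaths so the full vocabulary is exercised.  A seeded
±10% log-normal jitter individualizes countries; all outputs are bit-exact
functions of the seed.

The microsimulation oracle draws women by birth cohort (weighted by the
cohort's female population), realizes births as independent Bernoulli
woman-year events with probability equal to the fertility rate (capped at
0.5), child survival as annual Bernoulli events with probability
`exp(−Mx)` (times MRR-scaled hazards after a maternal death), and maternal
cancer deaths from the age-specific rates; standard errors come from 10
independent replicate blocks.  An optional parity mechanism multiplies a
woman's death hazard by φ per realized birth, with φ calibrated (by root
finding on the closed-form decedent-fertility ratio) so decedents' fertility
is a chosen multiple of their cohort's; the achieved ratio is reported, not
assumed.  This reproduces the bias the analytic RR_t correction removes, and
the tests verify the correction moves the analytic estimate onto the oracle.

Because the generator satisfies the analytic model's assumptions *exactly*
(independence of fertility and death except through the explicit parity
mechanism, hazard-consistent child survival, uniform within-band rates),
oracle agreement validates the estimator's arithmetic, not the model's
realism.  Features of real data the generator does not emulate: correlated
fertility and mortality across countries, non-stationary fertility, cohort
completion effects, migration, multiple births, fertility loss after cancer
diagnosis, and competing risks of child death.  Passing tests therefore say
nothing about those.

## Verified invariants

The suite asserts, among others: linearity in deaths; additivity over sites,
groups and countries; zero orphans from zero fertility or deaths at 68+;
monotonicity in fertility (up), child mortality (down) and MRR (down);
scenario ordering S3 ≥ S1 ≥ S2 per country; exact ×1.1 scaling of a site
under RR 1.1; and the cross-estimator identity — with stable rates, constant
population, zero child mortality and MRR 1, prevalence equals the sum over
death years of per-year new-orphan totals restricted to children still under
18 at the reference (to 10⁻⁹ relative).

## Problem sizes

The default validation world uses 3 countries, 4 active sites and 2×10⁵
simulated women per country, with 5 seeds in the acceptance tests; at this
size the full suite runs in well under a minute while keeping the oracle's
relative standard error below ~10%.  The analytic estimators themselves are
vectorized over (site × 53 maternal ages × 17 death years × 18 birth years)
per country and scale linearly in the number of countries.

## Known limitations

* Uniform within-band death splitting biases single-age rates where the true
  age curve is steep (ages 40–50); the published-table arithmetic is
  insensitive to this because ratios aggregate over bands.
* Prevalence inherits the reconstruction of historic deaths from a single
  reference year — the trend scenarios bound, but do not estimate, the
  history; the site split of prevalence is correspondingly weaker than that
  of new orphans.
* No uncertainty intervals are produced; the dominant uncertainty lives in
  the input death estimates, not in the convolution.
* Paternal orphans are out of scope (male fertility schedules are not
  modelled), as are downloads of the real input tables; inputs are assumed
  pre-aligned on a shared country identifier.
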