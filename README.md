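# cancer-orphans

Demographic estimation of **maternal orphans due to cancer**: children under
18 whose mother died of a malignancy.  The package is aimed at cancer
epidemiologists and demographers who want to turn routinely published
aggregate tables — female cancer deaths by country, site and 5-year age group;
cohort fertility schedules; child lifetables; population counts — into
country-, site- and age-resolved counts of newly and currently orphaned
children, without any individual-level data.

## The model

**New orphans.**  For a reference year *R* (default 2020), country *c*, cancer
site *t* and single maternal age at death *md* (15–67):

```
NMC(c,t,md) = D(c,t,md) · A(c,md,t)

A(c,md,t)   = Σ_{y=R-18}^{R-1}  RR_t · FR(c, y, md-(R-y)) · P_c(alive at R | y)

P_c(alive at R | y) = exp( − Σ_{x=0}^{R-1-y} Mx(c, x, y+x) )
```

`D` is the 5-year-band death count split uniformly over single ages;
`FR` is the per-woman fertility rate of the mother's birth cohort at the age
she had in calendar year *y* (zero outside 15–49); `Mx` is the child
mortality hazard at age *x* in year *y+x*; and `RR_t` corrects cohort
fertility for cancers whose risk depends on parity (cervix 1.1, ovary 0.80,
breast 0.93 for deaths over age 50).  Women dying at 68+ cannot leave minor
children, because fertility ends at 49.

**Prevalent orphans** at mid-*R* accumulate deaths over *yd = R−17 … R−1*,
reconstructed from the reference year's rates under trend scenarios
(S1 stable; S2 rates +1%/yr, so past rates were lower; S3 −1%/yr; S4 the S2
rule for low/medium-HDI and the S3 rule for high/very-high-HDI countries),
with each child's post-bereavement hazard multiplied by a mortality rate
ratio MRR ∈ {a:1.25, b:1.5, c:2.0, d:2.6, e:1.0} and children aged 18+ at
mid-*R* dropped.  The headline configuration is S1a.

**Validation.**  A synthetic-world generator emulates all five input tables,
and an individual-level microsimulation (Bernoulli woman-year births,
hazard-based child survival, age-specific maternal cancer death) provides an
independent oracle; the analytic estimators must agree with it within
Monte-Carlo error.  See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
import cancer_orphans as co

cfg = co.SyntheticConfig(seed=7)          # three-country synthetic world
bundle = co.make_world(cfg)               # or co.read_bundle(<five CSV paths>)

new = co.estimate_new_orphans(bundle)
prev = co.estimate_prevalent_orphans(bundle, co.ScenarioConfig())  # S1a

deaths = bundle.deaths.total_deaths()
children = sum(bundle.population.children_0_17(c, 2020) for c in bundle.countries)
print(round(new.total()), round(co.per_100_deaths(new.total(), deaths), 1),
      round(co.per_100k_children(new.total(), children), 1), round(prev.total()))
```

prints `3621 66.5 62.3 21925`: the 5,445 female cancer deaths of this
synthetic world leave 3,621 newly orphaned children in 2020 — 66.5 per 100
female cancer deaths, 62.3 per 100,000 children — and 21,925 children are
prevalent maternal orphans at mid-2020 under stable historic rates and a
1.25× bereavement hazard.  The high-fertility, high-mortality country C01
contributes 2,299 of the new orphans; breast (1,412) and cervix (1,275) are
the leading sites.

A `cancer-orphans` console script drives the same pipeline from the shell
(`synth`, `validate`, `estimate-new`, `estimate-prevalence`, `report`); all
outputs are plain CSV/JSON.

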