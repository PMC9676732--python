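"""Aggregate orphan arrays into publication-style summary tables.

Summary rows carry, per unit (country, subregion, region, world, HDI category
or site group): female cancer deaths, new orphans, orphans per 100 cancer
deaths in women, orphans per 100,000 children (both sexes, ages 0-17 at
mid-reference), the orphan age distribution (<5 / 5-9 / 10-17, row percent),
the mean age at orphaning, the deaths-weighted average age at cancer death
among ages 15-69, and the same quantities for prevalent orphans.

Ratios for aggregates are always ratio-of-sums (aggregate numerator over
aggregate denominator), never means of member ratios.  All stored values are
full precision; display rounding lives in :func:`format_display` only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .orphan_estimator import OrphanArray, SingleAgeDeaths, split_deaths_single_age
from .prevalence_estimator import PrevalenceResult
from .tables_io import WorldBundle

#: Child age bins at the reference, via the mid-period convention
#: (child age = ref - birth_year - 0.5): <5, 5-9, 10-17.
AGE_BINS = ("u5", "5_9", "10_17")


def per_100_deaths(orphans: float, deaths: float) -> float:
    """Orphans per 100 female cancer deaths; NaN when there are no deaths."""
    if deaths <= 0:
        return float("nan")
    return 100.0 * orphans / deaths


def per_100k_children(orphans: float, children: float) -> float:
    """Orphans per 100,000 children (both sexes, 0-17, mid-reference); NaN on
    a zero denominator."""
    if children <= 0:
        return float("nan")
    return 100000.0 * orphans / children


def _bin_of_birth_year(birth_year: int, ref_year: int) -> str:
    # mid-period ages: y >= ref-5 -> under 5; ref-10..ref-6 -> 5-9; else 10-17
    if birth_year >= ref_year - 5:
        return "u5"
    if birth_year >= ref_year - 10:
        return "5_9"
    return "10_17"


def age_distribution(arr: OrphanArray | PrevalenceResult) -> dict[str, float]:
    """Row-percent shares of orphans aged <5, 5-9 and 10-17 at the reference.

    Shares sum to 100 before any rounding; all-NaN for an empty array.
    """
    by_year = arr.by_birth_year()
    total = float(by_year.sum())
    if total <= 0:
        return {b: float("nan") for b in AGE_BINS}
    shares = {b: 0.0 for b in AGE_BINS}
    for y, v in by_year.items():
        shares[_bin_of_birth_year(int(y), arr.ref_year)] += float(v)
    return {b: 100.0 * v / total for b, v in shares.items()}


def mean_age_at_orphaning(arr: OrphanArray | PrevalenceResult) -> float:
    """Orphan-weighted mean child age at the reference (mid-period ages
    0.5, 1.5, ..., 17.5)."""
    by_year = arr.by_birth_year()
    total = float(by_year.sum())
    if total <= 0:
        return float("nan")
    ages = arr.ref_year - by_year.index.to_numpy() - 0.5
    return float((ages * by_year.to_numpy()).sum() / total)


def avg_age_at_death(deaths: SingleAgeDeaths, lo: int = 15, hi: int = 69) -> float:
    """Deaths-weighted mean single age at cancer death, restricted to ``lo..hi``.

    NaN when no deaths fall in the range.
    """
    sub = deaths.data[deaths.data["md"].between(lo, hi)]
    total = float(sub["deaths"].sum())
    if total <= 0:
        return float("nan")
    return float((sub["md"] * sub["deaths"]).sum() / total)


# ---------------------------------------------------------------------------
# country rows and aggregation
# ---------------------------------------------------------------------------

_COUNT_COLS = [
    "deaths",
    "new_orphans",
    "prevalent_orphans",
    "children",
    "deaths_15_69",
    "deaths_age_weight",
    "new_u5",
    "new_5_9",
    "new_10_17",
    "new_age_weight",
    "prev_u5",
    "prev_5_9",
    "prev_10_17",
]


def country_table(
    bundle: WorldBundle,
    new: OrphanArray,
    prevalence: PrevalenceResult | None = None,
) -> pd.DataFrame:
    """One raw-count row per country; ratios attached by :func:`finalize_rows`."""
    single = split_deaths_single_age(bundle.deaths)
    sd = single.data
    ref = new.ref_year
    rows = []
    for country in bundle.countries:
        csd = sd[sd["country"] == country]
        in_range = csd[csd["md"].between(15, 69)]
        cnew = new.data[new.data["country"] == country]
        by_year = cnew.groupby("birth_year")["orphans"].sum()
        bins = {f"new_{b}": 0.0 for b in AGE_BINS}
        for y, v in by_year.items():
            bins[f"new_{_bin_of_birth_year(int(y), ref)}"] += float(v)
        age_weight = float(((ref - by_year.index.to_numpy() - 0.5) * by_year.to_numpy()).sum())
        row = {
            "unit": country,
            "level": "country",
            "deaths": float(csd["deaths"].sum()),
            "new_orphans": float(cnew["orphans"].sum()),
            "children": bundle.population.children_0_17(country, ref),
            "deaths_15_69": float(in_range["deaths"].sum()),
            "deaths_age_weight": float((in_range["md"] * in_range["deaths"]).sum()),
            "new_age_weight": age_weight,
            **bins,
            "prevalent_orphans": 0.0,
            "prev_u5": 0.0,
            "prev_5_9": 0.0,
            "prev_10_17": 0.0,
        }
        if prevalence is not None:
            cprev = prevalence.data[prevalence.data["country"] == country]
            pby = cprev.groupby("birth_year")["orphans"].sum()
            row["prevalent_orphans"] = float(cprev["orphans"].sum())
            for y, v in pby.items():
                row[f"prev_{_bin_of_birth_year(int(y), ref)}"] += float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def finalize_rows(raw: pd.DataFrame, world_new_total: float | None = None) -> pd.DataFrame:
    """Attach ratio-of-sums statistics to raw count rows."""
    df = raw.copy()
    if world_new_total is None:
        world_new_total = float(df.loc[df["level"] == "country", "new_orphans"].sum()) or float(
            df["new_orphans"].sum()
        )
    df["pct_of_world"] = 100.0 * df["new_orphans"] / world_new_total if world_new_total else np.nan
    df["per_100_deaths"] = [per_100_deaths(o, d) for o, d in zip(df["new_orphans"], df["deaths"])]
    df["per_100k_children"] = [
        per_100k_children(o, c) for o, c in zip(df["new_orphans"], df["children"])
    ]
    df["prev_per_100k_children"] = [
        per_100k_children(o, c) for o, c in zip(df["prevalent_orphans"], df["children"])
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in AGE_BINS:
            df[f"age_share_{b}"] = 100.0 * df[f"new_{b}"] / df["new_orphans"].replace(0, np.nan)
            df[f"prev_age_share_{b}"] = (
                100.0 * df[f"prev_{b}"] / df["prevalent_orphans"].replace(0, np.nan)
            )
        df["mean_age_at_orphaning"] = df["new_age_weight"] / df["new_orphans"].replace(0, np.nan)
        df["avg_age_at_death_15_69"] = df["deaths_age_weight"] / df["deaths_15_69"].replace(
            0, np.nan
        )
    return df


def aggregate(
    rows: pd.DataFrame,
    bundle: WorldBundle,
    level: str,
) -> pd.DataFrame:
    """Aggregate country rows to subregion / region / hdi / world.

    Counts are summed; ratios are recomputed from the aggregated numerators and
    denominators.  Countries without an HDI value are excluded from HDI rows;
    the number excluded is recorded in ``DataFrame.attrs['excluded']``.
    """
    if level not in ("subregion", "region", "hdi", "world"):
        raise ValidationError(f"unknown aggregation level {level!r}")
    countries = rows[rows["level"] == "country"].copy()
    meta = bundle.country_meta.data.set_index("country")
    world_total = float(countries["new_orphans"].sum())
    excluded = 0
    if level == "world":
        countries["_key"] = "World"
    elif level == "hdi":
        countries["_key"] = meta.loc[countries["unit"], "hdi_category"].to_numpy()
        excluded = int((countries["_key"] == "missing").sum())
        countries = countries[countries["_key"] != "missing"]
    else:
        countries["_key"] = meta.loc[countries["unit"], level].to_numpy()
    agg = countries.groupby("_key")[_COUNT_COLS].sum().reset_index()
    agg = agg.rename(columns={"_key": "unit"})
    agg["level"] = level
    out = finalize_rows(agg, world_new_total=world_total)
    out.attrs["excluded"] = excluded
    return out


def summary_table(
    bundle: WorldBundle,
    new: OrphanArray,
    prevalence: PrevalenceResult | None = None,
) -> pd.DataFrame:
    """Country rows plus subregion, region, HDI-category and world rows
    (the shape of the paper-style global/regional table)."""
    raw = country_table(bundle, new, prevalence)
    world_total = float(raw["new_orphans"].sum())
    parts = [finalize_rows(raw, world_total)]
    for level in ("subregion", "region", "hdi", "world"):
        parts.append(aggregate(raw, bundle, level))
    return pd.concat(parts, ignore_index=True)


def site_group_table(
    bundle: WorldBundle,
    new: OrphanArray,
    prevalence: PrevalenceResult | None = None,
) -> pd.DataFrame:
    """World totals by the 14 reporting groups (the by-cancer table shape).

    Includes deaths, new/prevalent orphans, percent of total, per-100-deaths
    and per-100,000-children ratios and the age shares per group.
    """
    ref = new.ref_year
    groups = bundle.site_groups
    sd = split_deaths_single_age(bundle.deaths).data
    sd["group"] = [groups.group_of(s) for s in sd["site"]]
    nd = new.data.copy()
    nd["group"] = [groups.group_of(s) for s in nd["site"]]
    children = sum(bundle.population.children_0_17(c, ref) for c in bundle.countries)
    new_total = float(nd["orphans"].sum())

    pd_data = None
    prev_total = float("nan")
    if prevalence is not None:
        pd_data = prevalence.data.copy()
        pd_data["group"] = [groups.group_of(s) for s in pd_data["site"]]
        prev_total = float(pd_data["orphans"].sum())

    rows = []
    for group in groups.groups:
        gdeaths = sd[sd["group"] == group]
        gnew = nd[nd["group"] == group]
        by_year = gnew.groupby("birth_year")["orphans"].sum()
        bins = {b: 0.0 for b in AGE_BINS}
        for y, v in by_year.items():
            bins[_bin_of_birth_year(int(y), ref)] += float(v)
        n_orph = float(gnew["orphans"].sum())
        d = float(gdeaths["deaths"].sum())
        row = {
            "group": group,
            "deaths": d,
            "new_orphans": n_orph,
            "pct_of_total": 100.0 * n_orph / new_total if new_total else np.nan,
            "per_100_deaths": per_100_deaths(n_orph, d),
            "per_100k_children": per_100k_children(n_orph, children),
            **{f"age_share_{b}": (100.0 * v / n_orph if n_orph else np.nan) for b, v in bins.items()},
        }
        if pd_data is not None:
            gp = float(pd_data.loc[pd_data["group"] == group, "orphans"].sum())
            row["prevalent_orphans"] = gp
            row["prev_pct_of_total"] = 100.0 * gp / prev_total if prev_total else np.nan
            row["prev_per_100k_children"] = per_100k_children(gp, children)
        rows.append(row)
    return pd.DataFrame(rows)


def format_display(df: pd.DataFrame, text_rounding: bool = False) -> pd.DataFrame:
    """Display rounding dialect: ratios to the nearest integer, shares to one
    decimal; with ``text_rounding`` counts go to the nearest thousand.

    Purely a formatting layer — inputs are returned untouched.
    """
    out = df.copy()
    for col in out.columns:
        if col.startswith(("per_100", "prev_per_100")):
            out[col] = out[col].round(0)
        elif "share" in col or col.startswith("pct"):
            out[col] = out[col].round(1)
        elif col in ("mean_age_at_orphaning", "avg_age_at_death_15_69"):
            out[col] = out[col].round(1)
        elif text_rounding and col in ("deaths", "new_orphans", "prevalent_orphans"):
            out[col] = (out[col] / 1000.0).round(0) * 1000.0
    return out
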