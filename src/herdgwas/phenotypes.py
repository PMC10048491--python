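"""Analysis-ready trait tables and cohort construction from lactation records.

The raw input is a long table of 305-day lactation records (one row per cow
and lactation) carrying milk/fat/protein yields in kg plus the fixed-effect
covariates. This module turns it into a wide per-cow phenotype table with
one column per trait-lactation cell:

* the analysis cohort keeps only cows whose farm, sire and birth-year groups
  all have at least ``min_per_level`` members (iterated to a fixed point,
  since removals can shrink other groups);
* only full lactations (>= 270 days in milk) contribute records;
* fat/protein content (%) = 100 * yield / milk yield;
* per trait-lactation column, values outside mean +/- 3 SD are set missing
  (mean and SD computed once on the column, single pass);
* the lactation mean (LAm) exists only where all three lactations of the
  trait survived.

Trait columns are named ``"<trait>:<lactation>"``, e.g. ``"fat_pct:LA1"``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ("milk_kg", "fat_kg", "protein_kg", "fat_pct", "protein_pct")
LACTATIONS = ("LA1", "LA2", "LA3")
COHORT_LABELS = ("farm", "sire", "birth_year")


def trait_column(trait: str, lactation: str) -> str:
    return f"{trait}:{lactation}"


def split_trait_column(column: str) -> tuple[str, str]:
    trait, lactation = column.rsplit(":", 1)
    return trait, lactation


class EmptyCohortError(ValueError):
    pass


def derive_contents(fat_kg, protein_kg, milk_kg):
    """Fat and protein content in percent: ``100 * yield / milk``.

    Accepts scalars or arrays. Raises on non-positive milk yield.
    """
    milk = np.asarray(milk_kg, dtype=float)
    if np.any(milk <= 0):
        raise ValueError("content undefined for milk_kg <= 0")
    fat = 100.0 * np.asarray(fat_kg, dtype=float) / milk
    protein = 100.0 * np.asarray(protein_kg, dtype=float) / milk
    if np.isscalar(milk_kg):
        return float(fat), float(protein)
    return fat, protein


def full_lactation_filter(records: pd.DataFrame, dim_min: int = 270) -> pd.DataFrame:
    """Keep only full lactations (days in milk >= ``dim_min``)."""
    if records.empty:
        return records.copy()
    kept = records.loc[records["dim"] >= dim_min].reset_index(drop=True)
    logger.info("full-lactation filter: %d of %d records kept", len(kept), len(records))
    return kept


def cohort_filter(
    cows: pd.DataFrame,
    labels: tuple = COHORT_LABELS,
    min_per_level: int = 20,
) -> pd.DataFrame:
    """Restrict to cows whose every grouping level has >= ``min_per_level`` members.

    Iterates to a fixed point: dropping cows of a small sire group can push a
    farm or birth-year group below the threshold, which then also goes.
    ``cows`` must have one row per cow with complete label columns.
    """
    kept = cows.copy()
    while True:
        n_before = len(kept)
        for label in labels:
            counts = kept[label].value_counts()
            bad = counts.index[counts < min_per_level]
            if len(bad):
                kept = kept.loc[~kept[label].isin(bad)]
        if len(kept) == n_before:
            break
    if kept.empty:
        raise EmptyCohortError(
            f"no cows satisfy >= {min_per_level} per {'/'.join(labels)}; "
            "lower min_per_level"
        )
    logger.info("cohort filter: %d of %d cows kept", len(kept), len(cows))
    return kept.reset_index(drop=True)


def outlier_filter(values, sd_mult: float = 3.0) -> np.ndarray:
    """Set values strictly outside mean +/- ``sd_mult`` * SD to NaN.

    Mean and SD are computed once on the non-missing input (single pass,
    sample SD). Values exactly on the boundary are kept. With fewer than two
    non-missing values, or an all-missing column, the input is returned
    unchanged with a warning.
    """
    v = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(v)
    if finite.sum() == 0:
        warnings.warn("outlier filter skipped: all values missing")
        return v
    if finite.sum() < 2:
        warnings.warn("outlier filter skipped: fewer than 2 non-missing values")
        return v
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    out = finite & (np.abs(v - mean) > sd_mult * sd)
    v[out] = np.nan
    return v


def lactation_mean(la1, la2, la3):
    """Arithmetic mean across the three lactations, or NaN unless all present."""
    a1, a2, a3 = (np.asarray(x, dtype=float) for x in (la1, la2, la3))
    all_present = np.isfinite(a1) & np.isfinite(a2) & np.isfinite(a3)
    out = np.where(all_present, (a1 + a2 + a3) / 3.0, np.nan)
    if np.isscalar(la1) or (out.ndim == 0):
        return float(out) if np.ndim(out) == 0 else out
    return out


def build_phenotype_table(
    records: pd.DataFrame,
    min_per_level: int = 20,
    dim_min: int = 270,
    sd_mult: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Full phenotype pipeline: cohort, record filters, contents, outliers, LAm.

    Returns ``(table, report)``: a per-cow DataFrame (index ``cow_id``) with
    trait columns ``<trait>:<LA1|LA2|LA3|LAm>`` and covariate columns
    (farm, sire, birth_year, birth_season, age_first_calving and per-lactation
    calving_year/calving_season), plus a dict of per-stage record counts.
    """
    report: dict = {"n_records_in": len(records), "n_cows_in": records["cow_id"].nunique()}

    # one covariate row per cow (cow-level labels identical across records)
    cow_level = (
        records.sort_values(["cow_id", "lactation"])
        .groupby("cow_id", sort=True)
        .first()[["farm", "sire", "birth_year", "birth_season", "age_first_calving"]]
    )
    cohort = cohort_filter(cow_level.reset_index(), min_per_level=min_per_level)
    cohort_ids = set(cohort["cow_id"])
    report["n_cows_cohort"] = len(cohort)

    rec = records.loc[records["cow_id"].isin(cohort_ids)]
    rec = full_lactation_filter(rec, dim_min=dim_min)
    report["n_records_full_lactation"] = len(rec)

    fat_pct, protein_pct = derive_contents(
        rec["fat_kg"].to_numpy(), rec["protein_kg"].to_numpy(),
        rec["milk_kg"].to_numpy(),
    )
    rec = rec.assign(fat_pct=fat_pct, protein_pct=protein_pct)

    table = cohort.set_index("cow_id")
    # per-lactation calving covariates
    for la_num, la in zip((1, 2, 3), LACTATIONS):
        sub = rec.loc[rec["lactation"] == la_num].set_index("cow_id")
        table[f"calving_year:{la}"] = sub["calving_year"]
        table[f"calving_season:{la}"] = sub["calving_season"]
        for trait in TRAITS:
            table[trait_column(trait, la)] = sub[trait]

    n_outliers = 0
    for trait in TRAITS:
        for la in LACTATIONS:
            col = trait_column(trait, la)
            before = table[col].notna().sum()
            if before == 0:
                continue
            table[col] = outlier_filter(table[col].to_numpy(), sd_mult=sd_mult)
            n_outliers += before - table[col].notna().sum()
        table[trait_column(trait, "LAm")] = lactation_mean(
            table[trait_column(trait, "LA1")].to_numpy(),
            table[trait_column(trait, "LA2")].to_numpy(),
            table[trait_column(trait, "LA3")].to_numpy(),
        )
    report["n_outliers_removed"] = int(n_outliers)
    for la in LACTATIONS + ("LAm",):
        report[f"n_cows_{la}"] = int(table[trait_column("milk_kg", la)].notna().sum())
    logger.info("phenotype table: %s", report)
    return table, report
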