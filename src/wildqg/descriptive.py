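"""Variance partition, repeatability, CV, phenotypic correlation and
pollinator-census summaries.

The variance partition uses closed-form expected-mean-squares (Searle)
estimators for the two-fold nested random model

    y_ijk = mu + site_i + plant_ij + e_ijk

handling unbalanced designs through the exact EMS coefficients.  Negative
moment estimates are truncated at zero before converting to percentages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _nested_ems_components(df: pd.DataFrame, trait: str) -> dict:
    """Moment estimates (sigma2_site, sigma2_plant, sigma2_within)."""
    d = df.dropna(subset=[trait])
    counts = d.groupby(["site", "plant_id"], sort=False)[trait].count()
    if (counts < 2).any():
        n_single = int((counts < 2).sum())
        logger.info("excluding %d single-replicate plants", n_single)
        keep = counts[counts >= 2].reset_index()[["site", "plant_id"]]
        d = d.merge(keep, on=["site", "plant_id"])
    sites = d["site"].unique()
    if len(sites) < 2:
        raise ValueError("need >= 2 sites for a variance partition")

    y = d[trait].to_numpy(float)
    N = y.size
    grand = y.mean()
    g_site = d.groupby("site", sort=False)[trait]
    g_plant = d.groupby(["site", "plant_id"], sort=False)[trait]

    n_i = g_site.count()  # records per site
    n_ij = g_plant.count()  # records per plant
    a = len(n_i)
    b_total = len(n_ij)

    site_means = g_site.mean()
    plant_means = g_plant.mean()

    ss_site = float((n_i * (site_means - grand) ** 2).sum())
    site_of_plant = n_ij.index.get_level_values("site")
    ss_plant = float(
        (n_ij * (plant_means - site_means.loc[site_of_plant].to_numpy()) ** 2).sum()
    )
    plant_mean_per_record = d.set_index(["site", "plant_id"]).index
    ss_within = float(
        ((y - plant_means.loc[plant_mean_per_record].to_numpy()) ** 2).sum()
    )

    df_site = a - 1
    df_plant = b_total - a
    df_within = N - b_total
    if df_within <= 0:
        raise ValueError("need >= 2 flowers per plant")

    # Searle's EMS coefficients for the unbalanced two-fold nested design
    sum_nij2_over_ni = float(
        (n_ij**2).groupby(level="site").sum().div(n_i).sum()
    )
    sum_nij2_over_N = float((n_ij**2).sum()) / N
    sum_ni2_over_N = float((n_i**2).sum()) / N

    s2_within = ss_within / df_within
    c_plant = (N - sum_nij2_over_ni) / df_plant
    s2_plant = (ss_plant / df_plant - s2_within) / c_plant
    c1 = (sum_nij2_over_ni - sum_nij2_over_N) / df_site
    c2 = (N - sum_ni2_over_N) / df_site
    s2_site = (ss_site / df_site - s2_within - c1 * max(s2_plant, 0.0)) / c2

    return {
        "site": max(s2_site, 0.0),
        "plant": max(s2_plant, 0.0),
        "within": s2_within,
    }


def partition_trait_variance(data: pd.DataFrame, trait: str) -> dict:
    """Percent of flower-level variance among sites, among plants, within."""
    comp = _nested_ems_components(data, trait)
    total = sum(comp.values())
    if total <= 0:
        raise ValueError("zero total variance")
    return {
        "site_pct": 100.0 * comp["site"] / total,
        "individual_pct": 100.0 * comp["plant"] / total,
        "within_pct": 100.0 * comp["within"] / total,
        "components": comp,
    }


def repeatability(data: pd.DataFrame, trait: str) -> float:
    """Among-plant (site + individual) fraction of flower-level variance, %.

    Equals 100 minus the within-plant percentage of the variance partition.
    """
    part = partition_trait_variance(data, trait)
    return part["site_pct"] + part["individual_pct"]


def coefficient_of_variation(plant_means: np.ndarray) -> float:
    """100 * sample SD / mean of the plant means (ratio-scale traits)."""
    x = np.asarray(plant_means, float)
    m = x.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    return float(100.0 * x.std(ddof=1) / m)


def phenotypic_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation of plant means with its two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def visitation_summary(censuses: pd.DataFrame) -> dict:
    """Visitation rate, taxon shares, and the implied waiting time per flower.

    rate = mean over censuses of total visits / flowers surveyed;
    waiting time (hours, one decimal) = census duration / rate / 60.
    Taxon shares are percentages of total visits, rounded to integers.
    """
    per_census = censuses.groupby("census_id").agg(
        visits=("visits", "sum"),
        flowers=("flowers_surveyed", "first"),
        duration=("duration_min", "first"),
    )
    if (per_census["flowers"] <= 0).all():
        raise ValueError("no flowers surveyed")
    per_census = per_census[per_census["flowers"] > 0]
    rate = float((per_census["visits"] / per_census["flowers"]).mean())
    duration = float(per_census["duration"].iloc[0])
    total_visits = int(censuses["visits"].sum())
    by_taxon = censuses.groupby("taxon")["visits"].sum()
    shares = (
        {t: int(round(100.0 * v / total_visits)) for t, v in by_taxon.items()}
        if total_visits
        else {}
    )
    waiting_h = round(duration / rate / 60.0, 1) if rate > 0 else np.inf
    return {
        "rate_per_flower_per_census": rate,
        "duration_min": duration,
        "n_censuses": int(len(per_census)),
        "n_flowers_surveyed": int(per_census["flowers"].sum()),
        "total_visits": total_visits,
        "visits_by_taxon": {t: int(v) for t, v in by_taxon.items()},
        "taxon_share_pct": shares,
        "waiting_time_h": float(waiting_h),
        "frac_zero_censuses": float((per_census["visits"] == 0).mean()),
    }


def waiting_time_hours(rate: float, duration_min: float = 3.0) -> float:
    """Waiting time for one visit to a flower, in hours (one decimal)."""
    if rate <= 0:
        return float("inf")
    return round(duration_min / rate / 60.0, 1)
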