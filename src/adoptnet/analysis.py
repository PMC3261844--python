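"""Diffusion-of-innovations statistics for adoption tables.

Implements the classic adopter categorisation (early adopters, early
majority, late majority, laggards) by standard-deviation bands around the
mean adoption time, per-city composition profiles, critical-mass timing,
city grouping by critical-mass week, media-amplification estimation from
paired with/without-media runs, and simulation-versus-data comparison of
critical-mass times.  All functions accept either simulated output or any
adoption table with the documented CSV schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import SimulationResult

CATEGORIES = ("early_adopter", "early_majority", "late_majority", "laggard")


def classify_adopters(times) -> np.ndarray:
    """Label adopters by when they adopted relative to the whole population.

    With mean mu and (population) standard deviation sigma of adoption
    weeks: earlier than mu - sigma -> ``early_adopter``; in
    [mu - sigma, mu] -> ``early_majority``; in (mu, mu + sigma] ->
    ``late_majority``; later -> ``laggard``.  A degenerate sample
    (sigma = 0) labels everyone ``early_majority`` with a warning.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 adopters to classify")
    mu, sigma = t.mean(), t.std()
    out = np.empty(t.size, dtype=object)
    if sigma == 0:
        warnings.warn("zero spread in adoption times; all labelled early_majority")
        out[:] = "early_majority"
        return out
    out[t < mu - sigma] = "early_adopter"
    out[(t >= mu - sigma) & (t <= mu)] = "early_majority"
    out[(t > mu) & (t <= mu + sigma)] = "late_majority"
    out[t > mu + sigma] = "laggard"
    return out


def category_proportions(categories) -> dict[str, float]:
    """Fraction of adopters in each of the four categories."""
    c = np.asarray(categories)
    return {k: float((c == k).mean()) for k in CATEGORIES}


def city_composition(city_ids, categories) -> pd.DataFrame:
    """Per-city fractions of nationally classified adopter categories.

    Categories come from the *national* classification so that a city's
    profile is relative to the whole population; this also normalises
    locations with respect to their size.  Rows sum to one.
    """
    df = pd.DataFrame({"city_id": np.asarray(city_ids), "category": np.asarray(categories)})
    counts = df.groupby("city_id")["category"].value_counts().unstack(fill_value=0)
    for k in CATEGORIES:
        if k not in counts.columns:
            counts[k] = 0
    counts = counts[list(CATEGORIES)]
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass(frozen=True)
class CriticalMassRecord:
    """Week a city first accumulated a fraction ``theta`` of its eventual adopters."""

    city_id: int
    week: int | None
    theta: float


def critical_mass_time(weekly_counts, theta: float = 0.16, city_id: int = 0) -> CriticalMassRecord:
    """First week in which cumulative adoption reaches ``theta`` of the total.

    ``theta`` defaults to 0.16, the classical innovators-plus-early-adopters
    mass at which contagion is conventionally considered self-sustaining.
    ``week`` is ``None`` when the threshold is never reached within the
    observed horizon (possible only for theta handled under truncation).
    """
    if theta > 1:
        raise ValueError("theta must be <= 1")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    w = np.asarray(weekly_counts, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("city has no eventual adopters")
    frac = np.cumsum(w) / total
    hit = np.flatnonzero(frac >= theta)
    week = int(hit[0]) if len(hit) else None
    return CriticalMassRecord(city_id=city_id, week=week, theta=theta)


def critical_mass_table(city_weekly: np.ndarray, city_ids, theta: float = 0.16) -> pd.DataFrame:
    """Critical-mass week per city from a cities × weeks count matrix.

    Cities with zero eventual adopters are excluded with a warning.
    """
    rows = []
    for cid, series in zip(np.asarray(city_ids), np.asarray(city_weekly)):
        if series.sum() <= 0:
            warnings.warn(f"city {cid} has no adopters; excluded")
            continue
        rec = critical_mass_time(series, theta=theta, city_id=int(cid))
        rows.append({"city_id": rec.city_id, "week": rec.week, "theta": theta})
    if not rows:
        raise ValueError("no city has any adopters")
    return pd.DataFrame(rows)


def classify_cities(critical_mass_weeks) -> np.ndarray:
    """Group cities by critical-mass week relative to all cities.

    Applies the same mean/standard-deviation band rule used for individual
    adopters, yielding early-adopting, early-majority, late-majority and
    laggard city groups.
    """
    return classify_adopters(critical_mass_weeks)


def media_amplification(with_media, without_media) -> float:
    """Fold increase in final adopters attributable to the media.

    Accepts single paired runs or sequences of paired replicate runs; with
    ensembles the ratio of ensemble means is returned.  Both runs must share
    the horizon; the denominator run has media receptiveness zero.
    """
    w = _final_counts(with_media)
    wo = _final_counts(without_media)
    if len(w) != len(wo):
        raise ValueError("ensembles must be paired (equal lengths)")
    denom = float(np.mean(wo))
    if denom <= 0:
        raise ValueError("without-media run has zero adopters")
    return float(np.mean(w) / denom)


def media_amplification_interval(
    with_media, without_media, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """Fold ratio of ensemble means with a paired bootstrap interval."""
    w = np.asarray(_final_counts(with_media), dtype=float)
    wo = np.asarray(_final_counts(without_media), dtype=float)
    point = media_amplification(with_media, without_media)
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(w), size=(n_boot, len(w)))
    boots = w[idx].mean(axis=1) / wo[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return point, float(lo), float(hi)


def _final_counts(runs) -> list[float]:
    if isinstance(runs, SimulationResult):
        return [runs.final_adopters]
    return [r.final_adopters if isinstance(r, SimulationResult) else float(r) for r in runs]


def compare_critical_mass(sim_weeks_by_city: dict, empirical_weeks: dict) -> dict:
    """Compare replicate critical-mass weeks with observed ones, city by city.

    ``sim_weeks_by_city`` maps city_id -> sequence of simulated
    critical-mass weeks over replicates; ``empirical_weeks`` maps city_id ->
    observed week.  Returns per-city 25/50/75 percentiles, the fraction of
    cities whose observed week falls inside the simulated interquartile
    range, and the Spearman correlation between simulated medians and
    observed weeks (``None``, flagged, when either side is constant).
    """
    common = sorted(set(sim_weeks_by_city) & set(empirical_weeks))
    if not common:
        raise ValueError("no overlapping cities between simulation and data")
    rows = []
    for cid in common:
        q25, q50, q75 = np.percentile(np.asarray(sim_weeks_by_city[cid], dtype=float), [25, 50, 75])
        emp = float(empirical_weeks[cid])
        rows.append(
            {"city_id": cid, "q25": q25, "median": q50, "q75": q75,
             "empirical": emp, "covered": bool(q25 <= emp <= q75)}
        )
    table = pd.DataFrame(rows)
    medians, emps = table["median"].to_numpy(), table["empirical"].to_numpy()
    if np.ptp(medians) == 0 or np.ptp(emps) == 0 or len(table) < 2:
        rho, degenerate = None, True
    else:
        rho = float(stats.spearmanr(medians, emps).statistic)
        degenerate = False
    return {
        "table": table,
        "iqr_coverage": float(table["covered"].mean()),
        "spearman": rho,
        "spearman_degenerate": degenerate,
    }


def load_adoption_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an adoption CSV in either documented schema.

    Aggregated ``city_id,week,new_adopters`` rows or per-adopter
    ``agent_id,city_id,week`` rows are both accepted; returns
    ``(city_ids, city_weekly)`` with one row per city and one column per
    week from 0 to the maximum observed.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"city_id", "week", "new_adopters"} <= cols:
        agg = df.groupby(["city_id", "week"])["new_adopters"].sum()
    elif {"agent_id", "city_id", "week"} <= cols:
        agg = df.groupby(["city_id", "week"]).size()
    else:
        raise ValueError(
            "expected columns city_id,week,new_adopters or agent_id,city_id,week"
        )
    if (df["week"] < 0).any():
        raise ValueError("weeks must be nonnegative")
    mat = agg.unstack(fill_value=0)
    full = mat.reindex(columns=range(int(mat.columns.max()) + 1), fill_value=0)
    return full.index.to_numpy(), full.to_numpy()
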