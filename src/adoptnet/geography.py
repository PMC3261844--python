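"""Cities, distances, and agent placement.

The simulation operates on a metapopulation: a set of cities, each holding a
share of the national agent population and a measured (or synthesised)
fraction of *early adopters* — agents with a higher propensity to adopt.
This module provides the city table container, a synthetic-city generator
(Zipf-distributed sizes, Beta-distributed early-adopter compositions), CSV
I/O in the documented schema, great-circle distances, and the deterministic
allocation of agents to cities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Continental-US style default bounding box: (lat_min, lat_max, lon_min, lon_max).
DEFAULT_BOUNDING_BOX = (24.0, 49.0, -125.0, -66.0)

CITY_COLUMNS = ["city_id", "name", "lat", "lon", "user_count", "early_fraction"]


class SchemaError(ValueError):
    """Raised when a city/adoption CSV does not match the documented schema."""


@dataclass(frozen=True)
class City:
    """A single city: location, population weight and adopter composition."""

    city_id: int
    name: str
    lat: float
    lon: float
    pop_share: float
    early_fraction: float
    user_count: int | None = None


class CityTable:
    """Ordered collection of cities forming the metapopulation scaffold.

    Parameters
    ----------
    df
        DataFrame with columns ``city_id, name, lat, lon, early_fraction``
        plus ``pop_share`` and/or ``user_count``.  Shares are normalised to
        sum to one on construction.
    provenance
        ``"synthetic"`` or ``"loaded"``.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "loaded"):
        df = df.copy().reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("no cities: a CityTable needs at least one city")
        if df["city_id"].duplicated().any():
            dupes = df.loc[df["city_id"].duplicated(), "city_id"].tolist()
            raise ValueError(f"duplicate city_id values: {dupes}")
        if "pop_share" not in df.columns:
            if "user_count" not in df.columns:
                raise SchemaError("need either 'pop_share' or 'user_count'")
            total = float(df["user_count"].sum())
            if total <= 0:
                raise ValueError("total user_count is zero; cannot form shares")
            df["pop_share"] = df["user_count"] / total
        else:
            s = float(df["pop_share"].sum())
            if s <= 0:
                raise ValueError("pop_share sums to zero")
            df["pop_share"] = df["pop_share"] / s
        bad_lat = ~df["lat"].between(-90, 90)
        bad_lon = ~df["lon"].between(-180, 180)
        if bad_lat.any() or bad_lon.any():
            raise ValueError("coordinates outside [-90,90] lat / [-180,180] lon")
        bad_ef = ~df["early_fraction"].between(0, 1)
        if bad_ef.any():
            rows = df.index[bad_ef].tolist()
            raise ValueError(f"early_fraction outside [0,1] in rows {rows}")
        if "name" not in df.columns:
            df["name"] = [f"city-{i}" for i in df["city_id"]]
        self.df = df
        self.provenance = provenance
        self._dist: np.ndarray | None = None

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield City(
                city_id=int(row.city_id),
                name=str(row.name),
                lat=float(row.lat),
                lon=float(row.lon),
                pop_share=float(row.pop_share),
                early_fraction=float(row.early_fraction),
                user_count=int(row.user_count) if hasattr(row, "user_count") else None,
            )

    @property
    def city_ids(self) -> np.ndarray:
        return self.df["city_id"].to_numpy()

    @property
    def pop_shares(self) -> np.ndarray:
        return self.df["pop_share"].to_numpy(dtype=float)

    @property
    def early_fractions(self) -> np.ndarray:
        return self.df["early_fraction"].to_numpy(dtype=float)

    # -- geometry ------------------------------------------------------
    def distance_matrix(self) -> np.ndarray:
        """Pairwise great-circle distances (km), cached; symmetric, zero diagonal."""
        if self._dist is None:
            lat = np.radians(self.df["lat"].to_numpy(dtype=float))
            lon = np.radians(self.df["lon"].to_numpy(dtype=float))
            self._dist = _haversine_matrix(lat, lon)
        return self._dist

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        cols = [c for c in CITY_COLUMNS if c in self.df.columns]
        if "pop_share" not in cols:
            cols.append("pop_share")
        self.df[cols].to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CityTable(n_cities={len(self)}, provenance={self.provenance!r})"


@dataclass
class AgentPopulation:
    """Agents assigned to cities, each typed *early* or *regular* adopter.

    Attributes
    ----------
    city_index
        Per-agent index into the city table (0..C-1), sorted by city so that
        each city's agents occupy a contiguous block.
    is_early
        Per-agent boolean adopter type.
    city_offsets
        ``city_offsets[c]:city_offsets[c+1]`` slices agent ids of city ``c``.
    """

    city_index: np.ndarray
    is_early: np.ndarray
    city_offsets: np.ndarray = field(repr=False)

    @property
    def n_agents(self) -> int:
        return len(self.city_index)

    @property
    def n_cities(self) -> int:
        return len(self.city_offsets) - 1

    @property
    def n_early(self) -> int:
        return int(self.is_early.sum())

    def city_counts(self) -> np.ndarray:
        return np.diff(self.city_offsets)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = np.radians([lat1, lat2])
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def pairwise_distance(a: City, b: City) -> float:
    """Distance in km between two cities (haversine)."""
    return haversine_km(a.lat, a.lon, b.lat, b.lon)


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    dphi = lat[:, None] - lat[None, :]
    dlmb = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlmb / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def generate_synthetic_cities(
    n_cities: int,
    zipf_exponent: float = 1.0,
    early_fraction_spec: tuple = ("beta", 2.0, 8.0),
    bounding_box: tuple = DEFAULT_BOUNDING_BOX,
    seed: int | np.random.SeedSequence = 0,
) -> CityTable:
    """Generate a synthetic metapopulation with Zipf city sizes.

    The population share of the k-th largest city is proportional to
    ``k**-zipf_exponent``; coordinates are uniform in the bounding box; the
    early-adopter fraction of each city is drawn independently from the
    distribution in ``early_fraction_spec``:

    * ``("beta", a, b)`` — Beta(a, b) draw per city (default Beta(2, 8),
      mean 0.2, mimicking the wide spread of measured city compositions);
    * ``("constant", f)`` — every city gets fraction ``f``.

    Deterministic for a fixed ``seed``.
    """
    if n_cities < 1:
        raise ValueError("n_cities must be >= 1")
    if zipf_exponent <= 0:
        raise ValueError("zipf_exponent must be > 0")
    lat_min, lat_max, lon_min, lon_max = bounding_box
    if not (-90 <= lat_min < lat_max <= 90):
        raise ValueError(f"invalid latitude bounds ({lat_min}, {lat_max})")
    if not (-180 <= lon_min < lon_max <= 180):
        raise ValueError(f"invalid longitude bounds ({lon_min}, {lon_max})")

    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n_cities + 1, dtype=float)
    shares = ranks ** (-zipf_exponent)
    shares /= shares.sum()

    lat = rng.uniform(lat_min, lat_max, size=n_cities)
    lon = rng.uniform(lon_min, lon_max, size=n_cities)

    kind = early_fraction_spec[0]
    if kind == "beta":
        _, a, b = early_fraction_spec
        early = rng.beta(a, b, size=n_cities)
    elif kind == "constant":
        early = np.full(n_cities, float(early_fraction_spec[1]))
    else:
        raise ValueError(f"unknown early_fraction_spec kind {kind!r}")

    df = pd.DataFrame(
        {
            "city_id": np.arange(n_cities),
            "name": [f"synth-{i}" for i in range(n_cities)],
            "lat": lat,
            "lon": lon,
            "pop_share": shares,
            "early_fraction": early,
        }
    )
    return CityTable(df, provenance="synthetic")


def load_city_table(path) -> CityTable:
    """Read a city CSV (``city_id,name,lat,lon,user_count|pop_share,early_fraction``)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"no cities in {path}")
    required = {"city_id", "lat", "lon", "early_fraction"}
    missing = required - set(df.columns)
    if missing or ("user_count" not in df.columns and "pop_share" not in df.columns):
        raise SchemaError(
            f"missing columns {sorted(missing) or ['user_count|pop_share']}; "
            f"expected {CITY_COLUMNS} (pop_share may replace user_count)"
        )
    return CityTable(df, provenance="loaded")


def filter_cities_by_users(table: CityTable, min_users: int = 1000) -> tuple[CityTable, float]:
    """Keep cities with strictly more than ``min_users`` users.

    Mirrors the case-study convention of restricting analysis to locations
    with over 1000 users for statistical power.  Returns the filtered table
    (shares renormalised) and the fraction of users retained.
    """
    if "user_count" not in table.df.columns:
        raise ValueError("filter_cities_by_users requires a user_count column")
    df = table.df
    keep = df["user_count"] > min_users
    if not keep.any():
        raise ValueError(f"all cities filtered out at min_users={min_users}")
    retained = float(df.loc[keep, "user_count"].sum() / df["user_count"].sum())
    out = df.loc[keep].drop(columns=["pop_share"])
    return CityTable(out, provenance=table.provenance), retained


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Floors the exact quotas, then hands the leftover units to the largest
    fractional remainders (ties broken by lower index).  Conserves the total
    exactly and never deviates from any quota by one unit or more than one.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be nonnegative")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def allocate_agents(table: CityTable, n_agents: int, seed: int | np.random.SeedSequence = 0) -> AgentPopulation:
    """Place agents into cities by share and type them by city composition.

    A city holding 4% of users receives 4% of the agents (largest-remainder
    rounding, total conserved exactly); within a city with a measured 30%
    early-adopter composition, 30% of its agents (rounded) are typed early.
    Early-typed agents are placed at the start of each city's block; the
    ``seed`` argument is accepted for interface symmetry (allocation is
    deterministic).
    """
    if n_agents <= 0:
        raise ValueError("n_agents must be positive")
    counts = largest_remainder(table.pop_shares, n_agents)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    city_index = np.repeat(np.arange(len(table)), counts)
    is_early = np.zeros(n_agents, dtype=bool)
    n_early = np.rint(table.early_fractions * counts).astype(int)
    for c, (start, k) in enumerate(zip(offsets[:-1], n_early)):
        is_early[start : start + k] = True
    return AgentPopulation(city_index=city_index, is_early=is_early, city_offsets=offsets)
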