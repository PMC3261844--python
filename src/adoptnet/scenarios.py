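"""Named experiment scenarios: configuration, presets, reproducible runs.

A :class:`Scenario` bundles everything needed to reproduce an experiment:
the city source (synthetic recipe or CSV path), the network construction
and its kernel, the dynamic parameters, and the replicate count.  Four
presets cover the canonical model settings:

* ``si_baseline`` — one agent type, homogeneous-mixing network, media off:
  the classical network SI model, used to verify the reduction to the
  textbook S-curve.
* ``spatial_types`` — two adopter types on the spatially embedded
  homophilous network, media off: isolates geography and composition.
* ``exogenous_media`` — spatial network driven by a supplied weekly media
  series (e.g. a normalised news-volume export).
* ``twitter_like`` — spatial network plus the endogenous media agent;
  calibrated so word-of-mouth alone saturates only part of the population
  within the horizon, leaving room for the media to amplify adoption.

One master seed governs city generation, network build and dynamics via
fixed child streams, so paired counterfactuals share their random inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, geography, network
from .dynamics import ReplicateSummary, SimulationConfig, run_replicates, run_simulation
from .geography import CityTable, allocate_agents, generate_synthetic_cities, load_city_table
from .network import (
    KernelParams,
    build_mixing_network,
    build_nonspatial_homophilous_network,
    build_spatial_network,
)

NETWORK_KINDS = ("mixing", "spatial", "nonspatial_homophilous")


@dataclass(frozen=True)
class CitySpec:
    """Synthetic city recipe or a path to a city CSV."""

    source: str = "synthetic"  # "synthetic" | "file"
    path: str | None = None
    n_cities: int = 408
    zipf_exponent: float = 1.0
    early_mean: float = 0.2
    early_concentration: float = 10.0  # Beta(a,b) with a+b = concentration
    single_type: bool = False  # force early_fraction = 0 everywhere

    def build(self, seed) -> CityTable:
        if self.source == "file":
            if self.path is None:
                raise ValueError("city source 'file' needs a path")
            return load_city_table(self.path)
        if self.single_type:
            spec = ("constant", 0.0)
        else:
            a = self.early_mean * self.early_concentration
            b = (1 - self.early_mean) * self.early_concentration
            spec = ("beta", a, b)
        return generate_synthetic_cities(
            self.n_cities, zipf_exponent=self.zipf_exponent,
            early_fraction_spec=spec, seed=seed,
        )


@dataclass(frozen=True)
class Scenario:
    """A fully specified, reproducible experiment."""

    name: str = "custom"
    n_agents: int = 10_000
    network_kind: str = "spatial"
    mean_degree: float = 10.0
    kernel: KernelParams = field(default_factory=lambda: KernelParams(homophily_pref=0.8))
    cities: CitySpec = field(default_factory=CitySpec)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_reps: int = 50

    def __post_init__(self):
        if self.network_kind not in NETWORK_KINDS:
            raise ValueError(f"network_kind must be one of {NETWORK_KINDS}")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        for key, sub in (("kernel", KernelParams), ("cities", CitySpec), ("sim", SimulationConfig)):
            if key in d and isinstance(d[key], dict):
                unknown = set(d[key]) - {f.name for f in dataclasses.fields(sub)}
                if unknown:
                    raise ValueError(f"unknown keys under '{key}': {sorted(unknown)}")
                d[key] = sub(**d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _presets() -> dict[str, Scenario]:
    return {
        "si_baseline": Scenario(
            name="si_baseline",
            n_agents=100_000,
            network_kind="mixing",
            mean_degree=10.0,
            cities=CitySpec(n_cities=100, single_type=True),
            sim=SimulationConfig(
                n_weeks=420, beta_regular=0.003, adopt_ratio=1.0,
                media_mode="off", seed_fraction=0.001, seed_mode="uniform",
                contact_mode="annealed_well_mixed",
            ),
            n_reps=100,
        ),
        "spatial_types": Scenario(
            name="spatial_types",
            n_agents=10_000,
            network_kind="spatial",
            mean_degree=10.0,
            kernel=KernelParams(alpha=1.0, d_cutoff=1000.0, homophily_pref=0.8),
            cities=CitySpec(n_cities=408),
            sim=SimulationConfig(
                n_weeks=180, beta_regular=0.01, adopt_ratio=3.0,
                media_mode="off", seed_fraction=0.001, seed_mode="birthplace_city",
            ),
            n_reps=50,
        ),
        "exogenous_media": Scenario(
            name="exogenous_media",
            n_agents=10_000,
            network_kind="spatial",
            mean_degree=10.0,
            kernel=KernelParams(alpha=1.0, d_cutoff=1000.0, homophily_pref=0.8),
            cities=CitySpec(n_cities=408),
            sim=SimulationConfig(
                n_weeks=180, beta_regular=0.01, adopt_ratio=3.0,
                media_mode="exogenous", media_receptiveness=0.6,
                seed_fraction=0.001, seed_mode="birthplace_city",
            ),
            n_reps=50,
        ),
        "twitter_like": Scenario(
            name="twitter_like",
            n_agents=10_000,
            network_kind="spatial",
            mean_degree=10.0,
            kernel=KernelParams(alpha=1.0, d_cutoff=1000.0, homophily_pref=0.8),
            cities=CitySpec(n_cities=408),
            sim=SimulationConfig(
                n_weeks=180, beta_regular=0.004, adopt_ratio=3.0,
                media_mode="endogenous", media_receptiveness=0.6,
                media_exponent=1.5, shock_prob=0.02, shock_scale=0.5,
                seed_fraction=0.001, seed_mode="birthplace_city",
            ),
            n_reps=50,
        ),
    }


PRESET_NAMES = tuple(_presets())


def load_scenario(name_or_path: str) -> Scenario:
    """Resolve a preset name or load a scenario JSON file."""
    presets = _presets()
    if name_or_path in presets:
        return presets[name_or_path]
    p = Path(name_or_path)
    if p.exists():
        return Scenario.from_dict(json.loads(p.read_text()))
    raise ValueError(
        f"unknown scenario {name_or_path!r}: not a preset {sorted(presets)} and not a file"
    )


def build_world(scenario: Scenario, master_seed: int):
    """Instantiate cities, agents and the network from one master seed.

    Child streams: spawn key 0 -> city generation, 1 -> network build,
    2 -> dynamics (further split per replicate).
    """
    ss = np.random.SeedSequence(master_seed)
    city_ss, net_ss, dyn_ss = (np.random.SeedSequence(master_seed, spawn_key=(k,)) for k in range(3))
    table = scenario.cities.build(city_ss)
    pop = allocate_agents(table, scenario.n_agents)
    if scenario.network_kind == "mixing":
        net = build_mixing_network(pop, scenario.mean_degree, seed=net_ss)
    elif scenario.network_kind == "spatial":
        net = build_spatial_network(pop, table, scenario.mean_degree, scenario.kernel, seed=net_ss)
    else:
        net = build_nonspatial_homophilous_network(
            pop, table, scenario.mean_degree, scenario.kernel, seed=net_ss
        )
    return table, pop, net, dyn_ss


def run_scenario(
    scenario: Scenario,
    out_dir,
    master_seed: int = 0,
    media_series=None,
    no_media: bool = False,
) -> Path:
    """Run a scenario and write a self-describing artifact directory.

    Outputs: per-city weekly counts of the first replicate
    (``city_weekly.csv``), the ensemble band summary (``replicates.csv``),
    the media series of the first replicate (``media.csv``), and
    ``metadata.json`` with the master seed and a config hash.  Identical
    master seeds reproduce the directory byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if no_media:
        scenario = dataclasses.replace(
            scenario, sim=dataclasses.replace(scenario.sim, media_receptiveness=0.0)
        )
    table, pop, net, dyn_ss = build_world(scenario, master_seed)

    cfg = dataclasses.replace(scenario.sim, rng_seed=int(dyn_ss.generate_state(1)[0] % (2**31)))
    first = run_simulation(pop, net, table, cfg, media_series=media_series,
                           rng=np.random.default_rng(np.random.SeedSequence(cfg.rng_seed, spawn_key=(0,))))
    summary = run_replicates(pop, net, table, cfg, n_reps=scenario.n_reps,
                             media_series=media_series)

    long = pd.DataFrame(first.city_weekly, index=table.city_ids).stack()
    long = long[long > 0].rename("new_adopters").reset_index()
    long.columns = ["city_id", "week", "new_adopters"]
    long.to_csv(out / "city_weekly.csv", index=False)

    pd.DataFrame({"week": np.arange(cfg.n_weeks + 1),
                  "new_adopters": first.national,
                  "cumulative": first.cumulative}).to_csv(out / "national.csv", index=False)
    pd.DataFrame({"week": np.arange(cfg.n_weeks + 1),
                  "volume": first.media.volume}).to_csv(out / "media.csv", index=False)
    pd.DataFrame({
        "week": np.arange(cfg.n_weeks + 1),
        "mean": summary.mean,
        "p2.5": summary.band95[0], "p12.5": summary.band75[0],
        "p87.5": summary.band75[1], "p97.5": summary.band95[1],
    }).to_csv(out / "replicates.csv", index=False)
    table.to_csv(out / "cities.csv")

    meta = {
        "scenario": scenario.to_dict(),
        "master_seed": master_seed,
        "config_hash": scenario.config_hash(),
        "n_reps": scenario.n_reps,
        "final_adopters_first_rep": first.final_adopters,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    with open(out / "run.log", "w") as fh:
        fh.write(
            f"scenario={scenario.name} seed={master_seed} hash={scenario.config_hash()}\n"
            f"n_agents={scenario.n_agents} n_cities={len(table)} "
            f"n_edges={net.n_edges} mean_degree={net.mean_degree:.3f}\n"
            f"final adopters (first replicate): {first.final_adopters}\n"
        )
    return out
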