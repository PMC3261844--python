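"""Two-type SI adoption dynamics with an optional mass-media agent.

The contagion is a discrete-week susceptible–infected process: every week
each infected agent attempts to convince its neighbours, and a susceptible
agent of type tau with m infected neighbours adopts with probability
1 - (1 - beta_tau)**m (independent exposures; beta is the susceptible's
per-contact heed probability).  Early adopters heed with probability
``adopt_ratio`` times the regular rate, capped at one.  Adoption is
permanent — there is no recovery.

On top of word of mouth, a media agent can broadcast each week: every
susceptible adopts independently with probability a * M_t, the product of
media volume and the agents' receptiveness.  Volume is either a supplied
weekly series (exogenous) or generated endogenously from the number of
previously infected agents, M_t = clip((I_{t-1}/N)**gamma + eps_t, 0, 1),
with eps_t an occasional uniform shock mimicking discrete media events such
as celebrity endorsements.  The super-linear exponent gamma reflects news
volume reacting disproportionately once adoption takes off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geography import AgentPopulation, CityTable
from .network import SocialNetwork

MEDIA_MODES = ("off", "exogenous", "endogenous")
SEED_MODES = ("birthplace_city", "uniform")
CONTACT_MODES = ("network", "annealed_well_mixed")


@dataclass(frozen=True)
class SimulationConfig:
    """All dynamic model parameters.

    ``beta_regular`` is the weekly per-contact heed probability of a regular
    adopter; early adopters use ``min(1, adopt_ratio * beta_regular)``.
    ``media_receptiveness`` scales how closely agents listen to the media;
    setting it to zero removes media influence entirely.
    """

    n_weeks: int = 180
    beta_regular: float = 0.01
    adopt_ratio: float = 3.0
    media_receptiveness: float = 0.0
    media_mode: str = "off"
    media_exponent: float = 1.5
    shock_prob: float = 0.02
    shock_scale: float = 0.5
    seed_fraction: float = 0.001
    seed_mode: str = "birthplace_city"
    contact_mode: str = "network"
    rng_seed: int = 0

    def __post_init__(self):
        if self.media_mode not in MEDIA_MODES:
            raise ValueError(f"media_mode must be one of {MEDIA_MODES}")
        if self.contact_mode not in CONTACT_MODES:
            raise ValueError(f"contact_mode must be one of {CONTACT_MODES}")
        if self.seed_mode not in SEED_MODES:
            raise ValueError(f"seed_mode must be one of {SEED_MODES}")
        for name in ("beta_regular", "shock_prob", "seed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.adopt_ratio <= 0:
            raise ValueError("adopt_ratio must be positive")
        if self.media_receptiveness < 0 or self.shock_scale < 0:
            raise ValueError("media_receptiveness and shock_scale must be >= 0")
        if self.n_weeks < 0:
            raise ValueError("n_weeks must be >= 0")

    @property
    def beta_early(self) -> float:
        return min(1.0, self.adopt_ratio * self.beta_regular)


@dataclass
class EpidemicState:
    """Per-agent adoption status; infection is permanent (no I→S reversion)."""

    infected: np.ndarray
    adoption_week: np.ndarray  # -1 while susceptible
    week: int = 0

    @property
    def n_infected(self) -> int:
        return int(self.infected.sum())


@dataclass
class MediaSeries:
    """Weekly media volume, normalised to [0,1]."""

    volume: np.ndarray
    source: str  # "exogenous" | "endogenous" | "off"

    def __post_init__(self):
        v = np.asarray(self.volume, dtype=float)
        if len(v) and (v.min() < 0 or v.max() > 1):
            raise ValueError("media volume must lie in [0,1]")
        self.volume = v


@dataclass
class SimulationResult:
    """Weekly per-city adoption counts plus the realised media series.

    ``city_weekly[c, t]`` is the number of agents in city ``c`` newly
    adopting in week ``t`` (week 0 holds the seeds); ``national`` is the
    column sum.
    """

    city_weekly: np.ndarray
    national: np.ndarray
    media: MediaSeries
    final_state: EpidemicState
    config: SimulationConfig
    city_ids: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.national)

    @property
    def final_adopters(self) -> int:
        return int(self.national.sum())


@dataclass
class ReplicateSummary:
    """Ensemble mean and central percentile bands of cumulative adoption.

    ``band75`` holds the 12.5th/87.5th weekly percentiles, ``band95`` the
    2.5th/97.5th, so 75% and 95% of simulation runs fall inside them.
    """

    mean: np.ndarray
    band75: np.ndarray
    band95: np.ndarray
    n_reps: int
    trajectories: np.ndarray | None = field(default=None, repr=False)


def seed_infection(pop: AgentPopulation, cfg: SimulationConfig, rng: np.random.Generator,
                   table: CityTable | None = None) -> EpidemicState:
    """Initialise a small infected fraction at week 0.

    ``birthplace_city`` mode seeds inside the city with the largest
    early-adopter fraction (the innovation's birthplace analogue, as Twitter
    began in the San Francisco Bay Area); ``uniform`` seeds anywhere.
    """
    n = pop.n_agents
    n_seed = int(round(cfg.seed_fraction * n))
    if n_seed < 1:
        raise ValueError(
            f"seed_fraction={cfg.seed_fraction} yields zero seed agents for n={n}"
        )
    if cfg.seed_mode == "birthplace_city":
        if table is None:
            raise ValueError("birthplace_city seeding requires the city table")
        c = int(np.argmax(table.early_fractions))
        lo, hi = pop.city_offsets[c], pop.city_offsets[c + 1]
        candidates = np.arange(lo, hi)
        if len(candidates) == 0:
            raise ValueError("birthplace city holds no agents")
        n_seed = min(n_seed, len(candidates))
    else:
        candidates = np.arange(n)
    seeds = rng.choice(candidates, size=n_seed, replace=False)
    infected = np.zeros(n, dtype=bool)
    infected[seeds] = True
    adoption_week = np.full(n, -1, dtype=np.int64)
    adoption_week[seeds] = 0
    return EpidemicState(infected=infected, adoption_week=adoption_week, week=0)


def word_of_mouth_step(
    state: EpidemicState,
    net: SocialNetwork,
    pop: AgentPopulation,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ids of susceptibles adopting this week through their infected neighbours.

    Synchronous update from the week-start infected set: with m infected
    neighbours the heed probability is 1 - (1 - beta_tau)**m.
    """
    sus = np.flatnonzero(~state.infected)
    if len(sus) == 0:
        return sus
    m = (net.adjacency() @ state.infected.astype(np.int32))[sus]
    exposed = sus[m > 0]
    if len(exposed) == 0:
        return exposed
    beta = np.where(pop.is_early[exposed], cfg.beta_early, cfg.beta_regular)
    p = 1.0 - (1.0 - beta) ** m[m > 0]
    return exposed[rng.random(len(exposed)) < p]


def well_mixed_step(
    state: EpidemicState,
    mean_degree: float,
    pop: AgentPopulation,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Word-of-mouth step with contacts redrawn every week (annealed mixing).

    Each susceptible meets Poisson(mean_degree * I/N) infected contacts this
    week, the homogeneous-mixing limit in which the process reduces to the
    classical (discrete-week) SI model; a static graph retards spreading
    relative to this limit because an infected agent's neighbourhood
    saturates.
    """
    sus = np.flatnonzero(~state.infected)
    if len(sus) == 0:
        return sus
    m = rng.poisson(mean_degree * state.n_infected / pop.n_agents, size=len(sus))
    exposed = sus[m > 0]
    if len(exposed) == 0:
        return exposed
    beta = np.where(pop.is_early[exposed], cfg.beta_early, cfg.beta_regular)
    p = 1.0 - (1.0 - beta) ** m[m > 0]
    return exposed[rng.random(len(exposed)) < p]


def media_volume_endogenous(cumulative_adopters: int, n_agents: int,
                            cfg: SimulationConfig, rng: np.random.Generator) -> float:
    """Endogenous weekly media volume from the previous week's adopter count.

    M = clip((I/N)**gamma + eps, 0, 1); eps is a shock ~ shock_scale*U(0,1)
    occurring with probability shock_prob, else zero.  Dividing by N**gamma
    bounds the noiseless term by one without peeking at the realised
    maximum.
    """
    if not 0 <= cumulative_adopters <= n_agents:
        raise ValueError("cumulative adopters must lie in [0, N]")
    base = (cumulative_adopters / n_agents) ** cfg.media_exponent
    eps = cfg.shock_scale * rng.random() if rng.random() < cfg.shock_prob else 0.0
    return float(np.clip(base + eps, 0.0, 1.0))


def media_step(state: EpidemicState, m_t: float, cfg: SimulationConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Ids of susceptibles adopting via the media broadcast this week.

    Each susceptible flips a coin with probability min(1, a * M_t): the
    product of how much the media is reporting and how closely agents
    listen.
    """
    if not 0.0 <= m_t <= 1.0:
        raise ValueError("media volume must be in [0,1]")
    p = min(1.0, cfg.media_receptiveness * m_t)
    if p == 0.0:
        return np.empty(0, dtype=np.int64)
    sus = np.flatnonzero(~state.infected)
    return sus[rng.random(len(sus)) < p]


def run_simulation(
    pop: AgentPopulation,
    net: SocialNetwork,
    table: CityTable,
    cfg: SimulationConfig,
    media_series: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run one realisation of the adoption process for ``cfg.n_weeks`` weeks.

    Week 0 records the seeds; each subsequent week applies word of mouth
    then the media broadcast (an agent reached by both adopts once).
    Adopter counts are conserved (#S + #I = N) and cumulative adoption is
    monotone by construction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if cfg.media_mode == "exogenous":
        if media_series is None:
            raise ValueError("media_mode='exogenous' requires a media series")
        media_series = np.asarray(media_series, dtype=float)
        if len(media_series) < cfg.n_weeks + 1:
            raise ValueError(
                f"exogenous media series has {len(media_series)} weeks, "
                f"needs {cfg.n_weeks + 1}"
            )
    n = pop.n_agents
    n_cities = len(table)
    state = seed_infection(pop, cfg, rng, table=table)
    city_weekly = np.zeros((n_cities, cfg.n_weeks + 1), dtype=np.int64)
    volume = np.zeros(cfg.n_weeks + 1)
    seeds = np.flatnonzero(state.infected)
    city_weekly[:, 0] = np.bincount(pop.city_index[seeds], minlength=n_cities)

    for t in range(1, cfg.n_weeks + 1):
        prev_infected = state.n_infected
        if cfg.contact_mode == "network":
            new_wom = word_of_mouth_step(state, net, pop, cfg, rng)
        else:
            new_wom = well_mixed_step(state, net.mean_degree, pop, cfg, rng)
        if cfg.media_mode == "off":
            m_t = 0.0
        elif cfg.media_mode == "exogenous":
            m_t = float(media_series[t])
        else:
            m_t = media_volume_endogenous(prev_infected, n, cfg, rng)
        volume[t] = m_t
        new_media = media_step(state, m_t, cfg, rng)
        new = np.union1d(new_wom, new_media)
        state.infected[new] = True
        state.adoption_week[new] = t
        state.week = t
        city_weekly[:, t] = np.bincount(pop.city_index[new], minlength=n_cities)

    media = MediaSeries(volume=volume, source=cfg.media_mode)
    return SimulationResult(
        city_weekly=city_weekly,
        national=city_weekly.sum(axis=0),
        media=media,
        final_state=state,
        config=cfg,
        city_ids=table.city_ids,
    )


def replicate_rngs(master_seed: int, n_reps: int) -> list[np.random.Generator]:
    """Independent per-replicate generators derived from one master seed."""
    return [np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(k,)))
            for k in range(n_reps)]


def run_replicates(
    pop: AgentPopulation,
    net: SocialNetwork,
    table: CityTable,
    cfg: SimulationConfig,
    n_reps: int = 500,
    media_series: Sequence[float] | None = None,
    keep_trajectories: bool = False,
) -> ReplicateSummary:
    """Replicate ensemble of cumulative national adoption curves.

    Each replicate runs on an independent child stream of ``cfg.rng_seed``.
    Returns the per-week mean and the central 75%/95% percentile bands.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    traj = np.empty((n_reps, cfg.n_weeks + 1))
    for k, rng in enumerate(replicate_rngs(cfg.rng_seed, n_reps)):
        res = run_simulation(pop, net, table, cfg, media_series=media_series, rng=rng)
        traj[k] = res.cumulative
    band75 = np.percentile(traj, [12.5, 87.5], axis=0)
    band95 = np.percentile(traj, [2.5, 97.5], axis=0)
    return ReplicateSummary(
        mean=traj.mean(axis=0),
        band75=band75,
        band95=band95,
        n_reps=n_reps,
        trajectories=traj if keep_trajectories else None,
    )


def paired_media_counterfactual(
    pop: AgentPopulation,
    net: SocialNetwork,
    table: CityTable,
    cfg: SimulationConfig,
    rng_seed: int | None = None,
) -> tuple[SimulationResult, SimulationResult]:
    """Run one with-media and one no-media realisation with common random numbers.

    The no-media run uses the identical population, network and random
    stream with ``media_receptiveness`` forced to zero, so the paired
    difference isolates the media's contribution.
    """
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    cfg_off = replace(cfg, media_receptiveness=0.0)
    with_media = run_simulation(pop, net, table, cfg,
                                rng=np.random.default_rng(seed))
    without = run_simulation(pop, net, table, cfg_off,
                             rng=np.random.default_rng(seed))
    return with_media, without
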