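"""Social-network construction and structural measures.

Two constructions are provided:

* :func:`build_mixing_network` — a configuration-model random graph with a
  Poisson degree distribution and no geographic or type bias (homogeneous
  mixing baseline).
* :func:`build_spatial_network` — ties are placed in geographic space: a
  partner city is drawn with probability proportional to its population
  times a truncated power-law kernel of the inter-city distance, and a
  same-type (early/early or regular/regular) candidate is preferentially
  accepted, producing homophily by adopter type.  Forcing the kernel
  constant (``alpha=0``) yields the non-spatial homophilous variant used to
  isolate the effect of geography.

Structural measures: the mean fraction of early adopters among an early
adopter's neighbours (homophily), and the relative size of the largest
connected component of the early-adopter-induced subgraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .geography import AgentPopulation, CityTable


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the tie-placement kernel and homophily preference.

    alpha
        Exponent of the distance decay; friendship probability per capita
        falls off as d**-alpha up to the cutoff. ``alpha=0`` removes
        geography entirely.
    d_cutoff
        Distance (km) beyond which the kernel is flat, reflecting the
        roughly constant long-range connection probability of online
        friendships.
    homophily_pref
        Probability of accepting a candidate partner of the *same* adopter
        type; a different-type candidate is accepted with one minus this.
        0.5 is neutral.
    d_floor
        Regularisation (km) for within-city ties at distance zero.
    max_retries
        Rejected candidates are redrawn up to this many times, after which
        the draw is accepted unconditionally so construction always
        terminates.
    """

    alpha: float = 1.0
    d_cutoff: float = 1000.0
    homophily_pref: float = 0.5
    d_floor: float = 1.0
    max_retries: int = 25

    def __post_init__(self):
        if self.d_cutoff <= 0:
            raise ValueError("d_cutoff must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.homophily_pref <= 1.0:
            raise ValueError("homophily_pref must be in [0,1]")


def distance_kernel(d, params: KernelParams):
    """Truncated power-law tie weight: max(d, d_floor)**-alpha, flat past d_cutoff."""
    d_eff = np.clip(np.asarray(d, dtype=float), params.d_floor, params.d_cutoff)
    return d_eff ** (-params.alpha)


@dataclass
class SocialNetwork:
    """Undirected simple graph over agent ids ``0..n_nodes-1``.

    Edges are stored as a unique ``(E, 2)`` array with ``edges[:,0] <
    edges[:,1]``; the symmetric CSR adjacency is built lazily.
    """

    n_nodes: int
    edges: np.ndarray
    _adj: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def adjacency(self) -> sp.csr_matrix:
        if self._adj is None:
            if self.n_edges == 0:
                self._adj = sp.csr_matrix((self.n_nodes, self.n_nodes), dtype=np.int32)
            else:
                a, b = self.edges[:, 0], self.edges[:, 1]
                data = np.ones(2 * len(a), dtype=np.int32)
                self._adj = sp.csr_matrix(
                    (data, (np.concatenate([a, b]), np.concatenate([b, a]))),
                    shape=(self.n_nodes, self.n_nodes),
                )
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def to_edge_csv(self, path) -> None:
        """Write `agent_id_a,agent_id_b` rows, one undirected edge each, a<b."""
        np.savetxt(path, self.edges, fmt="%d", delimiter=",", header="agent_id_a,agent_id_b", comments="")


def _finalize_edges(n_nodes: int, a: np.ndarray, b: np.ndarray) -> SocialNetwork:
    """Drop self-loops and duplicate pairs; return a simple graph."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    keep = lo != hi
    pairs = np.unique(np.stack([lo[keep], hi[keep]], axis=1), axis=0)
    return SocialNetwork(n_nodes=n_nodes, edges=pairs)


def sample_degrees(n: int, mean_degree: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson degree sequence with an even sum (stub matching requires it).

    If the raw sum is odd, one uniformly chosen agent's degree is
    incremented by one.
    """
    if mean_degree < 0:
        raise ValueError("mean_degree must be >= 0")
    deg = rng.poisson(mean_degree, size=n)
    if deg.sum() % 2 == 1:
        deg[rng.integers(n)] += 1
    return deg


def build_mixing_network(
    pop: AgentPopulation, mean_degree: float, seed: int | np.random.SeedSequence = 0
) -> SocialNetwork:
    """Configuration-model graph: stubs paired uniformly at random.

    Removes any geographic or type bias in friendship (homogeneous mixing).
    Self-loops and multi-edges from the pairing are discarded, not rewired,
    so the realised mean degree sits marginally below the target.
    """
    n = pop.n_agents
    if n < 2:
        raise ValueError("need at least 2 agents")
    rng = np.random.default_rng(seed)
    deg = sample_degrees(n, mean_degree, rng)
    stubs = np.repeat(np.arange(n), deg)
    rng.shuffle(stubs)
    half = len(stubs) // 2
    return _finalize_edges(n, stubs[:half], stubs[half:])


def _city_choice_cumulative(table: CityTable, pop: AgentPopulation, params: KernelParams) -> np.ndarray:
    """Row-cumulative partner-city probabilities: weight ∝ city agent count × kernel."""
    D = table.distance_matrix()
    W = distance_kernel(D, params) * pop.city_counts()[None, :].astype(float)
    W /= W.sum(axis=1, keepdims=True)
    return np.cumsum(W, axis=1)


def build_spatial_network(
    pop: AgentPopulation,
    table: CityTable,
    mean_degree: float,
    params: KernelParams,
    seed: int | np.random.SeedSequence = 0,
) -> SocialNetwork:
    """Spatially embedded, homophily-preferring social network.

    Each agent initiates Poisson(mean_degree/2) tie proposals, so realised
    degrees (initiated plus received) are approximately Poisson with the
    target mean.  For each proposal a partner city is drawn with probability
    proportional to its agent count times the distance kernel from the
    initiator's city; a uniform agent within that city is the candidate.
    Same-type candidates are accepted with probability ``homophily_pref``,
    different-type ones with its complement; rejected proposals are redrawn
    (city and agent) up to ``max_retries`` times, then accepted
    unconditionally.  The result is reduced to a simple graph.
    """
    n = pop.n_agents
    rng = np.random.default_rng(seed)
    if n < 2:
        warnings.warn("fewer than 2 agents: returning an empty network")
        return SocialNetwork(n_nodes=n, edges=np.empty((0, 2), dtype=int))
    cum = _city_choice_cumulative(table, pop, params)
    counts = pop.city_counts()
    offsets = pop.city_offsets
    h = params.homophily_pref

    n_out = rng.poisson(mean_degree / 2.0, size=n)
    src = np.repeat(np.arange(n), n_out)
    partner = np.empty(len(src), dtype=np.int64)

    pending = np.arange(len(src))
    for attempt in range(params.max_retries + 1):
        if len(pending) == 0:
            break
        # draw partner cities grouped by source city so each group uses a
        # single 1-D inverse-CDF lookup
        sc = pop.city_index[src[pending]]
        order = np.argsort(sc, kind="stable")
        sc_sorted = sc[order]
        u = rng.random(len(pending))
        pc = np.empty(len(pending), dtype=np.int64)
        bounds = np.flatnonzero(np.diff(sc_sorted)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(sc_sorted)]])
        for s, e in zip(starts, stops):
            c = sc_sorted[s]
            pc[order[s:e]] = np.searchsorted(cum[c], u[s:e], side="right")
        np.minimum(pc, len(counts) - 1, out=pc)  # guard float round-off at the CDF tail
        cand = offsets[pc] + (rng.random(len(pending)) * counts[pc]).astype(np.int64)
        partner[pending] = cand
        if attempt < params.max_retries:
            same = pop.is_early[src[pending]] == pop.is_early[cand]
            p_acc = np.where(same, h, 1.0 - h)
            pending = pending[rng.random(len(pending)) >= p_acc]
        else:
            pending = pending[:0]
    return _finalize_edges(n, src, partner)


def build_nonspatial_homophilous_network(
    pop: AgentPopulation,
    table: CityTable,
    mean_degree: float,
    params: KernelParams,
    seed: int | np.random.SeedSequence = 0,
) -> SocialNetwork:
    """Same construction with the distance kernel forced constant.

    Partner cities are then drawn purely by population, isolating the
    contribution of geography from that of type homophily.
    """
    return build_spatial_network(pop, table, mean_degree, replace(params, alpha=0.0), seed=seed)


def measure_homophily(net: SocialNetwork, pop: AgentPopulation) -> float:
    """Mean fraction of an early adopter's friends who are also early adopters.

    Averaged over early adopters with at least one neighbour.
    """
    deg = net.degrees()
    mask = pop.is_early & (deg > 0)
    if not mask.any():
        raise ValueError("no early adopter with degree >= 1")
    early_nbrs = net.adjacency() @ pop.is_early.astype(np.int32)
    return float(np.mean(early_nbrs[mask] / deg[mask]))


def early_adopter_giant_component(net: SocialNetwork, pop: AgentPopulation) -> float:
    """Fraction of early adopters inside the largest component of their subgraph.

    The subgraph induced on early adopters shows whether type-similar agents
    form one connected cluster or sit isolated among regular adopters.
    """
    early_ids = np.flatnonzero(pop.is_early)
    n_early = len(early_ids)
    if n_early == 0:
        raise ValueError("population has no early adopters")
    remap = -np.ones(net.n_nodes, dtype=np.int64)
    remap[early_ids] = np.arange(n_early)
    e = net.edges
    both = pop.is_early[e[:, 0]] & pop.is_early[e[:, 1]]
    sub = e[both]
    if len(sub) == 0:
        return 1.0 / n_early
    a, b = remap[sub[:, 0]], remap[sub[:, 1]]
    adj = sp.csr_matrix((np.ones(len(a), dtype=np.int8), (a, b)), shape=(n_early, n_early))
    _, labels = connected_components(adj, directed=False)
    return float(np.bincount(labels).max() / n_early)
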