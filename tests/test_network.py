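import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy import stats

from adoptnet import (
    KernelParams,
    CityTable,
    allocate_agents,
    build_mixing_network,
    build_nonspatial_homophilous_network,
    build_spatial_network,
    distance_kernel,
    early_adopter_giant_component,
    generate_synthetic_cities,
    measure_homophily,
    sample_degrees,
)
from adoptnet.network import SocialNetwork, _finalize_edges


def _net_from_edges(n, pairs):
    return _finalize_edges(n, np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))


class TestDistanceKernel:
    def test_zero_exponent_is_flat(self):
        p = KernelParams(alpha=0.0)
        d = np.array([0.0, 5.0, 500.0, 5000.0])
        assert np.allclose(distance_kernel(d, p), 1.0)

    def test_power_law_ratio(self):
        p = KernelParams(alpha=1.0)
        assert distance_kernel(100.0, p) / distance_kernel(200.0, p) == pytest.approx(2.0)

    def test_plateau_beyond_cutoff(self):
        p = KernelParams(alpha=1.5, d_cutoff=1000.0)
        assert distance_kernel(1500.0, p) == distance_kernel(2500.0, p)

    def test_floor_regularises_within_city(self):
        p = KernelParams(alpha=1.0, d_floor=1.0)
        assert distance_kernel(0.0, p) == distance_kernel(1.0, p) == 1.0


class TestDegreeSequence:
    def test_zero_mean_degree_all_zero(self, rng):
        assert sample_degrees(100, 0.0, rng).sum() == 0

    def test_sum_always_even(self, rng):
        for _ in range(20):
            assert sample_degrees(101, 3.3, rng).sum() % 2 == 0

    def test_sample_mean_close_to_target(self, rng):
        n, mu = 100_000, 10.0
        deg = sample_degrees(n, mu, rng)
        assert abs(deg.mean() - mu) < 3 * np.sqrt(mu / n)


class TestMixingNetwork:
    def test_zero_mean_degree_empty(self, small_pop):
        net = build_mixing_network(small_pop, 0.0, seed=1)
        assert net.n_edges == 0

    def test_simple_graph_and_mean_degree(self):
        t = generate_synthetic_cities(20, seed=2)
        pop = allocate_agents(t, 20_000)
        net = build_mixing_network(pop, 10.0, seed=3)
        assert abs(net.mean_degree - 10.0) / 10.0 < 0.05
        e = net.edges
        assert (e[:, 0] < e[:, 1]).all()
        assert len(np.unique(e, axis=0)) == len(e)

    def test_edge_city_pairs_product_multinomial(self):
        # stub pairing implies ordered city pairs ~ product of city sizes
        df = pd.DataFrame(
            {
                "city_id": range(4),
                "lat": [10.0, 20.0, 30.0, 40.0],
                "lon": [10.0, 20.0, 30.0, 40.0],
                "pop_share": [0.4, 0.3, 0.2, 0.1],
                "early_fraction": 0.2,
            }
        )
        t = CityTable(df)
        pop = allocate_agents(t, 20_000)
        net = build_mixing_network(pop, 8.0, seed=4)
        c = pop.city_index[net.edges]  # E x 2
        both = np.concatenate([c, c[:, ::-1]])  # both orientations
        obs = np.zeros((4, 4))
        np.add.at(obs, (both[:, 0], both[:, 1]), 1)
        shares = pop.city_counts() / pop.n_agents
        expected = np.outer(shares, shares) * obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        # 15 dof (16 cells - 1); generous bound, loops/dupes removal perturbs slightly
        assert chi2 < stats.chi2.ppf(0.999, df=15)


class TestSpatialNetwork:
    def test_single_agent_empty_graph_with_warning(self):
        t = generate_synthetic_cities(1, seed=0)
        pop = allocate_agents(t, 1)
        with pytest.warns(UserWarning):
            net = build_spatial_network(pop, t, 5.0, KernelParams(), seed=0)
        assert net.n_edges == 0

    def test_single_city_reduces_to_within_city_mixing(self):
        t = generate_synthetic_cities(1, early_fraction_spec=("constant", 0.5), seed=0)
        pop = allocate_agents(t, 3_000)
        net = build_spatial_network(pop, t, 8.0, KernelParams(homophily_pref=0.5), seed=5)
        assert abs(net.mean_degree - 8.0) / 8.0 < 0.1
        # neutral homophily, equal types: early neighbour share matches type share
        assert abs(measure_homophily(net, pop) - 0.5) < 0.03

    def test_neutral_preference_recovers_global_early_share(self):
        t = generate_synthetic_cities(30, early_fraction_spec=("constant", 0.3), seed=1)
        pop = allocate_agents(t, 10_000)
        net = build_spatial_network(pop, t, 10.0, KernelParams(homophily_pref=0.5), seed=6)
        global_share = pop.n_early / pop.n_agents
        assert abs(measure_homophily(net, pop) - global_share) < 0.03

    def test_realised_mean_degree_near_target(self, small_table):
        pop = allocate_agents(small_table, 10_000)
        net = build_spatial_network(pop, small_table, 10.0, KernelParams(homophily_pref=0.5), seed=7)
        assert abs(net.mean_degree - 10.0) / 10.0 < 0.08

    def test_homophily_monotone_in_preference(self):
        # averaged over seeds, measured homophily rises with the preference
        t = generate_synthetic_cities(50, seed=3)
        pop = allocate_agents(t, 4_000)
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        rhos = []
        for s in range(20):
            m = [
                measure_homophily(
                    build_spatial_network(pop, t, 8.0, KernelParams(homophily_pref=h), seed=100 * s + i),
                    pop,
                )
                for i, h in enumerate(grid)
            ]
            rhos.append(stats.spearmanr(grid, m).statistic)
        assert np.mean(rhos) > 0.9

    def test_edge_distances_match_kernel(self):
        # two-sample KS between realised edge distances and kernel-sampled ones
        t = generate_synthetic_cities(60, seed=8)
        pop = allocate_agents(t, 12_000)
        params = KernelParams(alpha=1.0, d_cutoff=1000.0, homophily_pref=0.5)
        net = build_spatial_network(pop, t, 10.0, params, seed=9)
        assert net.n_edges >= 5e4
        D = t.distance_matrix()
        edge_d = D[pop.city_index[net.edges[:, 0]], pop.city_index[net.edges[:, 1]]]
        rng = np.random.default_rng(10)
        counts = pop.city_counts()
        W = distance_kernel(D, params) * counts[None, :].astype(float)
        src = rng.choice(len(t), p=counts / counts.sum(), size=100_000)
        probs = W / W.sum(axis=1, keepdims=True)
        tgt = np.array([rng.choice(len(t), p=probs[c]) for c in src[:20_000]])
        oracle_d = D[src[:20_000], tgt]
        ks = stats.ks_2samp(edge_d, oracle_d).statistic
        assert ks < 0.05


class TestHomophilyMeasure:
    def test_all_early_gives_one(self):
        pop = _pop_with_types([True] * 4)
        net = _net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert measure_homophily(net, pop) == 1.0

    def test_star_graph_hand_enumeration(self):
        # early centre 0 with two early leaves (1,2) and two regular (3,4):
        # centre 2/4, early leaves 1 and 1 -> mean 5/6... computed by hand:
        # (0.5 + 1 + 1)/3 = 5/6
        pop = _pop_with_types([True, True, True, False, False])
        net = _net_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert measure_homophily(net, pop) == pytest.approx(5 / 6)

    def test_fully_heterophilous_gives_zero(self):
        pop = _pop_with_types([True, False, True, False])
        net = _net_from_edges(4, [(0, 1), (2, 3), (2, 1)])
        assert measure_homophily(net, pop) == 0.0

    def test_error_without_qualifying_agents(self):
        pop = _pop_with_types([True, False])
        net = SocialNetwork(n_nodes=2, edges=np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError):
            measure_homophily(net, pop)


class TestGiantComponent:
    def test_path_of_early_agents_is_fully_connected(self):
        pop = _pop_with_types([True] * 5 + [False])
        net = _net_from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        assert early_adopter_giant_component(net, pop) == 1.0

    def test_isolated_early_agents(self):
        pop = _pop_with_types([True] * 50 + [False] * 10)
        net = SocialNetwork(n_nodes=60, edges=np.empty((0, 2), dtype=int))
        assert early_adopter_giant_component(net, pop) == pytest.approx(0.02)

    def test_matches_networkx_on_random_graphs(self):
        # independent oracle: induced-subgraph components via networkx
        rng = np.random.default_rng(11)
        for trial in range(5):
            n = 60
            g = nx.gnp_random_graph(n, 0.05, seed=trial)
            types = rng.random(n) < 0.4
            if not types.any():
                types[0] = True
            pop = _pop_with_types(types.tolist())
            edges = np.array(g.edges) if g.number_of_edges() else np.empty((0, 2), dtype=int)
            net = _net_from_edges(n, edges.tolist())
            sub = g.subgraph(np.flatnonzero(types))
            expected = (
                max(len(c) for c in nx.connected_components(sub)) / types.sum()
                if sub.number_of_nodes()
                else None
            )
            assert early_adopter_giant_component(net, pop) == pytest.approx(expected)

    def test_no_early_agents_is_an_error(self):
        pop = _pop_with_types([False, False])
        net = _net_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            early_adopter_giant_component(net, pop)


def _pop_with_types(types):
    from adoptnet.geography import AgentPopulation

    n = len(types)
    return AgentPopulation(
        city_index=np.zeros(n, dtype=int),
        is_early=np.array(types, dtype=bool),
        city_offsets=np.array([0, n]),
    )


class TestSpatialVsNonspatialStructure:
    def test_nonspatial_variant_ignores_distance(self):
        # moving cities around must not change the edge city-pair statistics
        base = generate_synthetic_cities(12, seed=13)
        moved = CityTable(
            base.df.assign(lat=base.df.lat.sample(frac=1, random_state=0).to_numpy()),
            provenance="synthetic",
        )
        pop = allocate_agents(base, 6_000)
        p = KernelParams(homophily_pref=0.6)
        n1 = build_nonspatial_homophilous_network(pop, base, 8.0, p, seed=14)
        n2 = build_nonspatial_homophilous_network(pop, moved, 8.0, p, seed=14)
        c1 = np.bincount(pop.city_index[n1.edges].ravel(), minlength=12)
        c2 = np.bincount(pop.city_index[n2.edges].ravel(), minlength=12)
        assert np.array_equal(c1, c2)

    def test_default_spatial_configuration_connects_early_adopters(self):
        t = generate_synthetic_cities(408, seed=15)
        pop = allocate_agents(t, 10_000)
        net = build_spatial_network(pop, t, 10.0, KernelParams(homophily_pref=0.8), seed=16)
        assert early_adopter_giant_component(net, pop) > 0.9


class TestEdgeExport:
    def test_edge_csv_roundtrip(self, tmp_path, small_spatial_net):
        p = tmp_path / "edges.csv"
        small_spatial_net.to_edge_csv(p)
        back = np.loadtxt(p, delimiter=",", skiprows=1, dtype=int)
        assert np.array_equal(back, small_spatial_net.edges)
        assert (back[:, 0] < back[:, 1]).all()
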