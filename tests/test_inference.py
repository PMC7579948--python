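"""Bootstrap machinery: p-values, samplers, tests, FDR, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsnet import (
    Network,
    adjust_fdr,
    build_matrices,
    empirical_pvalue,
    gna_test,
    gnt_test,
    map_geneset,
    sample_degree_matched,
    sample_uniform,
)
from gsnet.inference import degree_bins
from gsnet.simulate import HdnSpec, generate_hdn_network
from conftest import geneset, random_connected_graph


class TestEmpiricalPvalue:
    def test_worked_case(self):
        assert empirical_pvalue(5.5, np.arange(1, 11), "upper") == pytest.approx(6 / 11)

    def test_extremes(self):
        Q = np.arange(1, 11)
        assert empirical_pvalue(99, Q, "upper") == pytest.approx(1 / 11)
        assert empirical_pvalue(0, Q, "upper") == 1.0
        assert empirical_pvalue(0, Q, "lower") == pytest.approx(1 / 11)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([]))

    @settings(derandomize=True, max_examples=50)
    @given(
        q=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
        obs=st.floats(-1e6, 1e6),
        tail=st.sampled_from(["upper", "lower"]),
    )
    def test_pseudocount_bounds(self, q, obs, tail):
        p = empirical_pvalue(obs, np.array(q), tail)
        assert 1 / (len(q) + 1) <= p <= 1.0


class TestFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_case(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=30)
        adj = adjust_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestUniformSampler:
    def test_full_set(self):
        rng = np.random.default_rng(0)
        assert sample_uniform(list("abc"), 3, rng) == {"a", "b", "c"}

    def test_deterministic_given_seed(self):
        nodes = [f"n{i}" for i in range(50)]
        s1 = sample_uniform(nodes, 10, np.random.default_rng(42))
        s2 = sample_uniform(nodes, 10, np.random.default_rng(42))
        assert s1 == s2

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            sample_uniform(list("ab"), 3, np.random.default_rng(0))

    def test_frequencies_unbiased(self):
        """Each of 10 nodes drawn with rate 0.1 +- 3 sigma over 10k size-1 draws."""
        nodes = [f"n{i}" for i in range(10)]
        rng = np.random.default_rng(7)
        counts = {n: 0 for n in nodes}
        for _ in range(10_000):
            counts[next(iter(sample_uniform(nodes, 1, rng)))] += 1
        sigma = np.sqrt(0.1 * 0.9 / 10_000)
        for c in counts.values():
            assert abs(c / 10_000 - 0.1) < 3 * sigma


class TestDegreeMatchedSampler:
    def test_regular_graph_any_node(self, triangle_net):
        S = geneset(triangle_net, {"a"})
        s = sample_degree_matched(triangle_net, S, np.random.default_rng(0))
        assert len(s) == 1 and s <= set(triangle_net.nodes)

    def test_hub_reference_stays_in_hub_bin(self, star_net):
        S = geneset(star_net, {"c"})
        for seed in range(5):
            s = sample_degree_matched(star_net, S, np.random.default_rng(seed))
            assert s == {"c"}  # the center is alone in its degree bin

    def test_mean_degree_tracks_reference(self):
        """Sampler calibration on a hub-heavy network."""
        spec = HdnSpec(n_nodes=300, n_hd=10, p0=0.02, p_hd=0.3, seed=5)
        network, hubs = generate_hdn_network(spec)
        S = map_geneset(set(hubs[:3]) | set(network.nodes[50:56]), network, "ref")
        ref_mean = np.mean([network.degree_of(g) for g in S.mapped])
        rng = np.random.default_rng(11)
        means = [
            np.mean([network.degree_of(g)
                     for g in sample_degree_matched(network, S, rng)])
            for _ in range(1000)
        ]
        assert abs(np.mean(means) - ref_mean) / ref_mean < 0.10

    def test_exhausted_bin_errors(self, star_net):
        # two copies of the unique hub bin cannot be sampled without replacement
        S = geneset(star_net, {"c"})
        bins = degree_bins(star_net.degrees)
        from gsnet.inference import _sample_degree_matched_idx

        with pytest.raises(ValueError, match="candidate"):
            _sample_degree_matched_idx(
                np.random.default_rng(0), bins, np.array([2, 2])
            )


class TestGntTest:
    def test_planted_clique_detected(self):
        """An isolated clique in a sparse background is significant."""
        rng_net = random_connected_graph(60, 0.05, 21)
        adj = rng_net.adjacency.copy()
        idx = np.arange(6)
        adj[np.ix_(idx, idx)] = 1
        np.fill_diagonal(adj, 0)
        net = Network.from_adjacency(rng_net.nodes, adj)
        S = geneset(net, [net.nodes[i] for i in idx], "clique")
        res = gnt_test(S, "internal_degree", net=net, n_samples=500, seed=3)
        assert res.pvalue <= 0.05

    def test_single_sample_pvalues(self, triangle_net):
        S = geneset(triangle_net, {"a", "b"})
        res = gnt_test(S, "total_degree", net=triangle_net, n_samples=1, seed=0)
        assert res.pvalue in (0.5, 1.0)

    def test_pvalue_bounds(self):
        net = random_connected_graph(30, 0.15, 2)
        S = geneset(net, net.nodes[:5])
        res = gnt_test(S, "module", net=net, n_samples=50, seed=1)
        assert 1 / 51 <= res.pvalue <= 1.0

    def test_parallel_matches_serial(self):
        net = random_connected_graph(40, 0.15, 6)
        m = build_matrices(net)
        S = geneset(net, net.nodes[:6])
        kwargs = dict(net=net, matrices=m, n_samples=40, seed=9)
        serial = gnt_test(S, "heat", cores=1, **kwargs)
        parallel = gnt_test(S, "heat", cores=4, **kwargs)
        assert np.array_equal(serial.null.values, parallel.null.values)
        assert serial.pvalue == parallel.pvalue

    def test_seed_reproducibility(self):
        net = random_connected_graph(30, 0.2, 3)
        S = geneset(net, net.nodes[:5])
        r1 = gnt_test(S, "internal_degree", net=net, n_samples=30, seed=7)
        r2 = gnt_test(S, "internal_degree", net=net, n_samples=30, seed=7)
        assert np.array_equal(r1.null.values, r2.null.values)

    def test_unknown_statistic_rejected(self, triangle_net):
        S = geneset(triangle_net, {"a", "b"})
        with pytest.raises(ValueError, match="unknown"):
            gnt_test(S, "closeness", net=triangle_net)


@pytest.fixture(scope="module")
def planted():
    """A linked block pair from the association generator, at reduced scale."""
    from gsnet import gna_benchmark, largest_connected_component

    ds = gna_benchmark(
        n_nodes=500, block_size=30, p0=0.015, alpha=3.0, beta_mix=10.0,
        pi=2 / 30, n_networks=1, seed=23,
    )[0]
    net = largest_connected_component(ds.network)
    m = build_matrices(net)
    pair = ds.pairs[0]  # positive: blocks linked with high between probability
    S1 = map_geneset(pair.genes_a, net, pair.name_a)
    S2 = map_geneset(pair.genes_b, net, pair.name_b)
    return net, m, S1, S2


class TestGnaTest:
    def test_planted_association_detected(self, planted):
        _, m, S1, S2 = planted
        res = gna_test(S1, S2, "association_heat", m, n_samples=300, seed=5)
        assert res.pvalue <= 0.05

    def test_fix_first_no_less_conservative(self, planted):
        """Resampling only one set yields p-values at least as large on average."""
        _, m, S1, S2 = planted
        p_both, p_fix = [], []
        for seed in range(15):
            p_both.append(
                gna_test(S1, S2, "association_heat", m, n_samples=100,
                         mode="both_random", seed=seed).pvalue
            )
            p_fix.append(
                gna_test(S1, S2, "association_heat", m, n_samples=100,
                         mode="fix_first", seed=seed).pvalue
            )
        assert np.mean(p_fix) >= np.mean(p_both) - 0.02

    def test_modes_and_errors(self, planted):
        _, m, S1, S2 = planted
        with pytest.raises(ValueError, match="mode"):
            gna_test(S1, S2, "association_heat", m, mode="bogus")
        res = gna_test(S1, S2, "association_sp", m, n_samples=20, seed=0)
        assert res.statistic == "association_shortest_path"
        assert res.tail == "lower"
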