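import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltamaps.field import Field
from deltamaps.network import (BalanceResult, DomainSignal, Edge,
                               FunctionalNetwork, bartlett_variance_lagged,
                               domain_signal, edge_significance, edge_weight,
                               fdr_select, infer_lag_range,
                               infer_network_from_signals,
                               lag_consistent_triangles,
                               lagged_crosscorrelation, structural_balance)
from deltamaps.network import Correlogram


def ar1(T, phi, rng):
    x = np.zeros(T + 50)
    e = rng.standard_normal(T + 50)
    for t in range(1, T + 50):
        x[t] = phi * x[t - 1] + e[t]
    return x[50:]


def make_signal(x, did=0):
    return DomainSignal(domain_id=did, series=np.asarray(x, dtype=float), mode="test")


class TestDomainSignal:
    def test_single_cell_average_is_the_cell_series(self, rng):
        X = rng.standard_normal((40, 4))
        f = Field(X)
        s = domain_signal(f, [2], mode="average")
        np.testing.assert_allclose(s.series, X[:, 2])

    def test_equal_weights_make_modes_proportional(self, rng):
        X = rng.standard_normal((60, 5))
        f = Field(X)
        a = domain_signal(f, [0, 1, 3], mode="average")
        c = domain_signal(f, [0, 1, 3], mode="cumulative", cell_weight=np.full(5, 2.5))
        assert np.corrcoef(a.series, c.series)[0, 1] == pytest.approx(1.0)

    def test_cos_latitude_weighting(self, rng):
        # cells at latitude 0 and 60 degrees: the second carries half the weight
        X = rng.standard_normal((50, 2))
        f = Field(X)
        w = np.cos(np.deg2rad([0.0, 60.0]))
        s = domain_signal(f, [0, 1], mode="cumulative", cell_weight=w)
        expected = (1.0 * X[:, 0] + 0.5 * X[:, 1]) / 1.5
        np.testing.assert_allclose(s.series, expected)


class TestCorrelogram:
    def test_zero_lag_self_correlation_is_one(self, rng):
        x = rng.standard_normal(200)
        c = lagged_crosscorrelation(make_signal(x, 0), make_signal(x, 1), 5)
        assert c.r[c.lag_index(0)] == pytest.approx(1.0)

    def test_shifted_copy_peaks_at_the_shift(self, rng):
        # b(t) = a(t - 5): a precedes b, so the peak is at lag +5
        a = rng.standard_normal(400)
        b = np.roll(a, 5)
        c = lagged_crosscorrelation(make_signal(a, 0), make_signal(b, 1), 10)
        k = int(np.abs(c.r).argmax())
        assert c.lags[k] == 5
        assert c.r[k] > 0.9

    def test_uncorrelated_signals_stay_small(self):
        T = 400
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = lagged_crosscorrelation(
                make_signal(rng.standard_normal(T), 0),
                make_signal(rng.standard_normal(T), 1), 10)
            assert np.abs(c.r).max() < 4 / np.sqrt(T)

    def test_tau_max_guard(self, rng):
        x = rng.standard_normal(40)
        with pytest.raises(ValueError):
            lagged_crosscorrelation(make_signal(x), make_signal(x, 1), 11)


class TestBartlettLagged:
    def test_white_noise_limit(self):
        rng = np.random.default_rng(5)
        T = 1200
        v = bartlett_variance_lagged(make_signal(rng.standard_normal(T), 0),
                                     make_signal(rng.standard_normal(T), 1), 0)
        assert v == pytest.approx(1 / T, rel=0.2)

    def test_symmetric_in_lag_sign(self, rng):
        a = make_signal(ar1(300, 0.5, rng), 0)
        b = make_signal(ar1(300, 0.5, rng), 1)
        assert bartlett_variance_lagged(a, b, 7) == bartlett_variance_lagged(a, b, -7)

    def test_matches_monte_carlo_for_ar_pairs(self):
        T, phi, tau = 256, 0.8, 3
        rng = np.random.default_rng(9)
        rs, vs = [], []
        for _ in range(1000):
            a = make_signal(ar1(T, phi, rng), 0)
            b = make_signal(ar1(T, phi, rng), 1)
            c = lagged_crosscorrelation(a, b, 5)
            rs.append(c.r[c.lag_index(tau)])
            vs.append(bartlett_variance_lagged(a, b, tau))
        assert np.mean(vs) == pytest.approx(np.var(rs), rel=0.25)


class TestSignificanceAndFDR:
    def test_pvalue_trivia(self):
        c = Correlogram(pair=(0, 1), lags=np.array([-1, 0, 1]),
                        r=np.array([0.0, 0.2, 0.4]),
                        var=np.array([0.01, 0.01, 0.01]))
        p = edge_significance(c)
        assert p[0] == pytest.approx(1.0)
        assert np.all(np.diff(p) < 0)  # p monotone decreasing in |z|
        c2 = Correlogram(pair=(0, 1), lags=np.array([0]),
                         r=np.array([0.196]), var=np.array([0.01]))
        assert edge_significance(c2)[0] == pytest.approx(0.05, abs=0.002)

    def test_fdr_extremes(self):
        assert fdr_select(np.ones(30), 0.1).size == 0
        assert fdr_select(np.zeros(30), 0.1).size == 30
        with pytest.raises(ValueError):
            fdr_select([], 0.1)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-9, 1.0 - 1e-9), min_size=1, max_size=60),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_fdr_matches_bruteforce_oracle(self, pvals, q):
        """BH keep set equals exhaustive evaluation of the step-up rule."""
        p = np.asarray(pvals)
        kept = set(map(int, fdr_select(p, q)))
        M = p.size
        ranked = sorted(p)
        m_star = 0
        for m in range(1, M + 1):  # brute force: test every rank
            if ranked[m - 1] < q * m / M:
                m_star = m
        thresh = ranked[m_star - 1] if m_star else -1.0
        oracle = {i for i, v in enumerate(p) if v <= thresh}
        # resolve ties at the threshold the way the step-up does: keep m* total
        assert len(kept) == m_star
        assert kept <= oracle

    def test_fdr_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500) ** 2
        kept = np.zeros(500, dtype=bool)
        kept[fdr_select(p, 0.1)] = True
        ref = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        np.testing.assert_array_equal(kept, ref)


class TestLagRangeAndWeight:
    def _correlogram(self, r_by_lag, var=0.01):
        lags = np.array(sorted(r_by_lag))
        r = np.array([r_by_lag[t] for t in lags])
        c = Correlogram(pair=(0, 1), lags=lags, r=r, var=np.full(lags.size, var))
        edge_significance(c)
        return c

    def test_single_zero_lag_is_undirected(self):
        c = self._correlogram({-1: 0.0, 0: 0.8, 1: 0.0})
        info = infer_lag_range(c, [0])
        assert (info["lag_min"], info["lag_max"]) == (0, 0)
        assert info["direction"] == "undirected"

    def test_tied_maxima_within_one_sd_share_the_range(self):
        c = self._correlogram({1: 0.1, 2: 0.8, 3: 0.8, 4: 0.1}, var=0.0025)
        info = infer_lag_range(c, [2, 3])
        assert set(info["lag_set"]) == {2, 3}
        assert info["direction"] == "a->b"

    def test_negative_lags_direct_the_other_way(self):
        c = self._correlogram({-3: -0.9, -2: -0.85, 0: 0.1}, var=0.0025)
        info = infer_lag_range(c, [-3, -2])
        assert info["direction"] == "b->a"
        assert info["tau_star"] == -3
        assert (info["lag_min"], info["lag_max"]) == (-3, -2)

    def test_one_sd_rule_excludes_weak_lags(self):
        # sd = 0.05; |r*| = 0.8: lag with |r| = 0.7 is outside one sd
        c = self._correlogram({0: 0.7, 1: 0.8}, var=0.0025)
        info = infer_lag_range(c, [0, 1])
        assert set(info["lag_set"]) == {1}
        assert info["direction"] == "a->b"

    def test_edge_weight_scales_with_signal_sd(self, rng):
        a = make_signal(rng.standard_normal(100), 0)
        b = make_signal(rng.standard_normal(100), 1)
        w = edge_weight(a, b, 0.5)
        a3 = make_signal(3.0 * a.series, 0)
        assert edge_weight(a3, b, 0.5) == pytest.approx(3 * w)
        assert np.sign(edge_weight(a, b, -0.4)) == -1


class TestInferNetwork:
    def test_planted_lagged_edge_recovered(self, rng):
        T = 800
        base = ar1(T, 0.3, rng)
        sigs = [make_signal(base, 0),
                make_signal(np.roll(base, 5) + 0.4 * rng.standard_normal(T), 1),
                make_signal(rng.standard_normal(T), 2)]
        net = infer_network_from_signals(sigs, tau_max=10, q=0.05)
        assert [(e.a, e.b) for e in net.edges] == [(0, 1)]
        e = net.edges[0]
        assert e.lag_min <= 5 <= e.lag_max
        assert e.direction == "a->b"
        assert e.tau_star in e.lag_set
        assert net.n_tests == 3 * 21

    def test_fewer_than_two_domains_gives_empty_network(self, rng):
        net = infer_network_from_signals([make_signal(rng.standard_normal(100))])
        assert net.edges == []

    def test_swap_symmetry(self, rng):
        T = 600
        base = ar1(T, 0.4, rng)
        a = make_signal(base, 0)
        b = make_signal(np.roll(base, 3) + 0.5 * rng.standard_normal(T), 1)
        net_ab = infer_network_from_signals([a, b], tau_max=8, q=0.1)
        net_ba = infer_network_from_signals(
            [make_signal(b.series, 0), make_signal(a.series, 1)], tau_max=8, q=0.1)
        e1, e2 = net_ab.edges[0], net_ba.edges[0]
        assert abs(e1.r_star) == pytest.approx(abs(e2.r_star), abs=1e-12)
        assert e1.tau_star == -e2.tau_star
        assert (e1.lag_min, e1.lag_max) == (-e2.lag_max, -e2.lag_min)
        assert abs(e1.weight) == pytest.approx(abs(e2.weight))
        m = e2.mirrored()
        assert (m.lag_min, m.lag_max) == (e1.lag_min, e1.lag_max)
        assert m.direction == e1.direction

    def test_strength_conservation(self, rng):
        T = 500
        base = rng.standard_normal(T)
        sigs = [make_signal(base + 0.8 * rng.standard_normal(T), i) for i in range(4)]
        net = infer_network_from_signals(sigs, tau_max=5, q=0.1)
        assert net.edges
        assert sum(net.strength.values()) == pytest.approx(
            2 * sum(abs(e.weight) for e in net.edges))

    def test_null_fields_respect_the_fdr_guarantee(self):
        """Independent signals: the chance of any false edge stays near q."""
        rng = np.random.default_rng(17)
        q, n_draws, hits = 0.10, 150, 0
        for _ in range(n_draws):
            sigs = [make_signal(rng.standard_normal(300), i) for i in range(5)]
            net = infer_network_from_signals(sigs, tau_max=4, q=q)
            hits += bool(net.edges)
        se = np.sqrt(q * (1 - q) / n_draws)
        assert hits / n_draws <= q + 3 * se


def make_edge(a, b, weight, lag_set=(0,)):
    lag_set = tuple(sorted(lag_set))
    lo, hi = lag_set[0], lag_set[-1]
    direction = "undirected" if lo <= 0 <= hi else ("a->b" if lo > 0 else "b->a")
    return Edge(a=a, b=b, r_star=np.sign(weight) * 0.5, tau_star=lag_set[0],
                lag_min=lo, lag_max=hi, lag_set=lag_set,
                significant_lags=lag_set, direction=direction, weight=weight)


def make_network(edges, n_nodes):
    strength = {i: 0.0 for i in range(n_nodes)}
    for e in edges:
        strength[e.a] += abs(e.weight)
        strength[e.b] += abs(e.weight)
    return FunctionalNetwork(n_domains=n_nodes, edges=edges, strength=strength,
                             q=0.1, tau_max=5, n_tests=0,
                             domain_ids=list(range(n_nodes)))


def balance_oracle(gr):
    """Exhaustive oracle: a sign assignment s with s_i s_j = sign(ij) exists?"""
    nodes = sorted(gr.nodes)
    for signs in itertools.product([1, -1], repeat=len(nodes)):
        s = dict(zip(nodes, signs))
        if all(s[u] * s[v] == gr[u][v]["sign"] for u, v in gr.edges):
            return True
    return False


class TestStructuralBalance:
    def test_all_positive_triangle_is_balanced(self):
        net = make_network([make_edge(0, 1, 1.0), make_edge(1, 2, 1.0),
                            make_edge(0, 2, 1.0)], 3)
        res = structural_balance(net)
        assert res.balanced
        assert res.poles[0] == {0, 1, 2} or res.poles[1] == {0, 1, 2}

    def test_single_negative_edge_in_triangle_is_unbalanced(self):
        net = make_network([make_edge(0, 1, 1.0), make_edge(1, 2, 1.0),
                            make_edge(0, 2, -1.0)], 3)
        res = structural_balance(net)
        assert not res.balanced
        assert res.violating_cycle is not None
        # the reported cycle really has an odd number of negative edges
        gr = net.to_graph()
        cyc = res.violating_cycle
        negs = sum(gr[cyc[k]][cyc[(k + 1) % len(cyc)]]["sign"] < 0
                   for k in range(len(cyc)))
        assert negs % 2 == 1

    def test_two_pole_partition_separates_signs(self):
        net = make_network([make_edge(0, 1, 1.0), make_edge(2, 3, 1.0),
                            make_edge(1, 2, -1.0), make_edge(0, 3, -1.0)], 4)
        res = structural_balance(net)
        assert res.balanced
        assert {frozenset(p) for p in res.poles} == {frozenset({0, 1}), frozenset({2, 3})}

    @settings(derandomize=True, max_examples=150)
    @given(n=st.integers(2, 6), seed=st.integers(0, 10_000))
    def test_matches_exhaustive_oracle_on_small_signed_graphs(self, n, seed):
        rng = np.random.default_rng(seed)
        gr = nx.Graph()
        gr.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    gr.add_edge(i, j, sign=1 if rng.random() < 0.5 else -1)
        assert structural_balance(gr).balanced == balance_oracle(gr)


class TestLagConsistentTriangles:
    def test_all_zero_lags_are_consistent(self):
        net = make_network([make_edge(0, 1, 1.0, (0,)), make_edge(1, 2, 1.0, (0,)),
                            make_edge(0, 2, 1.0, (0,))], 3)
        (rep,) = lag_consistent_triangles(net)
        assert rep.consistent and rep.witness == (0, 0, 0)

    def test_offsets_summing_to_zero_around_the_cycle(self):
        # 0->1 at lag 8, 1->2 at lag -2, 0->2 at lag 6: 8 + (-2) - 6 = 0
        net = make_network([make_edge(0, 1, 1.0, (8,)), make_edge(1, 2, 1.0, (-2,)),
                            make_edge(0, 2, 1.0, (6,))], 3)
        (rep,) = lag_consistent_triangles(net)
        assert rep.consistent

    def test_head_to_tail_unit_lags_are_inconsistent(self):
        # 0->1, 1->2 and 2->0 all at lag 1: the offsets sum to 3
        net = make_network([make_edge(0, 1, 1.0, (1,)), make_edge(1, 2, 1.0, (1,)),
                            make_edge(2, 0, 1.0, (1,))], 3)
        (rep,) = lag_consistent_triangles(net)
        assert not rep.consistent and rep.witness is None

    def test_range_search_finds_a_witness(self):
        net = make_network([make_edge(0, 1, 1.0, (4, 5, 6)),
                            make_edge(1, 2, 1.0, (-3, -2)),
                            make_edge(0, 2, 1.0, (2, 3))], 3)
        (rep,) = lag_consistent_triangles(net)
        assert rep.consistent
        a, b, c = rep.witness
        assert a + b + c == 0
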