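"""Monte Carlo engine against exact enumeration and closed forms."""

import math

import networkx as nx
import numpy as np
import pytest

from capsidperc import (
    RemovalSpec,
    enumerate_pcon_exact,
    estimate_pcon,
    is_fully_connected,
    pcon_curve,
    sample_removal,
)
from capsidperc.percolation import (
    EnumerationCapExceeded,
    graph_arrays,
    mean_edge_fraction_mc,
)
from capsidperc.thresholds import expected_edge_fraction


class TestSampleRemoval:
    def test_zero_removal_is_identity(self, t3_networks):
        g = t3_networks["rhombic"]
        state = sample_removal(g, RemovalSpec("vertex", 0), np.random.default_rng(0))
        assert len(state.surviving_vertices) == 90
        assert len(state.surviving_edges) == 180

    def test_full_removal_empties_graph(self, small_graphs):
        state = sample_removal(
            small_graphs["c6"], RemovalSpec("vertex", 6), np.random.default_rng(0)
        )
        assert not state.surviving_vertices and not state.surviving_edges

    def test_exact_count_and_fraction(self, t3_networks):
        g = t3_networks["triangular"]
        spec = RemovalSpec("vertex", 6)
        assert spec.fraction_removed(g) == pytest.approx(0.10)
        state = sample_removal(g, spec, np.random.default_rng(1))
        assert len(state.removed) == 6
        assert len(state.surviving_vertices) == 54

    def test_bond_mode_keeps_vertices(self, small_graphs):
        state = sample_removal(
            small_graphs["c6"], RemovalSpec("bond", 3), np.random.default_rng(2)
        )
        assert len(state.surviving_vertices) == 6
        assert len(state.surviving_edges) == 3

    def test_out_of_range_rejected(self, small_graphs):
        with pytest.raises(ValueError, match="cannot remove 7"):
            sample_removal(
                small_graphs["c6"], RemovalSpec("vertex", 7),
                np.random.default_rng(0),
            )


class TestConnectivity:
    def test_intact_capsid_connected(self, t3_networks):
        state = sample_removal(
            t3_networks["rhombic"], RemovalSpec("vertex", 0),
            np.random.default_rng(0),
        )
        assert is_fully_connected(state)

    def test_cycle_with_opposite_vertices_removed_fragments(self):
        g = nx.cycle_graph(6)
        state = sample_removal(g, RemovalSpec("vertex", 0), np.random.default_rng(0))
        # construct the specific state: remove vertices 0 and 3
        from capsidperc.percolation import PerforatedState

        removed = frozenset({0, 3})
        surv_v = frozenset(set(g) - removed)
        surv_e = frozenset(
            (a, b) for a, b in g.edges() if a not in removed and b not in removed
        )
        state = PerforatedState("vertex", removed, surv_v, surv_e)
        assert not is_fully_connected(state)

    def test_complete_graph_always_connected(self):
        g = nx.complete_graph(5)
        for seed in range(5):
            state = sample_removal(g, RemovalSpec("vertex", 3),
                                   np.random.default_rng(seed))
            assert is_fully_connected(state)

    def test_agrees_with_independent_union_find(self, small_graphs, t3_networks):
        """Traversal-based and union-find connectivity agree on 1,000
        random perforated states."""

        def union_find_connected(state):
            verts = list(state.surviving_vertices)
            if len(verts) <= 1:
                return True
            parent = {v: v for v in verts}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in state.surviving_edges:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
            return len({find(v) for v in verts}) == 1

        rng = np.random.default_rng(12345)
        graphs = [small_graphs["c6"], small_graphs["ico"],
                  t3_networks["triangular"].graph]
        n = 0
        for g in graphs:
            V, E = g.number_of_nodes(), g.number_of_edges()
            for _ in range(167):
                for mode, total in (("vertex", V), ("bond", E)):
                    spec = RemovalSpec(mode, int(rng.integers(0, total + 1)))
                    state = sample_removal(g, spec, rng)
                    assert is_fully_connected(state) == union_find_connected(state)
                    n += 1
        assert n >= 1000


class TestEnumerationOracle:
    def test_cycle_pair_removal(self):
        assert enumerate_pcon_exact(
            nx.cycle_graph(6), RemovalSpec("vertex", 2)
        ) == pytest.approx(0.4)

    def test_tree_single_bond_always_fragments(self):
        tree = nx.random_labeled_tree(9, seed=4)
        assert enumerate_pcon_exact(tree, RemovalSpec("bond", 1)) == 0.0

    def test_icosahedron_regression_values(self):
        """Frozen oracle outputs for the icosahedron skeleton: removing
        up to 4 of its 12 vertices can never disconnect it (vertex
        connectivity 5); at i=5 the only disconnecting sets are the 12
        closed neighbourhoods, giving 1 - 12/C(12,5) = 65/66."""
        ico = nx.icosahedral_graph()
        assert enumerate_pcon_exact(ico, RemovalSpec("vertex", 2)) == 1.0
        assert enumerate_pcon_exact(ico, RemovalSpec("vertex", 5)) == pytest.approx(65 / 66)
        assert enumerate_pcon_exact(ico, RemovalSpec("vertex", 6)) == pytest.approx(29 / 33)

    def test_cap_exceeded(self):
        g = nx.cycle_graph(60)
        with pytest.raises(EnumerationCapExceeded, match="Monte Carlo"):
            enumerate_pcon_exact(g, RemovalSpec("vertex", 30))

    def test_exact_monotone_in_threshold_regime(self, small_graphs):
        """Exact P_con is non-increasing while at least half the vertices
        survive (the regime containing every fragmentation threshold).
        Beyond it the probability can rebound: very small survivor sets
        are connected whenever they happen to be contiguous, e.g. on the
        path P5 the exact values at i = 1, 2, 3 are 0.4, 0.3, 0.4."""
        for g in (small_graphs["c6"], small_graphs["p5"], small_graphs["s5"],
                  small_graphs["ico"]):
            V = g.number_of_nodes()
            vals = [enumerate_pcon_exact(g, RemovalSpec("vertex", i))
                    for i in range(V // 2 + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        p5 = [enumerate_pcon_exact(small_graphs["p5"], RemovalSpec("vertex", i))
              for i in (1, 2, 3)]
        assert p5 == [pytest.approx(0.4), pytest.approx(0.3), pytest.approx(0.4)]


class TestMonteCarlo:
    def test_zero_count_certain(self, small_graphs):
        p, se = estimate_pcon(small_graphs["c6"], RemovalSpec("vertex", 0), 100, 0)
        assert (p, se) == (1.0, 0.0)

    def test_seed_determinism(self, t3_networks):
        g = t3_networks["kite"]
        a = estimate_pcon(g, RemovalSpec("vertex", 20), 5000, 7)
        b = estimate_pcon(g, RemovalSpec("vertex", 20), 5000, 7)
        assert a == b

    def test_complete_graph_never_fragments(self):
        g = nx.complete_graph(6)
        for count in (1, 3, 5):
            p, _ = estimate_pcon(g, RemovalSpec("vertex", count), 2000, 1)
            assert p == 1.0

    @pytest.mark.parametrize("mode", ["vertex", "bond"])
    def test_mc_matches_enumeration_within_3se(self, small_graphs, mode):
        reps = 10_000
        for name, g in small_graphs.items():
            total = (g.number_of_nodes() if mode == "vertex"
                     else g.number_of_edges())
            for count in range(1, total + 1):
                if math.comb(total, count) > 50_000:
                    continue
                exact = enumerate_pcon_exact(g, RemovalSpec(mode, count))
                p, se = estimate_pcon(g, RemovalSpec(mode, count), reps, 11)
                tol = 3 * max(se, math.sqrt(exact * (1 - exact) / reps), 1e-9)
                assert abs(p - exact) <= max(tol, 3 / reps), (
                    f"{name} {mode} count={count}: MC {p} vs exact {exact}"
                )

    def test_cycle_curve_matches_closed_form(self):
        g = nx.cycle_graph(12)
        curve = pcon_curve(g, "vertex", [1, 2, 3], 20_000, 3)
        for count, p, se in zip(curve.counts, curve.pcon, curve.se):
            exact = 12 / math.comb(12, int(count)) if count >= 2 else 1.0
            assert abs(p - exact) <= 3 * max(se, 1e-3)

    def test_curve_grid_validation(self, small_graphs):
        g = small_graphs["c6"]
        with pytest.raises(ValueError, match="strictly increasing"):
            pcon_curve(g, "vertex", [3, 2], 100, 0)
        single = pcon_curve(g, "vertex", [0], 100, 0)
        assert single.pcon[0] == 1.0 and single.se[0] == 0.0

    def test_graph_arrays_canonical(self, t3_networks):
        eu, ev, n = graph_arrays(t3_networks["rhombic"])
        assert n == 90 and len(eu) == 180
        assert np.all(eu < ev)


class TestEdgeFractionMC:
    def test_matches_hypergeometric_expectation(self, t3_networks, small_graphs):
        for g, V in ((t3_networks["kite"], 60), (small_graphs["ico"], 12)):
            for remove in (V // 4, V // 2):
                mean, se = mean_edge_fraction_mc(g, remove, 20_000, 5)
                expect = expected_edge_fraction((V - remove) / V, V)
                assert abs(mean - expect) <= 3 * max(se, 1e-6)
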