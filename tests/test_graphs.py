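"""Signed digraph moves, randomization invariants, obstacles, state space."""

import random

import pytest

from causalsig.fixtures import GraphGenSpec, gen_connected_signed_graph
from causalsig.graphs import (
    Move,
    MoveRejected,
    RandomizationConfig,
    Restart,
    SignedDigraph,
    detect_obstacles,
    edge_switch,
    enumerate_state_space,
    flip_strong_triangle_aux,
    is_weakly_connected,
    propose_move,
    randomize,
    read_graph_tsv,
    read_sif,
    triangle_flip,
    write_graph_tsv,
)


@pytest.fixture
def path_graph():
    return SignedDigraph(edges=[("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])


@pytest.fixture
def strong_triangle_graph():
    return SignedDigraph(
        edges=[
            ("a", "b", 1), ("b", "c", 1), ("c", "a", 1),
            ("a", "c", -1), ("c", "b", -1), ("b", "a", -1),
        ]
    )


class TestEdgeSwitch:
    def test_basic_switch(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("c", "d", 1)])
        out = edge_switch(g, ("a", "b", 1), ("c", "d", 1))
        assert out.canonical_key() == frozenset({("a", "d", 1), ("c", "b", 1)})
        assert out.degree_signature() == g.degree_signature()

    def test_sign_mismatch_rejected(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("c", "d", -1)])
        with pytest.raises(MoveRejected, match="sign"):
            edge_switch(g, ("a", "b", 1), ("c", "d", -1))

    def test_strong_quadrilateral_blocks_switch(self):
        g = SignedDigraph(
            edges=[("a", "b", 1), ("c", "d", 1), ("a", "d", -1), ("c", "b", -1)]
        )
        with pytest.raises(MoveRejected, match="parallel"):
            edge_switch(g, ("a", "b", 1), ("c", "d", 1))

    def test_missing_edge_is_input_error(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("c", "d", 1)])
        with pytest.raises(ValueError):
            edge_switch(g, ("a", "x", 1), ("c", "d", 1))


class TestTriangleFlip:
    def test_pure_cycle_reverses(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        out = triangle_flip(g, "a", "b", "c", 1)
        assert out.canonical_key() == frozenset(
            {("a", "c", 1), ("c", "b", 1), ("b", "a", 1)}
        )

    def test_strong_triangle_blocks_flip(self, strong_triangle_graph):
        with pytest.raises(MoveRejected):
            triangle_flip(strong_triangle_graph, "a", "b", "c", 1)

    def test_mixed_sign_cycle_rejected(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", -1), ("c", "a", 1)])
        with pytest.raises(MoveRejected):
            triangle_flip(g, "a", "b", "c", 1)

    def test_missing_cycle_edge_is_input_error(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", 1)])
        with pytest.raises(ValueError):
            triangle_flip(g, "a", "b", "c", 1)


class TestProposeMove:
    def test_two_disjoint_edges_always_switch(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("c", "d", 1)])
        rng = random.Random(0)
        for _ in range(20):
            out = propose_move(g, rng)
            assert isinstance(out, Move) and out.kind == "switch"

    def test_path_pairs(self, path_graph):
        """Adjacent pairs have no completing triangle edge; only the end pair
        switches."""
        rng = random.Random(0)
        kinds = set()
        for _ in range(200):
            out = propose_move(path_graph, rng)
            if isinstance(out, Move):
                kinds.add(out.kind)
                assert {e[:2] for e in out.payload} == {("a", "b"), ("c", "d")}
            else:
                assert isinstance(out, Restart)
        assert kinds == {"switch"}

    def test_triangle_yields_flip(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        rng = random.Random(0)
        kinds = {type(propose_move(g, rng)).__name__ for _ in range(50)}
        out = next(
            o for o in (propose_move(g, rng) for _ in range(50)) if isinstance(o, Move)
        )
        assert out.kind == "flip"

    def test_strong_quadrilateral_classified(self):
        g = SignedDigraph(
            edges=[("a", "b", 1), ("c", "d", 1), ("a", "d", -1), ("c", "b", -1)]
        )
        rng = random.Random(0)
        obstacles = set()
        for _ in range(300):
            out = propose_move(g, rng)
            assert isinstance(out, Restart)
            if out.obstacle:
                obstacles.add(out.obstacle)
        assert obstacles == {"strong_quadrilateral"}


class TestConnectivity:
    def test_cycle_connected(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        assert is_weakly_connected(g)

    def test_disjoint_edges_disconnected(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("c", "d", 1)])
        assert not is_weakly_connected(g)

    def test_switched_path_disconnects(self, path_graph):
        out = edge_switch(path_graph, ("a", "b", 1), ("c", "d", 1))
        assert not is_weakly_connected(out)


class TestRandomize:
    def test_path_returns_unchanged(self, path_graph):
        out, stats = randomize(path_graph, RandomizationConfig(gamma=30, seed=5))
        assert out == path_graph
        assert stats.connectivity_failures > 0

    def test_determinism(self):
        g = gen_connected_signed_graph(GraphGenSpec(25, 40, 20, seed=3))
        cfg = RandomizationConfig(gamma=5, seed=11)
        out1, _ = randomize(g, cfg)
        out2, _ = randomize(g, cfg)
        assert out1.canonical_key() == out2.canonical_key()

    def test_invariants_on_fixture(self):
        g = gen_connected_signed_graph(GraphGenSpec(40, 130, 70, seed=8))
        out, stats = randomize(g, RandomizationConfig(gamma=5, seed=9))
        assert out.degree_signature() == g.degree_signature()
        assert is_weakly_connected(out)
        assert stats.proposals == 5 * g.n_edges
        assert stats.accepted_switches + stats.accepted_flips <= stats.proposals

    def test_batch_mode_reversion_restores_saved_state(self, path_graph):
        """With the check interval pinned at 1, every disconnecting window is
        caught and reverted, so the path graph always comes back unchanged."""
        cfg = RandomizationConfig(
            gamma=40, k0=1, q_plus_factor=1e-9, seed=2, connectivity="batch"
        )
        out, stats = randomize(path_graph, cfg)
        assert out == path_graph
        assert stats.connectivity_failures > 0

    def test_batch_mode_k_dynamics(self):
        """The check interval grows on passing checks and shrinks on failed
        ones."""
        g = gen_connected_signed_graph(GraphGenSpec(30, 80, 40, seed=6))
        cfg = RandomizationConfig(gamma=10, k0=10, seed=4, connectivity="batch")
        out, stats = randomize(g, cfg)
        assert out.degree_signature() == g.degree_signature()
        assert is_weakly_connected(out)
        ks = stats.k_trace
        assert len(ks) > 2
        grew = [ks[i + 1] > ks[i] for i in range(len(ks) - 1)]
        assert any(grew)
        if stats.connectivity_failures:
            assert any(not x for x in grew)

    def test_disconnected_input_rejected(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("c", "d", 1)])
        with pytest.raises(ValueError):
            randomize(g, RandomizationConfig(gamma=2, seed=0))


class TestObstacles:
    def test_quadrilateral_counted_once(self):
        g = SignedDigraph(
            edges=[("a", "b", 1), ("c", "d", 1), ("a", "d", -1), ("c", "b", -1)]
        )
        assert detect_obstacles(g) == {
            "strong_quadrilaterals": 1,
            "strong_triangles": 0,
            "flippable_triangles": 0,
        }

    def test_strong_triangle_counted_once(self, strong_triangle_graph):
        assert detect_obstacles(strong_triangle_graph) == {
            "strong_quadrilaterals": 0,
            "strong_triangles": 1,
            "flippable_triangles": 0,
        }

    def test_pure_cycle_is_flippable(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        counts = detect_obstacles(g)
        assert counts["flippable_triangles"] == 1
        assert counts["strong_triangles"] == counts["strong_quadrilaterals"] == 0


class TestAuxFlip:
    @pytest.fixture
    def fixture_graph(self, strong_triangle_graph):
        g = strong_triangle_graph.copy()
        for u, v in (("a1", "a2"), ("b1", "b2"), ("c1", "c2")):
            g.add_edge(u, v, 1)
        return g

    def test_net_effect_swaps_triangle_signs(self, fixture_graph):
        out = flip_strong_triangle_aux(
            fixture_graph, ("a", "b", "c"), (("a1", "a2"), ("b1", "b2"), ("c1", "c2"))
        )
        expected = fixture_graph.copy()
        for u, v in (("a", "b"), ("b", "c"), ("c", "a")):
            expected.remove_edge(u, v)
            expected.remove_edge(v, u)
        for u, v in (("a", "b"), ("b", "c"), ("c", "a")):
            expected.add_edge(u, v, -1)
            expected.add_edge(v, u, 1)
        assert out.canonical_key() == expected.canonical_key()

    def test_applying_twice_restores_original(self, fixture_graph):
        once = flip_strong_triangle_aux(
            fixture_graph, ("a", "b", "c"), (("a1", "a2"), ("b1", "b2"), ("c1", "c2"))
        )
        # after the flip the positive cycle runs the other way round
        twice = flip_strong_triangle_aux(
            once, ("a", "c", "b"), (("a1", "a2"), ("b1", "b2"), ("c1", "c2"))
        )
        assert twice.canonical_key() == fixture_graph.canonical_key()

    def test_aux_sharing_triangle_vertex_rejected(self, fixture_graph):
        with pytest.raises(ValueError):
            flip_strong_triangle_aux(
                fixture_graph, ("a", "b", "c"), (("a", "a2"), ("b1", "b2"), ("c1", "c2"))
            )


class TestStateSpace:
    def test_path_has_two_members(self, path_graph):
        states = enumerate_state_space(path_graph)
        other = frozenset({("a", "c", 1), ("c", "b", 1), ("b", "d", 1)})
        assert states == {path_graph.canonical_key(), other}

    def test_single_edge(self):
        g = SignedDigraph(edges=[("a", "b", 1)])
        assert enumerate_state_space(g) == {g.canonical_key()}

    def test_cap_refusal(self):
        g = gen_connected_signed_graph(GraphGenSpec(10, 15, 5, seed=0))
        with pytest.raises(ValueError):
            enumerate_state_space(g, cap=12)


class TestGraphIO:
    def test_tsv_roundtrip(self, tmp_path, strong_triangle_graph):
        path = tmp_path / "g.tsv"
        write_graph_tsv(strong_triangle_graph, path)
        assert read_graph_tsv(path) == strong_triangle_graph

    def test_sif_dialect(self, tmp_path):
        path = tmp_path / "g.sif"
        path.write_text("TP53 activates MDM2\nMDM2 inhibits TP53\n")
        g = read_sif(path)
        assert g.sign("TP53", "MDM2") == 1
        assert g.sign("MDM2", "TP53") == -1
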