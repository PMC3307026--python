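"""Signed directed graphs and degree-preserving randomization.

A causal graph is a simple signed digraph: no self-edges, at most one edge
per ordered vertex pair (anti-parallel pairs are allowed), each edge carrying
a sign for positive or negative regulation.  The null model for empirical
p-values fixes, for every vertex, its positive and negative in- and
out-degrees, forbids self/parallel edges, and requires weak connectedness;
sampling is by a Markov chain of same-sign *edge switches*
((a,b),(c,d) -> (a,d),(c,b)) and *triangle flips* (reversal of a same-sign
directed 3-cycle), with symmetric proposals and rejection, so the stationary
distribution is uniform over the reachable state space.

Connectedness is part of move legality.  By default it is verified after
every accepted move (the move is undone if it disconnects the graph); for
large graphs a batched mode checks only every K proposals, with K adapting
multiplicatively (Viger-Latapy heuristic): grow K after a passing check,
shrink it and revert to the last saved state after a failing one.

The module also provides diagnostics for the local sign patterns that block
individual moves (strong quadrilaterals and strong triangles), a
demonstration of how auxiliary edges bypass a strong triangle, and a
brute-force enumerator of the full state space for small graphs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SignedDigraph",
    "Edge",
    "MoveRejected",
    "RandomizationConfig",
    "RunStats",
    "edge_switch",
    "triangle_flip",
    "propose_move",
    "is_weakly_connected",
    "randomize",
    "detect_obstacles",
    "flip_strong_triangle_aux",
    "enumerate_state_space",
    "read_graph_tsv",
    "read_sif",
    "write_graph_tsv",
]

Edge = tuple[str, str, int]  # (source, target, sign in {+1, -1})

_SIGN_TOKENS = {"+": 1, "1": 1, "+1": 1, "-": -1, "-1": -1}

DEFAULT_SIF_RELATIONS = {
    "activates": 1,
    "increases": 1,
    "inhibits": -1,
    "decreases": -1,
}


class MoveRejected(Exception):
    """A chain move is illegal in the current graph; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class SignedDigraph:
    """Simple signed directed graph with O(1) uniform edge sampling.

    Simplicity: no self-edges; at most one edge per ordered (source, target)
    pair regardless of sign.  Anti-parallel pairs (a->b and b->a) are allowed.
    """

    def __init__(self, vertices: Iterable[str] = (), edges: Iterable[Edge] = ()):
        self._vertices: set[str] = set(vertices)
        self._sign: dict[tuple[str, str], int] = {}
        self._list: list[tuple[str, str]] = []
        self._pos: dict[tuple[str, str], int] = {}
        for u, v, s in edges:
            self.add_edge(u, v, s)

    # -- basic container ----------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._vertices)

    @property
    def n_edges(self) -> int:
        return len(self._list)

    def edges(self) -> list[Edge]:
        return [(u, v, self._sign[(u, v)]) for u, v in self._list]

    def has_pair(self, u: str, v: str) -> bool:
        """True if an edge u->v exists in either sign."""
        return (u, v) in self._sign

    def sign(self, u: str, v: str) -> int:
        return self._sign[(u, v)]

    def add_vertex(self, v: str) -> None:
        self._vertices.add(v)

    def add_edge(self, u: str, v: str, s: int) -> None:
        if u == v:
            raise ValueError(f"self-edge {u}->{v} not allowed")
        if s not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {s!r}")
        if (u, v) in self._sign:
            raise ValueError(f"parallel edge {u}->{v} not allowed")
        self._vertices.add(u)
        self._vertices.add(v)
        self._sign[(u, v)] = s
        self._pos[(u, v)] = len(self._list)
        self._list.append((u, v))

    def remove_edge(self, u: str, v: str) -> None:
        key = (u, v)
        if key not in self._sign:
            raise ValueError(f"edge {u}->{v} not in graph")
        i = self._pos.pop(key)
        last = self._list[-1]
        self._list[i] = last
        self._list.pop()
        if last != key:
            self._pos[last] = i
        del self._sign[key]

    def edge_at(self, i: int) -> Edge:
        u, v = self._list[i]
        return (u, v, self._sign[(u, v)])

    def copy(self) -> "SignedDigraph":
        g = SignedDigraph.__new__(SignedDigraph)
        g._vertices = set(self._vertices)
        g._sign = dict(self._sign)
        g._list = list(self._list)
        g._pos = dict(self._pos)
        return g

    def canonical_key(self) -> frozenset[Edge]:
        return frozenset(self.edges())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignedDigraph)
            and self._vertices == other._vertices
            and self._sign == other._sign
        )

    def __repr__(self) -> str:
        return f"SignedDigraph(|V|={len(self._vertices)}, |E|={self.n_edges})"

    def out_edges(self, u: str) -> list[Edge]:
        return [(a, b, s) for a, b, s in self.edges() if a == u]

    def degree_signature(self) -> dict[str, tuple[int, int, int, int]]:
        """Per vertex: (in+, in-, out+, out-)."""
        sig = {v: [0, 0, 0, 0] for v in self._vertices}
        for (u, v), s in self._sign.items():
            sig[v][0 if s > 0 else 1] += 1
            sig[u][2 if s > 0 else 3] += 1
        return {v: tuple(c) for v, c in sig.items()}


# ---------------------------------------------------------------------------
# Connectivity


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.n_components = len(self.parent)

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
            self.n_components -= 1


def is_weakly_connected(g: SignedDigraph) -> bool:
    """True iff the unsigned, undirected shadow graph has one component."""
    if not g.vertices:
        raise ValueError("empty vertex set")
    uf = _UnionFind(g.vertices)
    for u, v, _ in g.edges():
        uf.union(u, v)
    return uf.n_components == 1


# ---------------------------------------------------------------------------
# Elementary moves


def _check_switch(g: SignedDigraph, e1: Edge, e2: Edge) -> None:
    """Raise MoveRejected unless switching e1, e2 is legal (ignoring
    connectivity, which is checked in batches)."""
    a, b, s1 = e1
    c, d, s2 = e2
    if s1 != s2:
        raise MoveRejected("sign mismatch")
    if len({a, b, c, d}) != 4:
        raise MoveRejected("edges share an endpoint")
    if g.has_pair(a, d) or g.has_pair(c, b):
        raise MoveRejected("switch would create a parallel edge")


def edge_switch(g: SignedDigraph, e1: Edge, e2: Edge) -> SignedDigraph:
    """Replace (a,b), (c,d) by (a,d), (c,b); same-sign edges only.

    Preserves every vertex's signed in/out-degrees and simplicity.  Raises
    :class:`MoveRejected` if the move is illegal, ValueError if either edge
    is absent.
    """
    for u, v, s in (e1, e2):
        if not g.has_pair(u, v) or g.sign(u, v) != s:
            raise ValueError(f"edge {u}->{v} ({s:+d}) not in graph")
    _check_switch(g, e1, e2)
    a, b, s = e1
    c, d, _ = e2
    out = g.copy()
    out.remove_edge(a, b)
    out.remove_edge(c, d)
    out.add_edge(a, d, s)
    out.add_edge(c, b, s)
    return out


def _check_flip(g: SignedDigraph, a: str, b: str, c: str) -> None:
    if g.has_pair(a, c) or g.has_pair(c, b) or g.has_pair(b, a):
        raise MoveRejected("flip would create a parallel edge")


def triangle_flip(g: SignedDigraph, a: str, b: str, c: str, sign: int) -> SignedDigraph:
    """Reverse the same-sign directed 3-cycle (a,b), (b,c), (c,a).

    The reversed edges (a,c), (c,b), (b,a) must not exist in either sign.
    """
    for u, v in ((a, b), (b, c), (c, a)):
        if not g.has_pair(u, v):
            raise ValueError(f"cycle edge {u}->{v} not in graph")
        if g.sign(u, v) != sign:
            raise MoveRejected("cycle is not uniformly of the given sign")
    _check_flip(g, a, b, c)
    out = g.copy()
    for u, v in ((a, b), (b, c), (c, a)):
        out.remove_edge(u, v)
    for u, v in ((a, c), (c, b), (b, a)):
        out.add_edge(u, v, sign)
    return out


# ---------------------------------------------------------------------------
# Chain proposals


@dataclass(frozen=True)
class Move:
    """A legal proposal: an edge switch or a triangle flip."""

    kind: str  # "switch" | "flip"
    payload: tuple


@dataclass(frozen=True)
class Restart:
    """A proposal that failed a legality check; the chain stays put."""

    reason: str
    obstacle: str | None = None  # "strong_quadrilateral" | "strong_triangle"


def propose_move(g: SignedDigraph, rng: random.Random) -> Move | Restart:
    """Draw two distinct edges uniformly and classify the resulting proposal.

    Returns a legal switch, a legal flip, or a Restart token (with the
    blocking obstacle identified when the pattern is a strong quadrilateral
    or strong triangle).
    """
    m = g.n_edges
    if m < 2:
        raise ValueError("need at least two edges to propose a move")
    i = rng.randrange(m)
    j = rng.randrange(m - 1)
    if j >= i:
        j += 1
    e1, e2 = g.edge_at(i), g.edge_at(j)
    a, b, s1 = e1
    c, d, s2 = e2
    if s1 != s2:
        return Restart("sign mismatch")
    shared = len({a, b} & {c, d})
    if shared == 0:
        if g.has_pair(a, d) or g.has_pair(c, b):
            obstacle = None
            if (
                g.has_pair(a, d)
                and g.has_pair(c, b)
                and g.sign(a, d) == -s1
                and g.sign(c, b) == -s1
            ):
                obstacle = "strong_quadrilateral"
            return Restart("switch would create a parallel edge", obstacle)
        return Move("switch", (e1, e2))
    if shared == 1:
        # the pair must form a directed 2-path to belong to a 3-cycle
        if b == c:
            x, y, z = a, b, d
        elif d == a:
            x, y, z = c, d, b
        else:
            return Restart("edges share an endpoint but form no directed path")
        # cycle x -> y -> z -> x requires the closing edge (z, x)
        if not g.has_pair(z, x):
            return Restart("no closing triangle edge")
        if g.sign(z, x) != s1:
            return Restart("closing triangle edge has the wrong sign")
        try:
            _check_flip(g, x, y, z)
        except MoveRejected:
            if (
                g.has_pair(x, z)
                and g.has_pair(z, y)
                and g.has_pair(y, x)
                and g.sign(x, z) == -s1
                and g.sign(z, y) == -s1
                and g.sign(y, x) == -s1
            ):
                return Restart("flip blocked", "strong_triangle")
            return Restart("flip would create a parallel edge")
        return Move("flip", (x, y, z, s1))
    return Restart("edges share two endpoints")


def _apply_inplace(g: SignedDigraph, move: Move) -> None:
    if move.kind == "switch":
        (a, b, s), (c, d, _) = move.payload
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, s)
        g.add_edge(c, b, s)
    else:
        x, y, z, s = move.payload
        for u, v in ((x, y), (y, z), (z, x)):
            g.remove_edge(u, v)
        for u, v in ((x, z), (z, y), (y, x)):
            g.add_edge(u, v, s)


# ---------------------------------------------------------------------------
# Randomization driver


@dataclass(frozen=True)
class RandomizationConfig:
    """Chain configuration.

    Total proposals are ``gamma * |E|`` (restarts count).  ``k0`` is the
    initial interval between connectivity checks; on a passing check the
    interval grows by the factor 1 + ``q_plus_factor``, on a failing check it
    shrinks by 1 - ``q_minus_factor`` and the graph reverts to the state
    saved at the last passing check.
    """

    gamma: int = 100
    k0: int = 50
    q_plus_factor: float = 0.131
    q_minus_factor: float = 0.076
    seed: int = 0
    connectivity: str = "move"  # "move" | "batch"

    def __post_init__(self):
        if self.gamma < 1 or self.k0 < 1:
            raise ValueError("gamma and k0 must be >= 1")
        if not (0 < self.q_minus_factor < 1 and self.q_plus_factor > 0):
            raise ValueError("need 0 < q_minus_factor < 1 and q_plus_factor > 0")
        if self.connectivity not in ("move", "batch"):
            raise ValueError("connectivity must be 'move' or 'batch'")


@dataclass
class RunStats:
    """Statistics of one randomization run."""

    proposals: int = 0
    accepted_switches: int = 0
    accepted_flips: int = 0
    connectivity_failures: int = 0
    strong_quadrilaterals: int = 0
    flippable_triangles: int = 0
    strong_triangles: int = 0
    k_trace: list[float] = field(default_factory=list)


def _undo_inplace(g: SignedDigraph, move: Move) -> None:
    if move.kind == "switch":
        (a, b, s), (c, d, _) = move.payload
        g.remove_edge(a, d)
        g.remove_edge(c, b)
        g.add_edge(a, b, s)
        g.add_edge(c, d, s)
    else:
        x, y, z, s = move.payload
        for u, v in ((x, z), (z, y), (y, x)):
            g.remove_edge(u, v)
        for u, v in ((x, y), (y, z), (z, x)):
            g.add_edge(u, v, s)


def randomize(
    g: SignedDigraph, cfg: RandomizationConfig | None = None
) -> tuple[SignedDigraph, RunStats]:
    """Run the edge-switch/triangle-flip chain for gamma * |E| proposals.

    The input must be simple (guaranteed by construction) and weakly
    connected.  The returned graph has the identical signed degree signature,
    is simple and weakly connected; the run is deterministic given the seed.

    Weak connectedness is part of move legality.  In the default "move" mode
    every accepted move is immediately verified and undone if it disconnects
    the graph, so the chain never leaves the connected state space.  In
    "batch" mode the check runs only every K proposals with the adaptive
    K / revert-to-saved-state heuristic — much cheaper on large graphs, at
    the price that a window may pass through (and in rare cases exploit)
    disconnected intermediate states that a per-move check would reject.
    """
    cfg = cfg or RandomizationConfig()
    if not is_weakly_connected(g):
        raise ValueError("input graph must be weakly connected")
    rng = random.Random(cfg.seed)
    work = g.copy()
    saved = g.copy()
    stats = RunStats()
    k = float(cfg.k0)
    since_check = 0
    total = cfg.gamma * g.n_edges
    per_move = cfg.connectivity == "move"
    for _ in range(total):
        outcome = propose_move(work, rng)
        stats.proposals += 1
        if isinstance(outcome, Move):
            _apply_inplace(work, outcome)
            if per_move and not is_weakly_connected(work):
                _undo_inplace(work, outcome)
                stats.connectivity_failures += 1
            else:
                if outcome.kind == "switch":
                    stats.accepted_switches += 1
                else:
                    stats.accepted_flips += 1
                    stats.flippable_triangles += 1
        elif outcome.obstacle == "strong_quadrilateral":
            stats.strong_quadrilaterals += 1
        elif outcome.obstacle == "strong_triangle":
            stats.strong_triangles += 1
        if per_move:
            continue
        since_check += 1
        if since_check >= round(k):
            if is_weakly_connected(work):
                saved = work.copy()
                k *= 1 + cfg.q_plus_factor
            else:
                stats.connectivity_failures += 1
                work = saved.copy()
                k *= 1 - cfg.q_minus_factor
                k = max(k, 1.0)
            stats.k_trace.append(k)
            since_check = 0
    if not per_move and since_check and not is_weakly_connected(work):
        stats.connectivity_failures += 1
        work = saved.copy()
    return work, stats


# ---------------------------------------------------------------------------
# Obstacle diagnostics


def _iter_triangles(g: SignedDigraph) -> Iterator[tuple[str, str, str, int]]:
    """Same-sign directed 3-cycles, one canonical rotation each."""
    out: dict[str, list[tuple[str, int]]] = {}
    for u, v, s in g.edges():
        out.setdefault(u, []).append((v, s))
    for a, b, s in g.edges():
        for c, s2 in out.get(b, ()):
            if s2 != s or c == a:
                continue
            if g.has_pair(c, a) and g.sign(c, a) == s:
                if a == min(a, b, c):  # canonical rotation: smallest vertex first
                    yield a, b, c, s


def detect_obstacles(g: SignedDigraph) -> dict[str, int]:
    """Exhaustively count strong quadrilaterals, strong triangles, and
    flippable triangles (intended for small graphs)."""
    edges = g.edges()
    # each structure is counted once, via its positive same-sign pair/cycle
    quads = 0
    for idx, (a, b, s1) in enumerate(edges):
        if s1 != 1:
            continue
        for c, d, s2 in edges[idx + 1 :]:
            if s2 != 1 or len({a, b, c, d}) != 4:
                continue
            if (
                g.has_pair(a, d)
                and g.has_pair(c, b)
                and g.sign(a, d) == -1
                and g.sign(c, b) == -1
            ):
                quads += 1
    strong_tri = 0
    flippable = 0
    for a, b, c, s in _iter_triangles(g):
        reversed_present = (
            g.has_pair(a, c)
            and g.has_pair(c, b)
            and g.has_pair(b, a)
            and g.sign(a, c) == -s
            and g.sign(c, b) == -s
            and g.sign(b, a) == -s
        )
        if reversed_present:
            if s == 1:
                strong_tri += 1
        elif not (g.has_pair(a, c) or g.has_pair(c, b) or g.has_pair(b, a)):
            flippable += 1
    return {
        "strong_quadrilaterals": quads,
        "strong_triangles": strong_tri,
        "flippable_triangles": flippable,
    }


def flip_strong_triangle_aux(
    g: SignedDigraph,
    triangle: tuple[str, str, str],
    aux_edges: tuple[tuple[str, str], tuple[str, str], tuple[str, str]],
) -> SignedDigraph:
    """Flip a strong triangle using three disjoint positive auxiliary edges.

    ``triangle`` = (a, b, c) with positive cycle (a,b), (b,c), (c,a) and
    negative reversed cycle; ``aux_edges`` = ((a1,a2), (b1,b2), (c1,c2)),
    positive, pairwise disjoint and disjoint from the triangle.  Executes the
    four phases — Opening (3 switches), Flipping (1 triangle flip), Closing
    (3 switches), Restoring (2 switches) — and returns the graph with the six
    triangle edges' signs exchanged between the two orientations and the
    auxiliary edges restored.  Raises identifying the phase if any
    intermediate move is illegal.
    """
    a, b, c = triangle
    (a1, a2), (b1, b2), (c1, c2) = aux_edges
    aux_vertices = {a1, a2, b1, b2, c1, c2}
    if len(aux_vertices) != 6 or aux_vertices & {a, b, c}:
        raise ValueError("auxiliary edges must be pairwise disjoint and avoid the triangle")
    for u, v in ((a, b), (b, c), (c, a)):
        if not (g.has_pair(u, v) and g.sign(u, v) == 1):
            raise ValueError(f"positive triangle edge {u}->{v} missing")
        if not (g.has_pair(v, u) and g.sign(v, u) == -1):
            raise ValueError(f"negative reversed edge {v}->{u} missing")
    for u, v in aux_edges:
        if not (g.has_pair(u, v) and g.sign(u, v) == 1):
            raise ValueError(f"positive auxiliary edge {u}->{v} missing")

    def switch(graph, u1, v1, u2, v2, phase):
        try:
            return edge_switch(
                graph, (u1, v1, graph.sign(u1, v1)), (u2, v2, graph.sign(u2, v2))
            )
        except (MoveRejected, ValueError, KeyError) as exc:
            raise MoveRejected(f"{phase}: switch ({u1},{v1})x({u2},{v2}) illegal: {exc}")

    # Opening
    out = switch(g, a, b, c1, c2, "opening")
    out = switch(out, b, c, a1, a2, "opening")
    out = switch(out, c, a, b1, b2, "opening")
    # Flipping: the negative cycle (a,c), (c,b), (b,a) is now unobstructed
    try:
        out = triangle_flip(out, a, c, b, -1)
    except (MoveRejected, ValueError) as exc:
        raise MoveRejected(f"flipping: triangle flip illegal: {exc}")
    # Closing
    out = switch(out, a1, c, a, c2, "closing")
    out = switch(out, b1, a, b, a2, "closing")
    out = switch(out, c1, b, c, b2, "closing")
    # Restoring
    out = switch(out, b1, a2, c1, b2, "restoring")
    out = switch(out, c1, a2, a1, c2, "restoring")
    return out


# ---------------------------------------------------------------------------
# State-space enumeration (test oracle)


def _realize_digraphs(
    vertices: list[str],
    out_deg: dict[str, int],
    in_deg: dict[str, int],
    forbidden: frozenset[tuple[str, str]] = frozenset(),
) -> list[frozenset[tuple[str, str]]]:
    """All simple digraph edge sets realizing the degree sequence, avoiding
    forbidden ordered pairs (used to keep sign layers pair-disjoint)."""
    from itertools import combinations

    results: list[frozenset[tuple[str, str]]] = []
    order = [v for v in vertices if out_deg.get(v, 0) > 0]

    def rec(idx: int, remaining_in: dict[str, int], acc: list[tuple[str, str]]):
        if idx == len(order):
            if all(d == 0 for d in remaining_in.values()):
                results.append(frozenset(acc))
            return
        u = order[idx]
        k = out_deg[u]
        candidates = [
            v
            for v in vertices
            if v != u and remaining_in.get(v, 0) > 0 and (u, v) not in forbidden
        ]
        for targets in combinations(candidates, k):
            for v in targets:
                remaining_in[v] -= 1
            rec(idx + 1, remaining_in, acc + [(u, v) for v in targets])
            for v in targets:
                remaining_in[v] += 1

    rec(0, dict(in_deg), [])
    return results


def enumerate_state_space(g: SignedDigraph, cap: int = 12) -> set[frozenset[Edge]]:
    """All simple, weakly connected signed digraphs on V with the same signed
    degree signature as g, by exhaustive search.  Refuses beyond ``cap`` edges.
    """
    if g.n_edges > cap:
        raise ValueError(f"graph has {g.n_edges} edges, enumeration cap is {cap}")
    vertices = sorted(g.vertices)
    sig = g.degree_signature()
    out_pos = {v: sig[v][2] for v in vertices}
    in_pos = {v: sig[v][0] for v in vertices}
    out_neg = {v: sig[v][3] for v in vertices}
    in_neg = {v: sig[v][1] for v in vertices}
    pos_sets = _realize_digraphs(vertices, out_pos, in_pos)
    states: set[frozenset[Edge]] = set()
    for pos in pos_sets:
        for neg in _realize_digraphs(vertices, out_neg, in_neg, forbidden=pos):
            edges = [(u, v, 1) for u, v in pos] + [(u, v, -1) for u, v in neg]
            cand = SignedDigraph(vertices, edges)
            if is_weakly_connected(cand):
                states.add(cand.canonical_key())
    return states


# ---------------------------------------------------------------------------
# I/O


def read_graph_tsv(path: str | Path) -> SignedDigraph:
    """Read ``source<TAB>target<TAB>sign`` with sign in {+, -, 1, -1}."""
    g = SignedDigraph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed graph line: {line!r}")
            u, v, tok = parts
            if tok not in _SIGN_TOKENS:
                raise ValueError(f"unrecognised sign token {tok!r}")
            g.add_edge(u, v, _SIGN_TOKENS[tok])
    return g


def read_sif(
    path: str | Path, relation_signs: dict[str, int] | None = None
) -> SignedDigraph:
    """Read a SIF-like ``source relation target`` file; relations map to signs
    via ``relation_signs`` (defaults: activates/increases -> +,
    inhibits/decreases -> -)."""
    rel = relation_signs or DEFAULT_SIF_RELATIONS
    g = SignedDigraph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            u, relation, v = parts
            key = relation.lower()
            if key not in rel:
                raise ValueError(f"unmapped relation {relation!r}")
            g.add_edge(u, v, rel[key])
    return g


def write_graph_tsv(g: SignedDigraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, s in sorted(g.edges()):
            fh.write(f"{u}\t{v}\t{'+' if s > 0 else '-'}\n")
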