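"""Seeded generators of classifications and connected signed digraphs.

Everything downstream (the distribution algorithms, the randomization chain,
the hypothesis engine) is testable without any external data: classification
fixtures realize a uniform rearrangement of prescribed label counts, and
graph fixtures build a simple, weakly connected signed digraph with exact
sign-stratified edge counts (random spanning tree first — connectivity by
construction — then rejection-sampled extra arcs).  All generation is
deterministic per seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .graphs import SignedDigraph
from .ternary import Margins, TernaryClassification

__all__ = ["GraphGenSpec", "gen_classification", "gen_connected_signed_graph"]


@dataclass(frozen=True)
class GraphGenSpec:
    """Parameters of a random connected signed digraph fixture."""

    n_vertices: int
    n_pos_edges: int
    n_neg_edges: int
    seed: int = 0

    def __post_init__(self):
        n, e = self.n_vertices, self.n_pos_edges + self.n_neg_edges
        if n < 2:
            raise ValueError("need at least two vertices")
        if e < n - 1:
            raise ValueError("too few edges for weak connectivity")
        if e > n * (n - 1):
            raise ValueError("too many edges for a simple digraph")
        if min(self.n_pos_edges, self.n_neg_edges) < 0:
            raise ValueError("edge counts must be nonnegative")


def gen_classification(
    margins: Margins | tuple[int, int, int], seed: int = 0, side: str = "n"
) -> TernaryClassification:
    """Uniformly random arrangement of prescribed label counts.

    ``margins`` may be a Margins object (use its ``side`` — "n" for the
    randomized classification's counts, "q" for the fixed one's) or a bare
    (#+1, #-1, #0) triple.  Elements are ids "e0", "e1", ...
    """
    if isinstance(margins, Margins):
        counts = margins.n if side == "n" else margins.q
    else:
        counts = tuple(margins)
    n_plus, n_minus, n_zero = counts
    values = [1] * n_plus + [-1] * n_minus + [0] * n_zero
    rng = random.Random(seed)
    rng.shuffle(values)
    ids = [f"e{i}" for i in range(len(values))]
    return TernaryClassification(values, ids)


def gen_connected_signed_graph(spec: GraphGenSpec) -> SignedDigraph:
    """Simple, weakly connected signed digraph with exact signed edge counts.

    A random spanning tree over the vertices guarantees weak connectivity;
    tree edges get random orientations and signs drawn from the remaining
    sign budget, then the leftover positive/negative arcs are placed by
    rejection sampling of ordered pairs (no self-loops, no duplicates).
    """
    rng = random.Random(spec.seed)
    vertices = [f"v{i}" for i in range(spec.n_vertices)]
    g = SignedDigraph(vertices)
    pos_left, neg_left = spec.n_pos_edges, spec.n_neg_edges

    def draw_sign() -> int:
        nonlocal pos_left, neg_left
        if rng.random() < pos_left / (pos_left + neg_left):
            pos_left -= 1
            return 1
        neg_left -= 1
        return -1

    # spanning structure: attach each new vertex to a random earlier one
    for i in range(1, spec.n_vertices):
        other = vertices[rng.randrange(i)]
        u, v = (vertices[i], other) if rng.random() < 0.5 else (other, vertices[i])
        g.add_edge(u, v, draw_sign())

    # leftover arcs by rejection sampling
    remaining_signs = [1] * pos_left + [-1] * neg_left
    rng.shuffle(remaining_signs)
    attempts_cap = 1000 * (len(remaining_signs) + 1) * spec.n_vertices
    attempts = 0
    while remaining_signs:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError("rejection sampling stalled; spec too dense")
        u, v = rng.sample(vertices, 2)
        if g.has_pair(u, v):
            continue
        g.add_edge(u, v, remaining_signs.pop())
    return g
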