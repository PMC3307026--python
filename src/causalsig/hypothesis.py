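"""Scoring and ranking of causal hypotheses.

A *hypothesis* is a graph vertex together with a perturbation direction
(upregulation +1 or downregulation -1).  Tracing shortest directed paths
from the vertex predicts up/down classifications of downstream transcript
nodes (the sign of a path is the product of its edge signs); comparing the
predicted with the experimental classification gives correct, incorrect and
ambiguous counts, the score S = correct - incorrect, and two significance
measures:

* the exact ternary dot product p-value (rearrangement null of the
  experimental calls, computed by :mod:`causalsig.tdp`), and
* an empirical p-value over degree-preserving graph randomizations
  (computed from replicates produced by :mod:`causalsig.graphs`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .graphs import SignedDigraph
from .tdp import (
    ThresholdConfig,
    distribution_1a,
    distribution_1b,
    oracle_distribution,
    quartic_distribution,
)
from .ternary import Margins, TernaryClassification, make_contingency, score

__all__ = [
    "Hypothesis",
    "Prediction",
    "HypothesisResult",
    "EmpiricalPValue",
    "predict_classification",
    "score_hypothesis",
    "tdp_pvalue_for_hypothesis",
    "empirical_pvalue",
    "rank_hypotheses",
    "evaluate_hypotheses",
]

_ALGORITHMS = {
    "oracle": lambda m: oracle_distribution(m),
    "quartic": lambda m: quartic_distribution(m),
    "1a": lambda m: distribution_1a(m),
    "1b": lambda m: distribution_1b(m),
}


@dataclass(frozen=True)
class Hypothesis:
    """A perturbed vertex and its direction (+1 up, -1 down)."""

    vertex: str
    direction: int

    def __post_init__(self):
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")

    def __str__(self) -> str:
        return f"{self.vertex}{'+' if self.direction > 0 else '-'}"


@dataclass(frozen=True)
class Prediction:
    """A predicted classification plus the nodes where equally short paths
    disagreed in sign (predicted 0 and flagged)."""

    classification: TernaryClassification
    conflicted: frozenset[str]


@dataclass(frozen=True)
class HypothesisResult:
    hypothesis: Hypothesis
    correct: int
    incorrect: int
    ambiguous: int
    score: int
    tdp_p: float | None = None
    empirical_p: "EmpiricalPValue | None" = None
    rank: int | None = None


class EmpiricalPValue:
    """Empirical p-value from graph randomization replicates.

    ``value`` is (#replicates with score >= observed) / R.  When no replicate
    reaches the observed score the true p-value is only bounded above by 1/R,
    and the display follows the "< 1/R" convention.
    """

    def __init__(self, count: int, n_replicates: int):
        if n_replicates < 1 or not 0 <= count <= n_replicates:
            raise ValueError("invalid replicate counts")
        self.count = count
        self.n_replicates = n_replicates

    @property
    def value(self) -> float:
        return self.count / self.n_replicates

    @property
    def is_upper_bound(self) -> bool:
        return self.count == 0

    def __float__(self) -> float:
        return self.value

    def __str__(self) -> str:
        if self.is_upper_bound:
            return f"< {1 / self.n_replicates:g}"
        return f"{self.value:g}"

    def __repr__(self) -> str:
        return f"EmpiricalPValue({self.count}/{self.n_replicates})"

    def __eq__(self, other) -> bool:
        if isinstance(other, EmpiricalPValue):
            return (self.count, self.n_replicates) == (other.count, other.n_replicates)
        return NotImplemented


def predict_classification(
    g: SignedDigraph,
    h: Hypothesis,
    max_depth: int | float = 1,
    nodes: Sequence[str] | None = None,
) -> Prediction:
    """Predict downstream regulation by shortest directed signed paths.

    Each node within ``max_depth`` steps downstream of the hypothesis vertex
    is predicted direction * (product of edge signs along a shortest path);
    unreachable nodes (and the hypothesis vertex itself) get 0.  Nodes where
    equally short paths disagree in sign get 0 and are flagged as conflicted.
    ``max_depth`` may be ``math.inf`` for unlimited depth.
    """
    if h.vertex not in g.vertices:
        raise ValueError(f"hypothesis vertex {h.vertex!r} not in graph")
    if not (max_depth >= 1):
        raise ValueError("max_depth must be >= 1")
    out_adj: dict[str, list[tuple[str, int]]] = {}
    for u, v, s in g.edges():
        out_adj.setdefault(u, []).append((v, s))
    # BFS layer by layer, carrying the set of achievable shortest-path signs
    signs: dict[str, set[int]] = {h.vertex: {1}}
    frontier = [h.vertex]
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        layer: dict[str, set[int]] = {}
        for u in frontier:
            for v, es in out_adj.get(u, ()):
                if v in signs and v not in layer:
                    continue  # already reached at a strictly shorter distance
                layer.setdefault(v, set()).update(es * ps for ps in signs[u])
        for v, ss in layer.items():
            signs[v] = ss
        frontier = list(layer)
    node_order = list(nodes) if nodes is not None else sorted(g.vertices)
    values = []
    conflicted = set()
    for v in node_order:
        ss = signs.get(v)
        if v == h.vertex or ss is None:
            values.append(0)
        elif len(ss) == 2:
            values.append(0)
            conflicted.add(v)
        else:
            values.append(h.direction * next(iter(ss)))
    return Prediction(
        TernaryClassification(values, node_order), frozenset(conflicted)
    )


def _as_classification(pred) -> TernaryClassification:
    return pred.classification if isinstance(pred, Prediction) else pred


def score_hypothesis(
    predicted: Prediction | TernaryClassification,
    experimental: TernaryClassification,
    hypothesis: Hypothesis | None = None,
) -> HypothesisResult:
    """Count correct/incorrect/ambiguous predictions and form the score.

    Correct: predicted and experimental signs match and are nonzero;
    incorrect: they are nonzero and opposite; everything else is ambiguous.
    The score equals the ternary dot product of the two classifications.
    """
    pred = _as_classification(predicted)
    if pred.ids is not None and experimental.ids is not None:
        pred = pred.reordered(experimental.ids)
    elif len(pred) != len(experimental):
        raise ValueError("classifications are misaligned")
    table = make_contingency(experimental, pred)
    correct = table[1, 1] + table[-1, -1]
    incorrect = table[1, -1] + table[-1, 1]
    s = score(table)
    return HypothesisResult(
        hypothesis=hypothesis,
        correct=correct,
        incorrect=incorrect,
        ambiguous=len(pred) - correct - incorrect,
        score=s,
    )


def tdp_pvalue_for_hypothesis(
    predicted: Prediction | TernaryClassification,
    experimental: TernaryClassification,
    algorithm: str = "1b",
) -> float:
    """Right-tail exact p-value of the observed agreement score.

    Margins: q from the experimental classification (held fixed), n from the
    predicted one (rearranged under the null).
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    pred = _as_classification(predicted)
    if pred.ids is not None and experimental.ids is not None:
        pred = pred.reordered(experimental.ids)
    table = make_contingency(experimental, pred)
    dist = _ALGORITHMS[algorithm](table.margins)
    return dist.right_tail(score(table))


def empirical_pvalue(
    g: SignedDigraph,
    h: Hypothesis,
    experimental: TernaryClassification,
    replicate_graphs: Sequence[SignedDigraph],
    max_depth: int | float = 1,
) -> EmpiricalPValue:
    """Empirical p-value: fraction of randomized graphs scoring at least as
    well as the actual graph (ties count against the hypothesis)."""
    if not replicate_graphs:
        raise ValueError("need at least one replicate graph")
    sig = g.degree_signature()
    observed = score_hypothesis(
        predict_classification(g, h, max_depth, nodes=experimental.ids),
        experimental,
    ).score
    count = 0
    for rep in replicate_graphs:
        if rep.vertices != g.vertices or rep.degree_signature() != sig:
            raise ValueError("replicate does not match the graph's degree signature")
        rep_score = score_hypothesis(
            predict_classification(rep, h, max_depth, nodes=experimental.ids),
            experimental,
        ).score
        if rep_score >= observed:
            count += 1
    return EmpiricalPValue(count, len(replicate_graphs))


def rank_hypotheses(results: Iterable[HypothesisResult]) -> list[HypothesisResult]:
    """Sort by score descending with competition ranking (ties share the rank
    of their first member; the next distinct score resumes at its position)."""
    ordered = sorted(results, key=lambda r: -r.score)
    out = []
    for i, r in enumerate(ordered):
        if i > 0 and r.score == ordered[i - 1].score:
            rank = out[-1].rank
        else:
            rank = i + 1
        out.append(replace(r, rank=rank))
    return out


def evaluate_hypotheses(
    g: SignedDigraph,
    experimental: TernaryClassification,
    hypotheses: Sequence[Hypothesis] | None = None,
    max_depth: int | float = 1,
    algorithm: str = "1b",
    replicate_graphs: Sequence[SignedDigraph] | None = None,
    transcripts: Sequence[str] | None = None,
) -> list[HypothesisResult]:
    """Score, test and rank hypotheses against an experimental classification.

    ``transcripts`` restricts scoring to measurable transcript nodes
    (defaults to the experimental classification's ground set).  When
    ``hypotheses`` is None, every vertex in both directions is evaluated.
    """
    if experimental.ids is None:
        raise ValueError("experimental classification needs node ids")
    nodes = list(transcripts) if transcripts is not None else list(experimental.ids)
    exp = experimental.reordered(nodes) if transcripts is not None else experimental
    if hypotheses is None:
        hypotheses = [
            Hypothesis(v, d) for v in sorted(g.vertices) for d in (1, -1)
        ]
    results = []
    for h in hypotheses:
        pred = predict_classification(g, h, max_depth, nodes=nodes)
        res = score_hypothesis(pred, exp, hypothesis=h)
        tdp_p = tdp_pvalue_for_hypothesis(pred, exp, algorithm)
        emp = (
            empirical_pvalue(g, h, exp, replicate_graphs, max_depth)
            if replicate_graphs
            else None
        )
        results.append(replace(res, tdp_p=tdp_p, empirical_p=emp))
    return rank_hypotheses(results)
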