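"""Core types for the ternary dot product test.

A *ternary classification* assigns each element of a ground set (typically
gene transcripts) a label in {-1, 0, +1}: downregulated, unchanged, or
upregulated.  Comparing a fixed classification ``C`` (the experimental calls)
with a random rearrangement of a second classification ``C'`` (the model
predictions) gives rise to a 3x3 contingency table with fixed row margins
``q_sigma`` (from ``C``) and column margins ``n_tau`` (from ``C'``).  The
number of rearrangements producing a given table is a product of three
multinomial coefficients (the *D-value*); aggregating D-values by the score

    S = n(+,+) + n(-,-) - n(+,-) - n(-,+)

and normalising by the total count ``D_tot`` yields the exact null
distribution of the agreement score — a ternary generalisation of Fisher's
exact test.  This module houses the domain types and the closed-form
combinatorics; the distribution algorithms live in :mod:`causalsig.tdp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TernaryClassification",
    "Margins",
    "ContingencyTable3x3",
    "ScoreDistribution",
    "make_contingency",
    "score",
    "d_value",
    "log_d_value",
    "d_tot",
    "log_d_tot",
    "pvalue_right_tail",
    "read_classification_tsv",
    "write_classification_tsv",
]

_SIGNS = (1, -1, 0)  # canonical (+, -, 0) index order

_VALUE_ALIASES = {
    "1": 1, "+1": 1, "+": 1, "up": 1,
    "-1": -1, "-": -1, "down": -1,
    "0": 0, "none": 0,
}


class TernaryClassification:
    """An ordered assignment of {-1, 0, +1} labels to a ground set.

    Parameters
    ----------
    values
        Sequence of labels, one per element, each in {-1, 0, +1}.
    ids
        Optional parallel sequence of element identifiers.
    """

    __slots__ = ("values", "ids")

    def __init__(self, values: Sequence[int], ids: Sequence[str] | None = None):
        vals = tuple(int(v) for v in values)
        for v in vals:
            if v not in (-1, 0, 1):
                raise ValueError(f"classification value {v!r} not in {{-1, 0, 1}}")
        if ids is not None and len(ids) != len(vals):
            raise ValueError("ids and values must have equal length")
        self.values = vals
        self.ids = tuple(ids) if ids is not None else None

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TernaryClassification)
            and self.values == other.values
            and self.ids == other.ids
        )

    def __repr__(self) -> str:
        return f"TernaryClassification(T={len(self)}, counts={self.counts()})"

    def counts(self) -> tuple[int, int, int]:
        """Return (#+1, #-1, #0)."""
        return (
            self.values.count(1),
            self.values.count(-1),
            self.values.count(0),
        )

    def reordered(self, ids: Sequence[str]) -> "TernaryClassification":
        """Return a copy aligned to the given id order (ids must match as sets)."""
        if self.ids is None:
            raise ValueError("classification has no ids to align on")
        index = {g: v for g, v in zip(self.ids, self.values)}
        if set(ids) != set(index):
            raise ValueError("id sets differ; cannot align classifications")
        return TernaryClassification([index[g] for g in ids], ids)


@dataclass(frozen=True)
class Margins:
    """Fixed margin counts of the two classifications over a common ground set.

    ``q_*`` are the label counts of the fixed classification ``C`` (rows of the
    contingency table); ``n_*`` those of the randomised classification ``C'``
    (columns).  Both triples must sum to the common ground-set size ``T``.
    """

    q_plus: int
    q_minus: int
    q_zero: int
    n_plus: int
    n_minus: int
    n_zero: int

    def __post_init__(self):
        for name in ("q_plus", "q_minus", "q_zero", "n_plus", "n_minus", "n_zero"):
            if getattr(self, name) < 0:
                raise ValueError(f"margin {name} must be nonnegative")
        if self.q_plus + self.q_minus + self.q_zero != self.n_plus + self.n_minus + self.n_zero:
            raise ValueError("q margins and n margins must sum to the same total T")

    @property
    def total(self) -> int:
        return self.q_plus + self.q_minus + self.q_zero

    @property
    def q(self) -> tuple[int, int, int]:
        """(q+, q-, q0)."""
        return (self.q_plus, self.q_minus, self.q_zero)

    @property
    def n(self) -> tuple[int, int, int]:
        """(n+, n-, n0)."""
        return (self.n_plus, self.n_minus, self.n_zero)

    @classmethod
    def from_classifications(
        cls, c: TernaryClassification, c_prime: TernaryClassification
    ) -> "Margins":
        if len(c) != len(c_prime):
            raise ValueError("classifications must have equal length")
        qp, qm, qz = c.counts()
        np_, nm, nz = c_prime.counts()
        return cls(qp, qm, qz, np_, nm, nz)

    def mirrored(self) -> "Margins":
        """Swap the + and - columns (n+ <-> n-); maps score S to -S."""
        return Margins(self.q_plus, self.q_minus, self.q_zero,
                       self.n_minus, self.n_plus, self.n_zero)


@dataclass(frozen=True)
class ContingencyTable3x3:
    """The nine overlap counts n[sigma][tau] of a joint ternary classification.

    Rows are indexed by the fixed classification's label sigma, columns by the
    randomised classification's label tau, in the order (+, -, 0).
    """

    cells: tuple[tuple[int, int, int], ...]  # rows (+,-,0) x cols (+,-,0)
    margins: Margins

    def __post_init__(self):
        if len(self.cells) != 3 or any(len(r) != 3 for r in self.cells):
            raise ValueError("cells must be a 3x3 grid")
        if any(v < 0 for row in self.cells for v in row):
            raise ValueError("contingency cells must be nonnegative")
        for row, q in zip(self.cells, self.margins.q):
            if sum(row) != q:
                raise ValueError(f"row sum {sum(row)} != margin {q}")
        for j, n in enumerate(self.margins.n):
            col = sum(self.cells[i][j] for i in range(3))
            if col != n:
                raise ValueError(f"column sum {col} != margin {n}")

    def __getitem__(self, key: tuple[int, int]) -> int:
        """Cell lookup by signed labels, e.g. table[1, -1] is n(+,-)."""
        sigma, tau = key
        return self.cells[_SIGNS.index(sigma)][_SIGNS.index(tau)]

    @classmethod
    def from_corner(
        cls, margins: Margins, npp: int, npm: int, nmp: int, nmm: int
    ) -> "ContingencyTable3x3":
        """Build the full table from the top-left 2x2 corner; the remaining
        five cells are implied by the margins.  Raises if any implied cell is
        negative."""
        qp, qm, qz = margins.q
        np_, nm, nz = margins.n
        np0 = qp - npp - npm
        nm0 = qm - nmp - nmm
        n0p = np_ - npp - nmp
        n0m = nm - npm - nmm
        n00 = qz - n0p - n0m
        cells = ((npp, npm, np0), (nmp, nmm, nm0), (n0p, n0m, n00))
        if any(v < 0 for row in cells for v in row):
            raise ValueError(
                f"corner ({npp},{npm},{nmp},{nmm}) infeasible for margins {margins}"
            )
        return cls(cells, margins)

    @property
    def corner(self) -> tuple[int, int, int, int]:
        """(n++, n+-, n-+, n--)."""
        return (self.cells[0][0], self.cells[0][1], self.cells[1][0], self.cells[1][1])


def make_contingency(
    c: TernaryClassification, c_prime: TernaryClassification
) -> ContingencyTable3x3:
    """Cross-tabulate two aligned ternary classifications."""
    if len(c) != len(c_prime):
        raise ValueError("classifications must have equal length")
    counts = [[0, 0, 0], [0, 0, 0], [0, 0, 0]]
    for a, b in zip(c.values, c_prime.values):
        counts[_SIGNS.index(a)][_SIGNS.index(b)] += 1
    margins = Margins.from_classifications(c, c_prime)
    return ContingencyTable3x3(tuple(tuple(r) for r in counts), margins)


def score(table: ContingencyTable3x3) -> int:
    """Agreement score S = correct - incorrect = n++ + n-- - n+- - n-+.

    Equals the dot product of the two underlying ternary vectors.
    """
    npp, npm, nmp, nmm = table.corner
    return npp + nmm - npm - nmp


def _multinomial(total: int, parts: Iterable[int]) -> int:
    out = 1
    remaining = total
    for p in parts:
        out *= math.comb(remaining, p)
        remaining -= p
    if remaining != 0:
        raise ValueError("parts do not sum to total")
    return out


def d_value(table: ContingencyTable3x3) -> int:
    """Number of rearrangements of C' producing this table (exact integer).

    D = multinom(q+; n++, n+-, n+0) * multinom(q-; n-+, n--, n-0)
        * multinom(q0; n0+, n0-, n00).
    """
    out = 1
    for row, q in zip(table.cells, table.margins.q):
        out *= _multinomial(q, row)
    return out


def log_d_value(table: ContingencyTable3x3) -> float:
    """Natural log of the D-value, computed with lgamma (<=1e-12 relative)."""
    out = 0.0
    for row, q in zip(table.cells, table.margins.q):
        out += math.lgamma(q + 1)
        for v in row:
            out -= math.lgamma(v + 1)
    return out


def d_tot(margins: Margins) -> int:
    """Total number of rearrangements: multinom(T; n+, n-, n0)."""
    return _multinomial(margins.total, margins.n)


def log_d_tot(margins: Margins) -> float:
    t = margins.total
    out = math.lgamma(t + 1)
    for v in margins.n:
        out -= math.lgamma(v + 1)
    return out


class ScoreDistribution:
    """Exact probability mass over achievable agreement scores.

    ``pmf`` maps integer scores to probabilities (floats or Fractions).
    ``tail_bound`` is an optional upper bound on the total probability mass
    pruned by a thresholded algorithm; scores absent from ``pmf`` have
    probability at most this bound.
    """

    def __init__(
        self,
        pmf: Mapping[int, float | Fraction],
        margins: Margins,
        tail_bound: float = 0.0,
    ):
        self.pmf = dict(sorted(pmf.items()))
        self.margins = margins
        self.tail_bound = tail_bound
        total = float(sum(self.pmf.values()))
        # Pruned mass is bounded by tail_bound; total may fall short of 1 by
        # at most that much, and can never exceed 1.
        if total > 1 + 1e-6:
            raise ValueError(f"pmf sums to {total} > 1")
        if total + tail_bound < 1 - 1e-6:
            raise ValueError(
                f"pmf sums to {total} with tail bound {tail_bound}; mass is missing"
            )

    @property
    def support(self) -> list[int]:
        return list(self.pmf)

    def probability(self, s: int) -> float:
        return float(self.pmf.get(s, 0.0))

    def right_tail(self, s_obs: int) -> float:
        """P(S >= s_obs), inclusive of the observed score."""
        return float(sum(p for s, p in self.pmf.items() if s >= s_obs))

    def __repr__(self) -> str:
        lo, hi = (min(self.pmf), max(self.pmf)) if self.pmf else (None, None)
        return f"ScoreDistribution(support=[{lo}..{hi}], margins={self.margins})"


def pvalue_right_tail(dist: ScoreDistribution, s_obs: int) -> float:
    """Right-tail p-value P(S >= s_obs) of an observed agreement score."""
    return dist.right_tail(s_obs)


def _parse_value(raw: str) -> int:
    key = str(raw).strip().lower()
    if key not in _VALUE_ALIASES:
        raise ValueError(f"unrecognised classification value {raw!r}")
    return _VALUE_ALIASES[key]


def read_classification_tsv(path: str | Path, header: bool = False) -> TernaryClassification:
    """Read a two-column ``id<TAB>value`` classification file.

    Values may be -1/0/1 or the aliases up/down/none (case-insensitive).
    """
    df = pd.read_csv(path, sep="\t", header=0 if header else None,
                     dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("classification TSV needs two columns: id, value")
    ids = df.iloc[:, 0].tolist()
    values = [_parse_value(v) for v in df.iloc[:, 1]]
    return TernaryClassification(values, ids)


def write_classification_tsv(c: TernaryClassification, path: str | Path) -> None:
    ids = c.ids if c.ids is not None else [f"e{i}" for i in range(len(c))]
    pd.DataFrame({"id": ids, "value": c.values}).to_csv(
        path, sep="\t", header=False, index=False
    )
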