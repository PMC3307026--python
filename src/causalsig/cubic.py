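"""Cubic-algorithm machinery: the aggregated sum F[n] and its exact recursion.

Aggregating D-values by gamma1 = n++ + n-- and gamma2 = n-+ + n+- reduces
the quartic enumeration to sums of the form

    F[n] = sum_k C(n, k) C(v-n, w-k) C(x-n, y-k),

with (v, w, x, y) derived from the margins and the aggregation variables.
F[n] satisfies a low-order linear recurrence with polynomial-in-n
coefficients, which in principle yields an O(N^3) algorithm — but the
recurrence suffers catastrophic cancellation in floating point (consecutive
terms shrink roughly twofold), so it is only usable in exact arithmetic.
This module ships it as an exact-arithmetic research extra: the recurrence
for a given parameter set is derived by exact rational fitting over the
standard regime n <= min(v, x) and certified against the direct sum before
any value is produced.

The direct sum uses the standard binomial convention (C(a, b) = 0 when b < 0
or b > a) and restricts its domain to v - n >= 0 and x - n >= 0; outside
that regime the convention behind the aggregation is not well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .ternary import Margins

__all__ = ["CubicParams", "Recurrence", "f_direct", "derive_recurrence", "f_recursion"]


@dataclass(frozen=True)
class CubicParams:
    """Parameters (v, w, x, y) of the aggregated sum, plus the index n.

    Derived from margins and aggregation variables gamma1 = n++ + n--,
    gamma2 = n-+ + n+-, s = n++ via

        v = q+ + q- - gamma1,   w = q+ - s,
        x = n+ + n- - gamma1,   y = n- - gamma1 + s,   n = gamma2.
    """

    v: int
    w: int
    x: int
    y: int
    n: int = 0

    @classmethod
    def from_aggregates(
        cls, margins: Margins, gamma1: int, gamma2: int, s: int
    ) -> "CubicParams":
        return cls(
            v=margins.q_plus + margins.q_minus - gamma1,
            w=margins.q_plus - s,
            x=margins.n_plus + margins.n_minus - gamma1,
            y=margins.n_minus - gamma1 + s,
            n=gamma2,
        )

    @property
    def regime_max_n(self) -> int:
        """Largest n with v - n >= 0 and x - n >= 0 (the standard regime)."""
        return min(self.v, self.x)

    def at(self, n: int) -> "CubicParams":
        return CubicParams(self.v, self.w, self.x, self.y, n)


def _binom(a: int, b: int) -> int:
    if b < 0 or b > a or a < 0:
        return 0
    return math.comb(a, b)


def f_direct(p: CubicParams) -> int:
    """Evaluate F[n] = sum_k C(n,k) C(v-n, w-k) C(x-n, y-k) exactly.

    Raises outside the standard regime (v - n < 0 or x - n < 0), where the
    binomial convention underlying the aggregation is ambiguous.
    """
    if p.v - p.n < 0 or p.x - p.n < 0:
        raise ValueError(
            f"n={p.n} outside the standard regime (v-n={p.v - p.n}, x-n={p.x - p.n})"
        )
    return sum(
        _binom(p.n, k) * _binom(p.v - p.n, p.w - k) * _binom(p.x - p.n, p.y - k)
        for k in range(0, p.n + 1)
    )


def _rational_nullspace(rows: list[list[int]]) -> list[list[Fraction]]:
    """Basis of the nullspace of an integer matrix, by exact Gauss-Jordan."""
    if not rows:
        return []
    m, ncols = len(rows), len(rows[0])
    a = [[Fraction(v) for v in row] for row in rows]
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        pr = next((i for i in range(r, m) if a[i][c] != 0), None)
        if pr is None:
            continue
        a[r], a[pr] = a[pr], a[r]
        inv = a[r][c]
        a[r] = [v / inv for v in a[r]]
        for i in range(m):
            if i != r and a[i][c] != 0:
                f = a[i][c]
                a[i] = [vi - f * vr for vi, vr in zip(a[i], a[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    free = [c for c in range(ncols) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * ncols
        vec[fc] = Fraction(1)
        for pi, pc in enumerate(pivots):
            vec[pc] = -a[pi][fc]
        basis.append(vec)
    return basis


@dataclass(frozen=True)
class Recurrence:
    """An exact linear recurrence sum_i P_i(n) F[n+i] = 0.

    ``coeffs[i]`` holds the integer coefficients of P_i(n) in ascending powers
    of n.  Certified to hold on the full standard regime of its parameters.
    """

    coeffs: tuple[tuple[int, ...], ...]

    @property
    def order(self) -> int:
        return len(self.coeffs) - 1

    def poly(self, i: int, n: int) -> int:
        return sum(c * n**d for d, c in enumerate(self.coeffs[i]))

    def step(self, n: int, window: Sequence[int]) -> int:
        """Given F[n..n+order-1], return F[n+order] (exact)."""
        lead = self.poly(self.order, n)
        if lead == 0:
            raise ZeroDivisionError(f"leading recurrence coefficient vanishes at n={n}")
        num = -sum(self.poly(i, n) * window[i] for i in range(self.order))
        val = Fraction(num, lead)
        if val.denominator != 1:
            raise ArithmeticError(f"recurrence step at n={n} is not integral")
        return int(val)


def derive_recurrence(p: CubicParams, order: int = 3, max_degree: int = 6) -> Recurrence:
    """Derive an order-``order`` recurrence for F[n] at these parameters.

    Finds the lowest coefficient degree admitting an exact relation over the
    whole standard regime, by rational nullspace computation on the exact
    F-values, and verifies the relation at every applicable n before
    returning.  Exact arithmetic throughout.
    """
    nmax = p.regime_max_n
    if nmax < order:
        raise ValueError(f"standard regime 0..{nmax} too short for order {order}")
    vals = [f_direct(p.at(n)) for n in range(nmax + 1)]
    for deg in range(0, max_degree + 1):
        rows = []
        for n in range(nmax - order + 1):
            row = []
            for i in range(order + 1):
                for d in range(deg + 1):
                    row.append(n**d * vals[n + i])
            rows.append(row)
        basis = _rational_nullspace(rows)
        for vec in basis:
            den = math.lcm(*(f.denominator for f in vec)) if vec else 1
            ints = [int(f * den) for f in vec]
            g = math.gcd(*ints) if any(ints) else 1
            ints = [v // g for v in ints]
            coeffs = tuple(
                tuple(ints[i * (deg + 1) : (i + 1) * (deg + 1)])
                for i in range(order + 1)
            )
            rec = Recurrence(coeffs)
            if _certify(rec, vals):
                return rec
    raise ValueError(f"no recurrence of order {order}, degree <= {max_degree} found")


def _certify(rec: Recurrence, vals: list[int]) -> bool:
    """Check the relation at every n in the regime, and that the leading
    coefficient never vanishes where a step would be taken."""
    order = rec.order
    for n in range(len(vals) - order):
        if sum(rec.poly(i, n) * vals[n + i] for i in range(order + 1)) != 0:
            return False
        if rec.poly(order, n) == 0:
            return False
    return True


def f_recursion(
    p: CubicParams, seed_values: Sequence[int], length: int
) -> list[int]:
    """Extend the F-sequence from three consecutive exact seed values.

    ``seed_values`` are F at indices p.n, p.n+1, p.n+2 (as produced by
    :func:`f_direct`); returns the sequence F[p.n .. p.n+length-1], every
    value obtained by the derived recurrence in exact integer arithmetic.
    Only exact arithmetic is offered: in floating point the recurrence
    cancels catastrophically (consecutive terms shrink roughly twofold).
    """
    rec = derive_recurrence(p)
    if len(seed_values) != rec.order:
        raise ValueError(f"need {rec.order} consecutive seed values")
    if p.n + length - 1 > p.regime_max_n:
        raise ValueError("requested extension leaves the standard regime")
    out = [int(v) for v in seed_values]
    while len(out) < length:
        n = p.n + len(out) - rec.order
        out.append(rec.step(n, out[-rec.order :]))
    return out[:length]
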