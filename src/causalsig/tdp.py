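"""Algorithms for the ternary dot product distribution.

Four routes to the same exact null distribution of the agreement score S
between a fixed ternary classification and a random rearrangement of a
second one:

``oracle_distribution``
    Exhaustive enumeration of all feasible 3x3 contingency tables in rational
    arithmetic.  The reference implementation; refuses large problems.

``quartic_distribution``
    Visits every feasible top-left 2x2 corner (n++, n+-, n-+, n--), obtaining
    each D-value from a neighbour in O(1) via multiplicative ratio identities,
    working in log space.  O(N^4) where N = max(n+, n-, q+, q-).

``distribution_1a`` / ``distribution_1b``
    Thresholded algorithms.  Tables are grouped into one-parameter *families*
    (fixed 2x2 row and column sums r+, r-, c+, c-) within which the D-value
    is unimodal in u = n++; a family whose maximum D-value falls below
    eps * D_max is discarded after a constant amount of work.  Algorithm 1b
    adds an outer screen over *superfamilies* (only the 2x2 row sums fixed),
    pruning whole ranges of families at once — the production path for large
    margins.

All floating-point accumulation is additive in log space (log-add-exp); no
subtraction of D-values ever occurs, so rounding error cannot cancel
catastrophically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .ternary import (
    ContingencyTable3x3,
    Margins,
    ScoreDistribution,
    d_tot,
    d_value,
    log_d_tot,
    log_d_value,
)

__all__ = [
    "FamilySpec",
    "ThresholdConfig",
    "TdpStats",
    "oracle_distribution",
    "quartic_distribution",
    "family_opt_u",
    "delta_d",
    "global_max_d",
    "distribution_1a",
    "distribution_1b",
]

_NEG_INF = float("-inf")


def _logaddexp(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


@dataclass(frozen=True)
class FamilySpec:
    """A one-parameter family of tables: fixed 2x2 row sums (r+, r-) and
    column sums (c+, c-) of the top-left submatrix; parameterised by u = n++."""

    r_plus: int
    r_minus: int
    c_plus: int
    c_minus: int

    def __post_init__(self):
        if self.r_plus + self.r_minus != self.c_plus + self.c_minus:
            raise ValueError("2x2 row sums and column sums must share a total")
        if min(self.r_plus, self.r_minus, self.c_plus, self.c_minus) < 0:
            raise ValueError("family sums must be nonnegative")

    @property
    def t(self) -> int:
        return self.r_plus + self.r_minus

    @property
    def u_range(self) -> tuple[int, int]:
        """Inclusive range of feasible u = n++ (within-family feasibility only)."""
        return (max(0, self.c_plus - self.r_minus), min(self.r_plus, self.c_plus))

    def corner(self, u: int) -> tuple[int, int, int, int]:
        """(n++, n+-, n-+, n--) at parameter u."""
        return (u, self.r_plus - u, self.c_plus - u, self.r_minus - self.c_plus + u)


@dataclass(frozen=True)
class ThresholdConfig:
    """Pruning configuration for the thresholded algorithms.

    ``epsilon``
        Relative threshold: tables with D < epsilon * D_max are negligible.
        The default is double machine epsilon, sufficient because pruned mass
        is only ever excluded, never subtracted.
    ``safety_factor``
        Extra slack (<1) multiplied into the threshold because the D_max used
        for comparison comes from a heuristic proportional-fill maximiser.
    """

    epsilon: float = 1e-16
    safety_factor: float = 1e-2

    def __post_init__(self):
        if not 0 < self.epsilon * self.safety_factor < 1:
            raise ValueError("epsilon * safety_factor must be in (0, 1)")


@dataclass
class TdpStats:
    """Work counters from a thresholded run (for diagnostics and scaling tests)."""

    family_checks: int = 0
    superfamily_checks: int = 0
    sweep_steps: int = 0
    skipped_tables: int = 0

    @property
    def threshold_checks(self) -> int:
        return self.family_checks + self.superfamily_checks


# ---------------------------------------------------------------------------
# Exhaustive oracle


def _iter_corners(margins: Margins):
    """Yield all feasible (n++, n+-, n-+, n--) corners for the margins."""
    qp, qm, qz = margins.q
    np_, nm, nz = margins.n
    for i in range(min(qp, np_) + 1):
        for j in range(min(qp - i, nm) + 1):
            for k in range(min(qm, np_ - i) + 1):
                # n00 >= 0  <=>  l >= n+ + n- - q0 - i - j - k
                lmin = max(0, np_ + nm - qz - i - j - k)
                lmax = min(qm - k, nm - j)
                for l in range(lmin, lmax + 1):
                    yield (i, j, k, l)


def oracle_distribution(margins: Margins, cap: int = 10**7) -> ScoreDistribution:
    """Exact distribution by brute-force enumeration (rational arithmetic).

    Refuses problems with d_tot beyond ``cap``; intended as a test oracle.
    """
    total = d_tot(margins)
    if total > cap:
        raise ValueError(f"d_tot={total} exceeds oracle cap {cap}")
    acc: dict[int, int] = {}
    for i, j, k, l in _iter_corners(margins):
        table = ContingencyTable3x3.from_corner(margins, i, j, k, l)
        s = i + l - j - k
        acc[s] = acc.get(s, 0) + d_value(table)
    if sum(acc.values()) != total:
        raise AssertionError("enumeration does not conserve D_tot")
    pmf = {s: Fraction(v, total) for s, v in acc.items()}
    return ScoreDistribution(pmf, margins)


# ---------------------------------------------------------------------------
# Quartic algorithm


def quartic_distribution(margins: Margins) -> ScoreDistribution:
    """Log-space sweep over all feasible 2x2 corners.

    For fixed (i, j, k) = (n++, n+-, n-+), the D-value along l = n-- obeys

        D[l+1] / D[l] = n-0 / (l+1)  *  n0- / (n00 + 1),

    (remaining row margin over incremented cell, times remaining column
    margin over incremented zero-zero cell), so each value costs O(1).  All
    values are carried relative to the global maximum so the normalised
    weights stay within [0, 1].
    """
    qp, qm, qz = margins.q
    np_, nm, nz = margins.n
    _, log_dmax = global_max_d(margins)
    acc: dict[int, float] = {}
    for i in range(min(qp, np_) + 1):
        for j in range(min(qp - i, nm) + 1):
            for k in range(min(qm, np_ - i) + 1):
                lmin = max(0, np_ + nm - qz - i - j - k)
                lmax = min(qm - k, nm - j)
                if lmax < lmin:
                    continue
                base = ContingencyTable3x3.from_corner(margins, i, j, k, lmin)
                logd = log_d_value(base) - log_dmax
                l = lmin
                while True:
                    s = i + l - j - k
                    acc[s] = _logaddexp(acc.get(s, _NEG_INF), logd)
                    if l == lmax:
                        break
                    nm0 = qm - k - l          # remaining row margin of the - row
                    n0m = nm - j - l          # remaining column margin of the - col
                    n00 = qz - (np_ - i - k) - (nm - j - l)
                    logd += math.log(nm0) - math.log(l + 1)
                    logd += math.log(n0m) - math.log(n00 + 1)
                    l += 1
    log_total = log_d_tot(margins) - log_dmax
    pmf = {s: math.exp(v - log_total) for s, v in acc.items()}
    return ScoreDistribution(pmf, margins)


# ---------------------------------------------------------------------------
# Family machinery for the thresholded algorithms


def delta_d(u: int, fam: FamilySpec) -> Fraction:
    """Multiplicative change D[u-1]/D[u] upon decrementing u = n++.

    Equals u (r- - c+ + u) / ((r+ - u + 1)(c+ - u + 1)); both u and u-1 must
    be feasible in the family.
    """
    lo, hi = fam.u_range
    if not (lo + 1 <= u <= hi):
        raise ValueError(f"u={u} has no feasible predecessor in {fam}")
    return Fraction(
        u * (fam.r_minus - fam.c_plus + u),
        (fam.r_plus - u + 1) * (fam.c_plus - u + 1),
    )


def family_opt_u(fam: FamilySpec) -> int:
    """The u = n++ maximising D within the family.

    The ratio D[u-1]/D[u] is a ratio of monic quadratics in u crossing 1 at
    u* = (r+ + 1)(c+ + 1)/(t + 2); the maximiser is floor or ceil of u*,
    clamped to the feasible range.
    """
    lo, hi = fam.u_range
    if hi < lo:
        raise ValueError(f"family {fam} is empty")
    if lo == hi:
        return lo
    u_star = (fam.r_plus + 1) * (fam.c_plus + 1) / (fam.t + 2)
    u = min(max(math.floor(u_star), lo), hi)
    # D increases while delta_d(u+1) = D[u]/D[u+1] < 1; settle locally.
    while u < hi and delta_d(u + 1, fam) < 1:
        u += 1
    while u > lo and delta_d(u, fam) > 1:
        u -= 1
    return u


def _max_transport(row_sums: list[int], col_sums: list[int]) -> list[list[int]]:
    """Integer matrix with the given margins maximising -sum(lgamma(x+1)).

    Proportional fill with largest-remainder rounding, column repair, then
    greedy 2x2-swap local search.  The objective is separable concave, so a
    swap-local optimum is a global optimum on the transportation polytope.
    """
    total = sum(row_sums)
    if total != sum(col_sums):
        raise ValueError("row and column sums must agree")
    nr, nc = len(row_sums), len(col_sums)
    if total == 0:
        return [[0] * nc for _ in range(nr)]
    cells = [[0] * nc for _ in range(nr)]
    for i in range(nr):
        raws = [row_sums[i] * col_sums[j] / total for j in range(nc)]
        floors = [math.floor(x) for x in raws]
        deficit = row_sums[i] - sum(floors)
        order = sorted(range(nc), key=lambda j: raws[j] - floors[j], reverse=True)
        for j in order[:deficit]:
            floors[j] += 1
        cells[i] = floors
    # repair column sums (row sums already exact): move units between columns
    col_err = [sum(cells[i][j] for i in range(nr)) - col_sums[j] for j in range(nc)]
    while any(col_err):
        j_ex = max(range(nc), key=lambda j: col_err[j])
        j_def = min(range(nc), key=lambda j: col_err[j])
        best_i, best_gain = -1, _NEG_INF
        for i in range(nr):
            if cells[i][j_ex] > 0:
                gain = math.log(cells[i][j_ex]) - math.log(cells[i][j_def] + 1)
                if gain > best_gain:
                    best_i, best_gain = i, gain
        cells[best_i][j_ex] -= 1
        cells[best_i][j_def] += 1
        col_err[j_ex] -= 1
        col_err[j_def] += 1
    # greedy 2x2 swaps until local (= global, by concavity) optimum
    improved = True
    while improved:
        improved = False
        for i1 in range(nr):
            for i2 in range(nr):
                if i1 == i2:
                    continue
                for j1 in range(nc):
                    for j2 in range(nc):
                        if j1 == j2:
                            continue
                        # move a unit: (i1,j1)+, (i2,j2)+, (i1,j2)-, (i2,j1)-
                        if cells[i1][j2] < 1 or cells[i2][j1] < 1:
                            continue
                        gain = (
                            math.log(cells[i1][j2])
                            + math.log(cells[i2][j1])
                            - math.log(cells[i1][j1] + 1)
                            - math.log(cells[i2][j2] + 1)
                        )
                        if gain > 1e-12:
                            cells[i1][j1] += 1
                            cells[i2][j2] += 1
                            cells[i1][j2] -= 1
                            cells[i2][j1] -= 1
                            improved = True
    return cells


def global_max_d(margins: Margins) -> tuple[ContingencyTable3x3, float]:
    """A table attaining (up to rounding slack) the maximal D-value.

    D_max is achieved near the proportional fill n[s][t] ~ q_s n_t / T;
    proportional fill plus swap local search pins down the integer optimum.
    Returns the table and its log D-value.
    """
    cells = _max_transport(list(margins.q), list(margins.n))
    table = ContingencyTable3x3(tuple(tuple(r) for r in cells), margins)
    return table, log_d_value(table)


def _log_d_corner(margins: Margins, i: int, j: int, k: int, l: int) -> float:
    """log D for the table with top-left corner (i, j, k, l), no validation.

    The caller guarantees feasibility; this is the hot path of the
    thresholded algorithms.
    """
    qp, qm, qz = margins.q
    np_, nm, nz = margins.n
    lg = math.lgamma
    return (
        lg(qp + 1) + lg(qm + 1) + lg(qz + 1)
        - lg(i + 1) - lg(j + 1) - lg(qp - i - j + 1)
        - lg(k + 1) - lg(l + 1) - lg(qm - k - l + 1)
        - lg(np_ - i - k + 1) - lg(nm - j - l + 1)
        - lg(qz - (np_ - i - k) - (nm - j - l) + 1)
    )


def _family_sweep(
    margins: Margins,
    fam: FamilySpec,
    log_dmax: float,
    log_thresh: float,
    acc: dict[int, float],
    stats: TdpStats,
) -> None:
    """Sweep u outward from the family optimum, accumulating scores until the
    D-value drops below threshold in each direction.

    Uses float ratios for speed: the start point only needs to be near the
    in-family optimum (the D-profile is unimodal, so the outward stopping
    rule stays sound for any start within the above-threshold plateau).
    """
    lo, hi = fam.u_range
    if hi < lo:
        return
    rp, rm, cp = fam.r_plus, fam.r_minus, fam.c_plus
    # in-family optimum: crossing point of the monic quadratics, clamped
    if lo == hi:
        u0 = lo
    else:
        u0 = min(max(math.floor((rp + 1) * (cp + 1) / (fam.t + 2)), lo), hi)
        while u0 < hi and (u0 + 1) * (rm - cp + u0 + 1) < (rp - u0) * (cp - u0):
            u0 += 1
        while u0 > lo and u0 * (rm - cp + u0) > (rp - u0 + 1) * (cp - u0 + 1):
            u0 -= 1
    logd0 = _log_d_corner(margins, *fam.corner(u0)) - log_dmax
    if logd0 < log_thresh:
        stats.skipped_tables += hi - lo + 1
        return
    s_base = rm - rp - 2 * cp  # score at u is 4u + s_base
    steps = 1
    s = 4 * u0 + s_base
    acc[s] = _logaddexp(acc.get(s, _NEG_INF), logd0)
    logd = logd0
    for u in range(u0 + 1, hi + 1):
        # D[u]/D[u-1] = ((r+ - u + 1)(c+ - u + 1)) / (u (r- - c+ + u))
        logd += math.log(
            (rp - u + 1) * (cp - u + 1) / (u * (rm - cp + u))
        )
        if logd < log_thresh:
            stats.skipped_tables += hi - u + 1
            break
        s = 4 * u + s_base
        acc[s] = _logaddexp(acc.get(s, _NEG_INF), logd)
        steps += 1
    logd = logd0
    for u in range(u0 - 1, lo - 1, -1):
        logd += math.log(
            (u + 1) * (rm - cp + u + 1) / ((rp - u) * (cp - u))
        )
        if logd < log_thresh:
            stats.skipped_tables += u - lo + 1
            break
        s = 4 * u + s_base
        acc[s] = _logaddexp(acc.get(s, _NEG_INF), logd)
        steps += 1
    stats.sweep_steps += steps


def _iter_row_sums(margins: Margins):
    """Feasible (r+, r-) with the implied outer column cells nonnegative."""
    qp, qm, qz = margins.q
    np_, nm, nz = margins.n
    for rp in range(min(qp, np_ + nm) + 1):
        for rm in range(min(qm, np_ + nm - rp) + 1):
            r0 = np_ + nm - rp - rm          # left-block zero-row sum
            if qz - r0 < 0:                  # n00 = q0 - r0 must be >= 0
                continue
            yield rp, rm


def _iter_col_sums(margins: Margins, rp: int, rm: int):
    """Feasible c+ for the (r+, r-) superfamily."""
    t = rp + rm
    np_, nm, _ = margins.n
    for cp in range(max(0, t - nm), min(t, np_) + 1):
        yield cp


def _finish(
    margins: Margins,
    acc: dict[int, float],
    log_dmax: float,
    log_thresh: float,
    stats: TdpStats,
) -> ScoreDistribution:
    log_total = log_d_tot(margins) - log_dmax
    pmf = {s: math.exp(v - log_total) for s, v in acc.items()}
    tail = stats.skipped_tables * math.exp(log_thresh - log_total)
    dist = ScoreDistribution(pmf, margins, tail_bound=tail)
    dist.stats = stats
    return dist


def distribution_1a(
    margins: Margins, cfg: ThresholdConfig | None = None
) -> ScoreDistribution:
    """Thresholded algorithm over 2x2 families.

    Iterates the O(N^3) families (r+, r-, c+); discards a family when its
    maximum D-value (at the in-family optimum u) is below
    epsilon * safety * D_max, otherwise sweeps u outward from the optimum.
    """
    cfg = cfg or ThresholdConfig()
    _, log_dmax = global_max_d(margins)
    log_thresh = math.log(cfg.epsilon * cfg.safety_factor)
    acc: dict[int, float] = {}
    stats = TdpStats()
    for rp, rm in _iter_row_sums(margins):
        for cp in _iter_col_sums(margins, rp, rm):
            fam = FamilySpec(rp, rm, cp, rp + rm - cp)
            stats.family_checks += 1
            _family_sweep(margins, fam, log_dmax, log_thresh, acc, stats)
    return _finish(margins, acc, log_dmax, log_thresh, stats)


def distribution_1b(
    margins: Margins, cfg: ThresholdConfig | None = None
) -> ScoreDistribution:
    """Thresholded algorithm with an outer superfamily screen.

    For each (r+, r-) superfamily (only the 2x2 row sums fixed), the maximal
    D-value over all member tables is attained by filling the left 3x2
    submatrix (row sums r+, r-, r0; column sums n+, n-) proportionally.  A
    superfamily below threshold removes an entire one-parameter range of c+
    families at once; survivors fall through to the 1a inner loop.
    """
    cfg = cfg or ThresholdConfig()
    _, log_dmax = global_max_d(margins)
    log_thresh = math.log(cfg.epsilon * cfg.safety_factor)
    acc: dict[int, float] = {}
    stats = TdpStats()
    for rp, rm in _iter_row_sums(margins):
        stats.superfamily_checks += 1
        r0 = margins.n_plus + margins.n_minus - rp - rm
        left = _max_transport([rp, rm, r0], [margins.n_plus, margins.n_minus])
        corner = (left[0][0], left[0][1], left[1][0], left[1][1])
        if _log_d_corner(margins, *corner) - log_dmax < log_thresh:
            for cp in _iter_col_sums(margins, rp, rm):
                fam = FamilySpec(rp, rm, cp, rp + rm - cp)
                lo, hi = fam.u_range
                if hi >= lo:
                    stats.skipped_tables += hi - lo + 1
            continue
        for cp in _iter_col_sums(margins, rp, rm):
            fam = FamilySpec(rp, rm, cp, rp + rm - cp)
            stats.family_checks += 1
            _family_sweep(margins, fam, log_dmax, log_thresh, acc, stats)
    return _finish(margins, acc, log_dmax, log_thresh, stats)
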