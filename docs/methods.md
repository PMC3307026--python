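# Methods

## The ternary dot product null model

A ternary classification assigns each element of a ground set of size T a
label in {−1, 0, +1}. Fixing one classification C (margins q₊, q₋, q₀) and
rearranging the other C′ (margins n₊, n₋, n₀) uniformly over all
T!/(n₊! n₋! n₀!) arrangements induces a distribution over 3×3 contingency
tables; the number of arrangements giving a table is the product of three
multinomial coefficients (the D-value), and aggregating D-values by the
score S = n₊₊ + n₋₋ − n₊₋ − n₋₊ and normalising yields the exact null
distribution of the agreement score. The model conditions on both margin
triples, exactly as Fisher's exact test conditions on its 2×2 margins; it
does not model the upstream calling procedure that produced the ternary
labels (fold-change thresholds, test statistics), and exchangeability of
elements under rearrangement is the core assumption.

p-values are right tails, inclusive of the observed score (the standard
exact-test convention; inclusivity matters because the support is a lattice
of integers with steps of 2 within a family sweep and 1 overall).

### Algorithms

* **Oracle** (`oracle_distribution`): enumerate every feasible top-left 2×2
  corner (the other five cells are implied by the margins), compute exact
  integer D-values, normalise as rationals. Complexity O(N⁴) with big-int
  arithmetic; refuses problems with D_tot above a cap. This is the
  reference implementation used by the test suite, kept deliberately
  independent of the fast paths.

* **Quartic sweep** (`quartic_distribution`): the same enumeration in log
  space. Along the n₋₋ axis each D-value follows from its neighbour by the
  ratio (remaining row margin)/(new cell count) × (remaining column
  margin)/(n₀₀ + 1); each axis segment is seeded by a direct lgamma
  evaluation, so the r = q₀ + n₀ − T + 1 ≤ 0 corner case (where the
  all-zero corner is infeasible as a starting cell) needs no special
  handling. All values are carried relative to the global maximum D so
  normalised weights stay in [0, 1].

* **Thresholded families** (`distribution_1a`): tables are grouped into
  families sharing the 2×2 row sums (r₊, r₋) and column sums (c₊, c₋);
  within a family, parameterised by u = n₊₊, the D-value is proportional to
  1/(n₊₊! n₊₋! n₋₊! n₋₋!), which is unimodal in u with the maximiser at the
  crossing point u* = (r₊+1)(c₊+1)/(t+2) of the monic quadratics in the
  decrement ratio ΔD[u] = u(r₋ − c₊ + u)/((r₊ − u + 1)(c₊ − u + 1)). A
  family whose maximum falls below ε·D_max is discarded after O(1) work;
  otherwise u is swept outward from the optimum until the D-value drops
  below threshold. Because the profile is unimodal, the outward stopping
  rule is sound from any start inside the above-threshold plateau, which is
  why the sweep can use floating-point ratios while `delta_d` and
  `family_opt_u` expose the exact rational forms.

* **Superfamily screen** (`distribution_1b`): an outer loop over (r₊, r₋)
  only. The maximal D-value over the whole superfamily is attained by
  filling the left 3×2 submatrix (row sums r₊, r₋, r₀; column sums n₊, n₋)
  proportionally; a sub-threshold superfamily eliminates its entire range
  of c₊ families at once. This is the production path: sparse problems
  (n₀ ≫ n₊) see an order-of-magnitude drop in threshold checks, and
  margins of 512 with tenfold zeros complete in about two minutes on one
  CPU in pure Python.

### Maximiser, thresholds, tail reporting

The global maximum D is found by proportional fill n_στ ≈ q_σ n_τ / T with
largest-remainder rounding, column repair, and greedy 2×2-swap local
search. The objective log D is a sum of concave single-cell terms over a
transportation polytope, where swap-local optima are global; the small-case
tests confirm maximality against exhaustive enumeration. Because the fill
is heuristic, thresholds are multiplied by a safety factor (default 10⁻²)
so a slightly underestimated D_max cannot cause unsound pruning.

Default ε = 10⁻¹⁶ (double machine epsilon). Pruned mass is only ever
*excluded*, never subtracted, so rounding error is additive; accumulation
uses log-add-exp exclusively. Scores never reached by a surviving table are
reported as probability 0 together with `tail_bound`, an upper bound
ε·safety·D_max·(#pruned tables)/D_tot on the total pruned mass; a
`ScoreDistribution` validates that retained mass plus this bound covers 1.

### The aggregated sum F[n] and its recursion

Aggregating D-values by γ₁ = n₊₊ + n₋₋ and γ₂ = n₊₋ + n₋₊ reduces the
enumeration to sums F[n] = Σ_k C(n,k) C(v−n, w−k) C(x−n, y−k), with
(v, w, x, y) determined by the margins and aggregation variables. F[n]
satisfies a low-order linear recurrence with polynomial-in-n coefficients,
which would give a cubic-time algorithm — but consecutive terms shrink
roughly twofold, so the recursion cancels catastrophically in floating
point and is provided in exact arithmetic only, as a research extra
(`causalsig.cubic`; not exposed in the CLI). For a given parameter set the
recurrence is derived by exact rational nullspace fitting over the standard
regime n ≤ min(v, x) and certified against the direct sum at every
applicable index before use; `f_recursion` then extends the sequence from
three consecutive seed values. Outside the standard regime (v − n < 0 or
x − n < 0) the binomial convention underlying the aggregation is ambiguous
and `f_direct` refuses rather than guess.

## Graph randomization

The null model fixes each vertex's positive and negative in- and
out-degrees, forbids self-edges and parallel edges (at most one edge per
ordered pair; anti-parallel pairs are allowed — the strong triangle itself
requires them), and demands weak connectedness of the unsigned shadow
graph. Moves are same-sign edge switches and same-sign triangle flips;
proposals draw two distinct edges uniformly, and every failed legality
check is a restart that still counts as a proposal. Proposal symmetry plus
rejection makes the uniform distribution stationary on the reachable state
space; the chain runs for γ·|E| proposals (default γ = 100).

Connectedness is part of move legality. Two enforcement modes:

* `connectivity="move"` (default): each accepted move is immediately
  verified with a rebuilt union-find and undone in O(1) if it disconnects
  the graph. The chain then never leaves the connected state space — on the
  4-vertex directed path, whose only switch disconnects, the input graph is
  always returned.
* `connectivity="batch"`: the check runs every K proposals; K adapts
  multiplicatively (defaults K₀ = 50, growth 1 + 0.131 on success, shrink
  1 − 0.076 on failure) and a failed check reverts to the state saved at
  the last passing check. This is far cheaper on large graphs but a window
  can pass through disconnected intermediates, which slightly enlarges the
  reachable space; the trade-off is documented rather than hidden, and the
  interval trace is recorded in `RunStats.k_trace`.

Run statistics count proposals, accepted switches and flips, connectivity
failures, and encounters with the local sign patterns that block moves:
strong quadrilaterals (a same-sign edge pair whose switch targets exist
with the opposite sign) and strong triangles (a same-sign 3-cycle whose
reversal exists with the opposite sign). `detect_obstacles` counts these
exhaustively on small graphs, once per structure via its positive-sign
representative. `flip_strong_triangle_aux` demonstrates — as a diagnostic,
not a chain move — that three disjoint positive auxiliary edges suffice to
flip a strong triangle through nine legal switches/flips (opening,
flipping, closing, restoring).

`enumerate_state_space` brute-forces every simple weakly connected signed
digraph with the input's degree signature (≤ 12 edges), used to verify
chain uniformity: on a fixture whose move graph is connected, thinned chain
samples (every 10th proposal, 10⁵ samples) pass a chi-square test against
uniform; thinning is needed because consecutive chain states are
autocorrelated and would inflate the statistic. The proposal kernel's exact
symmetry on the 18-state fixture was additionally verified by constructing
the full transition matrix.

## Hypothesis engine

Predictions trace shortest directed paths from the hypothesis vertex; a
path's sign is the product of its edge signs, and a node's prediction is
the hypothesis direction times that sign. Default depth is 1 (direct
targets only), with any depth up to unlimited available. When equally short
paths disagree in sign the node is predicted 0 and flagged — a stated
placeholder rule, since tie resolution between conflicting shortest paths
is not prescribed by the scoring model; the hypothesis vertex itself
receives no prediction. Scoring restricts to measurable transcript nodes
(default: the experimental classification's ground set). The exact p-value
uses margins q from the experimental and n from the predicted
classification; the empirical p-value is the fraction of degree-preserving
replicates scoring at least the observed score (ties count against the
hypothesis — the conservative reading of "better"), reported as `< 1/R`
when no replicate reaches it. Ranking is by score descending with
competition ranking for ties.

## Synthetic fixtures

`gen_classification` realizes a uniform rearrangement of prescribed label
counts; `gen_connected_signed_graph` builds a random spanning tree
(connectivity by construction), assigns orientations and signs from the
sign budget, then places remaining arcs by rejection sampling. Generated
graphs have exact sign-stratified edge counts and are deterministic per
seed, but make no attempt to match the long-tailed degree distributions of
real regulatory networks — so passing randomization tests demonstrates
correctness of the invariant preservation and sampling machinery, not
mixing behaviour on hub-dominated biological graphs. Test problem sizes
(margin grids with T ≤ 10 for exactness, N up to 512 for scaling, fixture
graphs of 50–500 edges, 10⁵ chain samples) were chosen so the full suite
exercises every guarantee at desk scale.

## Known limitations

* Ergodicity of the switch/flip chain on the connected signed state space
  is not established in general (the 4-path's second member is provably
  unreachable without a 3-swap move, which is deliberately not included);
  empirical p-values are exact only with respect to the reachable subspace.
* The thresholded algorithms guarantee precision relative to the maximal
  probability, not per-score: tail probabilities below ε·D_max/D_tot are
  bounded, not computed.
* The cubic-route recursion requires exact arithmetic; no floating-point
  mode is offered.
* Mixing time is unquantified; γ = 100 follows common practice and the
  uniformity fixture, not theory.
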