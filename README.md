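# causalsig

Statistical significance for signed causal graph analysis.

Signed causal graphs — directed graphs whose edges carry a +/− sign for
positive or negative regulation — predict which gene transcripts should go
up or down when an upstream entity is perturbed. Scoring such a *hypothesis*
(a vertex plus a perturbation direction) against an experimental
up/down/unchanged classification raises two null-distribution questions,
and this package answers both:

1. **Ternary dot product distribution.** Encode each classification as a
   vector with entries in {−1, 0, +1}. The agreement score is the dot
   product S = u(C)·u(C′) = n₊₊ + n₋₋ − n₊₋ − n₋₊, where n_στ are the cells
   of the 3×3 contingency table with fixed row margins q_σ (experimental)
   and column margins n_τ (predicted). Under the null that the predicted
   labels are rearranged uniformly at random, the number of rearrangements
   producing a table is a product of three multinomial coefficients

       D[n±±] = (q₊; n₊₊, n₊₋, n₊₀) (q₋; n₋₊, n₋₋, n₋₀) (q₀; n₀₊, n₀₋, n₀₀),

   and p(S) = Σ_{tables with score S} D / D_tot with D_tot = (T; n₊, n₋, n₀).
   This is a ternary generalisation of Fisher's exact test. The package
   computes the exact distribution four ways: a brute-force rational oracle,
   a quartic log-space sweep using O(1) neighbour ratio identities, and two
   thresholded algorithms that prune entire families of negligible tables
   (the production path, fast up to margins in the thousands). An
   exact-arithmetic three-term-recursion route for the aggregated sums F[n]
   ships as a research extra.

2. **Causal graph randomization.** Empirical p-values need uniform samples
   from the family of simple, weakly connected signed digraphs with every
   vertex's positive/negative in/out-degrees fixed. A Markov chain of
   same-sign edge switches ((a,b),(c,d) → (a,d),(c,b)) and triangle flips
   (reversal of a same-sign directed 3-cycle) with symmetric proposals and
   rejection has the uniform stationary distribution. The module also
   diagnoses the local sign patterns (strong quadrilaterals and strong
   triangles) that block individual moves, demonstrates how auxiliary edges
   bypass a strong triangle, and can enumerate the full state space of small
   graphs for validation.

## Worked example

Experimental classification with q = (2, 1, 2) — two transcripts up, one
down, two unchanged — and a prediction with n = (1, 1, 3), observed
agreement score S = 1:

```sh
causalsig tdp --q-plus 2 --q-minus 1 --q-zero 2 \
              --n-plus 1 --n-minus 1 --n-zero 3 --score 1 --algorithm 1b
```

prints

```
score	probability	right_tail_p
-2	0.1	1
-1	0.3	0.9
0	0.2	0.6
1	0.3	0.4
2	0.1	0.1
# observed score 1: right-tail p = 0.4
```

i.e. of the 20 equally likely rearrangements of the predicted labels, 2
score +2 and 6 score +1, so observing S ≥ 1 has exact probability 0.4 — no
evidence of agreement beyond chance. The same quantities are available in
Python:

```python
from causalsig import Margins, distribution_1b

dist = distribution_1b(Margins(2, 1, 2, 1, 1, 3))
print(dist.pmf)            # {-2: 0.1, -1: 0.3, 0: 0.2, 1: 0.3, 2: 0.1}
print(dist.right_tail(1))  # 0.4
```

For the graph null model, generate a seeded fixture graph, draw
degree-preserving randomizations, and rank hypotheses with both p-values:

```sh
causalsig fixtures --kind graph --spec gspec.yaml --seed 3 --out g.tsv
causalsig randomize --graph g.tsv --gamma 5 --replicates 100 --seed 1 --out-dir reps
causalsig score --graph g.tsv --experimental expression.tsv \
                --depth 2 --replicate-dir reps --out results.tsv
```

`results.tsv` mirrors the hypothesis-ranking layout (rank, hypothesis,
correct, incorrect, score, exact p, empirical p), with tied scores sharing
a rank and empirical p-values below resolution reported as `< 1/R`.

## Layout

- `causalsig.ternary` — classifications, margins, contingency tables,
  D-values, score distributions, classification TSV I/O
- `causalsig.tdp` — the four distribution algorithms and family machinery
- `causalsig.cubic` — the aggregated sum F[n] and its exact recursion
- `causalsig.graphs` — signed digraphs, chain moves, randomization,
  obstacle diagnostics, state-space enumeration, graph TSV/SIF I/O
- `causalsig.hypothesis` — prediction, scoring, p-values, ranking
- `causalsig.fixtures` — seeded synthetic classifications and graphs
- `docs/methods.md` — model assumptions, parameter choices, numerical notes
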