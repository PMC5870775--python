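# Methods

## Model and assumptions

The substrate is a signed directed graph: an edge `(a, s, b)`,
`s ∈ {+1, −1}`, asserts that perturbing `a` moves `b` in direction `s`
(activation) or `−s` (inhibition). The analysis assumes signs compose
multiplicatively along directed paths and ignores edge confidence,
kinetics and magnitude — the experimental input is likewise reduced to
the ternary direction of change per gene. These are strong assumptions;
they buy a method that needs nothing beyond a curated sign for each
interaction.

The computational causal graph doubles every entity into two copies so
that path-sign bookkeeping becomes reachability: copy `(e, q)` is
reachable from `(h, p)` within δ arcs iff some walk of ≤ δ edges from
`h` to `e` has sign product `p·q`. Contradictory curation (the same
ordered pair asserted with both signs) is retained, not rejected: both
arcs exist and the target simply becomes ambiguous downstream of the
source, which is the honest summary of conflicting evidence. Self-loops
are kept for the same reason.

## Prediction, scoring, ambiguity

`predict_regulation` is a breadth-first search from the hypothesis copy
with depth cutoff δ (edges, inclusive). An entity with both copies
reachable within δ is *ambiguous* (prediction 0) — reachability of both
signs anywhere within the horizon, not merely at equal shortest
distance. This rule is monotone in δ (a signed prediction can only
persist or degrade to ambiguity as the horizon grows, never flip),
which the distance-tie rule would not be. The hypothesis node predicts
itself at distance 0: a regulator's own transcript change is legitimate
evidence, and a short negative feedback loop can legitimately make the
regulator ambiguous for itself.

Scoring counts only genes present in both the prediction map and the
mapped signature: +1 to `correct` when signs agree, +1 to `incorrect`
when they contradict, ambiguous genes counted separately and
contributing zero, unchanged (0-observed) and unreached genes ignored.
`score = correct − incorrect` is antisymmetric under flipping the
hypothesis sign, a property the test suite checks exhaustively.

Genes observed as 0 are *retained* in the mapped signature: they cannot
move the score, but they dilute the significance null exactly as an
unchanged measured gene should.

## Significance

The score null holds each hypothesis's predictions fixed and reassigns
the observed multiset of {+1, 0, −1} values uniformly at random across
the mapped genes. The exact tail `P(score ≥ observed)` is a sum over
3×3 (prediction class × observation class) contingency tables with
fixed margins: a table with `u±` observations of each sign in the
predicted-up bin and `v±` in the predicted-down bin has score
`(u+ − u−) − (v+ − v−)` and multiplicity given by products of
binomials; rational arithmetic (`fractions.Fraction`) makes the result
exact. The enumeration is O(min(n,q)⁴); when the margin-bounded table
count exceeds 10⁷ the `auto` mode falls back to seeded Monte Carlo with
the add-one estimator `(k+1)/(n_perm+1)` (default n_perm = 10 000).
Monte Carlo sub-seeds are derived per hypothesis from a SHA-256 hash of
(seed, node, sign), so the ranking table is identical under any
evaluation order or concurrency schedule.

The enrichment p-value is the one-sided hypergeometric tail for the
overlap between predicted (any value, ambiguous included) and
observed-nonzero genes. Both margins are counted within the mapped
signature, and the universe defaults to the mapped signature size
(callers may pass a larger universe). Counting the predicted margin
within the signature keeps the tie-break meaningful: of two hypotheses
with identical scores, the one whose predictions are not also scattered
over unmeasured genes is preferred. Neither p-value is corrected for
multiple testing across hypotheses; correction is the caller's job.

Ranking sorts by score (descending), then p-value, enrichment p, node
name, and sign (+1 before −1) — a fully deterministic, diff-able order
— and assigns ranks 1..2N.

## SCAN

`run_scan` ranks all hypotheses at each δ of a strictly increasing
sequence (defaults: δ = 1, 2, 3; top_n = 100) and intersects the top
lists. The cut is score-based: every hypothesis scoring at least the
score at rank `top_n` is in the list, so boundary ties cannot make
consensus membership depend on lexicographic order. The atomic unit is
the signed hypothesis — `X up` and `X down` are distinct candidates.
Consensus membership depends only on scores, so SCAN skips p-value
computation by default (`significance="none"` sets all p-values to 1;
any other mode may be requested). The consensus is ordered by rank at
the largest δ. The intersection is anti-monotone in the δ-sequence and
monotone in top_n; both properties are asserted in the suite.

## Reconstruction

For a hypothesis and δ, the *explained* nodes are the measured genes
whose nonzero prediction equals their nonzero observation. For each,
**all shortest sign-consistent CCG paths** from the hypothesis copy to
the matching node copy are retained and projected back to signed edges
(`(a,p)→(b,q)` came from `(a, p·q, b)`). All-shortest (rather than one
arbitrary path, or all bounded paths) keeps the output deterministic
and size-bounded while preserving redundant parallel branches.
Path nodes that are neither the hypothesis nor explained are
intermediate ("grey") nodes; annotations come from the signature with
default 0, covering every output node. An empty explained set produces
a hypothesis-only network with zero edges — a logged notice, not an
error. Output SIF lines and annotation rows are sorted
lexicographically; files carry no timestamps, so reruns are
byte-identical.

## Synthetic data generator

`fixtures` generates the study conditions for every test: uniform
random digraphs over distinct ordered node pairs (no self-loops at
generation; self-loop behaviour is tested on hand-built graphs) with
independent edge signs, and signatures obtained by propagating a
planted hypothesis at a generation δ, sampling a coverage fraction of
the predicted entities, and corrupting each value with probability
`noise` (half the corruptions flip the sign, half zero the value, so
both the mismatch and the dropout paths of the scorer are exercised).
All randomness is integer-only from `random.Random(seed)`, so fixtures
are bit-identical across platforms. Defaults: 30 nodes, 90 edges
(mean out-degree 3, enough for multi-step cascades), activation
fraction 0.75 (curated signalling networks skew activating), δ = 2,
noise 0, coverage 1.

What the generator does *not* emulate: the degree distributions, motif
content and hub structure of curated interactomes, correlated
measurement noise, or identifier mismatch between platforms. Passing
recovery tests therefore demonstrate correctness of the machinery under
the stated random model, not expected performance on real curated
networks.

The walk-enumeration oracle recomputes predictions by exhaustively
enumerating every walk of length ≤ δ over the substrate edges and
classifying entities by the set of achievable sign products. It is
deliberately brute-force and guarded to ≤ 12 entities and δ ≤ 4.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic instances
sized so every oracle stays exhaustive: 200 random graphs of ≤ 12 nodes
for propagation equivalence, 100 instances of ≤ 8 signature genes
(≤ 8! assignments enumerated) for the exact null, 50 planted-regulator
fixtures of 20–50 nodes (mean out-degree 3, generation δ = 2) for
recovery, with the planted node chosen as the maximum-out-degree node
so the planted cascade is non-trivial. Recovery is measured noise-free
(rank 1, with ties accepted only from hypotheses whose predictions on
the mapped signature are identical — scoring cannot distinguish such
hypotheses even in principle) and at noise 0.3 (top-5 membership).
SCAN recovery uses top_n = 5 over δ = 1..2, matching the top-5
criterion used for the noisy case.

Exact p-values are rational until the final float conversion; the Monte
Carlo estimator is compared against the exact tail within three
binomial standard errors. Ties everywhere are broken by fixed
lexicographic chains; no step of the pipeline reads wall-clock time or
iteration order of unordered containers.

## Known limitations

- Path-sign composition ignores synergy, saturation and magnitude;
  a single curated sign per edge is taken at face value.
- No identifier harmonisation: signature genes must use the network's
  vocabulary verbatim, or they are dropped (with a coverage warning).
- The permutation null conditions on the observed value multiset and
  the prediction margins; it does not model correlation between genes
  regulated by a shared upstream mechanism.
- SCAN's false-positive suppression is structural (multi-horizon
  agreement); no empirical FDR is attached to consensus membership.
- All-shortest-path reconstruction can omit longer redundant routes
  that a biologist might consider part of the same cascade.
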