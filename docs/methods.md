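# Methods

This note documents the models and algorithmic choices behind `rnaepm`:
what is computed, under which assumptions, and where the design was
genuinely open.

## Energy model and ensemble quantities

The matcher needs, per sequence, base-pair probabilities, stacked-pair
probabilities, and the joint probabilities that an element (an unpaired
position or a base pair) occurs *in the loop closed by* a specific pair
— i.e. jointly with its innermost enclosing ("parent") pair, the
exterior loop ψ = (0, n+1) closing everything unenclosed.

These are computed under a lightweight, loop-decomposed energy model
rather than full nearest-neighbour thermodynamics:

| parameter | default | meaning |
|---|---|---|
| pair energies | AU/UA −2, CG/GC −3, GU/UG −1 kcal/mol | per base pair |
| `stack_bonus` | −1 kcal/mol | per directly stacked pair |
| hairpin/interior/multiloop constants | 0 kcal/mol | per loop occurrence |
| `RT` | 0.6163 kcal/mol | Boltzmann scale (≈ 37 °C) |
| `min_hairpin` | 3 | minimum unpaired bases in a hairpin |
| `mode` | `weighted` | `uniform` gives every structure weight 1 |

The model exercises the same hairpin/interior(+stack)/multiloop
decomposition a full energy model would — which is what the algorithm's
structure depends on — while remaining exactly verifiable by exhaustive
enumeration at small n.  The open chain has energy 0 and weight 1, and
is included in the partition function.  `uniform` mode turns every
probability into a structure-counting ratio, which gives a second,
combinatorial oracle (a Nussinov-style counting DP cross-checks the
enumerator).

**Inside pass.**  `Qb(i,j)` is the pair-closed partition function;
region content is decomposed into `M` (≥ 1 outermost helix), `M1`
(exactly one helix) and the auxiliary `M2` (≥ 2 helices).  `M2` is what
prices the multiloop closing constant correctly and later lets loop
content be split around a distinguished element.  `M2` is built
incrementally (`M2(i,j) = M2(i,j−1) + Σ_h M(i,h−1)·Qb(h,j)`) rather than
as `M − M1`, avoiding cancellation.

**Outside pass.**  The outside weight `O(i,j)` sums an exterior-loop
term and parent terms (interior/stack and multiloop).  The naive parent
sum is quartic; expanding the multiloop factor
`(1+M_left)(1+M_right) − 1` into four separable sums and maintaining
suffix/prefix cumulatives of `O·w_pair` (plus one incrementally updated
mixed matrix) over decreasing spans keeps the pass cubic-time,
quadratic-space.  All Def-style joint probabilities then follow in
closed form from `O`, `Qb`, `M`, `M1`:
`Pr[(i′,j′) ∈ loop(i,j)] = O(i,j)·w_pair(i,j)·C·Qb(i′,j′)/Z` with `C`
the interior-or-multiloop content factor, and analogously for unpaired
positions (hairpin, interior and ≥2-helix multiloop cases).

**Numerics.**  Partition-function magnitudes grow like exp(c·n); when
the worst-case exponent approaches the float64 range (n ≳ 180 with the
default energies) the inside/outside arrays switch to 80-bit extended
precision (`numpy.longdouble`, range ~1e4932) instead of rescaling the
recursions — simpler, and exact to well beyond the 1e-9 oracle
tolerance at the sizes this package targets (n ≤ ~3000).  Probabilities
are returned as float64.

**Sparse storage.**  In-loop maps are kept per parent pair, entries
below `drop_tol` (default 1e-12) dropped; ψ entries are always stored so
the conservation identities (summing over parents recovers the
marginals) are assertable.  The pipeline passes `parent_min_bpp = θ1`
and `drop_tol = min(θ2, θ3)`: elements below these can never qualify
downstream, and this keeps memory proportional to what the sparsified
matcher can actually touch.  Tests that assert conservation use the full
maps (defaults).

## Matching DP

For every pair of significant base pairs ((i,j), (k,l)) — significance
is `bpp ≥ θ1`, inclusive, with a per-position cap (default 50, active
only at θ1 = 0) guarding the fully permissive setting — contracted
matrices are filled over candidate positions only:

* `L(j′,l′)`: best inner EPM connected to the left end (empty or
  containing i+1~k+1) ending at j′~l′; cases: forbidden / sequence match
  (needs θ2 on both in-loop unpaired probabilities) / structure match
  (needs θ3 on both in-loop pair probabilities, θ1 via the nested D).
* `G_A`, `G_AB`: gap states — skip positions of A first, then of B, so
  each loop match admits at most one gap per sequence without
  ambiguity.  `G_AB` is represented as a running row maximum (`glrun`)
  over `max(G_A, L)`, which resolves lookups at skipped (non-candidate)
  indices exactly.
* `LR(j′,l′)`: two sub-EPMs separated by a gap, the second ending at
  j′~l′; finite entries are reachable only through the gap states (the
  gapless origin (i,k) is excluded from the transient `H = max(G_A,
  G_AB)`), which enforces a real gap.
* `D(ij,kl) = τ(i,j,k,l) + max(best L entry or 0, LR(j−1,l−1),
  stacking case)`, computed in increasing span order.
* `F(j′,l′)`: best significant EPM of the prefixes ending at j′~l′;
  first case 0 (local-alignment semantics), and external elements skip
  the θ2/θ3 checks.

Initialization follows the empty-subsequence convention: first entry
`L = G_A = G_AB = 0`, `LR = −∞`; first row `G_AB = 0`, others −∞; first
column `G_A = 0`, others −∞.

**Stacking applicability.**  τ's α3 term rewards stacked pair matches;
it is added exactly when the directly nested base-pair match
(i+1,j−1)~(k+1,l−1) is part of the EPM, implemented as a dedicated case
in D (the nested match then necessarily fills the whole loop).  The
oracle scorer applies the identical rule, so both routes price EPMs
identically.

**−∞.**  Forbidden scores use a finite sentinel (−1e18) with saturating
addition, avoiding NaN propagation in float arithmetic.

**Tie-breaking** is by fixed case order (sequence before structure
match, L before LR, stacking case last), which fixes which co-optimal
trace is found first but never the scores.

## Traceback

The suboptimal traceback enumerates every significant EPM with score in
`[max(min_epm_score, opt − max_score_diff), opt]`.  It proceeds in two
stages: an F-level backward enumeration fixes the external skeleton
(sequence matches plus outermost base-pair matches, each carrying its
optimal D value as a placeholder and an upper-bound prune), then pending
D matrices are expanded into their local traces left to right, sharing
the remaining slack — so a D matrix's traceback completes before its
enclosed D matrices are entered.  Duplicate derivations of the same EPM
(e.g. the stacking case versus the generic nested case) are canonicalized
and deduplicated keeping the highest (true) score; every emitted EPM is
re-validated independently — definition conditions, Def-5 significance
straight from the ensembles, and score recomputed from (M, S) — and any
discrepancy raises instead of being silently returned.

Tracebacks start only at cells (j′,l′) with `A[j′+1] ≠ B[l′+1]` (or at a
sequence boundary): a strict EPM ending where the next diagonal match
exists is extensible, hence non-maximal, and the same forward argument
restricts relaxed starts.

**Maximality.**  A strict EPM is maximal iff no one-step extension —
an adjacent exact sequence match, or an attachable base-pair match with
its endpoint matches — yields a valid significant EPM that preserves all
existing matches' parents.  One step suffices: the elements of any
strictly larger comparable EPM can be added outermost-first without
re-parenting, so the first added element already witnesses
non-maximality.  Relaxed EPMs pass the same exact-extension test first;
survivors are then compared under the score-inclusion order (a
higher-scoring comparable EPM discards a lower-scoring one; equal scores
keep both).  This second filter is applied across the whole traced set
rather than per D matrix — a superset of the per-matrix comparison that
removes at least as many non-maximal EPMs; the rare survivors whose
dominators lie outside the traced band are tolerated and handled by
chaining.

The heuristic traceback reports, per eligible end match, one optimal EPM
(the first found under the deterministic case order), considering
positive-score EPMs only.  Output order is score-descending, then
leftmost end; `max_epms` caps the list after filtering.

## Chaining

Two EPMs are compatible iff their merged matches form a non-crossing
matching with disjoint positions and the merged structures stay
non-crossing.  For connected EPMs every internal gap is bridged by a
base pair, from which it follows that any compatible set decomposes into
strictly sequential blocks and blocks nested inside one another's
*holes* (the gap rectangles between consecutive matches).  The chaining
therefore scores each EPM as its own score plus the recursively optimal
chain of each hole (memoized per distinct hole rectangle), and combines
top-level blocks by classical sequential chaining — exhaustive subset
search confirms optimality on small instances.  Ties prefer fewer EPMs,
then the earliest candidates in canonical order.  When more than
`10·(n+m)` EPMs arrive, a pre-filter keeps only the best EPM per end
position pair, maintaining the intended complexity regime.  Coverage is
Σ|M| over chained EPMs divided by the shorter sequence length.

## Synthetic data and oracles

The generators define the test conditions: uniformly random sequences of
given GC content; an implanted hairpin motif (default 6-bp stem, 4-nt
loop — a stable, unambiguous fold at 80-nt scale, matching the motif
sizes the matcher is meant for) identical in both sequences with known
ground-truth matches.  The oracles restate the definitions by exhaustive
search: every non-crossing structure (for ensemble probabilities), every
valid EPM grown unit-by-unit in spanning-tree order (completeness
argument as above, capped at length 12), and every compatible EPM
subset.  They share nothing with the production path except the pure
scoring functions σ/τ and the validity checker, which is itself under
test from printed examples.

What passing these tests shows — and does not.  The synthetic sequences
are i.i.d. random with one implanted motif; real homologous RNAs have
correlated backgrounds, partial motif conservation, and indels inside
motifs, so recovery rates here bound the idealized, not the field,
behaviour.  The lightweight energy model preserves ensemble *structure*
but not thermodynamic accuracy; probabilities differ numerically from a
full nearest-neighbour model, so thresholds tuned here are not
transferable verbatim.

## Problem sizes

The verification suite uses exhaustive oracles at n ≤ 12–14 (where
enumeration is exact and fast), 100-pair corpora for the
set-equality checks, three seeded pairs per size at n = 100/200/400 for
the sparsity-scaling measurement, and 50 trials of 80-nt pairs for motif
recovery — sizes at which every check runs in seconds to a minute while
still exercising the extended-precision large-n path.

## Known limitations

* No full Turner thermodynamics, dangles, or coaxial stacking; no
  pseudoknots.
* The heuristic traceback's tie choice among equal-scoring EPMs is
  deterministic but arbitrary; scores, not witnesses, are its contract.
* Negative-score relaxed EPMs are invisible to the heuristic traceback
  (F's local-alignment floor); they are searchable with the suboptimal
  traceback and a negative `min_epm_score`.
* The anchor-file dialect (`#A1..#Aw` rows) is round-trip tested
  internally, not promised bit-compatible with any particular external
  aligner release.
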