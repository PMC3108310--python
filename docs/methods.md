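# Methods

## Problem and conventions

For binary strings `s_1..s_k` of length `L` (alphabet {0,1}) and a
threshold `d`, a center string `ŝ` has `d_H(ŝ, s_i) ≤ d` for all `i`.
Positions are 0-based and half-open internally; CLI reports echo 1-based
positions.  Strings are immutable values backed by integer bitmasks (bit
`p` = symbol at position `p`), so Hamming distances are popcounts of XORs.
The alphabet is fixed to {0,1}: the intended application (center gene
clusters over presence/absence encodings) is binary, and both the
cascading argument ("at most one position of `E_ij` may deviate when
`x_ij = 1`") and MismatchCount are binary-specific.  Permuting the
positions of all strings by one permutation yields an equivalent instance;
XOR-ing all strings columnwise with `s_1` likewise preserves all pairwise
and center distances.

## Data reduction

The pipeline is `remove_clean_columns → naive_reject →
(solve_trivial_positions → compute_pair_budgets → reduce_tuples →
cascade)`, iterated to a global fixpoint.  Every *permanent* assignment it
makes is satisfied by every center at threshold `d`; rejection implies no
center exists.  Both claims are checked against the brute-force oracle in
the test suite.

**Naive kernel.**  A clean column (all strings agree) can be removed; a
solvable instance has at most `k·d` dirty columns, and no pair may be
farther than `2d` apart (triangle inequality).

**Trivial positions.**  A pair at distance `2d` forces the center to sit
centrally between the two strings, hence to agree with both on their
agreement set `E_ij`; the same holds at `2d−1`.  This static rule is
applied first, on the original pair distances.  It is then generalized
with *remaining budgets* `r_i = d − (decided mismatches vs s_i)`: writing
`D^U` for a pair's undecided differing positions, `|D^U| > r_i + r_j`
rejects, and `|D^U| = r_i + r_j` (or `r_i + r_j − 1` when `r_i = r_j`)
fixes every undecided position of `E_ij` to `s_i`'s value.  A degenerate
case is applied as its own rule: a string whose budget reaches `r_i = 0`
pins the center to `s_i` on every undecided position.  Without it, the
fixpoint can depend on the order in which pairs consume each other's
budgets (processing one triggering pair can disarm another's trigger, yet
the missed positions remain forced); with it, the final permanent set is
empirically order-independent.  A stronger general trigger
(`|D^U| ≥ r_i + r_j − 1` regardless of `r_i = r_j`) is provable but not
enabled; the restricted form is kept deliberately.

A note on the budget sign convention: budgets here *decrease* as decided
mismatches accumulate, and triggers compare against undecided differing
positions.  The equivalent formulation in which thresholds `d_i` grow with
solved mismatching positions and full pair distances are compared makes
the trigger `d_H(s_i, s_j) = d_i + d_j` unreachable (it would exceed the
`2d` pair bound), so the decreasing convention — which is also what the
tuple machinery below uses — is implemented throughout.

**Pair budgets.**  For a pair at distance `h < 2d − 1`, the center pays at
least `⌈h/2⌉` on the differing positions against the worse of the two
strings, so it may disagree with *both* strings on at most
`x_ij = d − ⌈h/2⌉` agreement positions.  Tuples `(E_ij, x_ij)` (undecided
positions only; already-decided mismatches pre-subtracted) are reduced to
fixpoint: decided positions leave `E_ij`, decrementing `x_ij` when they
mismatch; `x_ij = 0` forces the remaining `E_ij` to `s_i`'s values;
`x_ij < 0` rejects.  Pairs at distance `≥ 2d − 1` are excluded — they
belong to the trivial-position rule.

**Cascading.**  For a pair with `x_ij = 1` and binary symbols, at most one
position `p ∈ E_ij` may deviate.  Each hypothesis `ŝ[p] = 1 − s_i[p]` is
propagated on a scratch copy through the full inner reduction.  A
contradiction proves `ŝ[p] = s_i[p]` for every center; the position is
fixed for real and the whole reduction restarts (termination: the
permanent set strictly grows, at most `L'` restarts).  Otherwise the pair
`(p, v)` with its partially solved string `ŝ_{p,v}` and newly fixed
("potentially permanent") positions is recorded as a rule for the search
trees.  Hypothesis order is pairs ascending, positions ascending; rules
are recomputed from scratch after every restart (recomputation is cheap at
these sizes and keeps the rule set consistent with the final partial).

## Search tree solvers

**Gramm et al.**  Start from `s_1`; while some `s_i` is farther than `d`,
branch over the first `d + 1` eligible positions of `D_{s,s_i}`, moving
the candidate toward `s_i`; positions are modified at most once per path
and at most `d` per path.  An admissible prune abandons a node when some
distance exceeds `d + Δd` (each change reduces a distance by at most 1).
The violating string is the smallest index, branch positions the smallest
eligible indices — any choice is correct; fixed choices make runs
reproducible.  With preprocessing: the root is `s_1` overlaid with the
permanent positions, the root depth budget and per-string branching
budgets shrink by the permanent-position mismatches, and branching over
`p` is forbidden when some tuple containing `p` has its allowance already
spent.  That allowance is counted over *committed* (changed or permanent)
positions only: counting provisional `s_1`-inherited mismatches — which
the search may still repair — can exceed `x_ij` on the path toward a
center and would prune it away, so the literal candidate-wide count is
unsound and not used.  When a branch commits a rule's `(p, v)`, the rule's
solved positions are applied immediately (each application consumes depth;
conflicts with committed positions prune the branch).

**Ma–Sun / Neighbor String.**  The Neighbor String problem allows a
per-string budget `d_i`; center string is the `d_i = d` special case.  If
`s_1` completes the current region without violating any true budget it is
returned.  Otherwise the violating string maximizing the region distance
is chosen, and all assignments `t` of the center on `D = D_{s_1,s_j}`
with `d_H(t, s_1|D) ≤ e_1` and `d_H(t, s_j|D) ≤ e_j` are tried in
ascending flip count, recursing on the remaining region with budgets
`e_i − d_H(t, s_i|D)`.  Because `s_1 = s_j` on the remaining region,
`s_j`'s leftover budget also bounds the center's remaining `s_1`-region
mismatches: the allowance for *further* flips is
`min(e_1 − d_H(t,s_1|D), e_j − d_H(t,s_j|D))`.  This tightening holds for
every center and is the default.  A stricter variant with an extra `−1`
on the second term (`strict_e1=True`) is implemented for comparison; it
can be shown to discard all centers of some instances (the suite pins
`{1110101, 1000100, 1101001, 0011001, 0000100}` at `d = 3`), so it is
*not* exact and not the default; it never returns an invalid center.  The
tightened allowance caps only future flips — candidate completions are
always validity-checked against true budgets first.  With preprocessing,
solved positions are committed up front; each `t` is checked against the
cascade rules (their solved strings are overlaid; conflicts discard `t`,
and overlay-decided positions shrink the recursion) and against the
tuples (a `t` spending more than `x_ij` inside `E_ij` is discarded).

**MismatchCount.**  After XOR-normalization (`s_1 = 0…0`), candidates
within distance `d` of `s_1` are mismatch-position sets, enumerated level
by level (level = number of mismatches); within a level, masks descend as
binary numbers whose most significant bit is position 0 — equivalently,
position tuples in ascending lexicographic order.  Distances to
`s_2..s_k` are maintained incrementally (`O(g·k)` per step for `g`
changed positions).  From each failing candidate's `d_max`, at least
`d_max − d` positions must change, and relocating one mismatch changes
two positions, so `c_min = ⌈(d_max − d)/2⌉` mismatches must move: the
enumeration jumps to the state where the `c_min`-th mismatch from the
right moves next, and jumps whole levels when `c_min` exceeds the current
level.  Every skipped mask differs from the skip point in fewer than
`2·c_min` positions (asserted exhaustively in the tests), so no center is
skipped; a `skip=False` mode exists solely for the differential suite.
With preprocessing only the permanent positions and the constant
per-string offsets `d_H(ŝ|perm, s_i|perm)` are consumed; tuples and rules
are deliberately not, since an enumeration that freely revisits positions
cannot also hold them fixed.

## d_opt search

`find_opt` iterates `d` upward from
`max(⌈max-pairwise-distance/2⌉, ⌈L'/k⌉)` (`L'` = dirty columns), running
preprocessing and then the selected solver at each `d`, and records which
layer (naive kernel, preprocessing, solver) settled each call.  A
`from_zero` flag restores the literal `d = 0, 1, 2, …` loop.  The
returned center is always re-verified.  An optional per-`d` time limit
marks the result as a timeout rather than guessing.

## Synthetic data

*Planted instances* draw a uniform hidden center and flip a uniform
`e_i`-subset per string (`e_i` uniform on `0..d_plant` by default; exact
mode sets all `e_i = d_plant`, which drives pairs toward the `2d` bound —
the hard regime, since real instances with optimal centers typically
contain pairs near distance `2d`).  By construction `d_opt ≤ d_plant`; no
claim is made that `d_opt = d_plant`.  *Gene-cluster-like instances*
build blocks of `k` gene-content sets (a reference cluster whose genes
drop out, and an accessory pool whose genes intrude, independently at
`perturb_rate`), encode presence/absence over the sorted union of each
block, and concatenate blocks columnwise; symmetric set distance equals
row Hamming distance, and distances add over blocks.  The default
`perturb_rate = 0.25` used in the acceptance script yields mixtures of
rejectable and solvable instances at `d_opt − 1`; uniform random
instances (used for the equivalence corpora) are harsher than either and
have no planted structure.  What these generators do *not* emulate:
correlated gene loss across genomes, block-length distributions of real
gene-cluster pipelines, and intermediate interval candidates — passing
tests show solver correctness and reduction soundness, not biological
fidelity.  The *unsolvable* generator returns `{0^L, 1^L}` for `L > 2d`
and otherwise complements a greedily built covering code of radius
`L − d − 1` (every candidate then lies too close to some complement),
giving deterministic all-dirty instances with no center — used to verify
the enumeration closed form `Σ_{i≤d} C(L', i)`.

## Oracle and problem sizes

The oracle enumerates the Hamming ball of radius `d` around `s_1` (sound
and complete: any center lies in it) and refuses `L > 22` — a hard error,
not a truncation.  Test corpora: 1000 random instances with `k ∈ 3..6`,
`L ∈ 6..12` for the equivalence and soundness suites (every `d` from the
lower bound to `d_opt + 1`), 300 smaller instances for module-level
checks, 200 planted instances for recovery, 100+ planted-exact instances
for the Lemma-1 floor, and the full grid `L' ≤ 16`, `d ≤ 4` for the
enumeration count.  These sizes keep the whole suite and the acceptance
script in the seconds-to-a-minute range while exercising every rule path;
all corpora are seeded and reproducible.

## Known limitations

* Binary alphabet only; general-Σ variants of the search trees are out of
  scope, as are Levenshtein/weighted edit distances.
* The preprocessing fixes a subset of the truly forced positions — no
  completeness claim is made for fixing, only soundness (and the
  restricted `r_i + r_j − 1` trigger is intentionally weaker than the
  provable general form).
* The `c_min` level-jump's completeness is asserted by exhaustive
  differential testing at small sizes, not proved here.
* Hinted search trees never expand more nodes than unhinted ones on
  exhausted (unsolvable) searches; on solvable instances the visit orders
  differ and either run may terminate first, so no per-instance count
  dominance holds there.
* Wall-clock performance claims are out of scope; counters (nodes, branch
  strings, candidates) are the comparison currency.
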