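"""Data reduction for the center string problem.

Pipeline: remove clean columns (naive kernel), reject on the kernel bounds
(> k*d dirty columns, or a string pair farther than 2d apart), then iterate
three mutually reinforcing rules to a global fixpoint:

* **Trivial positions.**  A center at distance d sits centrally between any
  string pair at distance 2d (or 2d-1), so it must agree with both strings
  on their agreement set E_ij.  Generalized with per-string *remaining*
  budgets r_i = d - (decided mismatches vs s_i): if the undecided differing
  positions D^U of a pair number r_i + r_j, or r_i + r_j - 1 when r_i = r_j,
  every undecided p in E_ij is fixed to s_i[p]; more than r_i + r_j is a
  rejection.

* **Pair budgets (tuples).**  For a pair at distance h < 2d - 1, a center
  may disagree with *both* strings on at most x_ij = d - ceil(h/2) positions
  of E_ij (triangle inequality on D_ij).  Tuples (E_ij, x_ij) are kept in an
  array; decided mismatching positions decrement x_ij, x_ij = 0 fixes the
  rest of E_ij, x_ij < 0 rejects.

* **Cascading.**  For binary strings a pair with x_ij = 1 allows at most one
  position of E_ij to deviate.  Hypothesizing each deviation and propagating
  either uncovers a contradiction — which *forces* the position to s_i[p]
  and restarts the reduction — or yields a conditional rule
  (p, v) -> partially solved string, consumed later by the search trees.

Every permanent assignment made here is satisfied by every center at
threshold d (oracle-checked in the test suite); rejection implies no center
exists.  All coordinates below are 0-based positions of the *reduced*
(dirty-columns-only) instance; ``column_map`` maps them back.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import BitString, Instance


class Rejection(str, enum.Enum):
    KD_BOUND = "kd_bound"          # more than k*d dirty columns
    PAIR_GT_2D = "pair_gt_2d"      # some pair farther than 2d apart
    PAIR_BUDGET = "pair_budget"    # |D^U| exceeds r_i + r_j for some pair
    BUDGET = "budget"              # some remaining budget r_i < 0
    NEGATIVE_X = "negative_x"      # some tuple budget x_ij < 0
    CONFLICT = "conflict"          # a position demanded to be both 0 and 1


class PartialCenter:
    """Partially solved center: per-position value in {0, 1, undecided}.

    Stored as two masks: ``decided`` (which positions are permanent) and
    ``ones`` (their values; subset of ``decided``).
    """

    __slots__ = ("length", "decided", "ones")

    def __init__(self, length: int, decided: int = 0, ones: int = 0):
        self.length = length
        self.decided = decided
        self.ones = ones

    def copy(self) -> "PartialCenter":
        return PartialCenter(self.length, self.decided, self.ones)

    @property
    def permanent(self) -> frozenset[int]:
        return frozenset(p for p in range(self.length) if self.decided >> p & 1)

    def value(self, p: int) -> int:
        """0/1 if decided, -1 if not."""
        if self.decided >> p & 1:
            return self.ones >> p & 1
        return -1

    def set(self, p: int, v: int) -> bool:
        """Fix position p to v; returns False on a 0-vs-1 conflict."""
        bit = 1 << p
        if self.decided & bit:
            return (self.ones >> p & 1) == v
        self.decided |= bit
        if v:
            self.ones |= bit
        return True

    def undecided_mask(self) -> int:
        return ~self.decided & ((1 << self.length) - 1)

    def mismatch_count(self, mask: int) -> int:
        """Decided positions at which the partial center differs from mask."""
        return ((self.ones ^ mask) & self.decided).bit_count()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PartialCenter)
            and (self.length, self.decided, self.ones)
            == (other.length, other.decided, other.ones)
        )

    def __repr__(self) -> str:
        return "".join(
            str(v) if (v := self.value(p)) >= 0 else "." for p in range(self.length)
        ) or "<empty>"


@dataclass(frozen=True)
class PairBudget:
    """Tuple (E_ij, x_ij): undecided agreement positions of strings i and j,
    and how many of them the center may still set against both."""

    i: int
    j: int
    E: int          # bitmask over reduced positions
    x: int

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for p in range(self.E.bit_length()) if self.E >> p & 1)


@dataclass(frozen=True)
class CascadeRule:
    """If the center sets position p to v, it must extend ``solved``; the
    positions fixed by that hypothesis are ``potentially_permanent``."""

    p: int
    v: int
    solved: PartialCenter
    potentially_permanent: frozenset[int]


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def remove_clean_columns(inst: Instance) -> tuple[Instance, tuple[int, ...], dict[int, int]]:
    """Drop columns where all strings agree.

    Returns the reduced instance (dirty columns, original order), the
    injective map reduced-position -> original-position, and the shared value
    of every removed clean column (any center carries it unchanged).
    """
    masks = inst.masks
    L = inst.length
    dirty = 0
    for m in masks[1:]:
        dirty |= m ^ masks[0]
    column_map = tuple(p for p in range(L) if dirty >> p & 1)
    fixed_values = {p: masks[0] >> p & 1 for p in range(L) if not dirty >> p & 1}
    reduced_masks = []
    for m in masks:
        bits = 0
        for q, p in enumerate(column_map):
            if m >> p & 1:
                bits |= 1 << q
        reduced_masks.append(BitString(bits, len(column_map)))
    return Instance(tuple(reduced_masks), inst.labels), column_map, fixed_values


def naive_reject(inst: Instance, d: int) -> Rejection | None:
    """The naive kernel's two rejection tests; None means pass."""
    masks = inst.masks
    dirty = 0
    for m in masks[1:]:
        dirty |= m ^ masks[0]
    if dirty.bit_count() > inst.k * d:
        return Rejection.KD_BOUND
    maxpair = 0
    for i in range(inst.k):
        for j in range(i + 1, inst.k):
            h = (masks[i] ^ masks[j]).bit_count()
            if h > maxpair:
                maxpair = h
    if maxpair > 2 * d:
        return Rejection.PAIR_GT_2D
    return None


def solve_trivial_positions(
    inst: Instance, d: int, partial: PartialCenter
) -> Rejection | None:
    """Trivial-position fixing, to fixpoint.  Mutates ``partial``.

    Three sound rules:
    (a) a pair at original distance 2d or 2d-1 forces the center to agree
        with both strings on their whole agreement set E_ij;
    (b) with remaining budgets r_i = d - (decided mismatches vs s_i), a
        pair whose undecided differing positions D^U number r_i + r_j
        (or r_i + r_j - 1 when r_i = r_j) forces every undecided p in E_ij
        to s_i[p]; |D^U| > r_i + r_j rejects;
    (c) a string with r_i = 0 pins the center to s_i on every undecided
        position (its budget is spent; the degenerate case of (b)).
    """
    masks = inst.masks
    k = inst.k
    full = (1 << inst.length) - 1
    # rule (a): static Lemma-1 pairs, original distances
    for i in range(k):
        for j in range(i + 1, k):
            diff = masks[i] ^ masks[j]
            if 2 * d - 1 <= diff.bit_count() <= 2 * d:
                E = ~diff & full
                conflict = (partial.decided & E) & (partial.ones ^ masks[i])
                if conflict:
                    return Rejection.CONFLICT
                partial.decided |= E
                partial.ones |= masks[i] & E
    while True:
        r = [d - partial.mismatch_count(m) for m in masks]
        if any(ri < 0 for ri in r):
            return Rejection.BUDGET
        und = ~partial.decided & full
        progressed = False
        # rule (c)
        for i in range(k):
            if r[i] == 0 and und:
                partial.decided |= und
                partial.ones |= masks[i] & und
                progressed = True
                r = [d - partial.mismatch_count(m) for m in masks]
                if any(ri < 0 for ri in r):
                    return Rejection.BUDGET
                und = 0
        # rule (b)
        for i in range(k):
            for j in range(i + 1, k):
                diff = masks[i] ^ masks[j]
                du = (diff & und).bit_count()
                if du > r[i] + r[j]:
                    return Rejection.PAIR_BUDGET
                if du == r[i] + r[j] or (r[i] == r[j] and du == r[i] + r[j] - 1):
                    EU = ~diff & und & full
                    if EU:
                        partial.decided |= EU
                        partial.ones |= masks[i] & EU
                        progressed = True
                        # budgets unchanged (fixed positions match both
                        # strings of the pair) but other pairs' D^U/E^U
                        # shrink: rescan from the top
                        r = [d - partial.mismatch_count(m) for m in masks]
                        if any(ri < 0 for ri in r):
                            return Rejection.BUDGET
                        und = ~partial.decided & full
        if not progressed:
            return None


def compute_pair_budgets(
    inst: Instance, d: int, partial: PartialCenter
) -> tuple[list[PairBudget], Rejection | None]:
    """Tuples (E_ij, x_ij) for every pair with d_H(s_i, s_j) < 2d - 1.

    x_ij = d - ceil(h/2) - (decided positions of E_ij mismatching the
    center); the pair's undecided agreement positions form E.  Pairs at
    distance >= 2d - 1 belong to the trivial-position rule and are excluded.
    """
    masks = inst.masks
    full = (1 << inst.length) - 1
    und = ~partial.decided & full
    tuples: list[PairBudget] = []
    for i in range(inst.k):
        for j in range(i + 1, inst.k):
            diff = masks[i] ^ masks[j]
            h = diff.bit_count()
            if h >= 2 * d - 1:
                continue
            E_all = ~diff & full
            spent = ((partial.ones ^ masks[i]) & partial.decided & E_all).bit_count()
            x = d - (h + 1) // 2 - spent
            if x < 0:
                return [], Rejection.NEGATIVE_X
            E_und = E_all & und
            if E_und:
                tuples.append(PairBudget(i, j, E_und, x))
    return tuples, None


def reduce_tuples(
    tuples: list[PairBudget], inst: Instance, partial: PartialCenter
) -> tuple[list[PairBudget], Rejection | None]:
    """Remove decided positions from every tuple, decrementing x_ij per
    decided mismatch; x_ij = 0 fixes the rest of E_ij, x_ij < 0 rejects.

    Mutates ``partial``; returns the surviving tuples.
    """
    masks = inst.masks
    work = list(tuples)
    while True:
        progressed = False
        out: list[PairBudget] = []
        for t in work:
            E, x = t.E, t.x
            newly = E & partial.decided
            if newly:
                x -= ((partial.ones ^ masks[t.i]) & newly).bit_count()
                E &= ~newly
            if x < 0:
                return [], Rejection.NEGATIVE_X
            if not E:
                continue
            if x == 0:
                for p in _bits(E):
                    if not partial.set(p, masks[t.i] >> p & 1):
                        return [], Rejection.CONFLICT
                progressed = True
                continue
            out.append(PairBudget(t.i, t.j, E, x))
        work = out
        if not progressed:
            return work, None


def _inner_reduce(
    inst: Instance, d: int, partial: PartialCenter
) -> tuple[list[PairBudget], Rejection | None]:
    """solve_trivial_positions -> compute_pair_budgets -> reduce_tuples,
    iterated until the permanent set stops growing."""
    while True:
        before = partial.decided
        rej = solve_trivial_positions(inst, d, partial)
        if rej is not None:
            return [], rej
        tuples, rej = compute_pair_budgets(inst, d, partial)
        if rej is not None:
            return [], rej
        tuples, rej = reduce_tuples(tuples, inst, partial)
        if rej is not None:
            return [], rej
        if partial.decided == before:
            return tuples, None


def cascade(
    inst: Instance, d: int, partial: PartialCenter, tuples: list[PairBudget]
) -> tuple[list[CascadeRule], bool, Rejection | None]:
    """Hypothesis propagation on pairs with x_ij = 1.

    For each undecided p in such a pair's E_ij, hypothesize the center
    deviates there (binary: at most one deviation is possible) and propagate
    on a scratch copy.  A contradiction forces ŝ[p] = s_i[p] in the real
    partial — the caller must then restart the whole reduction (returned
    flag True).  Otherwise a CascadeRule is recorded.
    """
    masks = inst.masks
    rules: list[CascadeRule] = []
    for t in tuples:
        if t.x != 1:
            continue
        for p in _bits(t.E):
            if partial.decided >> p & 1:
                continue
            si_bit = masks[t.i] >> p & 1
            v = 1 - si_bit
            scratch = partial.copy()
            scratch.set(p, v)
            _, rej = _inner_reduce(inst, d, scratch)
            if rej is not None:
                # the hypothesis is impossible for every center: force s_i[p]
                partial.set(p, si_bit)
                return [], True, None
            new_fixed = frozenset(
                q for q in _bits(scratch.decided & ~partial.decided) if q != p
            )
            rules.append(CascadeRule(p, v, scratch, new_fixed))
    return rules, False, None


@dataclass
class ReductionResult:
    """Outcome of :func:`preprocess` at a given threshold d."""

    status: str                       # "reduced" | "rejected"
    d: int
    original: Instance
    reduced: Instance                 # dirty columns only
    column_map: tuple[int, ...]       # reduced position -> original position
    clean_values: dict[int, int]      # original position -> shared value
    partial: PartialCenter            # over reduced coordinates
    tuples: list[PairBudget] = field(default_factory=list)
    rules: list[CascadeRule] = field(default_factory=list)
    budgets: list[int] = field(default_factory=list)
    rejection_reason: Rejection | None = None

    @property
    def rejected_by(self) -> str | None:
        if self.status != "rejected":
            return None
        if self.rejection_reason in (Rejection.KD_BOUND, Rejection.PAIR_GT_2D):
            return "naive"
        return "preprocess"

    @property
    def fixed_fraction(self) -> float:
        """Fraction of reduced (dirty) positions fixed permanently."""
        if self.reduced.length == 0:
            return 1.0
        return self.partial.decided.bit_count() / self.reduced.length

    def fixed_assignments_original(self) -> dict[int, int]:
        """Every forced (position, value), in original coordinates: clean
        columns plus permanent reduced positions."""
        out = dict(self.clean_values)
        for q in _bits(self.partial.decided):
            out[self.column_map[q]] = self.partial.ones >> q & 1
        return out

    @property
    def fully_decided(self) -> bool:
        return (
            self.status == "reduced"
            and self.partial.decided == (1 << self.reduced.length) - 1
        )

    def center(self) -> BitString | None:
        """The full-length center, when preprocessing decided everything."""
        if not self.fully_decided:
            return None
        bits = 0
        for p, v in self.fixed_assignments_original().items():
            if v:
                bits |= 1 << p
        return BitString(bits, self.original.length)

    def offsets(self) -> list[int]:
        """Per-string d_H(ŝ|permanent, s_i|permanent) on the reduced
        instance (constant part of every candidate's distance)."""
        return [self.partial.mismatch_count(m) for m in self.reduced.masks]


def preprocess(inst: Instance, d: int) -> ReductionResult:
    """Full data-reduction pipeline at threshold d.

    remove_clean_columns -> naive_reject -> (trivial positions -> pair
    budgets -> tuple reduction -> cascading), restarted after every
    conflict-forced fix, until a global fixpoint.
    """
    if d < 0:
        raise ValueError("d must be nonnegative")
    reduced, column_map, clean_values = remove_clean_columns(inst)
    partial = PartialCenter(reduced.length)
    result = ReductionResult(
        status="reduced",
        d=d,
        original=inst,
        reduced=reduced,
        column_map=column_map,
        clean_values=clean_values,
        partial=partial,
    )
    rej = naive_reject(inst, d)
    if rej is not None:
        result.status = "rejected"
        result.rejection_reason = rej
        return result
    while True:
        tuples, rej = _inner_reduce(reduced, d, partial)
        if rej is not None:
            result.status = "rejected"
            result.rejection_reason = rej
            return result
        rules, restarted, rej = cascade(reduced, d, partial, tuples)
        if rej is not None:
            result.status = "rejected"
            result.rejection_reason = rej
            return result
        if not restarted:
            result.tuples = tuples
            result.rules = rules
            result.budgets = [d - partial.mismatch_count(m) for m in reduced.masks]
            return result
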