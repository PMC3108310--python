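"""MismatchCount: ordered Hamming-ball enumeration around s_1.

After normalizing so that s_1 = 0...0, every candidate within distance d of
s_1 is a set of at most d mismatch positions.  Candidates are enumerated
level by level (level d' = number of mismatches); within a level, masks are
visited in decreasing order as binary numbers whose most significant bit is
position 0 — equivalently, mismatch-position tuples in ascending
lexicographic order.  Distances to s_2..s_k are maintained incrementally in
a ledger (O(g*k) per step, g = positions changed), giving
d_max = max_{i>=2} d_H(s, s_i) for free at each step.

When d_max > d, at least d_max - d positions of the candidate must change
before the center condition can hold, and moving one mismatch changes two
positions, so c_min = ceil((d_max - d)/2) mismatches must move.  The
enumeration therefore jumps to the state where the c_min-th mismatch from
the right moves next (every skipped mask differs from the current candidate
in fewer than 2*c_min positions), and jumps whole levels d'..c_min-1 when
c_min exceeds the current level.

Preprocessing supplies only the permanent positions: the enumeration runs
over the undecided positions and each ledger entry starts from the constant
offset d_H(ŝ|permanent, s_i|permanent).  Pair-budget tuples and cascade
rules are deliberately *not* consumed: they fix positions, which conflicts
with an enumeration that revisits and reverts positions freely.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .core import BitString, Instance, InputError
from .reduction import ReductionResult, _bits


class MismatchEnumerator:
    """Stateful enumeration of mismatch-position sets over [0, L).

    ``mask`` holds the current mismatch set (bit p = position p mismatches),
    ``level`` its size.  ``successor()`` advances one step; ``skip(c)``
    advances to the next state in which the c-th mismatch from the right
    (the c-th least significant) moves, treating the sub-enumeration over
    the c-1 lowest mismatches as completed.  Both return False when the
    enumeration is exhausted (level would exceed ``max_level``).
    """

    def __init__(self, L: int, max_level: int):
        if max_level > L:
            max_level = L
        self.L = L
        self.max_level = max_level
        self.tuple: list[int] = []      # ascending mismatch positions
        self.exhausted = max_level < 0

    def clone(self) -> "MismatchEnumerator":
        other = MismatchEnumerator(self.L, self.max_level)
        other.tuple = list(self.tuple)
        other.exhausted = self.exhausted
        return other

    @property
    def level(self) -> int:
        return len(self.tuple)

    @property
    def mask(self) -> int:
        m = 0
        for p in self.tuple:
            m |= 1 << p
        return m

    def _start_level(self, level: int) -> bool:
        if level > self.max_level or level > self.L:
            self.exhausted = True
            return False
        self.tuple = list(range(level))
        return True

    def successor(self) -> bool:
        if self.exhausted:
            return False
        q, L, m = self.tuple, self.L, len(self.tuple)
        for i in range(m - 1, -1, -1):
            if q[i] < L - m + i:
                q[i] += 1
                for j in range(i + 1, m):
                    q[j] = q[i] + (j - i)
                return True
        return self._start_level(m + 1)

    def skip(self, c: int) -> bool:
        if self.exhausted:
            return False
        if c < 1:
            raise InputError("c_min must be >= 1 when skipping")
        m = len(self.tuple)
        if c > m:
            return self._start_level(c)
        # exhaust the c-1 least significant mismatches, then step
        q, L = self.tuple, self.L
        for j in range(m - c + 1, m):
            q[j] = L - (m - j)
        return self.successor()

    def rank(self) -> int:
        """Index of the current state in the unskipped enumeration order."""
        if self.exhausted:
            return sum(comb(self.L, l) for l in range(self.max_level + 1))
        m = len(self.tuple)
        r = sum(comb(self.L, l) for l in range(m))
        prev = -1
        for i, qi in enumerate(self.tuple):
            for v in range(prev + 1, qi):
                r += comb(self.L - 1 - v, m - 1 - i)
            prev = qi
        return r


class DistanceLedger:
    """Incrementally maintained d_H(candidate, s_i) for i = 2..k."""

    def __init__(self, norm_masks: list[int], offsets: list[int]):
        # norm_masks are XORed with s_1 already; entry 0 is all-zero s_1
        self.norm_masks = norm_masks
        self.offsets = offsets
        self.dist = [off + m.bit_count() for off, m in zip(offsets, norm_masks)]

    def update(self, old_mask: int, new_mask: int) -> None:
        changed = old_mask ^ new_mask
        if not changed:
            return
        for i, m in enumerate(self.norm_masks):
            self.dist[i] += ((new_mask ^ m) & changed).bit_count() - (
                (old_mask ^ m) & changed
            ).bit_count()

    @property
    def d_max(self) -> int:
        if len(self.dist) == 1:
            return self.dist[0]         # k = 1: only s_1 itself
        return max(self.dist[1:])


@dataclass(frozen=True)
class MismatchCountResult:
    center: BitString | None
    candidates_visited: int
    candidates_skipped: int

    @property
    def solvable(self) -> bool:
        return self.center is not None


def mismatchcount_solve(
    inst: Instance,
    d: int,
    hints: ReductionResult | None = None,
    skip: bool = True,
) -> MismatchCountResult:
    """Exact center search by ordered enumeration around s_1.

    ``skip=False`` disables c_min skipping (every ball candidate is
    visited) and exists to support differential testing.
    """
    if d < 0:
        raise InputError("d must be nonnegative")
    if hints is not None:
        from .gramm import _check_hints

        _check_hints(inst, d, hints)
        if hints.status == "rejected":
            return MismatchCountResult(None, 0, 0)
        red = hints.reduced
        partial = hints.partial
        work_positions = sorted(_bits(partial.undecided_mask()))
        sub_masks = []
        for m in red.masks:
            bits = 0
            for idx, p in enumerate(work_positions):
                if m >> p & 1:
                    bits |= 1 << idx
            sub_masks.append(bits)
        offsets = hints.offsets()
        L_work = len(work_positions)
    else:
        sub_masks = list(inst.masks)
        offsets = [0] * inst.k
        work_positions = list(range(inst.length))
        L_work = inst.length

    s1 = sub_masks[0]
    norm = [m ^ s1 for m in sub_masks]
    max_level = d - offsets[0]
    if max_level < 0 or any(off > d for off in offsets):
        return MismatchCountResult(None, 0, 0)

    enum = MismatchEnumerator(L_work, max_level)
    ledger = DistanceLedger(norm, offsets)
    visited = 0
    skipped = 0
    mask = 0
    while not enum.exhausted:
        visited += 1
        d_max = ledger.d_max
        if d_max <= d:
            return MismatchCountResult(
                _inflate(mask ^ s1, work_positions, inst, hints),
                visited,
                skipped,
            )
        c_min = (d_max - d + 1) // 2
        if skip and c_min > 1:
            before = enum.rank()
            alive = enum.skip(c_min)
            skipped += enum.rank() - before - 1
        else:
            alive = enum.successor()
        if not alive:
            break
        new_mask = enum.mask
        ledger.update(mask, new_mask)
        mask = new_mask
    return MismatchCountResult(None, visited, skipped)


def _inflate(
    work_bits: int,
    work_positions: list[int],
    inst: Instance,
    hints: ReductionResult | None,
) -> BitString:
    """Map a candidate over the working positions back to full length."""
    if hints is None:
        return BitString(work_bits, inst.length)
    bits = 0
    for p, v in hints.clean_values.items():
        if v:
            bits |= 1 << p
    partial = hints.partial
    for q in _bits(partial.decided):
        if partial.ones >> q & 1:
            bits |= 1 << hints.column_map[q]
    for idx, q in enumerate(work_positions):
        if work_bits >> idx & 1:
            bits |= 1 << hints.column_map[q]
    return BitString(bits, inst.length)
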