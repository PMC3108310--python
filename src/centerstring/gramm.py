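"""Depth-bounded search tree for the center string problem (Gramm et al.).

Start from s_1 and repair it: while some input string is farther than d
from the candidate, branch over d + 1 of their differing positions, moving
the candidate toward the violating string; no position is modified twice on
a root-to-leaf path and at most d positions are modified in total.  Among
any d + 1 differing positions at least one must agree with every center
(a candidate at distance > d differs from a center in at most d of them),
so some branch makes an exact move and the search is complete.

With preprocessing hints the tree starts from s_1 overlaid with the
permanent positions, branches over only d_i + 1 positions (d_i = d minus
the mismatches already committed on permanent positions against the
violating string s_i), refuses to branch over positions whose pair-budget
tuple is exhausted, and applies cascade rules eagerly when a branch commits
a rule's trigger assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BitString, Instance, InputError
from .reduction import ReductionResult, _bits


@dataclass(frozen=True)
class GrammResult:
    center: BitString | None
    nodes_expanded: int

    @property
    def solvable(self) -> bool:
        return self.center is not None


def _check_hints(inst: Instance, d: int, hints: ReductionResult) -> None:
    if hints.original is not inst and hints.original != inst:
        raise InputError("hints were computed for a different instance")
    if hints.d != d:
        raise InputError(f"hints were computed for d={hints.d}, not d={d}")


class _Search:
    def __init__(self, masks, L, d, perm_mask, perm_ones, offsets, tuples, rules):
        self.masks = masks
        self.L = L
        self.d = d
        self.perm_mask = perm_mask
        self.perm_ones = perm_ones
        self.offsets = offsets          # per-string committed permanent mismatches
        self.tuples = tuples            # list of (i, j, E mask, x)
        self.rules = rules              # dict (p, v) -> solved PartialCenter
        self.nodes = 0

    def run(self, root: int, depth: int) -> int | None:
        if depth < 0:
            return None
        return self._rec(root, depth, 0)

    def _rec(self, s: int, depth: int, changed: int) -> int | None:
        self.nodes += 1
        d = self.d
        viol = -1
        for idx, m in enumerate(self.masks):
            h = (s ^ m).bit_count()
            if h > d + depth:
                return None            # distance cannot fall fast enough
            if h > d and viol < 0:
                viol = idx
        if viol < 0:
            return s
        if depth == 0:
            return None
        vm = self.masks[viol]
        budget = d - self.offsets[viol]
        diff = (s ^ vm) & ~self.perm_mask & ~changed
        chosen = []
        for p in _bits(diff):
            if self._interdicted(s, changed, p):
                continue
            chosen.append(p)
            if len(chosen) == budget + 1:
                break
        for p in chosen:
            v = vm >> p & 1
            child = s ^ (1 << p)
            child_changed = changed | (1 << p)
            child_depth = depth - 1
            rule = self.rules.get((p, v))
            ok = True
            if rule is not None:
                solved = rule.solved
                fix = solved.decided & ~self.perm_mask & ~(1 << p)
                for q in _bits(fix):
                    want = solved.ones >> q & 1
                    if (child >> q & 1) == want:
                        continue
                    if child_changed >> q & 1:
                        ok = False     # conflicts with an earlier commitment
                        break
                    child ^= 1 << q
                    child_changed |= 1 << q
                    child_depth -= 1
                    if child_depth < 0:
                        ok = False
                        break
            if not ok:
                continue
            res = self._rec(child, child_depth, child_changed)
            if res is not None:
                return res
        return None

    def _interdicted(self, s: int, changed: int, p: int) -> bool:
        """A position may not be branched over when some pair budget is
        already spent by committed mismatches and branching would add one.

        Only committed (changed or permanent) positions count against the
        budget: uncommitted positions still carry s_1's provisional values
        and may be repaired later.
        """
        bit = 1 << p
        committed = changed | self.perm_mask
        for (i, _j, E, x) in self.tuples:
            if not E & bit:
                continue
            mi = self.masks[i]
            if (s ^ mi) & bit:
                continue               # s already disagrees with s_i at p
            spent = ((s ^ mi) & E & committed).bit_count()
            if spent >= x:
                return True
        return False


def gramm_solve(inst: Instance, d: int, hints: ReductionResult | None = None) -> GrammResult:
    """Exact center search; returns a center at threshold d or None.

    ``hints`` must come from :func:`centerstring.reduction.preprocess` on
    the same instance and d.
    """
    if d < 0:
        raise InputError("d must be nonnegative")
    if hints is None:
        search = _Search(
            list(inst.masks), inst.length, d, 0, 0, [0] * inst.k, [], {}
        )
        found = search.run(inst.masks[0], d)
        center = BitString(found, inst.length) if found is not None else None
        return GrammResult(center, search.nodes)

    _check_hints(inst, d, hints)
    if hints.status == "rejected":
        return GrammResult(None, 0)
    red = hints.reduced
    partial = hints.partial
    offsets = hints.offsets()
    tuples = [(t.i, t.j, t.E, t.x) for t in hints.tuples]
    rules = {(r.p, r.v): r for r in hints.rules}
    search = _Search(
        list(red.masks), red.length, d,
        partial.decided, partial.ones, offsets, tuples, rules,
    )
    root = (red.masks[0] & ~partial.decided) | partial.ones
    found = search.run(root, d - offsets[0])
    if found is None:
        return GrammResult(None, search.nodes)
    bits = 0
    for p, v in hints.clean_values.items():
        if v:
            bits |= 1 << p
    for q, p in enumerate(hints.column_map):
        if found >> q & 1:
            bits |= 1 << p
    return GrammResult(BitString(bits, inst.length), search.nodes)
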