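"""Ma–Sun branching for the Neighbor String problem.

NEIGHBOR STRING generalizes CENTER STRING with a per-string budget d_i:
find ŝ with d_H(ŝ, s_i) <= d_i for every i.  The algorithm anchors on s_1:
if s_1 itself satisfies all budgets it is returned; otherwise a violating
string s_j is picked, D = D_{s_1,s_j}, and every admissible assignment t of
the center on D (d_H(t, s_1|D) <= d_1 and d_H(t, s_j|D) <= d_j) is tried,
recursing on the remaining region with budgets e_i = d_i - d_H(t, s_i|D).

Because on the remaining region s_1 and s_j coincide, the center's
mismatches there are bounded by s_j's leftover budget as well, so e_1 is
tightened to min(d_1 - d_H(t, s_1|D), d_j - d_H(t, s_j|D)); the published
bound subtracts one more from the second term (it keeps at least one
solution, not all), available via ``strict_e1=True``.

Preprocessing hints: cascade rules are matched against every position
assignment of t, their solved strings overlaid (conflicts discard t, the
overlay's decided positions shrink the recursive instance), and pair-budget
tuples discard any t that overspends some x_ij.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .core import BitString, Instance, InputError, mask_from_positions
from .gramm import _check_hints
from .reduction import CascadeRule, PairBudget, ReductionResult, _bits


@dataclass(frozen=True)
class NeighborStringInstance:
    """Strings plus per-string budgets; origin_map sends working positions
    back to the coordinates the strings were cut from (identity default)."""

    instance: Instance
    budgets: tuple[int, ...]
    origin_map: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.budgets) != self.instance.k:
            raise InputError("budgets length must equal k")
        if self.origin_map is not None and len(self.origin_map) != self.instance.length:
            raise InputError("origin_map length must equal L")


@dataclass(frozen=True)
class MaSunResult:
    center: BitString | None
    branch_strings: int     # number of candidate strings t tested

    @property
    def solvable(self) -> bool:
        return self.center is not None


class _Search:
    def __init__(self, masks, L, rules, tuples, strict_e1):
        self.masks = masks
        self.L = L
        self.rules: dict[tuple[int, int], CascadeRule] = rules
        self.tuples: list[PairBudget] = tuples
        self.strict_e1 = strict_e1
        self.branches = 0

    def run(self, cand: int, region: int, budgets: list[int]) -> int | None:
        if any(b < 0 for b in budgets):
            return None
        return self._rec(cand, region, budgets, budgets[0])

    def _rec(self, cand: int, region: int, budgets: list[int], cap: int) -> int | None:
        """``budgets`` are true remaining budgets (d_i minus committed
        mismatches); ``cap`` is the tightened allowance for *further*
        mismatches against s_1 in the free region.  The s_1-completion of
        the current node is always tested against the true budgets before
        the cap prunes branching, so a tightening that keeps only some
        solution never discards a node whose completion already works."""
        masks = self.masks
        m0 = masks[0]
        if any(b < 0 for b in budgets):
            return None
        # is s_1 (on the free region) already a valid completion?
        viol, viol_h = -1, -1
        for i, m in enumerate(masks[1:], start=1):
            h = ((m0 ^ m) & region).bit_count()
            if h > budgets[i] and h > viol_h:
                viol, viol_h = i, h
        if viol < 0:
            return cand | (m0 & region)
        D = (m0 ^ masks[viol]) & region
        dlist = sorted(_bits(D))
        nD = len(dlist)
        ej = budgets[viol]
        lo = max(0, nD - ej)
        hi = min(budgets[0], cap, nD)
        for nflips in range(lo, hi + 1):
            for flips in combinations(dlist, nflips):
                self.branches += 1
                fmask = mask_from_positions(flips)
                t_bits = (m0 & D) ^ fmask
                overlay = self._consistent(cand, region, D, t_bits)
                if overlay is None:
                    continue
                new_budgets = [
                    b - ((t_bits ^ masks[i]) & D).bit_count()
                    for i, b in enumerate(budgets)
                ]
                second = ej - (nD - nflips) - (1 if self.strict_e1 else 0)
                new_cap = min(cap - nflips, second)
                new_cand = cand | t_bits
                new_region = region & ~D
                ov_decided, ov_ones = overlay
                fix = ov_decided & new_region
                if fix:
                    new_cand |= ov_ones & fix
                    new_region &= ~fix
                    for i, m in enumerate(masks):
                        spent = ((ov_ones ^ m) & fix).bit_count()
                        new_budgets[i] -= spent
                        if i == 0:
                            new_cap -= spent
                if any(b < 0 for b in new_budgets):
                    continue
                res = self._rec(new_cand, new_region, new_budgets, new_cap)
                if res is not None:
                    return res
        return None

    def _consistent(self, cand: int, region: int, D: int, t_bits: int):
        """Check t against cascade rules and pair-budget tuples.

        Returns an overlay (decided, ones) of all matching rules' solved
        positions, or None when t cannot lead to a valid center.
        """
        ov_decided = ov_ones = 0
        if self.rules:
            for p in _bits(D):
                v = t_bits >> p & 1
                rule = self.rules.get((p, v))
                if rule is None:
                    continue
                solved = rule.solved
                conflict = (ov_decided & solved.decided) & (ov_ones ^ solved.ones)
                if conflict:
                    return None
                ov_decided |= solved.decided
                ov_ones |= solved.ones
            if ov_decided:
                # consistency with the assignment on D and with positions
                # committed earlier in the recursion
                if (ov_decided & D) & (ov_ones ^ t_bits):
                    return None
                committed = ~region & ((1 << self.L) - 1) & ~D
                if (ov_decided & committed) & (ov_ones ^ cand):
                    return None
        for t in self.tuples:
            overspent = ((t_bits ^ self.masks[t.i]) & D & t.E).bit_count()
            if overspent > t.x:
                return None
        return ov_decided, ov_ones


def neighbor_solve(
    ns: NeighborStringInstance,
    rules: dict[tuple[int, int], CascadeRule] | None = None,
    tuples: list[PairBudget] | None = None,
    strict_e1: bool = False,
) -> MaSunResult:
    """Solve a Neighbor String instance exactly.

    Negative budgets make the instance trivially unsolvable (returns None
    center, not an error).
    """
    inst = ns.instance
    search = _Search(list(inst.masks), inst.length, rules or {}, tuples or [], strict_e1)
    full = (1 << inst.length) - 1
    found = search.run(0, full, list(ns.budgets))
    center = BitString(found, inst.length) if found is not None else None
    return MaSunResult(center, search.branches)


def center_via_masun(
    inst: Instance,
    d: int,
    hints: ReductionResult | None = None,
    strict_e1: bool = False,
) -> MaSunResult:
    """Center string via the Neighbor String solver (d_i = d special case).

    With hints, solved positions are committed up front and each budget is
    lowered by the mismatches already charged to that string.
    """
    if d < 0:
        raise InputError("d must be nonnegative")
    if hints is None:
        ns = NeighborStringInstance(inst, (d,) * inst.k)
        return neighbor_solve(ns, strict_e1=strict_e1)

    _check_hints(inst, d, hints)
    if hints.status == "rejected":
        return MaSunResult(None, 0)
    red = hints.reduced
    partial = hints.partial
    budgets = [d - off for off in hints.offsets()]
    rules = {(r.p, r.v): r for r in hints.rules}
    search = _Search(list(red.masks), red.length, rules, hints.tuples, strict_e1)
    region = partial.undecided_mask()
    found = search.run(partial.ones, region, budgets)
    if found is None:
        return MaSunResult(None, search.branches)
    bits = 0
    for p, v in hints.clean_values.items():
        if v:
            bits |= 1 << p
    for q, p in enumerate(hints.column_map):
        if found >> q & 1:
            bits |= 1 << p
    return MaSunResult(BitString(bits, inst.length), search.branches)
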