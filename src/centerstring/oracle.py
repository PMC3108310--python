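"""Brute-force ground truth for solvers and reduction soundness.

Deliberately naive: every center at threshold ``d`` lies in the Hamming ball
of radius ``d`` around ``s_1``, so enumerating that ball and testing each
candidate finds the complete center set.  A hard guard at L <= 22 keeps the
worst case at a few million distance checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .core import BitString, Instance, InputError, mask_from_positions

#: largest instance length the oracle will touch
MAX_LENGTH = 22


@dataclass(frozen=True)
class OracleReport:
    centers: tuple[BitString, ...]
    d: int
    forced: dict[int, int]

    @property
    def solvable(self) -> bool:
        return bool(self.centers)


def _guard(inst: Instance) -> None:
    if inst.length > MAX_LENGTH:
        raise InputError(
            f"oracle refuses L={inst.length} > {MAX_LENGTH}; use a real solver"
        )


def brute_force_centers(inst: Instance, d: int) -> OracleReport:
    """All centers at threshold d, plus the positions every center agrees on."""
    _guard(inst)
    if d < 0:
        raise InputError("d must be nonnegative")
    L = inst.length
    masks = inst.masks
    s1 = masks[0]
    centers: list[BitString] = []
    # deterministic order: flip-set size ascending, lexicographic within a size
    for r in range(min(d, L) + 1):
        for flips in combinations(range(L), r):
            cand = s1 ^ mask_from_positions(flips)
            if all((cand ^ m).bit_count() <= d for m in masks):
                centers.append(BitString(cand, L))
    forced: dict[int, int] = {}
    if centers:
        all_and = all_or = centers[0].bits
        for c in centers[1:]:
            all_and &= c.bits
            all_or |= c.bits
        for p in range(L):
            if not (all_or >> p & 1):
                forced[p] = 0
            elif all_and >> p & 1:
                forced[p] = 1
    return OracleReport(tuple(centers), d, forced)


def brute_force_dopt(inst: Instance) -> tuple[int, BitString]:
    """Smallest d with a nonempty center set, plus one example center.

    Terminates because s_1 itself is a center at d = max_i d_H(s_1, s_i).
    """
    _guard(inst)
    d = 0
    while True:
        report = brute_force_centers(inst, d)
        if report.solvable:
            return d, report.centers[0]
        d += 1


def forced_positions(inst: Instance, d: int) -> dict[int, int]:
    """Map position -> value on which *all* centers at threshold d agree.

    Empty when the instance is unsolvable at d.  Any sound data-reduction
    rule may only fix (p, v) pairs contained in this map.
    """
    return brute_force_centers(inst, d).forced
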