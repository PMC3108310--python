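"""d_opt search, algorithm dispatch and batch reports.

The optimal threshold d_opt is found by calling a decision solver for
increasing d.  The iteration starts from the instance lower bound
max(ceil(max pairwise distance / 2), ceil(L'/k)) (L' = dirty columns): the
first term is the triangle inequality, the second the naive kernel bound.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from .core import BitString, Instance, InputError, is_center, max_pairwise_distance
from .gramm import gramm_solve
from .masun import center_via_masun
from .mismatchcount import mismatchcount_solve
from .oracle import brute_force_centers
from .reduction import preprocess

ALGORITHMS = ("gramm", "masun", "mismatchcount", "oracle")


def lower_bound(inst: Instance) -> int:
    """max(ceil(max pairwise distance / 2), ceil(L'/k)); never exceeds d_opt."""
    masks = inst.masks
    dirty = 0
    for m in masks[1:]:
        dirty |= m ^ masks[0]
    L_dirty = dirty.bit_count()
    return max((max_pairwise_distance(inst) + 1) // 2, -(-L_dirty // inst.k))


def upper_bound(inst: Instance) -> int:
    """min_i max_j d_H(s_i, s_j): any input string is a candidate center."""
    masks = inst.masks
    return min(
        max((mi ^ mj).bit_count() for mj in masks) for mi in masks
    )


def _solve_at(
    inst: Instance, d: int, algo: str, use_preprocess: bool, **kw
) -> tuple[BitString | None, str | None, dict]:
    """Run one (d, algo) decision call.

    Returns (center or None, rejecting layer or None, counters).
    """
    if algo not in ALGORITHMS:
        raise InputError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")
    if algo == "oracle":
        report = brute_force_centers(inst, d)
        center = report.centers[0] if report.solvable else None
        return center, None if center else "solver", {"centers": len(report.centers)}
    hints = None
    counters: dict = {}
    if use_preprocess:
        hints = preprocess(inst, d)
        counters["fixed_positions"] = hints.partial.decided.bit_count()
        counters["rules"] = len(hints.rules)
        if hints.status == "rejected":
            return None, hints.rejected_by, counters
    if algo == "gramm":
        res = gramm_solve(inst, d, hints)
        counters["nodes_expanded"] = res.nodes_expanded
    elif algo == "masun":
        res = center_via_masun(inst, d, hints, strict_e1=kw.get("strict_e1", False))
        counters["branch_strings"] = res.branch_strings
    else:
        res = mismatchcount_solve(inst, d, hints, skip=kw.get("skip", True))
        counters["candidates_visited"] = res.candidates_visited
        counters["candidates_skipped"] = res.candidates_skipped
    return res.center, None if res.center else "solver", counters


@dataclass(frozen=True)
class PerDRecord:
    d: int
    solvable: bool
    rejected_by: str | None     # "naive" | "preprocess" | "solver" | None
    counters: dict


@dataclass
class OptResult:
    d_opt: int | None
    center: BitString | None
    per_d_log: list[PerDRecord] = field(default_factory=list)
    status: str = "ok"          # "ok" | "timeout"


def find_opt(
    inst: Instance,
    algo: str = "mismatchcount",
    use_preprocess: bool = True,
    time_limit: float | None = None,
    from_zero: bool = False,
    **kw,
) -> OptResult:
    """Smallest d with a center, by increasing d from the lower bound.

    ``from_zero`` restores the literal d = 0, 1, 2, ... loop.  ``time_limit``
    (seconds) is a per-d budget checked between calls; on exhaustion the
    partial log is returned with status "timeout".
    """
    result = OptResult(None, None)
    d = 0 if from_zero else lower_bound(inst)
    ub = upper_bound(inst)
    while d <= ub:
        t0 = time.monotonic()
        center, rejected_by, counters = _solve_at(inst, d, algo, use_preprocess, **kw)
        elapsed = time.monotonic() - t0
        result.per_d_log.append(PerDRecord(d, center is not None, rejected_by, counters))
        if center is not None:
            if not is_center(center, inst, d):
                raise AssertionError("solver returned an invalid center")
            result.d_opt = d
            result.center = center
            return result
        if time_limit is not None and elapsed > time_limit:
            result.status = "timeout"
            return result
        d += 1
    raise AssertionError("no center found up to the trivial upper bound")


def batch_report(
    instances: Sequence[Instance],
    d_offsets: Sequence[int] = (-1, 0),
    algo: str = "mismatchcount",
    d_opt_fn: Callable[[Instance], int] | None = None,
) -> pd.DataFrame:
    """Preprocessing effectiveness over a batch, at offsets relative to d_opt.

    For each offset: fraction of instances rejected by the naive kernel,
    fraction of the remainder additionally rejected by full preprocessing,
    total rejected fraction, and the mean fraction of dirty positions fixed
    on instances that survive preprocessing.
    """
    if d_opt_fn is None:
        d_opt_fn = lambda inst: find_opt(inst, algo=algo).d_opt
    rows = []
    for offset in d_offsets:
        n = naive = extra = 0
        fixed_fracs = []
        for inst in instances:
            d = d_opt_fn(inst) + offset
            if d < 0:
                continue
            n += 1
            res = preprocess(inst, d)
            if res.status == "rejected":
                if res.rejected_by == "naive":
                    naive += 1
                else:
                    extra += 1
            else:
                fixed_fracs.append(res.fixed_fraction)
        remaining = n - naive
        rows.append(
            {
                "offset": offset,
                "n": n,
                "frac_naive_rejected": naive / n if n else 0.0,
                "frac_extra_rejected_of_remaining": extra / remaining if remaining else 0.0,
                "frac_total_rejected": (naive + extra) / n if n else 0.0,
                "mean_fixed_fraction": (
                    sum(fixed_fracs) / len(fixed_fracs) if fixed_fracs else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
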