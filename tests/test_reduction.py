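"""Data reduction: kernel, trivial positions, pair budgets, cascading."""

import random

import pytest

from centerstring import (
    BitString,
    Instance,
    PairBudget,
    PartialCenter,
    Rejection,
    brute_force_centers,
    brute_force_dopt,
    cascade,
    compute_pair_budgets,
    naive_reject,
    preprocess,
    reduce_tuples,
    remove_clean_columns,
    solve_trivial_positions,
)
from centerstring.core import mask_from_positions


def pc_assignments(partial: PartialCenter) -> dict[int, int]:
    return {p: partial.value(p) for p in range(partial.length) if partial.value(p) >= 0}


class TestRemoveCleanColumns:
    def test_worked_instance_drops_last_column(self, micro):
        red, cmap, fixed = remove_clean_columns(micro)
        assert cmap == (0, 1, 2, 3, 4)
        assert fixed == {5: 0}
        assert [str(s) for s in red.strings] == ["00000", "11100", "00111"]

    def test_identical_instance_reduces_to_empty(self):
        red, cmap, fixed = remove_clean_columns(Instance.from_texts(["0110", "0110"]))
        assert red.length == 0
        assert cmap == ()
        assert fixed == {0: 0, 1: 1, 2: 1, 3: 0}

    def test_no_clean_column_is_identity(self):
        inst = Instance.from_texts(["0000", "1111"])
        red, cmap, fixed = remove_clean_columns(inst)
        assert red == inst and cmap == (0, 1, 2, 3) and fixed == {}


class TestNaiveReject:
    def test_worked_instance(self, micro):
        assert naive_reject(micro, 1) is not None
        assert naive_reject(micro, 2) is None

    def test_identical_pair_at_zero(self):
        assert naive_reject(Instance.from_texts(["0101", "0101"]), 0) is None

    def test_pair_bound(self):
        # 3 dirty columns <= k*d = 5, but the pair is farther than 2d = 2
        inst = Instance.from_texts(["0111", "0000", "0000", "0000", "0000"])
        assert naive_reject(inst, 1) == Rejection.PAIR_GT_2D


class TestSolveTrivialPositions:
    def test_worked_instance_fully_determined(self, micro):
        partial = PartialCenter(micro.length)
        assert solve_trivial_positions(micro, 2, partial) is None
        assert pc_assignments(partial) == {0: 0, 1: 0, 2: 1, 3: 0, 4: 0, 5: 0}

    def test_complement_pair_fixes_nothing(self):
        inst = Instance.from_texts(["0000", "1111"])
        partial = PartialCenter(4)
        assert solve_trivial_positions(inst, 2, partial) is None
        assert partial.decided == 0

    def test_rejects_when_pair_exceeds_budgets(self):
        partial = PartialCenter(2)
        rej = solve_trivial_positions(Instance.from_texts(["00", "11"]), 0, partial)
        assert rej is not None

    def test_every_fixing_is_oracle_forced(self, small_corpus):
        for inst in small_corpus[:120]:
            for d in range(4):
                partial = PartialCenter(inst.length)
                rej = solve_trivial_positions(inst, d, partial)
                rep = brute_force_centers(inst, d)
                if rej is not None:
                    assert not rep.solvable
                elif rep.solvable:
                    for p, v in pc_assignments(partial).items():
                        assert rep.forced.get(p) == v


class TestComputePairBudgets:
    def test_direct_formula(self):
        inst = Instance.from_texts(["000000", "111100"])   # hamming 4, d=3
        tuples, rej = compute_pair_budgets(inst, 3, PartialCenter(6))
        assert rej is None
        (t,) = tuples
        assert t.x == 3 - 2 == 1
        assert t.positions == {4, 5}

    def test_three_string_example(self):
        inst = Instance.from_texts(["0000", "1100", "0011"])
        tuples, rej = compute_pair_budgets(inst, 2, PartialCenter(4))
        assert rej is None
        by_pair = {(t.i, t.j): t for t in tuples}
        assert set(by_pair) == {(0, 1), (0, 2)}   # pair (1,2) has h=4 >= 2d-1
        assert by_pair[(0, 1)].x == 1 and by_pair[(0, 1)].positions == {2, 3}
        assert by_pair[(0, 2)].x == 1 and by_pair[(0, 2)].positions == {0, 1}

    def test_pair_at_2d_minus_1_excluded(self):
        inst = Instance.from_texts(["00000", "11100"])     # h = 3 = 2d-1, d=2
        tuples, _ = compute_pair_budgets(inst, 2, PartialCenter(5))
        assert tuples == []


class TestReduceTuples:
    def test_zero_budget_fixes_remaining_positions(self):
        inst = Instance.from_texts(["000000", "110000", "001100"])
        partial = PartialCenter(6)
        T = [PairBudget(0, 1, mask_from_positions({4, 5}), 0)]
        T2, rej = reduce_tuples(T, inst, partial)
        assert rej is None and T2 == []
        assert pc_assignments(partial) == {4: 0, 5: 0}

    def test_decided_mismatch_decrements_budget(self):
        inst = Instance.from_texts(["000000", "110000"])
        partial = PartialCenter(6)
        partial.set(4, 1)                                  # mismatches s_1 at 4
        T = [PairBudget(0, 1, mask_from_positions({4}), 1)]
        T2, rej = reduce_tuples(T, inst, partial)
        assert rej is None and T2 == []                    # x -> 0, E -> empty
        assert partial.value(5) == -1

    def test_negative_budget_rejects(self):
        inst = Instance.from_texts(["000000", "110000"])
        partial = PartialCenter(6)
        partial.set(4, 1)
        partial.set(5, 1)
        T = [PairBudget(0, 1, mask_from_positions({4, 5}), 1)]
        _, rej = reduce_tuples(T, inst, partial)
        assert rej == Rejection.NEGATIVE_X


class TestCascade:
    def test_hypothesis_forces_companion_position(self):
        inst = Instance.from_texts(["0000", "1100", "0011"])
        partial = PartialCenter(4)
        assert solve_trivial_positions(inst, 2, partial) is None
        tuples, _ = compute_pair_budgets(inst, 2, partial)
        rules, restarted, rej = cascade(inst, 2, partial, tuples)
        assert rej is None and not restarted
        rule = next(r for r in rules if r.p == 2)
        assert rule.v == 1
        assert rule.solved.value(3) == 0
        assert rule.potentially_permanent == {3}

    def test_empty_agreement_set_yields_no_rules(self):
        inst = Instance.from_texts(["0000", "1111"])
        partial = PartialCenter(4)
        tuples = [PairBudget(0, 1, 0, 1)]
        rules, restarted, rej = cascade(inst, 2, partial, tuples)
        assert rules == [] and not restarted and rej is None

    def test_conflicting_hypothesis_is_forced_to_si(self, small_corpus):
        """Whenever cascading force-fixes a position after a contradiction,
        that assignment must be satisfied by every center."""
        seen = 0
        for inst in small_corpus:
            for d in range(1, 4):
                res = preprocess(inst, d)
                if res.status != "reduced":
                    continue
                rep = brute_force_centers(inst, d)
                if not rep.solvable:
                    continue
                for q in range(res.reduced.length):
                    v = res.partial.value(q)
                    if v >= 0:
                        seen += 1
                        assert rep.forced.get(res.column_map[q]) == v
        assert seen > 50


class TestPreprocess:
    def test_worked_instance_fully_determined(self, micro):
        res = preprocess(micro, 2)
        assert res.status == "reduced"
        assert res.fully_decided
        assert str(res.center()) == "001000"

    def test_worked_instance_rejected_below(self, micro):
        res = preprocess(micro, 1)
        assert res.status == "rejected"
        assert res.rejected_by == "naive"

    def test_single_string(self):
        res = preprocess(Instance.from_texts(["0101"]), 0)
        assert res.status == "reduced"
        assert str(res.center()) == "0101"

    def test_rejection_soundness_and_dominance(self, small_corpus):
        """preprocess never rejects a solvable (instance, d) and rejects a
        superset of what the naive kernel rejects."""
        for inst in small_corpus:
            for d in range(4):
                res = preprocess(inst, d)
                solvable = brute_force_centers(inst, d).solvable
                if res.status == "rejected":
                    assert not solvable
                if naive_reject(inst, d) is not None:
                    assert res.status == "rejected"

    def test_kernel_conserves_dopt(self, small_corpus):
        for inst in small_corpus[:60]:
            red, _, _ = remove_clean_columns(inst)
            if red.length == 0:
                assert brute_force_dopt(inst)[0] == 0
                continue
            assert brute_force_dopt(red)[0] == brute_force_dopt(inst)[0]

    def test_fixpoint_independent_of_string_order(self, small_corpus):
        """The final permanent assignment does not depend on the order in
        which string pairs are processed."""
        rng = random.Random(8)
        for inst in small_corpus[:80]:
            d = rng.randint(1, 3)
            res = preprocess(inst, d)
            base = (
                res.status,
                sorted(res.fixed_assignments_original().items())
                if res.status == "reduced"
                else None,
            )
            order = list(range(inst.k))
            rng.shuffle(order)
            shuffled = Instance(tuple(inst.strings[i] for i in order))
            res2 = preprocess(shuffled, d)
            got = (
                res2.status,
                sorted(res2.fixed_assignments_original().items())
                if res2.status == "reduced"
                else None,
            )
            assert base == got

    def test_monotone_progress_bounded_iterations(self):
        """The permanent set only grows; preprocess terminates and at the
        fixpoint budgets are nonnegative and tuples have positive budgets."""
        rng = random.Random(13)
        for _ in range(60):
            L, k, d = rng.randint(3, 10), rng.randint(2, 5), rng.randint(1, 3)
            inst = Instance(
                tuple(BitString(rng.getrandbits(L), L) for _ in range(k))
            )
            res = preprocess(inst, d)
            if res.status == "reduced":
                assert all(b >= 0 for b in res.budgets)
                assert all(t.x > 0 and t.E for t in res.tuples)
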