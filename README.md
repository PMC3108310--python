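# centerstring

Exact solvers and data reduction for the **center string** (closest string)
problem on binary strings.

Given `k` binary strings `s_1, …, s_k` of length `L` and a threshold `d`,
a *center string* `ŝ` satisfies `d_H(ŝ, s_i) ≤ d` for every `i`, where
`d_H` is the Hamming distance; `d_opt` is the smallest such `d`.  The
problem is NP-complete but fixed-parameter tractable in `d`, and the binary
case arises directly in comparative genomics: encoding the gene content of
approximate gene-cluster occurrences as presence/absence strings turns the
symmetric set distance `D(C, C') = |C \ C'| + |C' \ C|` into the Hamming
distance, so the *center gene cluster* of a set of occurrences is a binary
center string.

The package provides:

* **Data reduction** (`centerstring.reduction`) — the naive kernel (drop
  clean columns; reject if more than `k·d` dirty columns remain or a pair
  is farther than `2d` apart), *trivial-position solving* (a pair at
  distance `2d` or `2d−1` forces the center on its agreement set `E_ij`,
  generalized with per-string remaining budgets), *pair-budget tuples*
  `(E_ij, x_ij)` with `x_ij = d − ⌈d_H(s_i,s_j)/2⌉` for close pairs, and
  *cascading*, which turns `x_ij = 1` pairs into forced positions or
  conditional rules `(p, v) → ŝ_{p,v}`.
* **Three exact solvers** — the depth-bounded search tree of Gramm et al.
  (`gramm_solve`), the Ma–Sun branching algorithm for the more general
  Neighbor String problem (`neighbor_solve` / `center_via_masun`), and
  **MismatchCount** (`mismatchcount_solve`), an ordered enumeration of the
  Hamming ball around `s_1` with incrementally maintained distances and
  `c_min`-based skipping.  All three can consume the preprocessing.
* A **d_opt driver** (`find_opt`) iterating `d` upward from the lower
  bound `max(⌈max-pairwise/2⌉, ⌈L'/k⌉)`, a **brute-force oracle** for
  ground truth on small instances, **seeded generators** (planted-center,
  gene-cluster-like, provably unsolvable), plain-text/FASTA I/O, and a
  `centerstring` CLI.

## Worked example

The instance `{000000, 111000, 001110}` has pairwise distances 3, 3 and 4,
so no center exists below `⌈4/2⌉ = 2`:

```bash
$ printf '000000\n111000\n001110\n' > micro.txt
$ centerstring opt micro.txt
{
  "center": "001000",
  "d_opt": 2,
  "lower_bound": 2,
  "per_d": [
    {
      "candidates_skipped": 0,
      "candidates_visited": 1,
      "d": 2,
      "fixed_positions": 5,
      "rejected_by": null,
      "rules": 0,
      "solvable": true,
      ...
    }
  ],
  "status": "ok"
}
```

The search starts at the lower bound `d = 2` and succeeds immediately:
preprocessing alone fixes all five dirty positions (`fixed_positions: 5`),
so the solver verifies a single candidate.  `centerstring reduce micro.txt
--d 2` shows the forced assignments (1-based): position 3 must be `1`, all
others `0` — the unique center `001000` at distance 2.  At `d = 1` the
naive kernel already rejects (5 dirty columns > k·d = 3, and a pair at
distance 4 > 2d).

The same works from Python:

```python
from centerstring import Instance, find_opt, preprocess

inst = Instance.from_texts(["000000", "111000", "001110"])
res = find_opt(inst, algo="mismatchcount")
print(res.d_opt, res.center)        # 2 001000
print(preprocess(inst, 2).fixed_assignments_original())
```

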