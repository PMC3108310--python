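"""Seeded instance generators.

Two families emulate the conditions the solvers are meant for:

* **Planted-center instances**: a hidden center is drawn uniformly and each
  input string flips a random e_i-subset of positions, so d_opt <= d_plant
  by construction.  Exact-flip mode (all e_i = d_plant) produces hard
  instances whose string pairs sit close to the 2d bound.

* **Gene-cluster-like instances**: approximate occurrences of a gene
  cluster are gene sets C_1..C_k; encoding presence/absence of each gene of
  the union (fixed gene order) as a column turns the symmetric set distance
  D(C, C') = |C \\ C'| + |C' \\ C| into the Hamming distance of binary
  rows.  Realistic instances are short, so several independent blocks are
  concatenated columnwise to reach a target hardness.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .core import BitString, Instance, InputError


@dataclass(frozen=True)
class PlantedSpec:
    k: int
    L: int
    d_plant: int
    flip_counts: tuple[int, ...] | None = None   # per-string e_i <= d_plant
    exact: bool = False                          # force every e_i = d_plant
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.d_plant <= self.L):
            raise InputError("need 0 <= d_plant <= L")
        if self.flip_counts is not None:
            if len(self.flip_counts) != self.k:
                raise InputError("flip_counts length must equal k")
            if any(not 0 <= e <= self.d_plant for e in self.flip_counts):
                raise InputError("each e_i must satisfy 0 <= e_i <= d_plant")


def generate_planted(spec: PlantedSpec) -> tuple[Instance, BitString]:
    """Instance with a hidden center; hamming(s_i, center) = e_i exactly."""
    rng = random.Random(spec.seed)
    center = rng.getrandbits(spec.L) if spec.L else 0
    if spec.flip_counts is not None:
        counts = spec.flip_counts
    elif spec.exact:
        counts = (spec.d_plant,) * spec.k
    else:
        counts = tuple(rng.randint(0, spec.d_plant) for _ in range(spec.k))
    strings = []
    for e in counts:
        flips = rng.sample(range(spec.L), e)
        bits = center
        for p in flips:
            bits ^= 1 << p
        strings.append(BitString(bits, spec.L))
    return Instance(tuple(strings)), BitString(center, spec.L)


@dataclass(frozen=True)
class GeneContentBlock:
    """Gene-content occurrence sets of one approximate cluster."""

    gene_pool: tuple[str, ...]
    occurrences: tuple[frozenset[str], ...]
    delta: int = 0      # distance threshold of the cluster model (metadata)

    def __post_init__(self) -> None:
        pool = set(self.gene_pool)
        for occ in self.occurrences:
            if not occ <= pool:
                raise InputError("every occurrence must be a subset of gene_pool")


def symmetric_set_distance(a: frozenset, b: frozenset) -> int:
    """|a \\ b| + |b \\ a|."""
    return len(a ^ b)


def set_to_binary(block: GeneContentBlock) -> Instance:
    """Presence/absence encoding: one column per gene of the union, in a
    fixed (sorted) order shared by all rows; the symmetric set distance of
    two occurrences equals the Hamming distance of their rows."""
    union = sorted(set().union(*block.occurrences))
    if not union:
        raise InputError("occurrences are all empty")
    strings = []
    for occ in block.occurrences:
        bits = 0
        for p, gene in enumerate(union):
            if gene in occ:
                bits |= 1 << p
        strings.append(BitString(bits, len(union)))
    return Instance(tuple(strings))


def generate_cluster_like(
    k: int,
    n_blocks: int,
    genes_per_block: int,
    perturb_rate: float,
    seed: int = 0,
) -> Instance:
    """Concatenation of independent gene-cluster blocks.

    Each block has a reference cluster of ``genes_per_block`` genes; every
    genome's occurrence drops each reference gene and gains each accessory
    gene (an equally sized side pool) independently with ``perturb_rate``.
    """
    if k < 1 or n_blocks < 1 or genes_per_block < 1:
        raise InputError("parameters must be positive")
    if not 0.0 <= perturb_rate <= 1.0:
        raise InputError("perturb_rate must be in [0, 1]")
    rng = random.Random(seed)
    texts = [""] * k
    for b in range(n_blocks):
        core = [f"b{b}g{i}" for i in range(genes_per_block)]
        accessory = [f"b{b}x{i}" for i in range(genes_per_block)]
        occurrences = []
        for _ in range(k):
            occ = {g for g in core if rng.random() >= perturb_rate}
            occ |= {g for g in accessory if rng.random() < perturb_rate}
            if not occ:
                occ = {core[0]}     # keep occurrences nonempty
            occurrences.append(frozenset(occ))
        block = GeneContentBlock(tuple(core + accessory), tuple(occurrences))
        block_inst = set_to_binary(block)
        for i, s in enumerate(block_inst.strings):
            texts[i] += str(s)
    return Instance.from_texts(texts)


def unsolvable_instance(L: int, d: int) -> Instance | None:
    """A deterministic all-dirty instance with no center at threshold d.

    For L > 2d the pair {0^L, 1^L} works (a center would need distance
    >= ceil(L/2) > d to one of them).  For d < L <= 2d the construction
    uses a covering code: if the complements of the input strings cover
    {0,1}^L with Hamming balls of radius L - d - 1, then every candidate t
    lies within L - d - 1 of some complement, hence at distance >= d + 1
    from that input string.  The code is built greedily (e.g. L = 5, d = 3
    needs 7 codewords, the covering number K(5,1)).  Returns None when
    d >= L (every string of length L is then a center).
    """
    if d >= L:
        return None
    full = (1 << L) - 1
    if 2 * d < L:
        return Instance((BitString(0, L), BitString(full, L)))
    radius = L - d - 1
    balls = []
    for c in range(1 << L):
        ball = frontier = {c}
        for _ in range(radius):
            frontier = {f ^ (1 << p) for f in frontier for p in range(L)}
            ball = ball | frontier
        balls.append(frozenset(ball))
    uncovered = set(range(1 << L))
    code = []
    while uncovered:
        best = max(range(1 << L), key=lambda c: (len(balls[c] & uncovered), -c))
        code.append(best)
        uncovered -= balls[best]
    strings = [BitString(c ^ full, L) for c in code]
    dirty = 0
    for s in strings[1:]:
        dirty |= s.bits ^ strings[0].bits
    if dirty != full:
        # adding strings keeps the instance unsolvable; a complement pair
        # makes every column dirty
        strings.append(BitString(strings[0].bits ^ full, L))
    return Instance(tuple(strings))


def random_instance(k: int, L: int, seed: int = 0) -> Instance:
    """Uniformly random binary instance (for differential testing)."""
    rng = random.Random(seed)
    return Instance(tuple(BitString(rng.getrandbits(L), L) for _ in range(k)))


def planted_batch(
    n: int, k: int, L: int, d_plant: int, seed: int = 0, exact: bool = False
) -> list[tuple[Instance, BitString]]:
    """n independently seeded planted instances."""
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        spec = PlantedSpec(k, L, d_plant, exact=exact, seed=rng.randrange(2**31))
        out.append(generate_planted(spec))
    return out
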