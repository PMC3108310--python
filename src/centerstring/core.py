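"""Binary strings, Hamming machinery and instance normalization.

The center string (closest string) problem asks, for ``k`` binary strings
``s_1..s_k`` of common length ``L`` and a threshold ``d``, for a string with
Hamming distance at most ``d`` to every input string.  This module holds the
value types shared by every solver: immutable :class:`BitString`, the
:class:`Instance` container, and position-set algebra on 0-based indices.

Internally a bit string is an integer mask in which bit ``p`` (LSB = position
0) carries the symbol at position ``p``; Hamming distances are popcounts of
XORs.  Text representations read left to right, so ``"110"`` has a ``1`` at
positions 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence


class InputError(ValueError):
    """Raised on malformed instances, masks or position sets."""


def mask_from_positions(positions: Iterable[int]) -> int:
    m = 0
    for p in positions:
        m |= 1 << p
    return m


def positions_from_mask(mask: int) -> frozenset[int]:
    out = set()
    p = 0
    while mask:
        if mask & 1:
            out.add(p)
        mask >>= 1
        p += 1
    return frozenset(out)


@dataclass(frozen=True)
class BitString:
    """Immutable binary string of fixed length.

    ``bits`` is the integer mask; ``length`` the number of positions L.
    """

    bits: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 0:
            raise InputError("length must be nonnegative")
        if self.bits < 0 or self.bits >> self.length:
            raise InputError("bits outside [0, 2^length)")

    @classmethod
    def from_text(cls, text: str) -> "BitString":
        bits = 0
        for p, c in enumerate(text):
            if c == "1":
                bits |= 1 << p
            elif c != "0":
                raise InputError(f"non-binary symbol {c!r} at position {p}")
        return cls(bits, len(text))

    def __str__(self) -> str:
        return "".join("1" if self.bits >> p & 1 else "0" for p in range(self.length))

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, p: int) -> int:
        if not 0 <= p < self.length:
            raise InputError(f"position {p} out of range [0, {self.length})")
        return self.bits >> p & 1

    def __xor__(self, other: "BitString") -> "BitString":
        _check_lengths(self, other)
        return BitString(self.bits ^ other.bits, self.length)

    def flip(self, positions: Iterable[int]) -> "BitString":
        """Return a copy with the given positions inverted."""
        m = mask_from_positions(positions)
        if m >> self.length:
            raise InputError("flip position out of range")
        return BitString(self.bits ^ m, self.length)


@dataclass(frozen=True)
class Instance:
    """A center string instance: k binary strings of identical length L."""

    strings: tuple[BitString, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.strings:
            raise InputError("an instance needs at least one string (k >= 1)")
        L = self.strings[0].length
        for i, s in enumerate(self.strings):
            if s.length != L:
                raise InputError(f"string {i} has length {s.length}, expected {L}")
        if self.labels is not None and len(self.labels) != len(self.strings):
            raise InputError("labels/strings count mismatch")

    @classmethod
    def from_texts(cls, texts: Sequence[str], labels: Sequence[str] | None = None) -> "Instance":
        return cls(
            tuple(BitString.from_text(t) for t in texts),
            tuple(labels) if labels is not None else None,
        )

    @property
    def k(self) -> int:
        return len(self.strings)

    @property
    def length(self) -> int:
        return self.strings[0].length

    @property
    def masks(self) -> tuple[int, ...]:
        return tuple(s.bits for s in self.strings)

    def __iter__(self) -> Iterator[BitString]:
        return iter(self.strings)


def _check_lengths(s: BitString, t: BitString) -> None:
    if s.length != t.length:
        raise InputError(f"length mismatch: {s.length} != {t.length}")


def hamming(s: BitString, t: BitString) -> int:
    """Number of positions p with s[p] != t[p]."""
    _check_lengths(s, t)
    return (s.bits ^ t.bits).bit_count()


def _restriction_mask(R: Iterable[int], length: int) -> int:
    m = mask_from_positions(R)
    if m >> length:
        raise InputError("restriction position out of range")
    return m


def hamming_restricted(s: BitString, t: BitString, R: Iterable[int]) -> int:
    """Hamming distance restricted to the position set R."""
    _check_lengths(s, t)
    return ((s.bits ^ t.bits) & _restriction_mask(R, s.length)).bit_count()


def diff_positions(s: BitString, t: BitString) -> frozenset[int]:
    """D_{s,t}: positions where s and t differ."""
    _check_lengths(s, t)
    return positions_from_mask(s.bits ^ t.bits)


def eq_positions(s: BitString, t: BitString) -> frozenset[int]:
    """E_{s,t}: positions where s and t agree (complement of D_{s,t})."""
    _check_lengths(s, t)
    full = (1 << s.length) - 1
    return positions_from_mask(full & ~(s.bits ^ t.bits))


def max_pairwise_distance(inst: Instance) -> int:
    masks = inst.masks
    best = 0
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            h = (masks[i] ^ masks[j]).bit_count()
            if h > best:
                best = h
    return best


def permute(inst: Instance, pi: Sequence[int] | Mapping[int, int]) -> Instance:
    """Apply the same position permutation to every string.

    ``pi`` maps new position -> old position (``out[p] = s[pi[p]]``); any
    bijection on [0, L) yields an equivalent instance with all pairwise
    distances preserved.
    """
    L = inst.length
    if isinstance(pi, Mapping):
        pi = [pi[p] for p in range(L)]
    if sorted(pi) != list(range(L)):
        raise InputError("pi is not a bijection on [0, L)")
    out = []
    for s in inst.strings:
        bits = 0
        for p in range(L):
            if s.bits >> pi[p] & 1:
                bits |= 1 << p
        out.append(BitString(bits, L))
    return Instance(tuple(out), inst.labels)


def normalize_to_s1(inst: Instance) -> tuple[Instance, BitString]:
    """XOR every string columnwise with s_1, so the first string is all-zero.

    Returns the normalized instance and the mask (= original s_1).  XOR is
    distance-preserving, and XOR-ing any center of the normalized instance
    with the mask yields a center of the original.
    """
    mask = inst.strings[0]
    normalized = Instance(tuple(s ^ mask for s in inst.strings), inst.labels)
    return normalized, mask


def is_center(candidate: BitString, inst: Instance, d: int) -> bool:
    """True iff max_i hamming(candidate, s_i) <= d."""
    if candidate.length != inst.length:
        raise InputError("candidate length does not match instance")
    return all((candidate.bits ^ m).bit_count() <= d for m in inst.masks)


def max_distance(candidate: BitString, inst: Instance) -> int:
    """max_i hamming(candidate, s_i)."""
    if candidate.length != inst.length:
        raise InputError("candidate length does not match instance")
    return max((candidate.bits ^ m).bit_count() for m in inst.masks)
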