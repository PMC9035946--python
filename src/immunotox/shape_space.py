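"""Bit-string shape space: receptors, complementarity matching, repertoires.

Receptors, MHC molecules, peptides, epitopes and antibody paratopes are all
fixed-length binary strings.  Two strings are *complementary* where their
bits differ, so the Hamming distance ``d`` between them counts complementary
positions and affinity increases with ``d``.  The potential repertoire of a
length-``l`` shape space has ``2**l`` distinct specificities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BitString",
    "AffinityParams",
    "hamming_distance",
    "binding_probability",
    "sample_repertoire",
    "mutate_receptor",
]


@dataclass(frozen=True, order=True)
class BitString:
    """A receptor/ligand as an integer in ``[0, 2**length)``."""

    length: int
    value: int

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"length must be non-negative, got {self.length}")
        if not (0 <= self.value < (1 << self.length)):
            raise ValueError(
                f"value {self.value} out of range for length {self.length}"
            )

    def __str__(self) -> str:
        return format(self.value, f"0{self.length}b")

    @classmethod
    def from_bits(cls, bits: str) -> "BitString":
        """Build from a literal like ``"1010"``."""
        return cls(length=len(bits), value=int(bits, 2) if bits else 0)

    def complement(self) -> "BitString":
        return BitString(self.length, self.value ^ ((1 << self.length) - 1))


@dataclass(frozen=True)
class AffinityParams:
    """Parameters of the thresholded-exponential binding rule.

    ``d_min`` is the minimum number of complementary bits for any binding;
    ``alpha`` penalises each missing complementary bit; ``p_max`` is the
    binding probability of a perfectly complementary pair.
    """

    l: int = 12
    d_min: int = 9
    alpha: float = 0.7
    p_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.d_min <= self.l):
            raise ValueError(f"d_min must be in [0, l={self.l}], got {self.d_min}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 <= self.p_max <= 1.0):
            raise ValueError(f"p_max must be in [0, 1], got {self.p_max}")


def _check_lengths(a: BitString, b: BitString) -> None:
    if a.length != b.length:
        raise ValueError(
            f"bit-string length mismatch: {a.length} != {b.length}"
        )


def hamming_distance(a: BitString, b: BitString) -> int:
    """Number of positions where ``a`` and ``b`` differ (complementary bits)."""
    _check_lengths(a, b)
    return (a.value ^ b.value).bit_count()


def binding_probability(a: BitString, b: BitString, params: AffinityParams) -> float:
    """Probability that ``a`` and ``b`` bind in one Bernoulli recognition event.

    ``p = 0`` below the complementarity threshold ``d_min``, otherwise
    ``p_max * alpha**(l - d)`` where ``d`` is the Hamming distance; the rule
    is non-decreasing in ``d`` and reaches ``p_max`` at full complementarity.
    """
    _check_lengths(a, b)
    if a.length != params.l:
        raise ValueError(
            f"strings of length {a.length} but params.l = {params.l}"
        )
    d = hamming_distance(a, b)
    if d < params.d_min:
        return 0.0
    return params.p_max * params.alpha ** (params.l - d)


def sample_repertoire(n: int, l: int, rng: np.random.Generator) -> list[BitString]:
    """Draw ``n`` receptors uniformly and independently from the shape space."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return []
    values = rng.integers(0, 1 << l, size=n, dtype=np.uint64)
    return [BitString(l, int(v)) for v in values]


def mutate_receptor(r: BitString, n_bits: int, rng: np.random.Generator) -> BitString:
    """Flip ``n_bits`` distinct uniformly chosen positions (hypermutation)."""
    if not (0 <= n_bits <= r.length):
        raise ValueError(
            f"n_bits must be in [0, {r.length}], got {n_bits}"
        )
    if n_bits == 0:
        return r
    positions = rng.choice(r.length, size=n_bits, replace=False)
    mask = 0
    for p in positions:
        mask |= 1 << int(p)
    return BitString(r.length, r.value ^ mask)
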