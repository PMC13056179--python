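"""Canonical, strand-invariant multi-hashing of k-mers and spaced seeds.

Every filter structure in this package addresses its array through the same
contract: a k-mer window is reduced to one canonical 64-bit base hash that is
identical for the window and its reverse complement, and ``h`` derived hash
values are expanded from that base value (double-hashing style), one per hash
function.

The base hash is an xor-rotate scheme over per-base 64-bit constants,

    f(s) = XOR_j rol64(T[s_j], (w - 1 - j) mod 64)      (forward strand)
    r(s) = XOR_j rol64(T[comp(s_j)], j mod 64)          (reverse strand)

with ``w`` the number of care positions, so that ``f(revcomp(s)) == r(s)`` and
``min(f, r)`` is strand-invariant.  For plain k-mers (all-ones mask) both
values roll in O(1) per base, exactly like the classic nucleotide rolling
hashes; for spaced seeds the care-position substring is hashed per window.

Coordinates are 0-based; windows are half-open ``[i, i + k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpacedSeedPattern",
    "RollingHasher",
    "canonical_hashes",
    "canonical_kmer",
    "iter_hashes",
    "encode_sequence",
    "splitmix64",
    "derive_hashes",
    "DEFAULT_NUM_HASHES",
]

#: Number of hash functions per k-mer used throughout the cascade by default.
DEFAULT_NUM_HASHES = 7

_MASK64 = (1 << 64) - 1

# Per-base hash constants (A, C, G, T).  Arbitrary fixed 64-bit values with
# roughly balanced bit patterns; the contract needs uniformity, not any
# particular constants.
_BASE_TABLE = (
    0x3C8BFBB395C60474,
    0x3193C18562A02B4C,
    0x20323ED082572324,
    0x295549F54BE24456,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# byte code lookup: A/a->0, C/c->1, G/g->2, T/t->3, everything else -> 4
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_BASES = "ACGT"


class HashConfigError(ValueError):
    """Raised when a seed pattern or window does not match its configuration."""


class InvalidBaseError(ValueError):
    """Raised when a window contains a non-ACGT base.

    Callers iterating over reads should catch this and skip the window rather
    than abort; :func:`iter_hashes` does exactly that.
    """


@dataclass(frozen=True)
class SpacedSeedPattern:
    """Binary care/don't-care mask applied to k-mers before hashing.

    ``mask`` is a string over {0,1}; position ``i`` contributes to the hash
    iff ``mask[i] == '1'``.  An all-ones mask is a plain k-mer.
    """

    mask: str

    def __post_init__(self) -> None:
        if len(self.mask) < 1 or set(self.mask) - {"0", "1"}:
            raise HashConfigError(f"mask must be a non-empty 0/1 string, got {self.mask!r}")
        if "1" not in self.mask:
            raise HashConfigError("mask needs at least one care position")

    @classmethod
    def all_ones(cls, k: int) -> "SpacedSeedPattern":
        return cls("1" * k)

    @property
    def k(self) -> int:
        return len(self.mask)

    @property
    def weight(self) -> int:
        """Number of care positions."""
        return self.mask.count("1")

    @property
    def is_plain(self) -> bool:
        return self.weight == self.k

    @property
    def care_positions(self) -> np.ndarray:
        return np.flatnonzero(np.frombuffer(self.mask.encode(), dtype=np.uint8) == ord("1"))

    def reversed(self) -> "SpacedSeedPattern":
        """Mask as seen from the reverse-complement strand."""
        return SpacedSeedPattern(self.mask[::-1])


def splitmix64(x: int) -> int:
    """One round of the splitmix64 finalizer (pure-python, 64-bit wrap)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def derive_hashes(base: int, h: int) -> tuple[int, ...]:
    """Expand one canonical base hash into ``h`` derived 64-bit values.

    Double-hashing style derivation: value ``i`` mixes ``base + i*odd`` through
    splitmix64, so a single pass per k-mer feeds any number of hash functions.
    """
    return tuple(splitmix64((base + i * 0xD6E8FEB86659FD93) & _MASK64) for i in range(h))


def _rol(x: int, s: int) -> int:
    s &= 63
    if s == 0:
        return x
    return ((x << s) | (x >> (64 - s))) & _MASK64


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit-encode a DNA string; non-ACGT bases become code 4."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _strand_hashes_codes(codes) -> tuple[int, int]:
    """(forward, reverse) hash of a base-code sequence, from scratch."""
    w = len(codes)
    f = 0
    r = 0
    for j, c in enumerate(codes):
        if c > 3:
            raise InvalidBaseError("non-ACGT base in window")
        f ^= _rol(_BASE_TABLE[c], (w - 1 - j) % 64)
        r ^= _rol(_BASE_TABLE[3 - c], j % 64)
    return f, r


def canonical_kmer(window: str, pattern: SpacedSeedPattern | None = None) -> str:
    """Canonical (strand-collapsed) representation of a window.

    The care-position substring is extracted on both strands (the mask is
    reversed on the reverse complement) and the lexicographically smaller
    string is returned.  For plain k-mers this is the usual canonical k-mer.
    """
    window = window.upper()
    if pattern is not None and pattern.k != len(window):
        raise HashConfigError(f"pattern length {pattern.k} != window length {len(window)}")
    if pattern is not None and not pattern.is_plain:
        fwd = "".join(window[i] for i in pattern.care_positions)
    else:
        fwd = window
    try:
        rev = "".join(_COMPLEMENT[b] for b in reversed(fwd))
    except KeyError as exc:
        raise InvalidBaseError(f"non-ACGT base {exc.args[0]!r} in window") from None
    return min(fwd, rev)


def canonical_base_hash(window: str, pattern: SpacedSeedPattern | None = None) -> int:
    """Strand-invariant 64-bit base hash of one window."""
    codes = encode_sequence(window)
    if pattern is not None:
        if pattern.k != len(window):
            raise HashConfigError(f"pattern length {pattern.k} != window length {len(window)}")
        if not pattern.is_plain:
            codes = codes[pattern.care_positions]
    f, r = _strand_hashes_codes(codes)
    return min(f, r)


def canonical_hashes(
    window: str,
    pattern: SpacedSeedPattern | None = None,
    h: int = DEFAULT_NUM_HASHES,
) -> tuple[int, ...]:
    """Hash one k-mer window into ``h`` strand-invariant 64-bit values.

    Parameters
    ----------
    window:
        DNA string of length k (A/C/G/T only; anything else raises
        :class:`InvalidBaseError` so the caller can skip the window).
    pattern:
        Optional spaced-seed mask of the same length; only care positions
        contribute, so two windows differing at don't-care positions hash
        identically.
    h:
        Number of derived hash values.
    """
    if h < 1:
        raise HashConfigError("h must be >= 1")
    return derive_hashes(canonical_base_hash(window, pattern), h)


@dataclass
class RollingHasher:
    """Rolling strand-invariant hash state over a read.

    For plain k-mers the forward and reverse hashes advance in O(1) per base;
    for spaced seeds each window's care substring is hashed from scratch
    (O(weight) per window), which satisfies the same contract.

    Use :func:`iter_hashes` for the common "hash every valid window of a read"
    loop, which also handles non-ACGT masking.
    """

    pattern: SpacedSeedPattern
    h: int = DEFAULT_NUM_HASHES
    position: int = 0  # 0-based start of the current window
    _f: int = field(default=0, repr=False)
    _r: int = field(default=0, repr=False)
    _codes: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.pattern.k

    def prime(self, window: str, position: int = 0) -> "RollingHasher":
        """Initialize the state on a valid window starting at ``position``."""
        codes = encode_sequence(window)
        if len(codes) != self.k:
            raise HashConfigError(f"window length {len(codes)} != k={self.k}")
        if (codes > 3).any():
            raise InvalidBaseError("non-ACGT base in window")
        self._codes = codes.copy()
        self.position = position
        if self.pattern.is_plain:
            self._f, self._r = _strand_hashes_codes(codes)
        return self

    def roll(self, out_base: str, in_base: str) -> "RollingHasher":
        """Advance by one base: drop ``out_base``, append ``in_base``.

        After rolling, :meth:`hashes` equals ``canonical_hashes`` of the
        shifted window.  A non-ACGT incoming base raises
        :class:`InvalidBaseError`; the state must then be re-primed at the
        next valid window.
        """
        if self._codes is None:
            raise HashConfigError("roll() before prime()")
        out_c = int(_CODE_LUT[ord(out_base)])
        in_c = int(_CODE_LUT[ord(in_base)])
        if out_c != self._codes[0]:
            raise HashConfigError("out_base does not match window start")
        if in_c > 3:
            self._codes = None
            raise InvalidBaseError("non-ACGT incoming base; re-prime at next valid window")
        k = self.k
        if self.pattern.is_plain:
            # classic rolling recurrences for the xor-rotate scheme
            self._f = _rol(self._f, 1) ^ _rol(_BASE_TABLE[out_c], k % 64) ^ _BASE_TABLE[in_c]
            self._r = (
                _rol(self._r, 63)
                ^ _rol(_BASE_TABLE[3 - out_c], 63)
                ^ _rol(_BASE_TABLE[3 - in_c], (k - 1) % 64)
            )
        self._codes = np.concatenate([self._codes[1:], [np.uint8(in_c)]])
        self.position += 1
        return self

    def base_hash(self) -> int:
        if self._codes is None:
            raise HashConfigError("state not primed")
        if self.pattern.is_plain:
            return min(self._f, self._r)
        f, r = _strand_hashes_codes(self._codes[self.pattern.care_positions])
        return min(f, r)

    def hashes(self) -> tuple[int, ...]:
        """HashTuple of the current window."""
        return derive_hashes(self.base_hash(), self.h)


def iter_hashes(seq: str, pattern: SpacedSeedPattern, h: int = DEFAULT_NUM_HASHES):
    """Yield ``(position, HashTuple)`` for every valid window of ``seq``.

    Windows containing a non-ACGT base are skipped; the rolling state resets
    at the next valid window.  Reads shorter than k yield nothing.
    """
    k = pattern.k
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return
    invalid = np.concatenate([[0], np.cumsum(codes > 3)])
    hasher = RollingHasher(pattern, h)
    primed_at = -2
    for i in range(n):
        if invalid[i + k] - invalid[i] > 0:
            primed_at = -2
            continue
        if primed_at == i - 1:
            hasher.roll(seq[i - 1].upper(), seq[i + k - 1].upper())
        else:
            hasher.prime(seq[i : i + k].upper(), i)
        primed_at = i
        yield i, hasher.hashes()
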