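"""Plain and counting Bloom filters with minimum-selection counting.

A Bloom filter (BF) is a bit array of size ``m`` addressed by ``h`` hash
values per element (index = hash mod m); it has one-sided error — false
positives are possible, false negatives are not.  A counting Bloom filter
(CBF) stores fixed-width unsigned counters instead of bits and reports the
minimum counter among the element's ``h`` addressed positions.  Increments
follow the minimal-increase rule: only the counters currently equal to the
minimum are bumped, which reduces overestimation while keeping the
"reported count >= true multiplicity" guarantee (absent decrements).
Counters saturate at ``2**width - 1`` and never wrap.

Filters serialize to a self-described binary format: an ASCII magic tag,
a little-endian uint32 header length, a JSON header (kind, version, m, h,
counter width, k/mask metadata, insert count, payload byte size) and the raw
array payload — 1 bit per position for a BF, ``width`` bits per counter for
a CBF.  The format is documented in the README so external code can parse it.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .hashing import DEFAULT_NUM_HASHES

__all__ = [
    "BloomFilter",
    "CountingBloomFilter",
    "bf_size_for",
    "save_filter",
    "load_filter",
    "FilterFormatError",
]

_MAGIC = b"KSBF"
_FORMAT_VERSION = 1


class FilterFormatError(ValueError):
    """Raised for unreadable, truncated, or wrong-version filter files."""


def bf_size_for(n: int, fpr: float, h: int = DEFAULT_NUM_HASHES) -> int:
    """Smallest array size ``m`` meeting a target false-positive rate.

    Inverts the Bloom filter false-positive formula
    ``(1 - exp(-h*n/m))**h <= fpr`` for ``m`` given the expected number of
    insertions ``n`` and hash count ``h``.  The result is rounded up to a
    multiple of 8 so BF payloads are whole bytes.
    """
    if not 0.0 < fpr < 1.0:
        raise ValueError(f"fpr must be in (0, 1), got {fpr}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if h < 1:
        raise ValueError("h must be >= 1")
    # fpr^(1/h) = 1 - exp(-h n / m)  =>  m = h n / -ln(1 - fpr^(1/h))
    root = fpr ** (1.0 / h)
    m = math.ceil(h * n / -math.log1p(-root))
    return ((m + 7) // 8) * 8


def _positions(hash_values: Sequence[int] | np.ndarray, m: int) -> np.ndarray:
    arr = np.asarray(hash_values, dtype=np.uint64)
    return (arr % np.uint64(m)).astype(np.int64)


@dataclass
class _FilterBase:
    m: int
    h: int = DEFAULT_NUM_HASHES
    k: int | None = None
    mask: str | None = None
    n_inserted: int = 0

    def _check(self) -> None:
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if self.h < 1:
            raise ValueError("h must be >= 1")


class BloomFilter(_FilterBase):
    """Probabilistic set over hash tuples; bits packed on numpy uint8."""

    def __init__(self, m, h=DEFAULT_NUM_HASHES, k=None, mask=None):
        super().__init__(m=int(m), h=int(h), k=k, mask=mask)
        self._check()
        self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)

    @classmethod
    def sized_for(cls, n: int, fpr: float, h: int = DEFAULT_NUM_HASHES, **kw) -> "BloomFilter":
        return cls(bf_size_for(n, fpr, h), h, **kw)

    def insert(self, hash_values: Sequence[int]) -> None:
        idx = _positions(hash_values, self.m)
        np.bitwise_or.at(self.bits, idx >> 3, np.uint8(1) << (idx & 7).astype(np.uint8))
        self.n_inserted += 1

    def contains(self, hash_values: Sequence[int]) -> bool:
        idx = _positions(hash_values, self.m)
        sel = self.bits[idx >> 3] >> (idx & 7).astype(np.uint8)
        return bool((sel & 1).all())

    def clear(self) -> None:
        self.bits[:] = 0

    @property
    def payload_nbytes(self) -> int:
        return self.bits.nbytes

    def theoretical_fpr(self, n: int | None = None) -> float:
        n = self.n_inserted if n is None else n
        return (1.0 - math.exp(-self.h * n / self.m)) ** self.h


class CountingBloomFilter(_FilterBase):
    """Counting Bloom filter with minimum-selection queries.

    ``width`` is the counter width in bits (8 by default, per the 255-cap
    convention); counters are stored in the smallest numpy unsigned dtype
    that holds ``width`` bits and saturate at ``2**width - 1``.
    """

    def __init__(self, m, h=DEFAULT_NUM_HASHES, width=8, k=None, mask=None):
        super().__init__(m=int(m), h=int(h), k=k, mask=mask)
        self._check()
        if not 1 <= width <= 32:
            raise ValueError("counter width must be in [1, 32] bits")
        self.width = int(width)
        dtype = np.uint8 if width <= 8 else (np.uint16 if width <= 16 else np.uint32)
        self.counters = np.zeros(self.m, dtype=dtype)

    @classmethod
    def sized_for(cls, n, fpr, h=DEFAULT_NUM_HASHES, **kw) -> "CountingBloomFilter":
        return cls(bf_size_for(n, fpr, h), h, **kw)

    @property
    def cap(self) -> int:
        return (1 << self.width) - 1

    def count(self, hash_values: Sequence[int]) -> int:
        """Reported count = minimum over the h addressed counters."""
        idx = _positions(hash_values, self.m)
        return int(self.counters[idx].min())

    def increment(self, hash_values: Sequence[int]) -> int:
        """Minimal-increase increment; returns the new reported count.

        Only the counters currently equal to the minimum are incremented,
        and never beyond the saturation cap.
        """
        idx = _positions(hash_values, self.m)
        vals = self.counters[idx]
        mn = vals.min()
        if mn < self.cap:
            self.counters[idx[vals == mn]] = mn + 1
            mn += 1
        self.n_inserted += 1
        return int(mn)

    def decrement(self, hash_values: Sequence[int], amount: int = 1) -> None:
        """Reduce each addressed counter by ``min(amount, counter)`` (floor 0)."""
        if amount < 1:
            raise ValueError("amount must be a positive int")
        idx = np.unique(_positions(hash_values, self.m))
        vals = self.counters[idx]
        self.counters[idx] = np.where(vals > amount, vals - amount, 0).astype(vals.dtype)

    def clear(self) -> None:
        self.counters[:] = 0

    @property
    def payload_nbytes(self) -> int:
        return self.counters.nbytes


def save_filter(flt: BloomFilter | CountingBloomFilter, path) -> None:
    """Serialize a filter: magic, uint32 header length, JSON header, payload."""
    if isinstance(flt, CountingBloomFilter):
        kind, width, payload = "cbf", flt.width, flt.counters.tobytes()
    elif isinstance(flt, BloomFilter):
        kind, width, payload = "bf", 1, flt.bits.tobytes()
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a filter: {type(flt)}")
    header = {
        "kind": kind,
        "version": _FORMAT_VERSION,
        "m": flt.m,
        "h": flt.h,
        "width": width,
        "k": flt.k,
        "mask": flt.mask,
        "n_inserted": flt.n_inserted,
        "payload_nbytes": len(payload),
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.write(payload)


def load_filter(path) -> BloomFilter | CountingBloomFilter:
    """Load a filter written by :func:`save_filter`; validates the header."""
    data = Path(path).read_bytes()
    if data[:4] != _MAGIC:
        raise FilterFormatError(f"{path}: bad magic tag")
    if len(data) < 8:
        raise FilterFormatError(f"{path}: truncated header")
    (hlen,) = struct.unpack("<I", data[4:8])
    try:
        header = json.loads(data[8 : 8 + hlen])
    except (ValueError, UnicodeDecodeError) as exc:
        raise FilterFormatError(f"{path}: unreadable header: {exc}") from None
    if header.get("version") != _FORMAT_VERSION:
        raise FilterFormatError(f"{path}: unsupported format version {header.get('version')}")
    payload = data[8 + hlen :]
    if len(payload) != header["payload_nbytes"]:
        raise FilterFormatError(
            f"{path}: truncated payload ({len(payload)} of {header['payload_nbytes']} bytes)"
        )
    meta = dict(k=header["k"], mask=header["mask"])
    if header["kind"] == "bf":
        flt = BloomFilter(header["m"], header["h"], **meta)
        flt.bits = np.frombuffer(payload, dtype=np.uint8).copy()
    elif header["kind"] == "cbf":
        flt = CountingBloomFilter(header["m"], header["h"], width=header["width"], **meta)
        flt.counters = np.frombuffer(payload, dtype=flt.counters.dtype).copy()
    else:
        raise FilterFormatError(f"{path}: unknown filter kind {header['kind']!r}")
    flt.n_inserted = header["n_inserted"]
    return flt
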