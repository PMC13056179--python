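"""k-mer count histograms: parsing, exact construction, and comparison.

A k-mer count histogram is the counts-of-counts vector (h_1, ..., h_c):
h_i is the number of distinct (canonical) k-mers occurring exactly i times
in a read set, and c is the largest observed count.  It is the input of the
mixture-model analysis in :mod:`kmerstat.mixture` and the sizing input for
cascade planning.

The on-disk dialect is the two-column whitespace-separated text emitted by
streaming histogram estimators: rows whose first token is an integer ``i``
carry ``h_i``; rows keyed ``F0``/``F1`` carry the distinct/total metadata;
unknown non-integer keys are skipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import jensenshannon

__all__ = [
    "KmerHistogram",
    "load_histogram",
    "save_histogram",
    "histogram_from_counts",
    "histogram_from_reads",
    "histogram_similarity",
    "HistogramFormatError",
]

logger = logging.getLogger(__name__)


class HistogramFormatError(ValueError):
    """Raised for malformed histogram files."""


@dataclass
class KmerHistogram:
    """Counts-of-counts vector with totals and optional file metadata.

    ``values[i-1]`` is h_i for i = 1..c.  ``f0``/``f1`` carry the metadata
    rows of the input file when present (estimated distinct k-mers and total
    k-mer occurrences, possibly differing from the column sums for
    subsampled estimates).
    """

    values: np.ndarray
    f0: int | None = None
    f1: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise HistogramFormatError("histogram needs at least one bin")
        if (self.values < 0).any():
            raise HistogramFormatError("negative histogram values")

    @property
    def c(self) -> int:
        """Maximum k-mer count represented."""
        return len(self.values)

    @property
    def total_distinct(self) -> int:
        """Number of distinct k-mers (sum of h_i)."""
        return int(self.values.sum())

    @property
    def total_occurrences(self) -> int:
        """Total k-mer occurrences (sum of i * h_i)."""
        return int((np.arange(1, self.c + 1, dtype=np.int64) * self.values).sum())

    def get(self, i: int) -> int:
        """h_i (0 outside 1..c)."""
        return int(self.values[i - 1]) if 1 <= i <= self.c else 0

    def normalized(self) -> np.ndarray:
        """h as a probability vector over counts 1..c."""
        total = self.values.sum()
        if total == 0:
            raise HistogramFormatError("empty histogram cannot be normalized")
        return self.values / total


def load_histogram(path) -> KmerHistogram:
    """Parse a two-column count histogram file."""
    bins: dict[int, int] = {}
    f0 = f1 = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise HistogramFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        key, val = parts
        try:
            value = int(float(val))
        except ValueError:
            raise HistogramFormatError(f"{path}:{lineno}: non-numeric value {val!r}") from None
        if key == "F0":
            f0 = value
        elif key == "F1":
            f1 = value
        elif key.isdigit() or (key[0] == "-" and key[1:].isdigit()):
            i = int(key)
            if i < 1 or value < 0:
                raise HistogramFormatError(f"{path}:{lineno}: invalid row {line!r}")
            bins[i] = value
        else:
            warnings.warn(f"{path}:{lineno}: skipping unknown row key {key!r}")
    if not bins:
        raise HistogramFormatError(f"{path}: no integer histogram rows found")
    c = max(bins)
    values = np.zeros(c, dtype=np.int64)
    for i, v in bins.items():
        values[i - 1] = v
    return KmerHistogram(values, f0=f0, f1=f1)


def save_histogram(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"F0\t{hist.f0 if hist.f0 is not None else hist.total_distinct}\n")
        fh.write(f"F1\t{hist.f1 if hist.f1 is not None else hist.total_occurrences}\n")
        for i, v in enumerate(hist.values, start=1):
            fh.write(f"{i}\t{int(v)}\n")


def histogram_from_counts(counts: np.ndarray, max_count: int | None = None) -> KmerHistogram:
    """Histogram from per-distinct-k-mer multiplicities.

    Counts above ``max_count`` (when given) are folded into the top bin so a
    fixed support can be enforced; by default the support runs to the
    maximum observed count.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise HistogramFormatError("no k-mer counts supplied")
    if max_count is not None:
        counts = np.minimum(counts, max_count)
    values = np.bincount(counts, minlength=int(counts.max()) + 1)[1:]
    return KmerHistogram(values)


def exact_counts(reads, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact multiplicity of every distinct canonical k-mer (plain, k<=32).

    Returns (packed canonical k-mers, counts), both sorted by k-mer.  This is
    the dictionary-style oracle used for accuracy evaluation and for building
    noise-free histograms from simulated read sets.
    """
    from .cascade import scan_reads

    res = scan_reads(reads, k, pack=True)
    if res.packed is None or len(res.packed) == 0:
        raise HistogramFormatError("reads contained no valid k-mer windows")
    distinct, counts = np.unique(res.packed, return_counts=True)
    return distinct, counts


def histogram_from_reads(reads, k: int, max_count: int | None = None) -> KmerHistogram:
    """Exact count histogram of a read set (canonical k-mers, k <= 32)."""
    _, counts = exact_counts(reads, k)
    return histogram_from_counts(counts, max_count=max_count)


def histogram_similarity(a: KmerHistogram, b: KmerHistogram) -> float:
    """Jensen-Shannon similarity between two histograms, in [0, 1].

    The histograms are normalized over their common support (shorter one
    zero-padded); similarity = 1 - JSD with base-2 logarithms, so identical
    normalized histograms score 1 and disjoint supports score 0.
    """
    c = max(a.c, b.c)
    pa = np.zeros(c)
    pb = np.zeros(c)
    pa[: a.c] = a.normalized()
    pb[: b.c] = b.normalized()
    # scipy returns the JS *distance* (sqrt of the divergence)
    jsd = jensenshannon(pa, pb, base=2) ** 2
    if np.isnan(jsd):  # two all-zero vectors cannot reach here (normalized)
        jsd = 0.0
    return float(1.0 - jsd)
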