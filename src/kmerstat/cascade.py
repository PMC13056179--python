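"""Layered Bloom-filter counting with [C_min, C_max] thresholds and depths.

The cascade routes each k-mer occurrence through up to four structures:

* a **global BF** marking k-mers seen at least once (allocated when
  ``c_min >= 2``);
* an **intermediate CBF** accumulating occurrences 2..c_min-1 (allocated when
  ``c_min >= 3``) — most k-mers in sequencing data occur once, so keeping
  them out of counting structures saves most of the memory;
* the **output structure** (CBF for counts, BF for membership) receiving the
  c_min-th and later occurrences; a reported count is the stored counter plus
  ``c_min - 1``;
* an optional **secondary BF** recording k-mers whose reported count crossed
  ``c_max``; on crossing, the k-mer's reported value is decremented from its
  own counters (minimum rule) so it disappears from the output.

Filters are sized from a k-mer count histogram through the Bloom filter
false-positive formula at the target error rate ``e`` (0.001 by default)
with 7 hash functions, so the caller controls the accuracy/memory trade-off
with a single knob.

Depth extraction (the number of distinct reads containing each k-mer — the
document-frequency half of the TF-IDF analogue) runs in the same pass: a
per-read scratch BF deduplicates k-mers within a read and a global depth CBF
is incremented once per read per k-mer.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .bloom import BloomFilter, CountingBloomFilter, bf_size_for, save_filter
from .hashing import (
    DEFAULT_NUM_HASHES,
    SpacedSeedPattern,
    canonical_base_hash,
    derive_hashes,
    encode_sequence,
)

__all__ = [
    "CascadeConfig",
    "FilterPlan",
    "CountStore",
    "DepthStore",
    "ScanResult",
    "plan_sizes",
    "count_reads",
    "get_count",
    "get_depth",
    "export_tsv",
    "scan_reads",
    "packed_to_kmer",
]

_SCRATCH_FPR = 1e-4  # per-read scratch BF target FPR ("negligible" contract)


class CascadeConfigError(ValueError):
    """Invalid or inconsistent cascade configuration."""


class SizingError(ValueError):
    """Raised when no histogram or explicit sizes are available for planning."""


@dataclass
class CascadeConfig:
    """Parameters of one counting run.

    Attributes
    ----------
    k : k-mer length.
    mask : optional spaced-seed pattern (defaults to the all-ones mask).
    c_min, c_max : occurrence thresholds for a k-mer to be retained.
    error_rate : target Bloom-filter false-positive rate ``e`` used to size
        every filter in the cascade (default 0.001).
    output : ``"counts"`` for a counting output filter, ``"membership"`` for
        a plain BF (8x smaller, membership queries only).
    depth : extract per-read depth alongside counts.
    secondary : record over-``c_max`` k-mers in a secondary BF so later
        occurrences are ignored (otherwise they simply restart accumulating).
    counter_width : CBF counter width in bits; 8 by default, which caps
        counts (and hence admissible ``c_max``) at 255.
    """

    k: int
    mask: SpacedSeedPattern | str | None = None
    c_min: int = 1
    c_max: int = 255
    error_rate: float = 0.001
    num_hashes: int = DEFAULT_NUM_HASHES
    output: str = "counts"
    depth: bool = False
    secondary: bool = False
    counter_width: int = 8

    def __post_init__(self) -> None:
        if isinstance(self.mask, str):
            self.mask = SpacedSeedPattern(self.mask)
        if self.mask is None:
            self.mask = SpacedSeedPattern.all_ones(self.k)
        if self.mask.k != self.k:
            raise CascadeConfigError(f"mask length {self.mask.k} != k={self.k}")
        cap = (1 << self.counter_width) - 1
        if not 1 <= self.c_min <= self.c_max:
            raise CascadeConfigError("need 1 <= c_min <= c_max")
        if self.c_max > cap:
            raise CascadeConfigError(
                f"c_max={self.c_max} exceeds the {self.counter_width}-bit counter cap {cap}"
            )
        if not 0.0 < self.error_rate < 1.0:
            raise CascadeConfigError("error_rate must be in (0, 1)")
        if self.output not in ("counts", "membership"):
            raise CascadeConfigError("output must be 'counts' or 'membership'")

    @property
    def uses_global(self) -> bool:
        return self.c_min >= 2

    @property
    def uses_intermediate(self) -> bool:
        return self.c_min >= 3


@dataclass
class FilterPlan:
    """Expected insertions (n_*) and bit/counter array sizes (m_*) per layer.

    Layers not allocated under the config's thresholds have n = m = 0.
    """

    n_global: int = 0
    n_intermediate: int = 0
    n_output: int = 0
    n_secondary: int = 0
    n_depth: int = 0
    m_global: int = 0
    m_intermediate: int = 0
    m_output: int = 0
    m_secondary: int = 0
    m_depth: int = 0


def plan_sizes(
    config: CascadeConfig,
    histogram=None,
    distinct_counts: dict | None = None,
) -> FilterPlan:
    """Size every filter of the cascade from a count histogram.

    The global BF holds all distinct k-mers (sum of h_i), the intermediate
    CBF those occurring at least twice, the output structure those occurring
    at least ``c_min`` times, and the secondary BF those beyond ``c_max``;
    each is sized by :func:`kmerstat.bloom.bf_size_for` at the configured
    error rate.  ``distinct_counts`` may instead supply explicit expected
    insertions with keys among {"global", "intermediate", "output",
    "secondary", "depth"}.
    """
    if histogram is None and distinct_counts is None:
        raise SizingError(
            "filter sizing needs a k-mer count histogram or explicit distinct-count "
            "estimates; supply histogram=... or distinct_counts=..."
        )
    plan = FilterPlan()
    if histogram is not None:
        h = np.asarray(histogram.values, dtype=np.float64)
        total = int(h.sum())
        n_global = total
        n_inter = int(h[1:].sum())
        n_out = int(h[config.c_min - 1 :].sum())
        n_sec = int(h[config.c_max :].sum()) if config.c_max <= len(h) else 0
        n_depth = total
    else:
        n_global = int(distinct_counts.get("global", 0))
        n_inter = int(distinct_counts.get("intermediate", n_global))
        n_out = int(distinct_counts.get("output", n_global))
        n_sec = int(distinct_counts.get("secondary", 0))
        n_depth = int(distinct_counts.get("depth", n_global))
        if n_out <= 0:
            raise SizingError("distinct_counts must include a positive 'output' estimate")

    e, nh = config.error_rate, config.num_hashes
    size = lambda n: bf_size_for(max(n, 1), e, nh)
    if config.uses_global:
        plan.n_global, plan.m_global = n_global, size(n_global)
    if config.uses_intermediate:
        plan.n_intermediate, plan.m_intermediate = n_inter, size(n_inter)
    plan.n_output, plan.m_output = n_out, size(n_out)
    if config.secondary:
        plan.n_secondary, plan.m_secondary = n_sec, size(n_sec)
    if config.depth:
        plan.n_depth, plan.m_depth = n_depth, size(n_depth)
    return plan


@dataclass
class DepthStore:
    """Global depth CBF; reports the number of reads containing a k-mer."""

    config: CascadeConfig
    depth_cbf: CountingBloomFilter

    def depth_for_hash(self, base_hash: int) -> int:
        return self.depth_cbf.count(derive_hashes(base_hash, self.config.num_hashes))

    def depths_for_hashes(self, base_hashes: np.ndarray) -> np.ndarray:
        out = np.zeros(len(base_hashes), dtype=np.int64)
        _kernels.query_cbf_kernel(
            np.ascontiguousarray(base_hashes, dtype=np.uint64),
            self.config.num_hashes,
            self.depth_cbf.counters,
            self.depth_cbf.m,
            out,
        )
        return out


@dataclass
class CountStore:
    """The filters produced by one counting run, plus query methods."""

    config: CascadeConfig
    plan: FilterPlan
    global_bf: BloomFilter | None = None
    intermediate_cbf: CountingBloomFilter | None = None
    output_cbf: CountingBloomFilter | None = None
    output_bf: BloomFilter | None = None
    secondary_bf: BloomFilter | None = None
    depth: DepthStore | None = None
    n_short_reads: int = 0
    n_skipped_windows: int = 0
    n_windows: int = 0

    @classmethod
    def allocate(cls, config: CascadeConfig, plan: FilterPlan) -> "CountStore":
        store = cls(config=config, plan=plan)
        meta = dict(k=config.k, mask=config.mask.mask)
        nh, w = config.num_hashes, config.counter_width
        if config.uses_global:
            store.global_bf = BloomFilter(plan.m_global, nh, **meta)
        if config.uses_intermediate:
            store.intermediate_cbf = CountingBloomFilter(plan.m_intermediate, nh, width=w, **meta)
        if config.output == "counts":
            store.output_cbf = CountingBloomFilter(plan.m_output, nh, width=w, **meta)
        else:
            store.output_bf = BloomFilter(plan.m_output, nh, **meta)
        if config.secondary:
            store.secondary_bf = BloomFilter(plan.m_secondary, nh, **meta)
        if config.depth:
            store.depth = DepthStore(
                config, CountingBloomFilter(plan.m_depth, nh, width=w, **meta)
            )
        return store

    # -- queries ---------------------------------------------------------

    def _base_hash(self, kmer: str) -> int:
        return canonical_base_hash(kmer, self.config.mask)

    def count_for_hash(self, base_hash: int) -> int:
        cfg = self.config
        if self.output_cbf is None:
            raise CascadeConfigError("membership output has no counts; use contains()")
        hv = derive_hashes(base_hash, cfg.num_hashes)
        if self.secondary_bf is not None and self.secondary_bf.contains(hv):
            return 0
        stored = self.output_cbf.count(hv)
        return stored + cfg.c_min - 1 if stored > 0 else 0

    def get_count(self, kmer: str) -> int:
        """Reported count of one k-mer: 0 below c_min / beyond c_max."""
        return self.count_for_hash(self._base_hash(kmer))

    def counts_for_hashes(self, base_hashes: np.ndarray) -> np.ndarray:
        cfg = self.config
        if self.output_cbf is None:
            raise CascadeConfigError("membership output has no counts; use contains()")
        out = np.zeros(len(base_hashes), dtype=np.int64)
        use_sec = self.secondary_bf is not None
        _kernels.query_counts_kernel(
            np.ascontiguousarray(base_hashes, dtype=np.uint64),
            cfg.num_hashes,
            cfg.c_min,
            self.output_cbf.counters,
            self.output_cbf.m,
            self.output_cbf.cap,
            use_sec,
            self.secondary_bf.bits if use_sec else np.zeros(1, dtype=np.uint8),
            self.secondary_bf.m if use_sec else 8,
            out,
        )
        return out

    def contains(self, kmer: str) -> bool:
        """Membership query against the output structure."""
        hv = derive_hashes(self._base_hash(kmer), self.config.num_hashes)
        if self.secondary_bf is not None and self.secondary_bf.contains(hv):
            return False
        if self.output_bf is not None:
            return self.output_bf.contains(hv)
        return self.output_cbf.count(hv) > 0

    def get_depth(self, kmer: str) -> int:
        if self.depth is None:
            raise CascadeConfigError("depth extraction was not enabled for this run")
        return self.depth.depth_for_hash(self._base_hash(kmer))

    # -- persistence -----------------------------------------------------

    def save(self, prefix) -> list[Path]:
        """Write each allocated filter as ``<prefix>.<layer>.ksbf``."""
        prefix = Path(prefix)
        written = []
        parts = {
            "global": self.global_bf,
            "intermediate": self.intermediate_cbf,
            "counts": self.output_cbf,
            "membership": self.output_bf,
            "secondary": self.secondary_bf,
            "depth": self.depth.depth_cbf if self.depth else None,
        }
        for name, flt in parts.items():
            if flt is not None:
                path = prefix.with_name(prefix.name + f".{name}.ksbf")
                save_filter(flt, path)
                written.append(path)
        return written


# -- read scanning -------------------------------------------------------


@dataclass
class ScanResult:
    """Hashed windows of a batch of reads (one entry per valid window)."""

    hashes: np.ndarray  # uint64 canonical base hashes
    read_ids: np.ndarray  # int64 read index within the batch
    packed: np.ndarray | None  # uint64 canonical packed k-mers (plain k <= 32)
    n_reads: int
    n_short_reads: int
    n_skipped_windows: int


def _as_sequences(reads) -> Iterator[str]:
    """Accept a path, an iterable of strings, or of record-like objects."""
    if isinstance(reads, (str, Path)):
        from .io import read_sequences

        for rec in read_sequences(reads):
            yield rec.sequence
        return
    for item in reads:
        yield getattr(item, "sequence", item)


def _flatten(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    codes = np.empty(int(offsets[-1]), dtype=np.uint8)
    for i, s in enumerate(seqs):
        codes[offsets[i] : offsets[i + 1]] = encode_sequence(s)
    return codes, offsets


def scan_reads(
    reads,
    k: int,
    pattern: SpacedSeedPattern | None = None,
    pack: bool | None = None,
) -> ScanResult:
    """Hash every valid window of a read set in one vectorized pass.

    ``pack=True`` additionally emits canonical 2-bit-packed k-mers (plain
    k-mers with k <= 32 only), the currency of the exact-counting oracle and
    the ground-truth labelling in :mod:`kmerstat.simulate`.
    """
    seqs = list(_as_sequences(reads))
    pattern = pattern or SpacedSeedPattern.all_ones(k)
    if pattern.k != k:
        raise CascadeConfigError(f"mask length {pattern.k} != k={k}")
    if pack is None:
        pack = pattern.is_plain and k <= 32
    if pack and (not pattern.is_plain or k > 32):
        raise CascadeConfigError("packed k-mers need a plain mask and k <= 32")
    codes, offsets = _flatten(seqs)
    lengths = np.diff(offsets)
    max_windows = int(np.maximum(lengths - k + 1, 0).sum())
    hashes = np.empty(max_windows, dtype=np.uint64)
    read_ids = np.empty(max_windows, dtype=np.int64)
    packed = np.empty(max_windows if pack else 0, dtype=np.uint64)
    if pattern.is_plain:
        nw = _kernels.scan_kernel(codes, offsets, k, pack, hashes, read_ids, packed)
    else:
        care = pattern.care_positions.astype(np.int64)
        nw = _kernels.scan_kernel_spaced(codes, offsets, k, care, hashes, read_ids)
    n_short = int((lengths < k).sum())
    return ScanResult(
        hashes=hashes[:nw],
        read_ids=read_ids[:nw],
        packed=packed[:nw] if pack else None,
        n_reads=len(seqs),
        n_short_reads=n_short,
        n_skipped_windows=max_windows - nw,
    )


def hashes_for_packed(packed: np.ndarray, k: int) -> np.ndarray:
    """Canonical base hashes for packed canonical k-mers."""
    out = np.empty(len(packed), dtype=np.uint64)
    _kernels.hashes_from_packed(np.ascontiguousarray(packed, dtype=np.uint64), k, out)
    return out


def packed_to_kmer(packed: int, k: int) -> str:
    """Decode a 2-bit-packed k-mer back to its string form."""
    return "".join("ACGT"[(int(packed) >> (2 * (k - 1 - j))) & 3] for j in range(k))


# -- counting ------------------------------------------------------------


def count_reads(
    reads,
    config: CascadeConfig,
    histogram=None,
    plan: FilterPlan | None = None,
    distinct_counts: dict | None = None,
    chunk_reads: int = 200_000,
) -> CountStore:
    """Run the cascade over a read stream and return the populated store.

    Reads may be a FASTA/FASTQ path (plain or gzipped), an iterable of
    sequence strings, or of record objects with a ``sequence`` attribute.
    Filter sizes come from ``plan`` if given, else from ``histogram`` /
    ``distinct_counts`` via :func:`plan_sizes`.  Reads shorter than k are
    skipped and tallied, as are windows containing non-ACGT bases.
    Processing is single-threaded and in input order, so results are
    deterministic.
    """
    if plan is None:
        plan = plan_sizes(config, histogram=histogram, distinct_counts=distinct_counts)
    store = CountStore.allocate(config, plan)
    nh = config.num_hashes

    dummy_bits = np.zeros(1, dtype=np.uint8)
    dummy_cnt = np.zeros(1, dtype=np.uint8)
    scratch_bits = np.zeros(0, dtype=np.uint8)
    scratch_pos = np.zeros(0, dtype=np.uint64)
    scratch_m = 8

    batch: list[str] = []

    def run_batch(seqs: list[str]) -> None:
        nonlocal scratch_bits, scratch_pos, scratch_m
        res = scan_reads(seqs, config.k, config.mask, pack=False)
        store.n_short_reads += res.n_short_reads
        store.n_skipped_windows += res.n_skipped_windows
        store.n_windows += len(res.hashes)
        if config.depth:
            max_read_windows = max(
                1, max((len(s) - config.k + 1 for s in seqs), default=1)
            )
            need_m = bf_size_for(max_read_windows, _SCRATCH_FPR, nh)
            if need_m > scratch_m or scratch_bits.size == 0:
                scratch_m = need_m
                scratch_bits = np.zeros((scratch_m + 7) // 8, dtype=np.uint8)
                scratch_pos = np.zeros(max_read_windows * nh, dtype=np.uint64)
            elif scratch_pos.size < max_read_windows * nh:
                scratch_pos = np.zeros(max_read_windows * nh, dtype=np.uint64)
        _kernels.count_kernel(
            res.hashes,
            res.read_ids,
            nh,
            config.c_min,
            config.c_max,
            config.uses_global,
            store.global_bf.bits if store.global_bf is not None else dummy_bits,
            store.global_bf.m if store.global_bf is not None else 8,
            config.uses_intermediate,
            store.intermediate_cbf.counters if store.intermediate_cbf is not None else dummy_cnt,
            store.intermediate_cbf.m if store.intermediate_cbf is not None else 1,
            config.output == "membership",
            store.output_bf.bits if store.output_bf is not None else dummy_bits,
            store.output_cbf.counters if store.output_cbf is not None else dummy_cnt,
            store.output_bf.m if store.output_bf is not None else store.output_cbf.m,
            store.output_cbf.cap if store.output_cbf is not None else 255,
            config.secondary,
            store.secondary_bf.bits if store.secondary_bf is not None else dummy_bits,
            store.secondary_bf.m if store.secondary_bf is not None else 8,
            config.depth,
            store.depth.depth_cbf.counters if store.depth is not None else dummy_cnt,
            store.depth.depth_cbf.m if store.depth is not None else 1,
            store.depth.depth_cbf.cap if store.depth is not None else 255,
            scratch_bits if config.depth else dummy_bits,
            scratch_m,
            scratch_pos,
        )

    for seq in _as_sequences(reads):
        batch.append(seq)
        if len(batch) >= chunk_reads:
            run_batch(batch)
            batch = []
    if batch:
        run_batch(batch)
    return store


# -- module-level query/export conveniences ------------------------------


def get_count(store: CountStore, kmer: str) -> int:
    """Reported count of ``kmer``: 0 if below c_min or filtered above c_max."""
    return store.get_count(kmer)


def get_depth(store: CountStore | DepthStore, kmer: str) -> int:
    """Number of reads containing ``kmer`` (depth <= count by construction)."""
    if isinstance(store, DepthStore):
        return store.depth_for_hash(canonical_base_hash(kmer, store.config.mask))
    return store.get_depth(kmer)


def export_tsv(store: CountStore, reads, path=None) -> int:
    """Write ``kmer<TAB>count[<TAB>depth]`` rows for retained k-mers.

    Bloom filters cannot enumerate their contents, so the distinct k-mers are
    re-derived from a second pass over ``reads``.  Returns the number of rows
    written; rows are canonical k-mers with ``c_min <= count <= c_max``.
    """
    cfg = store.config
    out = sys.stdout if path is None else open(path, "w")
    close = path is not None
    try:
        header = ["kmer", "count"] + (["depth"] if store.depth is not None else [])
        out.write("\t".join(header) + "\n")
        n = 0
        if cfg.mask.is_plain and cfg.k <= 32:
            res = scan_reads(reads, cfg.k, cfg.mask, pack=True)
            distinct = np.unique(res.packed)
            hashes = hashes_for_packed(distinct, cfg.k)
            counts = store.counts_for_hashes(hashes)
            depths = store.depth.depths_for_hashes(hashes) if store.depth else None
            keep = counts > 0
            for i in np.flatnonzero(keep):
                row = [packed_to_kmer(int(distinct[i]), cfg.k), str(int(counts[i]))]
                if depths is not None:
                    row.append(str(int(depths[i])))
                out.write("\t".join(row) + "\n")
                n += 1
        else:
            from .hashing import canonical_kmer, iter_hashes

            seen: set[str] = set()
            for seq in _as_sequences(reads):
                for pos, _ in iter_hashes(seq, cfg.mask, cfg.num_hashes):
                    seen.add(canonical_kmer(seq[pos : pos + cfg.k], cfg.mask))
            for kmer in sorted(seen):
                # spaced-seed canonical forms are care-position substrings
                c = store.count_for_hash(canonical_base_hash(kmer))
                if c > 0:
                    row = [kmer, str(c)]
                    if store.depth is not None:
                        row.append(str(store.depth.depth_for_hash(canonical_base_hash(kmer))))
                    out.write("\t".join(row) + "\n")
                    n += 1
        return n
    finally:
        if close:
            out.close()
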