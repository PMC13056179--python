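"""Synthetic diploid genomes, error-bearing reads, and ground-truth labels.

This module generates the controlled inputs the rest of the package is
validated against, emulating the standard simulation design for k-mer
spectrum studies at desk scale: a random haploid sequence is copied into a
second haplotype carrying single-nucleotide variants (and optionally short
indels) at stated rates, reads are drawn uniformly from both haplotypes with
iid substitution errors, and every distinct read k-mer is labelled against
the two haplotypes:

* **robust** — present in at least one haplotype (i.e. not an artifact);
* **heterozygous** — present in exactly one haplotype (robust by definition);
* **error** — present in neither haplotype.

The simulators are intentionally simple (uniform start positions, iid
errors, flat quality strings): they reproduce the statistical structure the
histogram model assumes — an error component plus heterozygous and
homozygous coverage peaks — not any platform's empirical error profile.
Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReadRecord

__all__ = [
    "DiploidGenome",
    "GroundTruthLabels",
    "make_diploid",
    "simulate_reads",
    "label_kmers",
    "pack_kmers",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Long-read mode defaults: mean length and gamma shape of the length law.
LONG_READ_MEAN = 2000.0
LONG_READ_SHAPE = 3.0


@dataclass
class DiploidGenome:
    """Two haplotypes differing exactly at the recorded variants."""

    hap_a: str
    hap_b: str
    variants: list[tuple[int, str, str, str]]  # (pos in A, kind, ref, alt)
    snv_rate: float
    indel_rate: float
    seed: int

    @property
    def n_snvs(self) -> int:
        return sum(1 for v in self.variants if v[1] == "snv")

    @property
    def n_indels(self) -> int:
        return sum(1 for v in self.variants if v[1] != "snv")


def _random_codes(length: int, rng) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def make_diploid(
    length: int,
    snv_rate: float = 0.001,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> DiploidGenome:
    """Random haploid sequence plus a mutated copy as the second haplotype.

    Each position of haplotype A independently carries an SNV in haplotype B
    with probability ``snv_rate`` (substituted to a uniformly random other
    base) and a short indel (1-3 bp insertion or deletion, equiprobable)
    with probability ``indel_rate``.  The realized variant count is
    binomial; positions and alleles are recorded.
    """
    if not 0.0 <= snv_rate <= 0.05 or not 0.0 <= indel_rate <= 0.05:
        raise ValueError("variant rates must be in [0, 0.05]")
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    a = _random_codes(length, rng)
    b = a.copy()
    variants: list[tuple[int, str, str, str]] = []

    snv_pos = np.flatnonzero(rng.random(length) < snv_rate)
    # substitute to one of the three other bases
    shifts = rng.integers(1, 4, size=len(snv_pos)).astype(np.uint8)
    b[snv_pos] = (b[snv_pos] + shifts) % 4
    for pos in snv_pos:
        variants.append((int(pos), "snv", "ACGT"[a[pos]], "ACGT"[b[pos]]))

    if indel_rate > 0:
        indel_pos = np.flatnonzero(rng.random(length) < indel_rate)
        indel_pos = np.setdiff1d(indel_pos, snv_pos)
        pieces = []
        prev = 0
        for pos in indel_pos:
            sizes = int(rng.integers(1, 4))
            pieces.append(b[prev : pos + 1])
            if rng.random() < 0.5:  # insertion after pos
                ins = _random_codes(sizes, rng)
                pieces.append(ins)
                variants.append((int(pos), "ins", "", _codes_to_str(ins)))
            else:  # deletion of up to `sizes` following bases
                del_end = min(pos + 1 + sizes, length)
                variants.append((int(pos), "del", _codes_to_str(a[pos + 1 : del_end]), ""))
                prev = del_end
                continue
            prev = pos + 1
        pieces.append(b[prev:])
        b = np.concatenate(pieces)

    return DiploidGenome(
        hap_a=_codes_to_str(a),
        hap_b=_codes_to_str(b),
        variants=sorted(variants),
        snv_rate=snv_rate,
        indel_rate=indel_rate,
        seed=seed,
    )


def simulate_reads(
    genome: DiploidGenome,
    coverage: float,
    read_length: float = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    mode: str = "short",
) -> list[ReadRecord]:
    """Draw reads uniformly from both haplotypes with iid substitution errors.

    ``coverage`` is per haploid genome (total bases ~= coverage x haploid
    length).  In ``"short"`` mode all reads have length ``read_length``; in
    ``"long"`` mode lengths follow a gamma law with mean ``read_length``
    (shape 3), clipped to [50, haplotype length].  Base qualities encode the
    per-base error probability actually used (flat Phred score), so the
    quality-vs-error-posterior analysis has a ground truth to compare with.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    haps = [
        np.frombuffer(genome.hap_a.encode(), dtype=np.uint8),
        np.frombuffer(genome.hap_b.encode(), dtype=np.uint8),
    ]
    hap_codes = [np.searchsorted(_BASES, h) for h in haps]
    glen = len(genome.hap_a)
    total_bases = coverage * glen
    if error_rate > 0:
        q = int(round(-10.0 * np.log10(error_rate)))
    else:
        q = 40
    reads: list[ReadRecord] = []
    produced = 0
    i = 0
    while produced < total_bases:
        if mode == "long":
            L = int(rng.gamma(LONG_READ_SHAPE, read_length / LONG_READ_SHAPE))
            L = max(50, L)
        elif mode == "short":
            L = int(read_length)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        hap = int(rng.integers(0, 2))
        codes = hap_codes[hap]
        L = min(L, len(codes))
        start = int(rng.integers(0, len(codes) - L + 1))
        fragment = codes[start : start + L].copy()
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(L) < error_rate)
            if len(errs):
                fragment[errs] = (
                    fragment[errs] + rng.integers(1, 4, size=len(errs)).astype(np.uint8)
                ) % 4
        seq = _codes_to_str(fragment)
        reads.append(
            ReadRecord(
                identifier=f"read_{i}_hap{'AB'[hap]}_{start}",
                sequence=seq,
                qualities=np.full(L, q, dtype=np.int16),
            )
        )
        produced += L
        i += 1
    return reads


def pack_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit-packed k-mers of every valid window (k <= 32)."""
    from .cascade import scan_reads

    return scan_reads([seq], k, pack=True).packed


@dataclass
class GroundTruthLabels:
    """Per-distinct-k-mer truth labels plus the derived summary rates.

    ``kmers``/``counts`` cover every distinct canonical k-mer of the read
    set; ``label`` codes 0 = error, 1 = heterozygous, 2 = homozygous
    (in both haplotypes).  Robust = heterozygous or homozygous.  The
    alternative main-text convention (robust = present in *both*
    haplotypes) is exposed as ``n_distinct_in_both`` for comparison.
    """

    kmers: np.ndarray
    counts: np.ndarray
    label: np.ndarray
    n_distinct_hap_a: int
    k: int

    @property
    def robust_mask(self) -> np.ndarray:
        return self.label >= 1

    @property
    def het_mask(self) -> np.ndarray:
        return self.label == 1

    @property
    def n_distinct_robust(self) -> int:
        return int(self.robust_mask.sum())

    @property
    def n_distinct_het(self) -> int:
        return int(self.het_mask.sum())

    @property
    def n_distinct_error(self) -> int:
        return int((self.label == 0).sum())

    @property
    def n_distinct_in_both(self) -> int:
        return int((self.label == 2).sum())

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    @property
    def robust_occurrences(self) -> int:
        return int(self.counts[self.robust_mask].sum())

    # -- the three ground-truth rates the histogram model estimates -------

    @property
    def het_pct(self) -> float:
        """Distinct heterozygous k-mers as % of distinct robust k-mers."""
        return 100.0 * self.n_distinct_het / max(self.n_distinct_robust, 1)

    @property
    def robust_rate_pct(self) -> float:
        """Robust k-mer occurrences as % of all k-mer occurrences."""
        return 100.0 * self.robust_occurrences / max(self.total_occurrences, 1)

    @property
    def robust_coverage(self) -> float:
        """Robust occurrences per distinct k-mer of the initial haplotype."""
        return self.robust_occurrences / max(self.n_distinct_hap_a, 1)


def label_kmers(reads, genome: DiploidGenome, k: int) -> GroundTruthLabels:
    """Label every distinct read k-mer by presence in the two haplotypes."""
    from .cascade import scan_reads

    res = scan_reads(reads, k, pack=True)
    kmers, counts = np.unique(res.packed, return_counts=True)
    set_a = np.unique(pack_kmers(genome.hap_a, k))
    set_b = np.unique(pack_kmers(genome.hap_b, k))
    in_a = _member(kmers, set_a)
    in_b = _member(kmers, set_b)
    label = np.where(in_a & in_b, 2, np.where(in_a | in_b, 1, 0)).astype(np.int8)
    return GroundTruthLabels(
        kmers=kmers,
        counts=counts,
        label=label,
        n_distinct_hap_a=len(set_a),
        k=k,
    )


def _member(values: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(sorted_set, values)
    idx = np.minimum(idx, len(sorted_set) - 1)
    return sorted_set[idx] == values if len(sorted_set) else np.zeros(len(values), bool)
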