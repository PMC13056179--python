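"""Desk-scale evaluation protocols with simulated ground truth.

Each function runs one end-to-end experiment against the synthetic fixtures
from :mod:`kmerstat.simulate` and reports both the package's estimates and
the fixture's ground truth, so accuracy claims are recomputed rather than
asserted.  Problem sizes default to desk scale — a 1-2 Mbp genome at
30-fold coverage — which keeps each protocol within a few minutes on one
core while preserving the statistical structure (error, heterozygous and
homozygous components) the methods rely on.
"""

from __future__ import annotations

import numpy as np

from .cascade import CascadeConfig, count_reads, hashes_for_packed
from .histogram import exact_counts, histogram_from_counts
from .mixture import DEConfig, fit, summary_stats
from .simulate import make_diploid, simulate_reads, label_kmers

__all__ = ["counting_accuracy", "diploid_histogram_recovery"]


def counting_accuracy(
    seed: int,
    genome_length: int = 1_000_000,
    coverage: float = 30.0,
    read_length: int = 100,
    base_error_rate: float = 0.001,
    k: int = 25,
    c_min: int = 1,
    c_max: int = 255,
    filter_error_rate: float = 0.001,
) -> dict:
    """Fraction of distinct k-mers counted exactly right by the cascade.

    Simulates short reads from a random (haploid) genome, counts them with
    filters auto-sized from the exact count histogram at the target filter
    error rate, and compares every distinct k-mer's reported count against
    an exact dictionary-style counter.
    """
    genome = make_diploid(genome_length, snv_rate=0.0, seed=seed)
    reads = simulate_reads(
        genome, coverage, read_length, base_error_rate, seed=seed + 1, mode="short"
    )
    seqs = [r.sequence for r in reads]
    packed, true_counts = exact_counts(seqs, k)
    hist = histogram_from_counts(np.minimum(true_counts, c_max))
    config = CascadeConfig(
        k=k, c_min=c_min, c_max=c_max, error_rate=filter_error_rate, output="counts"
    )
    store = count_reads(seqs, config, histogram=hist)
    reported = store.counts_for_hashes(hashes_for_packed(packed, k))
    expected = np.where((true_counts >= c_min) & (true_counts <= c_max), true_counts, 0)
    expected = np.minimum(expected, store.output_cbf.cap + c_min - 1)
    correct = int((reported == expected).sum())
    return {
        "n_distinct": int(len(packed)),
        "n_correct": correct,
        "pct_correct": 100.0 * correct / len(packed),
        "n_reads": len(reads),
        "n_windows": store.n_windows,
    }


def diploid_histogram_recovery(
    seed: int,
    snv_rate: float = 0.005,
    genome_length: int = 2_000_000,
    coverage: float = 30.0,
    read_length: float = 2000.0,
    base_error_rate: float = 0.02,
    k: int = 30,
    de_seed: int | None = None,
) -> dict:
    """Histogram-model recovery of heterozygosity, coverage, and robustness.

    Builds a diploid fixture, simulates long-mode reads, fits the mixture to
    the exact k-mer count histogram, and reports estimates next to the
    label-derived ground truth: heterozygosity (distinct heterozygous over
    distinct robust k-mers), robust k-mer rate (robust occurrences over all
    occurrences), and robust k-mer coverage (robust occurrences per distinct
    k-mer of the initial haplotype).
    """
    genome = make_diploid(genome_length, snv_rate=snv_rate, seed=seed)
    reads = simulate_reads(
        genome, coverage, read_length, base_error_rate, seed=seed + 1, mode="long"
    )
    seqs = [r.sequence for r in reads]
    truth = label_kmers(seqs, genome, k)
    hist = histogram_from_counts(np.minimum(truth.counts, 255))
    de = DEConfig() if de_seed is None else DEConfig(seed=de_seed)
    result = fit(hist, p=2, de=de)
    stats = summary_stats(result, hist, k=k, read_length=read_length)
    return {
        "est_het_pct": stats.heterozygosity_pct,
        "true_het_pct": truth.het_pct,
        "abs_err_het_pct": abs(stats.heterozygosity_pct - truth.het_pct),
        "est_coverage": stats.kmer_coverage,
        "true_coverage": truth.robust_coverage,
        "abs_err_coverage": abs(stats.kmer_coverage - truth.robust_coverage),
        "est_robust_pct": stats.robust_rate_pct,
        "true_robust_pct": truth.robust_rate_pct,
        "abs_err_robust_pct": abs(stats.robust_rate_pct - truth.robust_rate_pct),
        "est_genome_size": stats.genome_size,
        "model_err": result.err,
        "generations": result.n_generations,
        "families": [c.family for c in result.model.components],
        "n_distinct": hist.total_distinct,
    }
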