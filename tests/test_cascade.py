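"""Cascade semantics: planning, threshold filtering, oracle equivalence, depth."""

import collections

import numpy as np
import pytest

from kmerstat.bloom import BloomFilter, CountingBloomFilter
from kmerstat.cascade import (
    CascadeConfig,
    CascadeConfigError,
    SizingError,
    count_reads,
    export_tsv,
    get_count,
    get_depth,
    hashes_for_packed,
    plan_sizes,
    scan_reads,
)
from kmerstat.hashing import derive_hashes
from kmerstat.histogram import KmerHistogram, exact_counts


def oracle_counts(reads, k):
    packed, counts = exact_counts(reads, k)
    return packed, counts


class TestPlanning:
    def test_partial_sums_from_histogram(self):
        hist = KmerHistogram([900, 90, 10])
        plan = plan_sizes(CascadeConfig(k=9, c_min=3), histogram=hist)
        assert plan.n_global == 1000
        assert plan.n_intermediate == 100
        assert plan.n_output == 10

    def test_unbounded_config_allocates_only_output(self):
        plan = plan_sizes(CascadeConfig(k=9, c_min=1, c_max=255), histogram=KmerHistogram([10, 5]))
        assert plan.m_global == 0 and plan.m_intermediate == 0 and plan.m_output > 0

    def test_cmin_two_skips_intermediate(self):
        plan = plan_sizes(CascadeConfig(k=9, c_min=2), histogram=KmerHistogram([10, 5]))
        assert plan.m_global > 0 and plan.m_intermediate == 0

    def test_missing_sizing_information_is_actionable_error(self):
        with pytest.raises(SizingError, match="histogram"):
            plan_sizes(CascadeConfig(k=9))

    @pytest.mark.parametrize("c_min,c_max", [(1, 255), (2, 255), (3, 200), (5, 10)])
    def test_allocation_rules_hold(self, c_min, c_max, small_reads):
        config = CascadeConfig(k=15, c_min=c_min, c_max=c_max, secondary=True)
        store = count_reads(small_reads[:20], config, distinct_counts={"global": 2000, "output": 2000})
        assert (store.global_bf is not None) == (c_min >= 2)
        assert (store.intermediate_cbf is not None) == (c_min >= 3)
        assert store.output_cbf is not None and store.secondary_bf is not None

    def test_cmax_beyond_counter_cap_rejected(self):
        with pytest.raises(CascadeConfigError, match="cap"):
            CascadeConfig(k=9, c_max=256)


class TestCounting:
    def test_single_read_duplicate_kmer(self):
        config = CascadeConfig(k=3, c_min=1, depth=True)
        store = count_reads(["AAAAA"], config, distinct_counts={"global": 16, "output": 16})
        assert store.get_count("AAA") == 3
        assert store.get_depth("AAA") == 1

    @pytest.mark.parametrize("c_min", [1, 2, 3, 5])
    def test_counts_match_dictionary_oracle(self, multiplicity_reads, c_min):
        k = 21
        packed, counts = oracle_counts(multiplicity_reads, k)
        config = CascadeConfig(k=k, c_min=c_min, c_max=255, error_rate=1e-6)
        store = count_reads(
            multiplicity_reads, config, histogram=KmerHistogram(np.bincount(counts)[1:])
        )
        got = store.counts_for_hashes(hashes_for_packed(packed, k))
        expected = np.where(counts >= c_min, counts, 0)
        assert (got == expected).all()

    def test_multiplicity_one_absent_when_cmin_two(self, multiplicity_reads):
        k = 21
        packed, counts = oracle_counts(multiplicity_reads, k)
        config = CascadeConfig(k=k, c_min=2, error_rate=1e-6)
        store = count_reads(
            multiplicity_reads, config, histogram=KmerHistogram(np.bincount(counts)[1:])
        )
        got = store.counts_for_hashes(hashes_for_packed(packed, k))
        assert (got[counts == 1] == 0).all()

    def test_never_seen_kmer_reports_zero(self, small_reads):
        config = CascadeConfig(k=15, error_rate=1e-6)
        store = count_reads(small_reads, config, distinct_counts={"global": 20000, "output": 20000})
        assert store.get_count("A" * 15) == 0

    def test_overcount_only_with_undersized_filters(self, multiplicity_reads):
        """Without c_max decrements, reported counts never fall below truth."""
        k = 21
        packed, counts = oracle_counts(multiplicity_reads, k)
        config = CascadeConfig(k=k, c_min=1, error_rate=0.2)  # deliberately tight
        store = count_reads(
            multiplicity_reads, config, distinct_counts={"output": len(packed)}
        )
        got = store.counts_for_hashes(hashes_for_packed(packed, k))
        assert (got >= counts).all()
        dev = got - counts
        assert dev.sum() > 0  # undersizing does produce overcounts...
        assert np.median(dev[dev > 0]) <= 5  # ...concentrated at small deviations

    def test_over_cmax_kmer_removed_and_in_secondary(self):
        reads = ["ACGTACGTACGTAC"] * 10  # every k-mer occurs 10 times
        config = CascadeConfig(k=11, c_min=1, c_max=5, error_rate=1e-6, secondary=True)
        store = count_reads(reads, config, distinct_counts={"output": 64, "secondary": 64})
        assert store.get_count("ACGTACGTACG") == 0
        ht = derive_hashes(
            __import__("kmerstat.hashing", fromlist=["canonical_base_hash"]).canonical_base_hash(
                "ACGTACGTACG"
            ),
            config.num_hashes,
        )
        assert store.secondary_bf.contains(ht)

    def test_reads_shorter_than_k_are_tallied(self):
        config = CascadeConfig(k=10)
        store = count_reads(["ACGT", "ACGTACGTACGT"], config, distinct_counts={"output": 64})
        assert store.n_short_reads == 1

    def test_kernel_matches_scalar_filter_api(self, multiplicity_reads):
        """The compiled cascade equals a replay through the per-element API."""
        k, c_min, c_max = 17, 3, 255
        reads = multiplicity_reads[:60]
        config = CascadeConfig(k=k, c_min=c_min, c_max=c_max, error_rate=1e-4)
        packed, counts = oracle_counts(reads, k)
        hist = KmerHistogram(np.bincount(counts)[1:])
        store = count_reads(reads, config, histogram=hist)
        plan = plan_sizes(config, histogram=hist)
        gbf = BloomFilter(plan.m_global)
        icbf = CountingBloomFilter(plan.m_intermediate)
        ocbf = CountingBloomFilter(plan.m_output)
        res = scan_reads(reads, k)
        for base in res.hashes:
            ht = derive_hashes(int(base), config.num_hashes)
            if not gbf.contains(ht):
                gbf.insert(ht)
                continue
            if icbf.count(ht) < c_min - 2:
                icbf.increment(ht)
                continue
            ocbf.increment(ht)
        assert (store.output_cbf.counters == ocbf.counters).all()
        assert (store.global_bf.bits == gbf.bits).all()
        assert (store.intermediate_cbf.counters == icbf.counters).all()


class TestDepth:
    def test_count_five_depth_four(self):
        kmer = "ACGTTGCAGGTCAAT"  # aperiodic; flanks break spurious windows
        filler = "TTGGCCAATTGGCCA"
        reads = [
            "GG" + kmer,
            "CC" + kmer,
            "TT" + kmer,
            kmer + "GGCC" + kmer,  # twice within one read
            filler,
        ]
        config = CascadeConfig(k=15, depth=True, error_rate=1e-6)
        store = count_reads(reads, config, distinct_counts={"global": 256, "output": 256})
        assert store.get_count(kmer) == 5
        assert store.get_depth(kmer) == 4

    def test_depth_never_exceeds_count(self, tiny_fixture):
        genome, reads = tiny_fixture
        seqs = [r.sequence for r in reads[:2000]]
        k = 21
        packed, counts = oracle_counts(seqs, k)
        config = CascadeConfig(k=k, depth=True, error_rate=1e-6)
        store = count_reads(seqs, config, histogram=KmerHistogram(np.bincount(counts)[1:]))
        hashes = hashes_for_packed(packed, k)
        assert (store.depth.depths_for_hashes(hashes) <= store.counts_for_hashes(hashes)).all()

    def test_depths_match_per_read_membership_oracle(self, multiplicity_reads):
        k = 21
        packed, counts = oracle_counts(multiplicity_reads, k)
        config = CascadeConfig(k=k, depth=True, error_rate=1e-6)
        store = count_reads(
            multiplicity_reads, config, histogram=KmerHistogram(np.bincount(counts)[1:])
        )
        res = scan_reads(multiplicity_reads, k, pack=True)
        truth = collections.Counter()
        for rid in range(len(multiplicity_reads)):
            for x in set(res.packed[res.read_ids == rid].tolist()):
                truth[x] += 1
        expected = np.array([truth[int(p)] for p in packed])
        assert (store.depth.depths_for_hashes(hashes_for_packed(packed, k)) == expected).all()

    def test_depth_disabled_raises(self, small_reads):
        config = CascadeConfig(k=15)
        store = count_reads(small_reads[:5], config, distinct_counts={"output": 1000})
        with pytest.raises(CascadeConfigError, match="depth"):
            get_depth(store, "A" * 15)


class TestExport:
    def test_empty_store_writes_header_only(self, tmp_path):
        config = CascadeConfig(k=15)
        store = count_reads([], config, distinct_counts={"output": 64})
        path = tmp_path / "counts.tsv"
        export_tsv(store, [], path)
        assert path.read_text() == "kmer\tcount\n"

    def test_rows_match_oracle(self, multiplicity_reads, tmp_path):
        k = 21
        packed, counts = oracle_counts(multiplicity_reads, k)
        config = CascadeConfig(k=k, c_min=2, error_rate=1e-6, depth=True)
        store = count_reads(
            multiplicity_reads, config, histogram=KmerHistogram(np.bincount(counts)[1:])
        )
        path = tmp_path / "counts.tsv"
        n = export_tsv(store, multiplicity_reads, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "kmer\tcount\tdepth"
        assert n == len(lines) - 1 == int((counts >= 2).sum())
        from kmerstat.cascade import packed_to_kmer

        expected = {packed_to_kmer(int(p), k): int(c) for p, c in zip(packed, counts) if c >= 2}
        for line in lines[1:]:
            kmer, count, depth = line.split("\t")
            assert expected[kmer] == int(count)
            assert int(depth) <= int(count)
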