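"""Classify individual k-mers and compute count/depth (TF-IDF) statistics.

Counts a small read set with depth extraction on, fits the histogram model,
and profiles every k-mer: posterior class probabilities, argmax label, and
the count-to-depth ratio flagging within-read repeats.
"""

import numpy as np

from kmerstat import CascadeConfig, DEConfig, count_reads, fit, make_diploid, simulate_reads
from kmerstat.characterize import count_depth_profile, error_prob_to_phred
from kmerstat.histogram import exact_counts, histogram_from_counts

genome = make_diploid(length=200_000, snv_rate=0.005, seed=21)
reads = [r.sequence for r in simulate_reads(genome, coverage=20, read_length=100,
                                            error_rate=0.005, seed=22)]

k = 21
_, counts = exact_counts(reads, k)
hist = histogram_from_counts(np.minimum(counts, 255))
result = fit(hist, de=DEConfig(seed=42))

config = CascadeConfig(k=k, depth=True, error_rate=0.001)
store = count_reads(reads, config, histogram=hist)
profile = count_depth_profile(store, reads, model=result.model)

t = profile.table
print(f"profiled {len(t)} distinct k-mers (count, depth, ratio, posteriors, label)")
print(t.head(5).to_string(index=False))
by_label = t.groupby("label").size()
print("\nlabel counts:", dict(by_label))
err_row = t[t.label == "error"].iloc[0] if (t.label == "error").any() else None
if err_row is not None:
    q = error_prob_to_phred(max(err_row.p_err, 1e-12))
    print(f"an error-labelled k-mer with p_err={err_row.p_err:.3f} corresponds to "
          f"a Phred-style score of {q:.1f}")
print("ratio > 1 marks k-mers occurring several times within single reads")
print(f"(count==depth for {(t['count'] == t['depth']).mean() * 100:.1f}% of k-mers here).")
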