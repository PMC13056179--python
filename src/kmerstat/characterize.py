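"""Per-k-mer characterization: posteriors, labels, Phred proxies, TF-IDF.

Given a fitted mixture model, the posterior probability that a k-mer with
count ``x`` arose from component ``c`` is

    P(Component = c | x) = w_c f_c(x) / F(x),

and a k-mer is labelled by the argmax component (ties broken toward the
lower-mean component, i.e. error < heterozygous < homozygous).  The error
posterior serves as a proxy for base quality: a Phred score Q converts to an
error probability via P = 10^(-Q/10), and because a single base error makes
a whole k-mer erroneous, the minimum base quality inside the window is the
representative score of the k-mer.

The count/depth pair is the genomic analogue of TF-IDF: count is term
frequency (total occurrences) and depth is document frequency (reads
containing the k-mer); a count-to-depth ratio above 1 flags k-mers that
repeat within single reads, i.e. close-proximity repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CountStore, hashes_for_packed, packed_to_kmer, scan_reads
from .mixture import MixtureModel

__all__ = [
    "posterior",
    "posterior_matrix",
    "classify",
    "classify_counts",
    "error_prob_to_phred",
    "phred_to_error_prob",
    "kmer_min_phred",
    "count_depth_profile",
    "PosteriorUndefinedError",
    "COMPONENT_LABELS",
]

COMPONENT_LABELS = ("error", "heterozygous", "homozygous")


class PosteriorUndefinedError(ValueError):
    """Raised when F(x) = 0 and the posterior is undefined."""


def _labels_for(model: MixtureModel) -> tuple[str, ...]:
    if model.p == 2:
        return COMPONENT_LABELS
    return ("error",) + tuple(f"genomic_{i + 1}" for i in range(model.p))


def posterior(model: MixtureModel, x: int) -> np.ndarray:
    """Posterior component probabilities at count ``x`` (sums to 1)."""
    if not 1 <= x <= model.c:
        raise ValueError(f"count x={x} outside model support 1..{model.c}")
    pmfs = model.component_pmfs()[:, x - 1]
    num = model.weights * pmfs
    total = num.sum()
    if total <= 0:
        raise PosteriorUndefinedError(f"F({x}) = 0; posterior undefined")
    return num / total


def posterior_matrix(model: MixtureModel) -> np.ndarray:
    """(c, n_components) posteriors for every count in 1..c; NaN where F=0."""
    num = (model.weights[:, None] * model.component_pmfs()).T
    total = num.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / total
    out[total[:, 0] <= 0] = np.nan
    return out


def classify(model: MixtureModel, x: int) -> str:
    """Label a count by its maximum-posterior component.

    Ties break toward the lower-mean component; an undefined posterior
    (F(x) = 0) yields ``"unclassified"``.
    """
    try:
        post = posterior(model, x)
    except PosteriorUndefinedError:
        return "unclassified"
    order = np.argsort([s.mean for s in model.components], kind="stable")
    labels = _labels_for(model)
    best, best_p = None, -1.0
    for idx in order:  # scan in increasing-mean order so ties keep the lower mean
        if post[idx] > best_p + 1e-12:
            best, best_p = idx, post[idx]
    return labels[best]


def classify_counts(model: MixtureModel, counts: np.ndarray) -> np.ndarray:
    """Vectorized argmax-posterior labels (int codes into the label tuple).

    Counts outside 1..c or with undefined posteriors code as -1.
    """
    counts = np.asarray(counts, dtype=np.int64)
    post = posterior_matrix(model)
    means = np.array([s.mean for s in model.components])
    order = np.argsort(means, kind="stable")
    # reorder columns by mean, argmax picks the first (lowest-mean) on ties
    reordered = post[:, order]
    best = order[np.nanargmax(np.where(np.isnan(reordered), -1.0, reordered), axis=1)]
    out = np.full(len(counts), -1, dtype=np.int64)
    ok = (counts >= 1) & (counts <= model.c)
    out[ok] = best[counts[ok] - 1]
    undef = np.isnan(post).all(axis=1)
    out[ok & undef[np.clip(counts - 1, 0, model.c - 1)]] = -1
    return out


def error_prob_to_phred(p: float) -> float:
    """Q = -10 log10(p) for an error probability p in (0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def phred_to_error_prob(q: float) -> float:
    """P = 10^(-Q/10); inverse of :func:`error_prob_to_phred`."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def kmer_min_phred(qualities, k: int) -> np.ndarray:
    """Minimum base quality of each k-mer window of a read.

    ``qualities`` is a per-base Phred array (or FASTQ quality string,
    Phred+33).  The minimum is the representative k-mer score: one bad base
    corrupts the whole window.
    """
    if isinstance(qualities, str):
        qualities = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8) - 33
    q = np.asarray(qualities)
    if len(q) < k:
        return np.empty(0, dtype=q.dtype)
    windows = np.lib.stride_tricks.sliding_window_view(q, k)
    return windows.min(axis=1)


@dataclass
class CountDepthProfile:
    """Per-k-mer counts/depths plus the aggregate (count, depth) density."""

    table: pd.DataFrame  # kmer, count, depth, ratio[, p_err, p_het, p_hom, label]
    density: np.ndarray  # density[i, j] = #k-mers with count i+1, depth j+1

    @property
    def max_count(self) -> int:
        return self.density.shape[0]


def count_depth_profile(
    store: CountStore,
    reads,
    model: MixtureModel | None = None,
    max_bin: int = 255,
) -> CountDepthProfile:
    """Profile every distinct k-mer of a read set: C, D, C/D, posteriors.

    Requires a store built with depth extraction enabled.  The aggregate
    density table bins counts and depths linearly up to ``max_bin``.
    """
    if store.depth is None:
        raise ValueError("counting ran without depth extraction; re-run with depth=True")
    cfg = store.config
    if not (cfg.mask.is_plain and cfg.k <= 32):
        raise ValueError("profiling enumerates k-mers and needs a plain mask with k <= 32")
    res = scan_reads(reads, cfg.k, cfg.mask, pack=True)
    distinct = np.unique(res.packed)
    hashes = hashes_for_packed(distinct, cfg.k)
    counts = store.counts_for_hashes(hashes)
    depths = store.depth.depths_for_hashes(hashes)
    keep = counts > 0
    distinct, counts, depths = distinct[keep], counts[keep], depths[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(depths > 0, counts / np.maximum(depths, 1), np.nan)
    data = {
        "kmer": [packed_to_kmer(int(p), cfg.k) for p in distinct],
        "count": counts,
        "depth": depths,
        "ratio": ratio,
    }
    if model is not None:
        post = posterior_matrix(model)
        labels = _labels_for(model)
        idx = np.clip(counts, 1, model.c) - 1
        for j, lab in enumerate(labels):
            data[f"p_{lab[:3]}" if model.p == 2 else f"p_{lab}"] = post[idx, j]
        codes = classify_counts(model, np.clip(counts, 1, model.c))
        data["label"] = [labels[c] if c >= 0 else "unclassified" for c in codes]
    cmax = int(min(max(counts.max(), depths.max()), max_bin))
    density, _, _ = np.histogram2d(
        np.minimum(counts, cmax),
        np.minimum(depths, cmax),
        bins=[np.arange(0.5, cmax + 1.5)] * 2,
    )
    return CountDepthProfile(table=pd.DataFrame(data), density=density.astype(np.int64))
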