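# Methods

`kmerstat` has two engines: a probabilistic counting engine for k-mers and
spaced seeds, and an analysis engine that fits a mixture model to k-mer
count histograms.  This note records the models, the numerical choices, and
what the synthetic fixtures do and do not establish.

## Hashing

Every window of length k is reduced to one canonical 64-bit *base hash*
that is identical for the window and its reverse complement.  The scheme is
an xor-rotate rolling hash over four per-base constants:

    f(s) = XOR_j rol64(T[s_j],       (w-1-j) mod 64)   (forward)
    r(s) = XOR_j rol64(T[comp(s_j)],  j      mod 64)   (reverse)

with `w` the number of care positions, so `f(revcomp(s)) = r(s)` and
`min(f, r)` is strand-invariant.  For plain k-mers both values advance in
O(1) per base; for spaced seeds the care-position substring is hashed per
window.  The `h` per-filter hash values are derived from the base hash by a
double-hashing expansion through the splitmix64 finalizer, so one pass per
k-mer serves any number of hash functions (`h = 7` throughout, the value
the filter-sizing formula assumes).  The constants are arbitrary fixed
64-bit values; the contracts that matter — strand invariance, rolling/direct
equivalence, spaced-seed insensitivity, uniformity — are property-tested,
and no compatibility with any external hash implementation is claimed.

Canonical *representation* of a k-mer (for TSV output and oracle keys) is
the lexicographically smaller of the care-position substring and its
reverse complement; its numeric 2-bit packing preserves that order, which
is what the exact-counting oracle sorts on.

## Counting cascade

Counting uses a cascade of Bloom filters so that the expensive per-element
structures only hold k-mers that matter:

1. a global BF records first occurrences (allocated when `c_min >= 2`);
2. an intermediate CBF accumulates occurrences 2..c_min-1 (when
   `c_min >= 3`) — most k-mers in sequencing data occur once, so this layer
   keeps them out of the counting structures;
3. the output structure (CBF, or BF for membership-only output at 1/8 the
   space) receives the c_min-th and later occurrences; a reported count is
   the stored counter plus `c_min - 1`;
4. optionally, a secondary BF records k-mers whose reported count crossed
   `c_max`; on crossing, the k-mer's reported value is decremented from its
   own counters so it vanishes from the output.  Without the secondary BF
   the k-mer restarts accumulating and is removed again at the next
   crossing.

CBF queries report the minimum of the `h` addressed counters; increments
follow the minimal-increase rule (only minimum counters are bumped), which
keeps `reported >= true` in the absence of decrements while reducing
overestimation.  Counters are 8-bit by default and saturate at 255 — hence
255 is the largest admissible `c_max`.  Decrement-based removal has a
documented side effect: counters shared with a removed k-mer can be
collaterally reduced, so exact oracle agreement is only guaranteed for
configurations in which no k-mer crosses `c_max`; the error is bounded by
the position-collision rate of the output array.

Filter sizes are derived from a count histogram by inverting the Bloom
false-positive formula `(1 - exp(-hn/m))^h <= e` for each layer's expected
insertions (partial sums of the histogram), with `e = 0.001` by default.
On a simulated 1 Mbp / 30x / 0.1%-error dataset this sizing reproduces
counts exactly for ≈99.9% of distinct 25-mers (the acceptance suite
recomputes this number).

Depth (the number of distinct reads containing a k-mer — document frequency
in the TF-IDF analogy, where count is term frequency) is extracted in the
same pass: a per-read scratch BF (sized for the read's windows at FPR 1e-4,
cleared between reads) deduplicates within-read occurrences, and a global
depth CBF is incremented once per read per k-mer.  Reported depth can
exceed reported count only if thresholds suppress the count; for unbounded
configurations depth <= count holds and is tested.

Processing is single-threaded and in input order, so results are exactly
reproducible.  The hot loops (window hashing, per-occurrence cascade
updates) are numba-compiled kernels; the scalar per-element API implements
the same semantics and the test suite asserts bit-for-bit agreement between
the two paths, alongside dictionary-oracle equivalence.

## Histogram mixture model

The count histogram (h_1..h_c, h_i = distinct k-mers occurring i times) is
modelled as

    F(x) = w_err f_err(x) + sum_{i=1..p} w_i f_i(x),   x = 1..c,

with the error family drawn from {gamma, exponential} and each genomic
family from {normal, skew-normal, Poisson, negative binomial}.  For a
diploid genome (p = 2) the genomic components are the heterozygous
(half-coverage) and homozygous (full-coverage) peaks.  All densities are
evaluated at the integer support and renormalized to sum to one over 1..c;
the skew-normal is parameterized by its distribution mean (location derived
internally) so component means are comparable across families, and the
negative binomial by mean and dispersion `r` (variance = mu + mu²/r, Poisson
as r → ∞ — the numerical limit checks are in the test suite).

The objective is the L1 distance between the mixture and the normalized
histogram, `Err(F) = sum_x |F(x) - h_x / sum_j h_j|`: non-negative, zero
only for a perfect fit, invariant to histogram scale.

### Optimization

A candidate genome carries the categorical family choices (continuous genes
rounded at evaluation), the component parameters, and positive weight genes
normalized to the simplex.  The search has three stages:

1. **Differential Evolution** (scipy's engine, `best1bin`, immediate
   updating) with population 16, mutation factor resampled uniformly in
   [0.5, 1.0] each generation, recombination 0.8, at most 500 generations,
   stopping early when the best error has improved by less than 1e-6 for 50
   consecutive generations.  Half the initial population is placed at
   method-of-moments anchors (error rate from the h1/h2 ratio, error weight
   from bin 1, peak location from the histogram's post-valley mode, both
   the "dominant peak is homozygous" and "dominant peak is heterozygous"
   hypotheses); the rest is a Latin hypercube.  Anchoring avoids the
   degenerate attractor where a genomic component parks on the error bulk
   at count 1; the search remains free to leave the anchors.
2. **Profiled local refinement.**  For fixed component pmfs the optimal
   weights solve a small linear program (auxiliary variables bound the
   per-bin absolute deviations), so the weight/parameter trade-off is
   removed exactly.  Nelder-Mead searches the distribution parameters under
   this profile for the best-scoring (family-combination, start-point)
   candidates — the categorical space is tiny (2 x 4^p) — with the DE
   optimum and the histogram anchors ranked as separate start classes (top
   8 of each) so neither can crowd the other out.
3. **Bounded BFGS polish** (L-BFGS-B) of all continuous genes with the
   families fixed.

The optimized objective adds a small parsimony term (2e-4 per continuous
distribution parameter of the chosen families) to the L1 error.  This is a
model-selection tie-break, not a fit criterion: at desk scale several
family combinations fit a diploid histogram within ~1e-4 of each other
while splitting the peak weights differently — a strongly skewed component
can "lean" mass between overlapping peaks and reach a marginally lower L1
error with a substantially wrong weight split — so without the term the
selected decomposition depends on the optimizer seed.  With it, a flexible
family wins only when it buys an error reduction larger than the penalty,
and the selected decomposition is stable across seeds (verified over
optimizer seeds and fixture realizations in the test suite).  The reported
`err` is always the plain L1 value; the reported `objective` is the
penalized one.

Each stage is accepted only if it lowers the objective, so the final
objective never exceeds the best DE candidate's, and the per-generation
best-objective trace is non-increasing by construction.  The optimizer
seed is a first-class configuration field (default 42); identical seeds
give identical results.  An ordering penalty keeps genomic means ascending
(heterozygous below homozygous); ties in posterior classification break
toward the lower-mean component.

`fit` optionally takes a fixed family assignment.  This matters at small
histogram sizes: with ~1e6 distinct k-mers of sampling noise, the free
search can find flexible (e.g. skew-normal) decompositions with *lower* L1
error than the generating mixture, trading weight between overlapping
peaks.  With ~3e7 distinct k-mers (the desk-scale fixtures) the free search
recovers the generating decomposition reliably.

### Derived statistics

With weights w and renormalized pmfs f over 1..c:

* **k-mer coverage** — mean of the highest-mean genomic (homozygous)
  component over the support;
* **heterozygosity** — `100 * w_het / (w_het + w_hom)` (fraction of
  *distinct* genomic k-mers on one haplotype), plus an occurrence-weighted
  variant, since published percentages are ambiguous between the two;
* **error fraction** (occurrence-weighted) —
  `sum_x x w_err f_err(x) / sum_x x F(x)`; **robust rate** = 1 − that;
* **genome size** — `total_occurrences * (1 - error fraction) / coverage`,
  optionally corrected by `L/(L-k+1)` for the k−1 bases per read that never
  start a window (noticeable for short reads).

Undefined cases (all-error model, zero genomic mass) report NaN rather than
a number.

### Per-k-mer characterization

Posterior `P(component | x) = w_c f_c(x) / F(x)`; classification is argmax
with the lower-mean tie rule; `F(x) = 0` yields an explicit unclassified
state.  The error posterior maps to a Phred-style score via
`Q = -10 log10(p)`; the representative observed score of a k-mer window is
the minimum base quality inside it, since a single bad base corrupts the
whole k-mer.  The count-to-depth ratio (term frequency over document
frequency) is 1 for k-mers occurring at most once per read and grows with
within-read repetition, i.e. with repeat proximity.

## Synthetic fixtures

`make_diploid` copies a uniform-random haploid sequence and plants iid SNVs
(and optionally 1-3 bp indels) at stated rates; `simulate_reads` draws
reads uniformly from both haplotypes — fixed-length in short mode, gamma
lengths (shape 3) in long mode — with iid substitution errors and flat
quality strings encoding the error rate actually used.  `label_kmers`
marks every distinct read k-mer as *robust* (present in ≥1 haplotype),
*heterozygous* (exactly one), or *error* (neither); the alternative
"present in both" reading of robustness is also counted but the at-least-one
definition is the one the summary statistics are defined against.

Ground-truth conventions used by the recovery protocols: heterozygosity =
distinct het / distinct robust; robust rate = robust occurrences / total
occurrences; robust coverage = robust occurrences / distinct k-mers of the
initial haplotype.

These generators reproduce the *statistical structure* the model assumes —
an error component plus two coverage peaks with binomially-sampled depths —
but not platform realism: no quality-dependent or context-dependent errors,
no homopolymer artifacts, no chimeras, no GC bias, and uniform coverage.
Passing the recovery tests therefore shows the estimator is correct under
its own model assumptions at realistic rates, not that it is robust to
every real-platform artifact.

## Study conditions and problem sizes

The evaluation protocols use: counting accuracy on a 1 Mbp genome with 30x
100 bp reads at 0.1% base error (k = 25, thresholds [1, 255], e = 0.001);
model recovery on 2 Mbp diploid fixtures (SNV rates 0.1%, 0.5%, 1%) with
30x long-mode reads (mean 2 kb) at 2% base error, k = 30, histogram support
capped at 255.  These sizes give ~2.3e7 windows and ~2.8e7 distinct k-mers
per fixture — large enough for the weight estimates to be identifiable,
small enough to run on one core in minutes.

## Known limitations

* Identifiability degrades as the heterozygous weight approaches the
  homozygous weight (high SNV rates): at a 1% SNV rate the minimizer of the
  L1 objective is measurably *not* the generating decomposition (its error
  is lower), and the heterozygosity estimate degrades even though coverage
  and robustness remain accurate.  This is a property of the objective, not
  of the optimizer.
* Decrement-based `c_max` removal collaterally undercounts colliding
  k-mers (bounded by the output array's position-collision rate).
* Membership-only output supports `c_min` filtering but not `c_max`
  (a bit array cannot count).
* Counting is exact-duplicating single-threaded; no parallel mode.
* Exact-counting helpers (oracle, histogram construction, TSV enumeration
  fast path) require plain masks with k <= 32; counting itself has no such
  limit.
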