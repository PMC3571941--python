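# Methods

## Model and procedure

The segmenter operates on Bernoulli indicator sequences derived from
log2-ratio copy-number profiles. For a sequence `a_1..a_m` the constant
model M₀ has one success rate θ₀; the two-change-point model M₁ treats the
sequence as a circle and gives the arc `[c₁+1, c₂]` rate θ₂ and its
wrapping complement `[1, c₁] ∪ [c₂+1, m]` rate θ₁. Both likelihoods are
maximized in closed form (the MLEs are the within-region fractions of 1s)
and compared by

    BIC₁₀ = log L₁(ĉ₁, ĉ₂) − log L₀ − ½ (q₁ − q₀) log m,

with q₁ = 4 (two rates, two change-point indices) and q₀ = 1, i.e. a
penalty of (3/2)·log m in natural-log units. The pair (ĉ₁, ĉ₂) is the
exhaustive maximizer of log L₁ over 1 ≤ c₁ < c₂ ≤ m. A positive BIC₁₀
splits the region in three; each part is re-scanned recursively as a fresh
problem — in particular **each subregion uses its own length in the
penalty**, since it is subjected to the same procedure. Recursion stops
when no region scores positive.

Conventions that the formulas leave open, fixed here once:

- **BIC₁₀ = 0 accepts M₀.** Zero evidence is treated as no evidence.
- **Ties in the arc scan** go to the lexicographically smallest (c₁, c₂);
  the scan enumerates pairs c₁-major, so "first maximum" implements this.
- **0 · log 0 = 0** throughout (`scipy.special.xlogy`).
- **Edge pairs.** ĉ₁ < ĉ₂ = m means the arc runs to the end of the region:
  only ĉ₁ is a change-point (the model defines change-points strictly
  inside the region, c_K < c_{K+1} = m) and the empty right part is
  skipped. Regions shorter than two probes are leaves.
- **Indices are 1-based inclusive** in the public API; a change-point c
  separates probe c from probe c+1.

The scan is computed with prefix sums over all pairs at once (O(m²) time
and memory, ~8 ms at m = 500); a property test and the acceptance suite
verify it is bit-identical to a naive double loop, so the vectorization is
purely an implementation detail.

## Thresholds

Gain and loss searches are independent and always run separately.
Comparisons are strict (`x > τ⁺`, `x < τ⁻`); a value exactly at the
threshold yields 0. Missing log2 ratios map to indicator 0 — absence of
evidence — and are never interpolated; segment mean log2 ratios likewise
skip missing values. Useful reference points on the log2 scale: τ⁺ = 0.32,
1 and 1.58 correspond to the classical low/medium/high amplification bands
(log₂ 1.2, log₂ 2, log₂ 3), and τ⁻ = −0.32 (log₂ 0.8) to single-copy loss.

Band thresholds (`τ < x < τ + ε` for gains, mirrored for losses) restrict
the indicator to a window so that consistent low-level aberrations light up
while spikes beyond the band are excluded; ε → ∞ recovers the plain
threshold.

## Multi-source consensus

Sources measuring the same individual are thresholded each with its own
τ (different platforms attenuate true copy number differently; no
cross-source standardization is applied) and the indicator sequences are
interleaved by genomic coordinate into a single merged sequence — the union
of all probe grids. Every source probe contributes exactly one merged
element, so per-chromosome 1-counts are additive and the merge is
order-insensitive up to ties. Coincident coordinates are kept as distinct
adjacent elements, stably ordered by the position of the source in the
input list; this is a convention (recorded in the provenance columns), not
a claim about the true probe order. All sources must be on one genome
assembly; no liftover is attempted. Segmenting the merged sequence gives a
consensus at the combined resolution: loci too sparse in any single source
(e.g. one flagged probe, which the penalty always absorbs) become
detectable when several sources flag neighbouring coordinates. Genomic
intervals are reported as [position of first probe, position of last probe]
of each segment; the gap to the next segment is not apportioned.

## Cohort standardization

For a probes × samples matrix on one shared grid, each probe row is
standardized to mean 0 and unit variance across samples (sample SD, n − 1
denominator). A zero-variance row carries no relative evidence; its z-row
is set to 0 with a warning rather than fabricating ±∞ scores. Thresholding
the z matrix at γ⁺/γ⁻ (default ±3: probes deviating by three standard
deviations from the cohort mean) gives one indicator sequence per sample,
each segmented independently. Detected segments with indicator rate above
0.5 are reported as aberrant calls — with the sparse background that
survives |z| > 3, real events sit near rate 1 and background near 0, so the
0.5 cut is uncritical — and calls from different samples are
cross-referenced by nonempty probe-index overlap on the same chromosome.

Standardization is relative by construction: an aberration shared by most
or all samples inflates the per-probe mean and SD and is masked (with two
of n carriers the attainable z is capped well below n-independent levels).
No correction is attempted; this is inherent to the approach and is what
the cross-referencing of *some-but-not-all* samples is for.

## Search scope

Per-chromosome scope segments each chromosome as an independent sequence;
results for one chromosome never depend on the others. Genome-wide scope
concatenates chromosomes 1–22, X in karyotype order into one sequence
first. A chromosome that is uniformly elevated is invisible per-chromosome
(its indicator sequence is constant) but forms a detectable arc against the
rest of the genome; the test suite covers this on a three-chromosome
fixture. In genome-wide output, segments crossing a chromosome border are
written as one row per overlapped chromosome, carrying the whole segment's
rate and mean with global probe indices.

## Simulation study and power

The generator emulates a single aberration in an otherwise normal
chromosome: m = 500 probes, x_i ~ N(μ_i, 1) independent, μ_i = c on an
elevated block of width k (uniform on 3..30 — at least three probes, the
minimum a segmenter of this kind can hope to recover) placed uniformly at
random, and μ_i = 0 elsewhere. Elevations c = 1, 2, 3 represent low,
moderate and high amplification. Defaults (m, k-range, c grid, τ⁺ grid
0.5..3.0, 1000 replicates per cell) are the study conditions; `noise_sd`
exists only as a test hook for the noiseless limit.

**Power is exact recovery read strictly**: the detected change-point set
must equal the true set — any missing, extra or shifted change-point is a
failure. The true set is {l, l+k}, except that a block reaching the end of
the sequence (l + k = m) has the single true change-point {l}, because the
model defines change-points strictly inside [1, m]. Per-cell RNG streams
are derived deterministically from (seed, c, τ⁺), so the grid can be
evaluated in any order or in part without changing any cell.

Exact recovery is a demanding yardstick. The detected arc can never begin
or end on an unflagged probe (trimming a boundary 0 from a hot arc always
raises the likelihood), so power is bounded above by the probability that
both boundary block probes exceed τ⁺, which is Φ(c − τ⁺)² — about 0.48 at
c = 2, τ⁺ = 1.5 — and short blocks below the penalty's detection limit
contribute further failures. The resulting power surface is therefore low
in absolute terms at c = 1 and c = 2; its qualitative structure — power
non-decreasing in c at fixed τ⁺, decaying once τ⁺ moves past c, exactly 1
in the noiseless limit — is asserted by the test suite, and
`scripts/acceptance.py` recomputes four grid cells at full replicate count.
Users interested in "was the aberration found at roughly the right place"
rather than probe-exact boundaries should evaluate detected segments
against their own overlap criterion; the strict reading is kept because it
is the only unambiguous one.

What the generator does not emulate: autocorrelated or heavy-tailed array
noise, GC waves, variable probe spacing, multiple aberrations per
chromosome, and platform attenuation differences. Passing simulation tests
therefore demonstrate correctness of the change-point machinery under the
stated model, not calibrated performance on real arrays.

## Problem sizes in the shipped tests

The default test run keeps the full grid at 200 replicates per cell (the
fast mode; identical protocol, wider binomial error) and the oracle,
closed-form and property suites at a few hundred to a thousand random
instances each; the whole suite runs in about a minute. The acceptance
script uses the full 1000 replicates for the four cells it reports.

## Known limitations

- Single flagged probes are never called (the penalty always dominates);
  this is by design, not a bug.
- O(m²) memory in the pair scan; genome-wide runs on very dense grids
  (m ≫ 10⁴) would need a blocked scan.
- No merging or pruning of adjacent segments and no permutation p-values;
  segment significance is entirely the BIC decision that created it.
- Cohort mode requires an identical probe grid across samples; use the
  integration mode for heterogeneous grids.
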