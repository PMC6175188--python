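# Methods

## Model

At a biallelic SNV locus, sample the allelic ratio r = alt/(alt+ref). In a
diploid genome without mosaicism, the true alternative-allele fraction is
0, ½ or 1 by genotype, and read counts are modelled as binomial draws
around it at the realised depth. A postzygotic mutation carried by a
fraction *f* of cells occupies one haplotype of those cells and shifts the
carrier's true fraction by *f*/2: gains take 0 → *f*/2, heterozygous-state
events move ½ → ½ ± *f*/2, losses take 1 → 1 − *f*/2. Monozygotic
co-twins share germline genotypes, so the between-twin allelic-ratio
difference ARD = r_A − r_B has mean 0 at every non-mosaic locus and mean
±*f*/2 at a twin-specific mosaic locus. Two independent sequencing
platforms (nominal depths 40X and 13X) provide two independent
measurements of the same contrast; concordance of the ARD *sign* across
platforms is the detection signal, because sampling noise flips signs
independently.

## Filter chain and its parameters

Applied in fixed order to the four-track locus intersection:

1. **Region restriction.** Keep loci inside the high-confidence inclusion
   mask and outside the repeat exclusion mask (BED, 0-based half-open;
   internal positions 1-based).
2. **Double-hom-ref drop.** A locus where both twins are homozygous
   reference carries no between-twin information. A twin is called
   hom-ref from its genotype calls when any track has one (all informative
   calls must agree on hom-ref), else from the absence of alt reads on all
   of its tracks.
3. **Clear-call filter** (tolerance 0.05, strict `<`). At least one twin
   must be clearly non-mosaic: its ratio within tolerance of the *same*
   canonical value {0, ½, 1} on *both* platforms. Requiring the same
   canonical on both platforms is the strictest reading of "clearly not
   mosaic"; a twin near 0 on one platform and near ½ on the other is not
   clear.
4. **Dual ARD threshold** (0.25, strict `>`, applied to |ARD| on both
   platforms). The default 0.25 places the null false-positive rate at
   0.31% per heterozygous locus (exact enumeration; see below) — below
   the 2% working bound.
5. **Sign classification.** Matching iff `ard_hi × ard_lo > 0`;
   nonmatching iff `< 0`; an exactly-zero ARD on either platform leaves
   the sign undefined and the locus out of both tallies (it also cannot
   pass any positive threshold).

The matching count is tested against ½ with the exact two-sided binomial
test (for a symmetric null this equals twice the smaller tail, capped at
1), with exact Clopper–Pearson 95% intervals. The matching-minus-
nonmatching fraction estimates the true-positive share of the candidates:
false positives split evenly between the two sign patterns and cancel.

## Null calibration

Null model: both twins truly heterozygous, counts
kA, kB ~ Binomial(d_hi, ½) and mA, mB ~ Binomial(d_lo, ½), all
independent; a locus is flagged iff |kA−kB|/d_hi > t and |mA−mB|/d_lo > t.
Sign agreement is deliberately *not* part of the flag (the quantity
calibrated is the threshold step, which precedes sign classification); a
`require_sign_match` switch exists for sensitivity analysis and exactly
halves the rate by symmetry.

Two routes cross-check each other:

- **Exact enumeration**: D = kA − kB satisfies D + d ~ Binomial(2d, ½),
  so each platform's two-sided tail is an exact binomial sum and the
  platforms multiply by independence. At (40, 13, 0.25) this gives
  0.30888%. A quadratic brute-force enumeration over all count pairs is
  kept as an independent oracle and agrees to 12+ digits.
- **Monte Carlo**: replicates of 893,581 loci (the heterozygous-set scale
  the simulation emulates), default 1,000 replicates; the acceptance
  script uses 120 and the test suite 10–12, which already put the standard
  error of the mean near 2e−6 — the estimate is insensitive to the
  replicate count well below the full default.

The strict threshold is evaluated on integer-valued statistics, so
floating-point placement of the boundary matters: ARD is computed with a
single division, (alt_A·d_B − alt_B·d_A)/(d_A·d_B), which is exact at
boundary cases such as a count difference of exactly 10 at depth 40
(0.25, excluded by strict `>`). Computing r_A − r_B as a float
subtraction instead would push such cases one ulp above the threshold and
inflate the fixed-depth null rate by ~15% relative.

Per-locus depths are fixed at the nominal values by default in the
calibration (matching the binomial null exactly); a truncated-Poisson
(≥ 1) depth mode is available for robustness checks.

## Clustering permutation tests

Distances are same-chromosome, between unordered position pairs, window
bounds inclusive, distance 0 excluded (windows start at ≥ 1 bp). The
within-pair statistic is the number of candidate pairs at in-window
distance; the between-pair statistic counts pair-1 candidates with at
least one pair-2 candidate in the window. Null distributions resample the
candidate-set size uniformly without replacement from the background
heterozygous loci (between-pair: pair 2 resampled, pair 1 fixed; a
`resample_both` switch also resamples pair 1 from its own background).
One-sided enrichment p-values use the add-one estimator
(1 + #{perm ≥ obs})/(n_perm + 1), so p ≥ 1/(n_perm+1) and a zero p-value
is impossible; fold change is observed/mean(permuted), undefined (NaN)
when the permutation mean is 0.

## Category enrichment and the negative control

Annotations are multi-label over a declared universe (default: 14
VEP-style consequence categories), so category percentages need not sum
to 100%. Per category, the 2×2 table contrasts candidates against
*background minus candidates* (disjoint strata), with a one-sided
(greater) Fisher exact test — the question is enrichment, and printed
two-column outputs report percentages against the full background for
readability. Odds ratios use the cross-product, adding 0.5 to every cell
only when some cell is zero. BH step-up adjustment runs across the
category family (m = 14 by default). Note BH adjusted values are not a
fixed point of the procedure on generic input; re-adjusting an adjusted
vector inflates it. The same-individual control repeats selection and
testing on one person's two platforms, where every ARD is noise: the
clear-call analogue requires either platform's ratio near a canonical
value, the threshold applies to the single between-platform ARD, and the
single-category p is reported unadjusted.

## Synthetic data generator

The generator emulates the study design: two co-twins × two platforms,
shared germline genotypes (default split 0.2 / 0.6 / 0.2 for
hom-ref / het / hom-alt so that the double-hom-ref drop and both mosaic
event types are exercised), an inclusion mask built from ~77% of 1-Mb
blocks and a repeat-style exclusion mask (~5% in 500-bp intervals),
positions uniform over include-minus-exclude without replacement, depths
Poisson around 40 and 13 truncated at ≥ 1 (fixed-depth mode for exact
null comparisons), and per-track binomial read counts, optionally through
a symmetric per-read error rate (off by default — the calibrated null is
sampling-only). Genotype calls are emitted per track from the observed
ratio (< 0.15 hom-ref, > 0.85 hom-alt, else het), mimicking a naive
caller including its occasional miscalls; a `missing` mode exercises the
count-based fallback of the hom-ref logic.

Defaults plant 200 mosaic loci among 100,000 at cell fraction f = 1.0 —
a full-organism twin difference, expected |ARD| ≈ 0.5 — which is the
regime where the detector should have high power; the parameter-recovery
test demands ≥ 90% recall there. Hotspots place a configured fraction of
mosaics inside fixed-width spans; hotspot centers can be supplied
explicitly to co-locate hotspots across two generated pairs. Category
labels are drawn per locus from baseline prevalences chosen to follow a
genome-wide consequence-frequency profile, with multiplicative enrichment
among mosaic loci.

What the generator deliberately does not model: alignment and mapping
error, reference bias, PCR duplicates, overdispersed (beta-binomial)
counts, and clonal dynamics. Passing tests therefore demonstrate
correctness of the statistical machinery under the binomial sampling
model, not robustness to artefacts of real sequencing — on real data the
nonmatching fraction absorbs those artefacts, which is exactly why the
matching-minus-nonmatching estimate, not the raw candidate count, is the
quantity to interpret.

## Numerical and design choices

- Strict inequalities at both thresholds (0.25 and 0.05), per the
  "higher than" / "less than" reading; boundary cases are excluded.
- Loci absent from any of the four tracks, with zero depth in any track,
  or with ref/alt disagreement across tracks are excluded at join time
  (no comparable ratio exists); exclusions are counted and logged.
- Multi-allelic and non-SNV records are skipped (not decomposed) on VCF
  input and tallied per reason.
- Permutation p-values use add-one estimators; exact tests use scipy's
  implementations, each cross-checked in the test suite against an
  independent brute-force oracle (log-space binomial tails,
  hypergeometric summation, all-pairs distance loops, full outcome
  enumeration).
- Every stochastic component takes an explicit integer seed
  (`numpy.random.default_rng`); identical configuration implies
  byte-identical outputs.
- Test problem sizes (tens of thousands of loci, 10–50 seeds or
  permutations × hundreds of replicates) are chosen so each statistical
  assertion has adequate power while the whole suite stays fast;
  calibration checks pool across seeds rather than asserting one noisy
  draw.

## Known limitations

- The clear-call + dual-threshold chain conditions candidate discovery on
  one twin sitting near a canonical ratio on both platforms; its null
  pass rate is therefore far below the unconditional threshold-only rate,
  and the two must not be conflated (the calibration module quantifies
  the unconditional rate by design).
- The true-positive estimate assumes false positives are sign-symmetric
  across platforms; platform-shared artefacts (e.g. mapping bias at the
  same locus in both datasets) would violate this and bias the estimate
  upward.
- The between-pair clustering statistic is asymmetric in the two pairs;
  with `resample_both` the null resamples both, but the observed
  statistic still counts pair-1 loci.
- `heritability_bias` implements the closed-form illustration only, not a
  variance-components fit.
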