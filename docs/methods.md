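# Methods

This note documents the statistical model, the default parameters, the
numerical choices, and the known limitations of the `seroclass` toolkit.

## Problem setting

Serum electrospray-ionization mass spectra are profiled as whole-unit
(nominal-mass) intensity vectors over m/z 400–2000, acquired in
triplicate per serum sample. Two clinically labelled groups (e.g., mild
Alzheimer's disease vs age-matched control) are compared by a
leave-one-out cross-validated peak classifier, and the resulting
per-sample scores are summarized with effect sizes, power, and
cut-off-line confusion metrics. A tandem-MS peptidome stage filters
protein hit tables for differential serum representation.

## Spectral preprocessing (`seroclass.preprocess`)

1. **Nominal binning** — raw (m/z, intensity) points accumulate onto the
   unit-mass grid at `round(m/z)` with half-up tie breaking; points
   rounding outside the grid are dropped.
2. **Segment normalization** — each non-overlapping 25-m/z window is
   scaled so its summed intensity equals 100. All-zero windows are left
   untouched (scaling is undefined there; leaving them preserves mass
   conservation and idempotence). A final partial window is scaled the
   same way.
3. **Valley-to-valley centroiding** — the intensity sequence is
   partitioned at valleys, defined as zero bins plus strict local minima
   (for a plateau minimum, the leftmost plateau bin is the valley and
   starts the next run). Each maximal run with positive total intensity
   becomes one peak whose area is the run sum and whose key is the
   half-up round of the intensity-weighted mean m/z. This partition is
   deterministic and conserves total intensity exactly.
4. **Triplicate averaging** — peak areas are averaged across replicates
   per unit m/z with absent peaks counted as zero; zero-mean keys are
   dropped. Replicate counts other than 3 are accepted with a warning.

Normalization is applied before centroiding; the source description is
ambiguous about the order, so this choice is recorded here rather than
asserted as the original authors' order.

## LOOCV/PCV classifier (`seroclass.loocv`)

For each left-out sample, every unit m/z observed in the remaining N−1
samples (absent = 0) is tested with a Welch unequal-variance t-test,
one-tailed in the direction of the observed mean difference
(p = two-tailed/2). A peak is retained if p < 0.05 **and** the larger
group mean is at least 0.3% of the maximum group-mean peak area over all
m/z in the left-in data (either group passing the floor keeps
down-regulated peaks). Each retained peak gets a peak classification
value (PCV) equal to the arithmetic midpoint of the two left-in group
means — "midpoint" is an interpretation, since no formula is published —
and a direction (the higher-mean group).

The left-out sample is scored peak by peak: an area strictly above the
PCV classifies to the peak's direction group; an area at or below the
PCV classifies to the opposite group. The sample's score is the percent
of peaks classified to group A (`pct_A`); `pct_A + pct_B = 100`.

Degenerate Welch columns are handled deterministically: zero variance in
both groups with equal means → the m/z is skipped; zero variance with
unequal means → p = 0 (kept).

## Group-level metrics (`seroclass.metrics`)

On the two groups' score distributions:

- **Welch t** (two-tailed by default; the peak-level tests are the
  one-tailed ones), p via the regularized incomplete beta function.
- **Cohen's d** = (mean_A − mean_B) / sqrt((SD_A² + SD_B²)/2). The
  root-mean-square pooling of the two SDs (no sample-size weighting) is
  the variant that reproduces the published summary effect sizes
  (4.88, 7.12, 3.67, 2.17) to two decimals.
- **Power** via the noncentral-t two-sample formulation with
  noncentrality d·sqrt(n_A·n_B/(n_A+n_B)), df = n_A+n_B−2, two-sided
  α = 0.05; a normal approximation covers extreme noncentralities where
  the noncentral-t tail underflows.
- **Cut-off lines**: multiplier M = (mean_A − mean_B)/(SD_A + SD_B);
  line A = mean_A − M·SD_A, line B = mean_B + M·SD_B. Self-computed
  lines coincide algebraically. When the true-comparison multiplier is
  reused on randomized statistics the lines separate and can cross; a
  group-A sample between crossed lines counts as a true positive and a
  false negative simultaneously. A score exactly on a coincident line
  counts once, as correctly classified (the boundary convention is not
  published; this one is deterministic and symmetric).
- **Confusion metrics**: sensitivity, specificity, PPV, NPV, efficiency;
  zero-denominator metrics are reported as null.

## Randomization control (`seroclass.randomize`)

Group labels are permuted within strata of sex crossed with cohort-wide
age tertiles (falling back to sex-only strata, with a warning, when a
stratum is a singleton), preserving group sizes and demographic
composition. The shuffled cohort is re-analyzed with the identical LOOCV
loop, except each fold's peak listing is forced to exactly the median
per-fold count of the true-pathology run (rank by ascending p, threshold
relaxed as needed) and the true-pathology multiplier is reused for the
cut-off lines. On real effects the randomized group p collapses toward
non-significance while the true p stays extreme.

## External assignment (`seroclass.assign`)

A blinded subset can be held out of the cohort and scored once against
the full training-set peak listing; training members keep ordinary LOOCV
scores. Unrelated external samples (same grid and preprocessing) are
scored against a fixed listing and tallied by cut-off side; samples in
the dual TP/FN zone between crossed lines are tallied indeterminate
rather than forced to a side.

## MS/MS hit-table filter (`seroclass.msms`)

A protein entry passes toward group A when: group-A positive sera ≥ 3
(of 8 per group), the positive-sera ratio A/B ≥ 2, and the hit (spectral
count) ratio A/B — rounded half-up to one decimal first — is ≥ 1.5.
A zero-count denominator passes its ratio test (required to admit
exclusive-detection entries such as 4(84):0(0)). The filter is
idempotent and exactly mirrored under a group swap. Downstream exports:
log2((hits_A + 1)/(hits_B + 1)) per symbol for pathway-analysis tools,
and per-phenotype-annotation tallies with half-up integer percentages.
The packaged differential tables (90 + 64 = 154 entries) all pass in
their stated directions.

## Synthetic cohorts (`seroclass.simulate`)

Patient sera are not publicly deposited, so cohorts are simulated.
Signal-carrying bins (fraction `peak_density` = 0.2 of the 1601-bin
grid, placed on slots ≥ 3 m/z apart so centroiding resolves each peak)
receive a shared log-baseline mu_j ~ Normal(2, 1). A sample's true log
intensity is mu_j + eps with eps ~ Normal(0, 0.4); planted
discriminatory bins (default 100) add `effect_delta` × 0.4 in group A.
Each of 3 replicates multiplies the truth by log-normal noise with
coefficient of variation 0.15. Sex and age are drawn per group from
study-like ranges and feed only the randomization balancing. Everything
is deterministic per seed (`numpy.random.default_rng`).

Defaults are the documented study-like conditions (15 vs 14 samples,
100 planted peaks, standardized shift 2) and were fixed before any
acceptance evaluation. Realism limits: no isotope envelopes, charge
states, chemical baseline, or instrument drift.

## Known limitation: score t-test under the null

The group-level Welch t-test on LOOCV scores is **anti-conservative
under the null**. The N per-fold peak listings share N−2 samples, so the
N scores are strongly positively dependent, while the t-test treats them
as independent; on label-exchangeable simulated data it rejects at
roughly 20–40% instead of 5%. This is a property of the method (verified
with an independent brute-force reimplementation and across a wide range
of candidate-bin counts), not of this implementation. It is why the
randomization control matters: inference about a real effect should rest
on the contrast between the true-pathology p and randomized-relabeling
p, not on the raw score t-test alone. The corresponding null-calibration
acceptance test is left failing by design, with this analysis.

## Numerical choices

- Student-t tail probabilities via `scipy.special.betainc` (vectorized
  per-column in the fold loop) and `scipy.stats` elsewhere.
- Half-up rounding (`floor(x·10^k + 0.5)/10^k`) wherever the published
  tables use spreadsheet-style rounding.
- All percentages are exact ratios of integer counts until final
  rounding for display.
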