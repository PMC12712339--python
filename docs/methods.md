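# Methods

This note documents the statistical procedures implemented in `ecmet`, the
defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Study design assumed throughout

Four endothelial cell lines — two lymphatic (iLEC, HDLEC) and two
blood-derived (HDBEC, HUVEC) — cultured to confluence and sampled daily in
triplicate over a ten-day course. Days ≤ 2 are treated as actively
proliferating, days ≥ 5 as contact-inhibited quiescent, and days 3–4 as a
transitional window that is excluded from two-group contrasts. The
canonical state contrast is day 5 (quiescent) versus day 2 (proliferating);
the identity contrast is LEC versus BEC, with the vascular bed constant
within a cell line.

## Ion annotation

Flow-injection TOF data carry no retention time, so identification is by
accurate mass alone and is therefore *putative*: every reference compound
whose adduct-predicted m/z lies within the tolerance of a measured ion is
reported, ambiguity included, ordered by |Δm|. The default adduct model is
deprotonation only (negative mode), m/z = M − 1.007276; an [M+F]⁻ entry is
available for fluoride-rich mobile phases and the table is extensible.
Tolerance is absolute (1 mDa default, 3 mDa recommended for supernatant
data, which are acquired on a different instrument); a ppm mode exists but
is off by default. The interval search over a sorted reference array is
exactly equivalent to the all-pairs scan (tested against it), and hit sets
are monotone in the tolerance.

## Drift and cell-number normalization

Instrument response in long flow-injection sequences drifts slowly with
injection order. Because injection order is randomized against the design,
the per-sample **median** intensity over all ions is a design-independent,
outlier-robust tracer of that drift. Each sample *j* is rescaled by

s_j = reference / median{ m_k : k in window(j) },

where m_k are per-sample medians in acquisition order, window(j) is a
centered window of `window` consecutive acquisitions (default 15; at the
sequence edges the window slides inward so it always spans `window`
acquisitions, and `window = n` degenerates to a single global median
scaling), and the reference is the global median of the m_k — a
scale-preserving choice. A per-ion variant (each ion trace corrected by its
own windowed median) is available behind a flag.

Properties worth knowing: on planted monotone drift of amplitude 0.5 the
correction reduces |Spearman ρ| between sample medians and acquisition
order from > 0.9 to ≈ 0.05–0.1; it is exactly idempotent for samples whose
window members all have fully centered windows on noise-free smooth drift,
while under replicate noise a second pass produces residual factors at the
noise scale (they shrink by more than an order of magnitude versus the
first pass). The window length trades bias against variance: windows much
shorter than the drift time scale track it faithfully; windows approaching
the sequence length undercorrect.

Cell-number differences at sampling scale all ions of a sample together;
within each cell type every sample is rescaled so its mean ion intensity
equals the cell-type grand mean (the mean of per-sample means), which
preserves the total signal per cell type.

Z-scoring (used for heatmaps, correlation and PLS-DA autoscaling) uses the
sample standard deviation (ddof = 1); vectors with fewer than two observed
values or zero variance become all-missing with a warning rather than ±∞.

## Differential statistics

Tests run on log2-transformed intensities; the fold change is the
difference of group means on the log2 scale, oriented
quiescent − proliferating. The default test is Welch's (unequal variances
are likely between growth states); a pooled-variance Student variant is
available. Missing values are handled pairwise-complete per feature;
features with fewer than two observations in either group yield missing
results and are excluded from the multiplicity-correction denominator.

Note on small samples: with 3 replicates per group Welch's approximation is
conservative — its true type-I error at nominal 0.05 is ≈ 0.035 (measured
by direct simulation in the acceptance script); the Student variant sits at
0.05 under equal variances. This is inherent to the Welch–Satterthwaite
degrees of freedom at n = 3, not an implementation artifact.

Storey–Tibshirani q-values estimate the null proportion as
π̂₀(λ) = #{p > λ} / (m(1 − λ)) on λ = 0.05, …, 0.95, smooth the profile
with a cubic smoothing spline, evaluate it at λ = 0.95 and clip to
[1/m, 1]; q(p₍ᵢ₎) = min over t ≥ p₍ᵢ₎ of π̂₀ m t / #{p ≤ t}, which is
monotone in p by construction. Below m = 20 p-values the spline is
unstable and π₀ falls back to 1, making the q-values identical to BH.

Significance calls use strict inequalities: |log2 FC| > 0.5 **and**
q < 0.05 (proteomics-style, Storey) or adjusted p < 0.05
(metabolomics-style, BH). The cross-line core signature intersects
per-cell-line calls at the stricter |log2 FC| > 1, q < 0.01.

## Pathway over-representation

One-sided upper-tail hypergeometric test of a selection of size n against
each pathway (K members in a universe of N), BH-corrected across pathways.
Directional mode tests the up- and down-regulated selections separately
(BH within each direction by default, pooled on request) and attaches a
signed score, ±(−log10 FDR). Protein mode selects by q < 0.05 and
|log2 FC| > 0.5; metabolite mode by raw p < 0.05 and |log2 FC| > 0.25 with
the pathway call at BH-adjusted enrichment p < 0.05. The universe defaults
to the analyzed features that belong to at least one pathway set; ORA
p-values are sensitive to this choice, so it is an explicit argument.

## PLS-DA marker discovery

A two-class PLS-DA is a PLS1 regression of the centered class code
y ∈ {+1 = LEC, −1 = BEC} on autoscaled intensities (constant features
dropped); the fit is the NIPALS algorithm (via scikit-learn, cross-checked
in the tests against an independent w ∝ Xᵀy / deflation oracle to 1e-8).
Component signs are arbitrary, so the first latent variable is oriented to
score LEC samples positive; its unit-norm weight vector ranks features by
class-discriminating information.

Raw weight tails are noisy, so selection is stabilized by bootstrap:
samples are resampled with replacement within each class, the model refit,
the replicate's LV1 sign-aligned to the full-data weights (flipped when the
correlation is negative), and each feature scored for membership in the top
or bottom `tail` fraction (default 10%, i.e. the 90th/10th weight
percentiles) of that replicate's weights. The **consensus** rule keeps a
feature as LEC-associated when it occupies the top tail in at least
`consensus` (default 0.9) of B replicates (default 1,000; 200 suffices at
the tested effect sizes), BEC-associated symmetrically; the lists are
disjoint. The alternative **ci** rule keeps a feature when its bootstrap
weight distribution's [tail, 1 − tail] percentile interval excludes zero —
it is markedly more liberal, and both modes are exposed because a plain
decile cut of the full-data weights would force equal-sized lists, which is
not how stability selection behaves. Resampling strata are tied to sample
positions rather than class labels, so swapping the two class labels
exactly swaps the output lists under the same seed.

The permutation null re-runs the full bootstrap selection under permuted
bed labels and records the null distribution of selected-feature counts;
p = (1 + #{null ≥ observed}) / (1 + n_permutations). Labels can be permuted
at the sample level (default, 999 permutations) or at the cell-type level.
With four cell types the cell-type level has only C(4,2) = 6 assignments,
of which the observed one and its complement (the same partition with
class labels swapped — selection lists merely exchange) are not genuine
null points; the remaining 4 are enumerated exhaustively with a warning,
so the smallest achievable p is 1/5. A significant sample-level p with a
floor-bound cell-type p is the expected pattern when bed identity is real.

## Exometabolite rates

Each (ion, condition, replicate) supernatant series at 0/2/22/24 h after
medium exchange is divided by its t = 0 intensity (series with missing or
non-positive t = 0 are excluded with a warning); the uptake/secretion rate
is the OLS slope of normalized intensity on time, in normalized
intensity·h⁻¹, negative for net uptake. Replicates are pooled into one
regression per condition by default (one slope from all points, more
stable at 4 time points); with balanced identical designs this equals the
mean of per-replicate slopes, and a per-replicate mode reports mean ± SD.
No blank or medium-degradation correction is applied by default. Because
absolute rates scale with each compound's initial medium abundance,
cross-condition figures use the per-ion z-score of rates.

## Phenotype statistics

Growth: every confluence curve is interpolated to the control time grid
and divided pointwise by the control **mean** curve (no replicate pairing
is assumed); the per-replicate statistic is the trapezoidal AUC of the
normalized curve (so an ineffective treatment has AUC equal to the time
span), compared by a two-sided Welch t test of treated versus
control-normalized-control AUCs. Migration: rate = (width₀ − width₁₂)/12 h
in µm·h⁻¹ from scratch widths at 0 and 12 h; negative closure is kept but
flagged; rates are reported as fractions of the control mean (a 60%
decrease prints as 0.4) with a Welch t test per condition.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the analysis assumes:
log2-normal intensities around feature baselines Uniform(10, 25) log2
units (the dynamic range of label-free data); planted state markers
shifting ±effect (default 1.5 log2) in quiescence (half-effect on the
transitional days); planted bed markers shifting the full effect between
LEC and BEC lines; i.i.d. replicate noise (default SD 0.25 log2);
multiplicative injection-order drift rising linearly to 1 + amplitude
(default 1.5×) over the randomized acquisition sequence; supernatant series
I(t) = I₀(1 + rt) + ε with rates ~N(0, 0.02 h⁻¹) truncated at ±0.04 (so
24 h intensities stay positive) and ε relative to I₀ (2%); logistic growth
curves (g = 0.08 h⁻¹, treatment-scaled) and an 800 µm scratch closing
400 µm in 12 h (treatment-scaled), both with 2% multiplicative noise.
An optional missing-not-at-random dropout censors intensities below a log2
threshold (off by default).

It does **not** emulate raw spectra, isotope patterns, chromatography,
correlated (e.g. batch- or pathway-structured) noise, heavy-tailed
outliers, or intensity-dependent variance. Passing recovery tests
therefore demonstrates correctness of the procedures under their stated
assumptions, not robustness to every pathology of real instrument data.
Replicate-to-replicate variance defaults are field conventions, not
estimates fit to any particular dataset.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the statistical checks at
the sizes that make them meaningful and quick: 2,000-feature null and
planted-FDR simulations (50 seeds), 1,000 features × 24 samples with
B = 200 for bootstrap marker recovery, 120-sample day courses for drift
correction, 100 ions for slope recovery, and exhaustive oracle sweeps
(all hypergeometric instances with N ≤ 12; 1,000 ions versus 500
compounds). All randomness flows through explicit `numpy` Generator seeds;
identical configs give byte-identical pipeline outputs, and the pipeline
stamps every output file with the tool version, a hash of the analytic
parameters, and the seed.

## Known limitations

- Storey's π₀ spline uses scipy's default smoothing, not the exact
  smoothing parameter of the original R implementation; at m ≥ a few
  hundred the difference in q-values is negligible, but single-digit
  feature counts near the q = 0.05 boundary can differ from other
  implementations.
- The moving-median correction assumes drift is shared across ions;
  ion-specific drift requires the per-ion mode, which is noisier.
- Bootstrap selection sizes depend on B, tail, consensus and the noise
  level; the consensus and ci readings of percentile-based selection give
  deliberately different list sizes on real data.
- Rates are relative (normalized intensity·h⁻¹); conversion to molar
  exchange fluxes would need cell counts and calibration, which are out of
  scope.
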