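# Methods

## The adjustment model

Two-step cis-MR treats a crude variant–outcome association
β<sub>GO</sub> as the sum of a direct path through the exposure of
interest and one or more biasing paths through confounder phenotypes
(phenotypes affected either pleiotropically by the instrument itself or
by a variant in LD with it). Each biasing path equals the product of
the variant–confounder association β<sub>GC</sub> and the
confounder→outcome causal effect β<sub>CO</sub>; the adjusted
association subtracts these products:

    b_adj = b_GO − Σ_k b_GC,k · b_CO,k

β<sub>CO</sub> is itself an MR estimate (typically from a genome-wide
instrument for the confounder), so the adjustment inherits the
instrumental-variable assumptions of both MR analyses plus those of the
product-of-coefficients method: no residual confounding of any input
estimate, correctly specified pathways, linearity, and no effect
modification. With several pathways, validity additionally requires the
pathways to be **mutually independent**; if one confounder causes
another, their paths share a segment that is subtracted twice, and the
package emits a `PathwayIndependenceWarning` whenever more than one
pathway is supplied. The dependent-pathway simulation scenario
quantifies that failure mode.

## Uncertainty propagation

The three estimates entering each subtraction are assumed to come from
independent (non-overlapping) samples; no covariance inputs are
accepted. The propagated variance uses the exact variance of a product
of two independent normal estimates,

    se_pe² = se_GO² + b_GC²·se_CO² + b_CO²·se_GC² + se_GC²·se_CO²,

accumulated additively over pathways. The `se_GC²·se_CO²` cross term
makes this exact rather than first-order; a `first_order=True` flag
drops it for comparison (the first-order value is never larger).
`se_pe ≥ se_GO` always — adjustment cannot reduce uncertainty. The
parametric bootstrap redraws each input from a normal distribution
centred on its estimate (the only bootstrap available in a summary-data
setting), with a mandatory seed; at the default 10,000 replicates it
agrees with the closed form to well under 2% and converges to it as the
replicate count grows, since the closed form is exact for this
functional. Both SEs are biased if the input estimators are far from
normal. Pathway SEs of zero are accepted as degenerate point-mass
inputs (useful for expressing known-exact components); the
variant–outcome SE must be strictly positive.

## Harmonization rules

Records are keyed by `snp_id` only (no positions, no genome-build
logic) and aligned to the base study's effect allele. Swapped alleles
negate the beta and complement the EAF; alleles matching only after
strand complement (A↔T, C↔G) are relabelled. For palindromic variants
(A/T, G/C) the letters cannot identify the strand, so the allele
frequency decides: if either study's EAF is missing or within a window
of 0.5 (default w = 0.08, configurable) the variant is dropped as
ambiguous; otherwise frequency concordance determines keep-versus-flip.
Instrument selection uses a strict inequality, p < 5×10⁻⁸ by default,
with a two-sided normal p computed from beta/se when no p-value is
reported. LD clumping and proxy imputation require an external
reference panel and are out of scope: inputs are assumed pre-clumped.

## Estimator suite

Per-SNP Wald ratios default to the first-order SE (se<sub>GY</sub>/|b<sub>GX</sub>|);
the delta-method SE including variant–exposure uncertainty is opt-in.
IVW is the fixed-effect inverse-variance-weighted mean of the ratios
(algebraically a zero-intercept weighted regression). MR-Egger is a
weighted regression with intercept after orienting all variant–exposure
effects positive; its SEs use the multiplicative random-effects
convention (residual scale floored at 1), and it is undefined when all
|b<sub>GX</sub>| are identical. The weighted median interpolates the
cumulative standardized weights at 0.5 using S<sub>j</sub> − w<sub>j</sub>/2
pivots; the weighted mode maximizes an inverse-variance-weighted normal
kernel density whose bandwidth is 0.9·(MAD/Φ⁻¹(0.75))·n^(−1/5) scaled
by a user `bandwidth_factor` (default 1). Median and mode SEs come from
a seeded parametric bootstrap (default 1,000 replicates). Cochran's Q
with first-order weights serves as the pleiotropy falsification test;
instrument strength is the squared z-score F = b<sub>GX</sub>²/se<sub>GX</sub>².
In the pipeline the primary estimator is IVW unless Q's p-value falls
below 0.05 (configurable), in which case the weighted median is used —
for the confounder→outcome step and the exposure→outcome step alike.

## Simulation study

The generator reproduces the validation experiment's conditions: a
single cis variant coded additively as binomial(2, p) under
Hardy–Weinberg equilibrium (the standard reading of a three-level
genotype), allele frequency drawn per repetition from N(0.5, 0.1)
truncated to (0.01, 0.99); variant effects on the exposure and on each
confounder drawn independently from N(0.1, 0.05) per repetition; all
other nodes standard normal with unit structural effects; true
exposure→outcome effect 1. Each confounder carries a genome-wide
genetic liability Z with unit effect, used as its MR instrument. Every
association (variant–exposure, variant–outcome, variant–confounder,
liability–confounder, liability–outcome) is estimated by simple OLS in
its own independent sample of 200,000 individuals — five samples in the
single-pathway scenario; a `joint` mode estimating both liability
regressions in one sample is available (`split` is the default). Per
repetition the crude estimate is the Wald ratio b<sub>GY</sub>/b<sub>GX</sub>
and the adjusted estimate applies the pathway subtraction (sequentially
for two-pathway scenarios) before taking the ratio. Scenarios:
`single_pathway`; `two_independent` (two separate pleiotropic
confounders); `two_dependent` (the first confounder causes the second
with unit effect, so the pathways share a segment).

Summaries report means, biases against the true effect, mean crude /
propagated / bootstrap SEs, mean 95% CI bounds, and a Monte-Carlo SE
(sample SD / √n_reps) for every mean.

### Engines

`run_simulation` defaults to an *analytic* engine that samples the OLS
estimates from their exact finite-sample distribution given the
genotype design: multinomial genotype counts give the regressor sum of
squares, the slope is normal around the true structural coefficient
with variance (residual variance)/S<sub>xx</sub>, and the residual sum
of squares is chi-square. For this linear-Gaussian mechanism the
resulting estimate distribution is the same as simulating individuals
(up to the negligible non-normality of the small binomial component in
the liability-regression residuals), and it is ~1000× faster, which is
what makes full-sample-size repetition counts practical on one CPU. The
literal `individual` engine draws every participant and is
cross-validated against the analytic engine in the test suite.

### Ratio instability and the instrument guard

Because the variant–exposure effect distribution N(0.1, 0.05) places
mass near zero, the per-repetition crude ratio 1 + b<sub>GC</sub>/b<sub>GX</sub>
is Cauchy-like: its mean over repetitions does not converge, and the
mean of 1/|b<sub>GX</sub>| (which enters the mean reported SEs)
diverges logarithmically. Repetitions whose estimated instrument
z-score falls below `min_instrument_z` (default 2) are flagged and
redrawn, which truncates the worst of the tail; with this guard the
mean crude estimate stabilizes around 2.2–2.3 and the mean crude SE
around 0.09 at 5,000 repetitions, but both remain tail-sensitive and
seed-dependent in a way the adjusted estimate is not. Consequently,
only tail-insensitive summaries of this design are reproducible across
independent implementations and seeds: the adjusted mean (1.000), the
near-unity adjusted mean under two independent pathways, the *sign* of
the dependent-pathway overadjustment, the ratio of propagated to crude
SE (≈1.23), and the bootstrap/closed-form SE agreement. Crude-side
means and the magnitude of the dependent-pathway overadjustment are
realizations of a non-convergent average, and externally printed values
for them should not be expected to replicate. The test suite keeps the
corresponding assertions at their stated bands and lets them fail
rather than widening them.

### What the generator does and does not emulate

It emulates two-sample summary-data MR with perfectly independent
samples, a single causal variant, linear effects, continuous
phenotypes, and normally distributed estimates. It does not emulate LD
structure (the pleiotropic-variant and LD-confounding cases are
formally identical at the level of summary statistics), binary traits /
liability-scale transformations, sample overlap, population
stratification, or weak-instrument bias beyond the guard. Passing
simulation checks therefore validate the adjustment algebra and its
error propagation, not robustness to those real-data features.

## Numerical choices and degenerate inputs

95% CIs use Φ⁻¹(0.975) = 1.959964. The weighted-mode grid spans the
ratio range ± 3 bandwidths at 10,000 points; all-equal ratios short-
circuit to that value (zero bandwidth). Zero b<sub>GX</sub> raises an
undefined-ratio error; bootstrap draws that hit exactly zero are
nudged to the smallest positive float (measure-zero event). Instruments
missing from a confounder table are excluded with a warning rather than
imputed as zero, since a silent zero would masquerade as "no bias".
Harmonization is idempotent, and a double allele flip restores the
original record — both are property-tested.

## Known limitations

- No correlated-instrument (LD-matrix) IVW, MR-PRESSO, or
  contamination-mixture estimators.
- No adjustment for overlapping samples between the three input
  estimates.
- Positionless records: duplicate rsIDs across strands are not
  resolvable.
- The applied CRP→CAD workflow requires user-downloaded OpenGWAS
  extracts (`ukb-d-30710_raw`, `ebi-a-GCST005195`, `finn-b-T2D`); the
  package never downloads data.
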