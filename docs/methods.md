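# Methods

## The two-step pool model

The autophagosome pool is modelled as a single compartment with an input
(formation of new autophagosomes, marked by LC3-II) and an output
(lysosomal degradation). Two assumptions make the four-condition LC3
turnover assay identify both arms:

1. **Basal equilibrium.** In the control condition the pool is at steady
   state, so basal formation equals basal degradation; both equal the
   basal flux, LC3-II(EXP−, BAF+) − LC3-II(EXP−, BAF−).
2. **Complete inhibition.** The lysosomal inhibitor fully blocks
   degradation during the treatment window, so the BAF+ lane accumulates
   every autophagosome formed in that window on top of the starting pool.

Under these assumptions, for any condition *c*:

- degradation D(c) = value(c, BAF+) − value(c, BAF−) — the conventional flux;
- formation  F(c) = value(c, BAF+) − value(EXP−, BAF−);
- pool(c)    = pool_ss + F(c) − D(c), which algebraically equals
  value(c, BAF−). The `pool_balance` residual checks this identity and is a
  pipeline self-test, not a biological quantity: any nonzero residual means
  a software defect.

Quantities are *amounts per treatment window* in the arbitrary units of the
chosen normalisation; no per-hour division is applied because the defining
differences contain no time term. `duration_h` is carried as metadata for
cross-experiment comparison.

Ratios: F(c)/F(EXP−), D(c)/D(EXP−), and the net turnover ratio D(c)/F(c).
The basal condition's ratios are returned as exactly 1 — the equilibrium
assumption forces flux/flux — even when a replicate's basal flux is
nonpositive (which still triggers a warning and leaves the treatment
conditions' ratios undefined, since their denominators are then
meaningless). Undefined ratios propagate as NaN with a logged count; they
are excluded from downstream t-tests, never silently dropped. Negative
rates are reported as-is with a flag: clamping at zero would bias the ratio
statistics, and a negative rate usually signals incomplete inhibition or
densitometry noise worth surfacing.

Rates are computed per replicate (each replicate's four lanes come from one
blot) and summarised as mean ± SEM afterwards, preserving the pairing the
statistics need. Multiple treatment levels (e.g. a dose series) are handled
as k conditions each referenced to the single control.

### Normalisation schemes

`lc3ii_over_control` divides LC3-II by the loading-control band (typically
β-actin); `lc3ii_over_lc3i` divides by LC3-I; `percent_over_control`
further divides by the same replicate's reference-cell quotient and
multiplies by 100, so the control/BAF− cell is 100 by construction. All
ratios are invariant to the choice as long as one scheme is applied to all
four cells (tested); the formation/degradation *amounts* scale with it.

## Scenario simulator

The simulator draws the four cell expectations from
(pool_ss, basal_flux, f_mult, d_mult):

```
(EXP−, BAF−) = pool_ss                  (EXP−, BAF+) = pool_ss + b
(EXP+, BAF+) = pool_ss + f·b            (EXP+, BAF−) = pool_ss + f·b − d·b
```

A spec is rejected up front if d·b exceeds pool_ss + f·b (more degraded
than exists). Lane noise is multiplicative lognormal with mean 1 and a
stated coefficient of variation, independent per lane — densitometry error
scales with band intensity, and the assay literature offers no measured
noise model to prefer. Defaults (pool 100 au, basal flux 50 au, CV 0.1,
n = 3) mirror a typical three-replicate blot experiment. Presets use 2×
("up") and 0.5× ("down") multipliers; the magnitudes are conventional, only
the directions are meaningful, and both are overridable.

What the generator does *not* emulate: partial lysosomal inhibition,
saturating chemiluminescent detection, blot-to-blot transfer gradients, or
correlated noise across lanes of one blot. Passing recovery tests therefore
demonstrates that the estimators invert the model, not that real blots meet
the model's assumptions.

A note on ratio estimators: per-replicate condition ratios are ratios of
noisy differences and are right-skewed at realistic noise (their mean
exceeds the true multiplier even though the rate estimators themselves are
unbiased). This is inherent to the per-replicate design choice, which is
kept because it preserves the pairing needed for t-tests.

## Densitometry

The lane workflow mirrors classic gel-analysis software with the manual
steps made explicit and automatic: rectangular lane ROIs (row/col, 0-based,
half-open everywhere) are summed across the lane width into a migration
profile; a baseline is estimated; band areas are the baseline-subtracted
profile, clamped at zero (areas are physical), summed over caller-supplied
intervals. Band intervals come from configuration rather than peak
detection because band identity (LC3-I vs LC3-II) requires
molecular-weight knowledge the image does not contain.

Baselines: `rolling-ball` is a 1-D grey opening with a flat structuring
element of radius `window` px (default 50); `straight-line` interpolates
between the local minima flanking detected peaks. The flat-element opening
leaves a plateau at the higher shoulder of a peak on a slanted background,
so the window should comfortably exceed the widest band *cluster* — on a
clean background a window of half the profile length is safe, while on
sloped backgrounds smaller windows (≥ 4σ of the band) keep the plateau
error under a few percent.

The synthetic gel generator renders each band as a discrete Gaussian
truncated at ±4σ and renormalised so the stated total intensity is carried
exactly — this makes conservation checks exact with finite integration
windows. Suggested integration windows (±4σ, clipped at the midpoint
between adjacent bands so neighbouring windows never overlap) are provided
by `integration_intervals`. Bands closer than 6σ are refused: their ground
truth is ambiguous. Pixels at ≥ 98% of the dynamic range flag the band as
saturated, since chemiluminescent detection is nonlinear near saturation.

## Statistics

The decision cascade for a k × 2 design:

1. Two-way ANOVA (treatment × inhibitor, type-I sums of squares; designs
   are balanced, where all SS types coincide) on the raw normalised table.
2. If the interaction is significant at α = 0.05, the treatment effect is
   re-tested by one-way ANOVA within each inhibitor level.
3. Flux, formation and degradation: one-tailed two-sample Student t-tests
   (pooled variance; Welch behind a flag; paired optional) for a single
   treatment level, or one-way ANOVA followed by a Holm–Šidák step-down
   over each-treatment-vs-control comparisons (all-pairwise by flag) for
   dose series.
4. Formation, degradation and net ratios are tested against the basal
   reference value 1 with one-tailed one-sample t-tests. "Compared to one"
   is only meaningful for the dimensionless ratios, so that is what is
   tested.

Every p-value is tiered: significant (p < 0.05), tendency (p < 0.1), ns.
One-tailed directions are never inferred from the data — post-hoc direction
choice doubles the type-I error — and default to "greater" with a note in
the report when unconfigured. Shapiro–Wilk and Levene screens are reported
as advisory only; no automatic nonparametric fallback is applied. Zero
within-group variance raises a degenerate-data error rather than returning
p = 0: real densitometry never has zero variance, so such input indicates a
pipeline bug. The end-to-end runner downgrades that error (and n = 1
inputs) to a skipped-statistics warning so noiseless sanity runs still
produce estimates.

Holm–Šidák: with m hypotheses sorted by ascending raw p, adjusted
p(i) = 1 − (1 − p(i))^(m − i + 1) with a running maximum; rejection
proceeds while adjusted p < α. The implementation is cross-checked against
statsmodels' `multipletests` in the test suite.

## Problem sizes and numerics

Test and acceptance runs use: 1,000 randomized designs for the
mass-balance identity (tolerance 10⁻⁹ relative — pure floating point),
500 random specs for exact recovery, 10,000 replicates at CV 0.1 for the
unbiasedness check (criterion: |bias| < 3 Monte-Carlo SEM), 20,000 null
simulations for the type-I error of the vs-1 test (0.05 ± 0.01), and 100
random synthetic gels for the densitometry round-trip (every band within
5%, bands ≥ 6σ apart, pixel noise ≤ 2% of the faintest band's peak
height). These sizes keep every Monte-Carlo criterion's sampling error
well below its tolerance while completing in seconds.

## Known limitations

- The equilibrium and complete-inhibition assumptions are untestable from
  the four lanes themselves; violations bias formation estimates downward
  (partial inhibition) or shift the basal anchor (non-steady basal state).
- Formation and degradation are treated as independent; biologically they
  are coupled through lysosomal capacity and feedback.
- No kinetic (time-course) modelling: one treatment window, amounts not
  rates per hour.
- Densitometry assumes rectangular, pre-located lanes and caller-supplied
  band windows; lane finding and molecular-weight calibration are out of
  scope.
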