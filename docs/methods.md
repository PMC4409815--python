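# Methods

This note documents the models, rules and numerical conventions the
package implements, the assumptions behind the synthetic-data
generators, and the design choices made where the underlying procedure
left room for interpretation.

## Imaging and quantification

A field is three single-plane 16-bit grayscale channels (nuclear stain,
GFP, DiI); coordinates are 0-based row-major pixels, areas are in
pixels, intensities in arbitrary units as acquired.

**Nucleus segmentation** thresholds the nuclear channel (Otsu by
default, or a fixed threshold from config), labels 8-connected
components and keeps those within the configured area bounds
(30–1,500 px by default).  **Cell approximation** grows each nucleus
outward by a constrained nearest-nucleus expansion
(`skimage.segmentation.expand_labels`): growth stops at the maximum
dilation radius (24 px) or where two nuclei are equidistant.  Pixels
exactly equidistant between nuclei are assigned deterministically by
the Euclidean feature transform; which of the tied nuclei wins is not
specified beyond determinism.  **Compartment detection** marks a pixel
as endosome-like when it exceeds the local mean over a square window
(31 px) by more than a fixed offset (30 a.u.), clips the foreground to
cell regions, splits connected pieces that straddle a cell boundary,
and applies segment-area bounds (3–400 px).  A uniform image has no
local contrast and yields no segments.

**Quantification** subtracts per-channel background levels (the GFP
level must come from the experiment's transfection-control sample;
negative background-subtracted pixels clamp to zero) and reports per
cell: mean GFP within the cell region; summed DiI within that cell's
segments (total LDL signal); mean DiI within segments (= total / summed
segment area, so the identity concentration x area = total is exact);
segment count; summed segment area.  Cells touching the configured edge
margin, outside the equivalent-diameter bounds, or with nucleus
centroids closer than the minimum neighbor distance are omitted
entirely.  The defaults for all QC bounds are package choices declared
in `SegmentationConfig`; they are not claimed to equal any particular
laboratory pipeline's values.

On rendered synthetic fields at default noise (Gaussian sd 4 on
backgrounds of 100–200), the recovered five-parameter vectors correlate
with ground truth at r > 0.99 and per-cell totals are within 5% of the
programmed values; the limiting factors are 16-bit quantization and the
local-threshold segment boundary, not the statistics downstream.

## Gating and replicate aggregation

The GFP-negative cutoff is the 97th percentile — linear interpolation
between closest ranks, numpy's default and configurable — of the
transfection control's GFP; cells at or above twice that cutoff are
GFP-positive; cells in between belong to neither group and are excluded
from both means.  Thresholds are derived per experiment, since each
experiment carries its own transfection control; whether the original
analysis pooled experiments is unknown, and per-experiment derivation
is the assumption made here.

Under the complementation ("rescue") setting an upper threshold removes
over-compensating cells: a GFP-positive cell is kept only if its total
LDL signal is below 1.25x the mean of the transfection control **or**
below 5x the mean of siRNA-treated cells.  The two caps combine with
logical OR by default (the literal reading of the rule); AND is
available for sensitivity analysis, as is the choice of siRNA baseline
sample (siRNA-only or siRNA + GFP-control).

Replicate summaries compute per-image means within each GFP group, then
average across images — never pooling cells across images, so an image
with many cells does not dominate.  The per-parameter ratio is the
GFP-positive over the GFP-negative replicate mean.  A replicate is a
valid independent observation only with at least 25 GFP-positive cells
and defined ratios.

## Significance and classification

For each parameter, variant replicate ratios are compared with the
wildtype ratios of the same experiments by a paired, two-tailed
Student's t-test at alpha = 0.05.  For total LDL signal a call
additionally requires a deviation value above 1.  The deviation value
is implemented as a z-score-like effect measure:

    deviation = |mean(variant ratios) - mean(wildtype ratios)|
                / SD(wildtype ratios)

This is an interpretation — the measure is named but not restated in
the underlying description — and both the formula's inputs and the
parameters it applies to are configurable (`SignificanceConfig`).  The
deviation criterion applies to total LDL signal only; the other
parameters use p < 0.05 alone.  No multiple-testing correction is
applied across parameters or variants, matching the stated criteria.
Fewer than two valid paired replicates make a call undeterminable
(neither significant nor non-significant); zero-variance paired
differences leave p undefined and the call not significant.

Classification: **disruptive_missense** requires overexpression total
LDL signal plus at least two other DiI parameters significant, and a
significant complementation total LDL signal as validation when
complementation data exist; with complementation data present but total
not significant the variant falls back to unclear, and with no
complementation data the disruptive call stands but is flagged as not
validated (the original study tolerated sparse complementation
replication).  **non_disruptive** requires that none of the eight DiI
parameters (four per setting) reach significance.  Everything else is
**unclear**.  GFP expression is reported but never enters the rule.
Free-cholesterol validation applies the identical criteria to filipin
GFP-positive/GFP-negative ratios.

A structural property worth stating: because three of the four DiI
parameters are gated by p < 0.05 alone and the two settings are
independent experiments, a truly neutral variant fails the
non-disruptive rule with probability at least 1 - 0.95² ≈ 10% even when
the four parameters are perfectly correlated — and the original screen
itself rated ~14% of its variants unclear.  Simulated screens at the
default conditions show ~10–15% of neutral variants landing in unclear;
recovery of programmed labels is therefore expected around 90–95% for a
20-variant screen, with seed-to-seed variation.

## Composite prediction score

Tool categories map to integers (PolyPhen-2: probably damaging -1,
possibly damaging 0, benign +1; SIFT: damaging -1, tolerated +1;
MutationAssessor: high/medium -1, low/neutral +1; MutationTaster:
disease-causing -1, polymorphism +1) and are summed.  Sums above 1 are
likely benign, below -1 likely FH.  Sums of exactly -1 or +1 — reachable
because PolyPhen-2 can contribute 0 — fall between the published
cutpoints and are assigned to unclear here.  Missing tools contribute 0
and are counted in `n_tools`.

## Burden association

A variant class collapses to a carrier flag (any allele of the class);
the 2x2 table against the binary phenotype is analyzed conditionally on
its margins: two-sided Fisher exact p (sum of table probabilities no
larger than the observed one, with the customary 1 + 1e-7 relative
slack), the conditional-MLE odds ratio solving E[X | psi] = a under the
Fisher noncentral hypergeometric distribution, and the exact conditional
95% CI inverting the one-sided tail tests at 0.025 each — the
conventions of standard exact-test software.  A zero carrier cell gives
an unbounded point estimate with a finite one-sided bound.  The sample
cross-product OR is reported alongside.  Roots are found by `brentq` on
the log odds to ~1e-12, which is tighter than the default tolerance of
common implementations; on one published table this moves the estimate
across a one-decimal rounding boundary (19.9497 vs a conventionally
reported 19.951).

Conventions: allele frequency is allele count divided by the number of
*subjects* analyzed (not chromosomes), matching the source table's
convention — a singleton among 3,235 subjects is 1/6,470 chromosomes ≈
1.5e-4 when expressed per chromosome.  Subjects with missing LDL-C are
excluded from LDL analyses only (hypercholesterolemia is LDL-C > 190
mg/dl) and retained for MI.  Effect sizes come from OLS of LDL-C on
carrier status with sex and age as covariates (statsmodels).  Polygenic
scores are plain weighted dosage sums.

The two-sided p-value is computed in-package by vectorized log-binomial
summation rather than per-call library routines; the exhaustive
small-table validation (~632k tables, exact integer arithmetic) and the
power simulation make ~1e6 evaluations, which requires the ~20 µs/call
implementation.  It is cross-checked against `scipy.stats.fisher_exact`
property-wise and against exact enumeration exhaustively.

## Power simulation

The disease model gives carriers a relative risk R at population
prevalence K, so P(carrier | case) = fR/(1+f(R-1)) and
P(carrier | control) = f(1 - RK/(1+f(R-1)))/(1-K).  Under retrospective
sampling, carrier counts per arm are binomial with those probabilities
— exact for this model, no individual-level simulation needed.  At each
total sample size (default grid: steps of 200 to 2,000, of 400 to
4,000, of 2,000 to 20,000; equal cases and controls), 1,000 simulations
draw the two counts and apply the two-sided Fisher exact test at
alpha = 2.5e-6 (exome-wide, ~20,000 genes); power is the fraction at or
below alpha, with its binomial Monte-Carlo SE.  Each grid point uses an
independent seed substream so single points reproduce in isolation.
The scenario frequency is taken as the pooled cohort class frequency,
held fixed across sample sizes (no modeling of new-variant discovery at
larger n).

Validation: the simulated power agrees, within Monte-Carlo error, with
the exact power obtained by enumerating the two binomial counts and
summing probability over the rejection region.  The common
normal-approximation two-proportion power formula is *not* an accurate
oracle at this alpha: the exact test's true power differs from it by up
to ~0.06 mid-curve (e.g. n_total = 1,400: exact 0.809 vs approximation
0.748), which is many Monte-Carlo standard errors at 1,000 simulations.

## Synthetic-data generators

**Cell feature tables.**  An experiment is one biological replicate of a
sample panel (the setting's required controls plus variant samples),
imaged at a configurable number of positions (default 30) with
Poisson-distributed cells per image.  Fluorescence intensities are
log-normal (strictly positive and right-skewed, as fluorescence data
are).  A fraction of cells in construct-transfected samples express GFP
(transfection efficiency 0.3); expressing cells draw GFP around a
median of 2,000 a.u. vs a background median of 100 a.u., so the
97th-percentile/2x gating recovers them cleanly.

Per-cell DiI readouts share structure at three levels, reflecting the
strong cross-parameter and cross-setting correlations reported for such
assays: a per-experiment batch factor (log-sd 0.15) common to every
sample of the experiment — the component that pairing variant and
wildtype within an experiment cancels; a per-sample-per-replicate
uptake jitter (log-sd 0.15) loading on all DiI readouts of the
GFP-positive subpopulation; and a per-cell uptake factor (log-sd 0.45)
shared by a cell's readouts, with residual per-parameter noise (log-sd
0.15).  The state of a cell sets its expected total LDL signal relative
to the endogenous baseline: 1 for non-expressing cells, 5x for
GFP-positive receptor-expressing cells under overexpression, 0.25x
after LDLR siRNA, 0.7x for GFP-positive rescued cells under
complementation (partial average rescue; the caps remove the
over-compensating tail).  A variant multiplies the GFP-positive
expectations: `ldl_multiplier` acts on total LDL signal exactly (the
identity-effect and multiplicative-recovery contracts are tested),
`seg_number_multiplier` and `seg_area_multiplier` on their parameters,
and LDL concentration is derived as total / area, so its effective
multiplier is ldl / seg_area — a deliberate deviation from treating it
as a free parameter, preserving the accounting identity.  The
disruptive preset splits a multiplier m as sqrt(m) on count and area.
Segment counts are Poisson; a zero-segment cell has zero total and
area by convention.

**What the generator does not emulate**: spatial context (the feature
tables are generated directly, not via rendered images), uptake-vs-GFP
dose dependence within the GFP-positive gate, plate or edge effects,
image-QC failures, hypomorphic variants with effects between 0.5 and 1,
or correlated annotation errors.  Passing tests on these tables show
the *statistical machinery* behaves as specified under the stated
model; they do not certify performance on real screens, where effect
sizes, noise shapes and unclear-rate behavior may differ.

**Images.**  Rendered cells are disk nuclei, diffuse GFP disks and
small DiI puncta placed on a ring between nucleus and cell boundary,
over constant backgrounds with additive Gaussian noise, quantized to
16 bits.  Ground truth records the rendered (pre-noise) per-cell sums,
so recovery tests compare against exactly what was drawn.  Optics are
deliberately idealized: no point-spread function, no shot noise, no 3-D
structure, no cell motion.

**Cohorts.**  Carrier flags are drawn per variant at the configured
population frequencies; a subject's disease probability is K0 times the
relative risk of the highest-risk class it carries, with K0 solved so
the marginal prevalence matches; cases and controls are then filled to
the requested sizes by rejection sampling, matching case-control
ascertainment.  LDL-C is baseline (135 ± 30 mg/dl) plus the shift of
the largest-shift carried class (defaults configured to reproduce group
means of 221 / 154 / 275 mg/dl for disruptive-missense / non-disruptive
/ LoF carriers) plus Gaussian noise, with a configurable missingness
rate (default 0.335, the fraction without LDL-C in the motivating
cohort).  Sex is Bernoulli(0.5) and age normal (42 ± 5 years); both are
used only as regression covariates.  A parameter combination implying a
carrier penetrance above 1 is rejected at generation time.

## Problem sizes and numerical conventions

The test suite exercises the full pipeline at reduced but statistically
meaningful sizes: screens of 12–24 samples x 4 replicates x 8–30 images
x 40–80 cells; imaging on three 512x512 fields of 20 cells; cohorts of
600–35,000 subjects; power curves at 200–1,000 simulations per grid
point; and the exhaustive exact-test validation over every 2x2 table
with total ≤ 60.  The acceptance script uses 30 images x 60 cells and
three screen repetitions, full default power grids at 1,000 simulations,
and the published cohort arm sizes (1,716 / 1,519).  All randomness
flows from explicit seeds through numpy Generators; per-stage substreams
derive from (seed, index) pairs.  Percentiles use linear interpolation;
ties and degenerate inputs (empty classes, zero-variance vectors,
all-missing tool calls) raise informative errors rather than guessing.

## Known limitations

- The deviation-value formula is an interpretation of a briefly named
  measure; alternatives (e.g. normalizing by a pooled SD) would shift
  borderline significance calls.
- The unclear category is irreducible under the stated rule: its rate
  is bounded below by the per-setting alpha, so label-recovery figures
  near 90–95% are the expected operating point, not a deficiency of the
  implementation.
- Power extrapolation holds the carrier frequency fixed as n grows;
  discovery of additional rare variants in larger samples is out of
  scope, so sample-size statements are conditional on the configured
  frequency.
- The burden test is a carrier-collapse Fisher test; dosage-weighted or
  variance-component tests (SKAT-style) are out of scope.
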