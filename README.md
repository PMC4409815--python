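# funcvar

Rare-variant association studies (RVAS) aggregate the carriers of rare
alleles in a gene and compare their burden between cases and controls.
Their power is throttled by a signal-to-noise problem: most rare missense
alleles are functionally neutral, and collapsing them together with the
few disruptive ones dilutes the association signal.  `funcvar`
implements, end to end, a strategy that fixes this for a gene with a
measurable cellular phenotype — the LDL receptor (*LDLR*) and its uptake
of fluorescent DiI-LDL: profile every missense allele in a cell-based
imaging assay, classify it as *disruptive-missense*, *non-disruptive* or
*unclear*, and run the burden association only on the alleles the assay
calls disruptive.

The package is aimed at statistical geneticists and high-content
screening analysts who want a tested, reusable implementation of each
stage, plus synthetic-data generators so every stage can be exercised
and validated without access to the original cohort or images.

## What is implemented

- **`funcvar.synthdata`** — generators with known, recoverable
  parameters: per-cell five-parameter feature tables for overexpression
  and complementation (siRNA rescue) experiments, and case-control
  cohorts with rare carriers, class-specific LDL-C shifts and a
  relative-risk MI model (carrier first, penetrance solved from RR and
  prevalence, rejection sampling to the requested arm sizes).
- **`funcvar.render` / `funcvar.imagequant`** — synthetic three-channel
  microscopy fields with exact ground truth, and the segmentation /
  quantification chain that turns nuclei + GFP + DiI images into the
  per-cell features: global-threshold nucleus masks with area bounds,
  constrained nearest-nucleus expansion for cell regions, local-adaptive
  (mean + offset) compartment detection, background-subtracted
  quantification with QC filters (edge contact, diameter, neighbor
  distance).
- **`funcvar.gating`** — GFP gating: the negative cutoff is the 97th
  percentile of the transfection control's GFP, the positive cutoff is
  twice that; under the rescue setting, GFP-positive cells above 1.25x
  the transfection-control mean total LDL signal *and* above 5x the
  siRNA-control mean are excluded as over-compensating.  Replicate
  summaries average per-image means and require >= 25 GFP-positive
  cells.
- **`funcvar.phenotyping`** — per-parameter paired two-tailed t-tests of
  variant vs wildtype replicate ratios, the deviation value (a
  z-score-like effect measure, |Δmean| / SD(wildtype ratios), required
  > 1 for total LDL signal), and the classification rule; also
  free-cholesterol validation and cross-setting concordance (Pearson
  r / r²).
- **`funcvar.insilico`** — the composite four-tool prediction score
  (PolyPhen-2, SIFT, MutationAssessor, MutationTaster mapped to
  -1/0/+1 and summed; > 1 likely benign, < -1 likely FH, else unclear).
- **`funcvar.rvas`** — burden association: carrier x phenotype 2x2
  tables (hypercholesterolemia at LDL-C > 190 mg/dl, or MI status),
  two-sided Fisher exact p, the conditional-MLE odds ratio of the
  noncentral hypergeometric likelihood with its exact conditional 95%
  CI (`funcvar.exact`), OLS effect sizes in mg/dl adjusted for sex and
  age, and weighted polygenic risk scores.
- **`funcvar.powersim`** — power curves for the burden test under the
  relative-risk carrier model: P(carrier|case) = fR/(1+f(R-1)),
  carrier counts drawn binomially per arm, two-sided Fisher exact test
  at exome-wide alpha = 2.5e-6, 1,000 simulations per sample size.
- **`funcvar.pipeline` / `funcvar.cli`** — a `funcvar` console script
  with subcommands (`simulate-cells`, `render-fields`, `quantify`,
  `gate`, `phenotype`, `insilico`, `simulate-cohort`, `burden`,
  `power`, `run-all`) and a reproducible end-to-end run directory.

## Worked example

The headline computation is the exact burden association.  Carriers of
disruptive-missense or loss-of-function *LDLR* alleles among subjects
with LDL-C above 190 mg/dl versus below: 27 of 251 hypercholesterolemic
and 9 of 1,901 normolipidemic subjects.

```python
>>> from funcvar import rvas
>>> res = rvas.exact_association(27, 224, 9, 1892)
>>> print(f"OR (conditional MLE) = {res['or_cmle']:.1f}")
OR (conditional MLE) = 25.3
>>> print(f"95% CI = {res['ci95'][0]:.1f}-{res['ci95'][1]:.1f}")
95% CI = 11.4-61.9
>>> print(f"two-sided exact p = {res['p_two_sided']:.1e}")
two-sided exact p = 6.3e-19
```

A carrier of a functionally disruptive rare allele has ~25-fold higher
odds of hypercholesterolemia; collapsing *all* missense alleles instead
gives OR 3.2 — the dilution the functional stratification removes.

Power of the burden test at the disruptive+LoF carrier frequency
(f = 0.0142, RR = 5, prevalence 0.05, alpha = 2.5e-6):

```python
>>> from funcvar.powersim import PowerSimConfig, simulate_power_curve
>>> curve = simulate_power_curve(
...     PowerSimConfig(carrier_freq=0.0142, grid=[1200, 1600, 2000]),
...     seed=1)
>>> print(curve[["n_total", "power", "mc_se"]].to_string(index=False))
 n_total  power    mc_se
    1200  0.655 0.015032
    1600  0.923 0.008430
    2000  0.980 0.004427
```

With equal cases and controls, roughly 1,500–2,000 sequenced subjects
in total suffice for exome-wide significance when only the functionally
disruptive alleles are counted.

A full synthetic demonstration (screen → classification → cohort →
stratified burden → power) runs with:

```sh
funcvar run-all --out demo_run --seed 0
```

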