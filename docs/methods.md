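# Methods

## Model

Interspecies scaling of clearance assumes the power law `CL = a · W^b`
across species, with `W` the species body weight in kg and `CL` absolute
clearance in mL/day. Fitting is ordinary least squares of `log CL` on
`log W` (natural log internally; the base is irrelevant to the recovered
`(a, b)` since `a = exp(intercept)` and `b = slope`). No weighting or
robust alternative is offered: with two or three points per fit a
spreadsheet-style power trendline — plain log-space OLS — is exactly what
the field uses, and a two-point fit is then the exact interpolant through
both points. The OLS itself is delegated to statsmodels; the grid-search
oracle in the test suite provides an independent check of every bundled
fit.

Correction-factor variants regress the product of clearance with a
species constant on body weight:

* **MLP method**: `CL × MLP` (years) fitted against `W`; the 70-kg
  evaluation is divided by the human MLP, 93.4 years.
* **Brain-weight method**: `CL × brain weight` (g) fitted against `W`;
  the evaluation is divided by the human brain weight, 1400 g.

Because the species correction constants (relative to the human values)
increase with body weight and are all below 1, both corrections pull the
human prediction below the simple-allometry value; the MLP pull is strong
enough that for therapeutic proteins it reliably lands far under the
observation. That is why the Rule of Exponents implemented here never
selects MLP for a biologic.

## Rule of Exponents

The decision variable is the exponent of the simple fit. Bands: `< 0.56`
(low, flagged), `0.56–0.70` (simple allometry), `0.71–0.99` (MLP band),
`1.0–1.3` (brain-weight band), `> 1.3` (high, flagged). For biologics —
the relevant class for ADCs — the rule collapses to a single threshold:
brain-weight correction iff `b > 1.0`, simple allometry otherwise. The
full small-molecule band logic is retained behind a `molecule_class`
switch for generality. Out-of-band exponents trigger no invented
correction; the band is recorded on the decision object so callers can
flag extrapolations they should not trust. The ROE requires at least
three species; two-species scaling is always plain simple allometry here,
and the API makes the other choice unrepresentable.

## Species constants and data conventions

Default registry: mouse 0.02 kg / 0.36 g / 3 y, rat 0.25 kg / 1.8 g /
4.4 y, monkey 3.5 kg / 63 g / 18 y, human 70 kg / 1400 g / 93.4 y
(body weight / brain weight / MLP). Clearances are stored as absolute
mL/day only — every computation in the reproduced analysis uses absolute
values, so a per-kg mode would add a silent unit-error surface for no
benefit. The observed human clearance lives on the series object, not
among the animal observations, so no fit can accidentally include humans.
Species matching is case-insensitive; animal panels are normalised to
ascending body weight on load. CSV interchange is comma-separated UTF-8
with a required header and `.` decimal.

## Fold-error evaluation

Prediction ratio = predicted / observed. Classification is a partition
with inclusive boundaries: `under` (< 0.5), `within` ([0.5, 2.0]),
`over` (> 2.0), always applied to the unrounded ratio — rendered tables
round to 2 decimals for display, but a ratio of 2.004 must classify as
`over` regardless of how it prints. Display percentages round half-up to
integers.

## One-species scaling

The fixed-exponent form is `CL_human = CL_species · (W_human/W_species)^b`
— the weight-ratio reading, under which exponent 1.0 is exactly linear
per-kg extrapolation (`CL × 70 / W_species`). This is the only reading
that reproduces the published one-species tables (e.g. monkey 46.55 × 20
= 931). Default exponent set {0.75, 0.80, 0.85, 1.0}; the averaging
strategy takes the arithmetic mean of the predictions over
{0.85, 1.0, 1.1}. The published description of the averaging exponents is
internally inconsistent (its methods text, discussion text and table
imply different third exponents); this package implements the stated
formula with the {0.85, 1.0, 1.1} default and documents the table-level
consequences in `docs/discrepancies.md` rather than chasing the printed
column.

## Synthetic data

The generator draws panels from the generative form of the model:
`CL_i = a · W_i^b · ε_i` with `log ε_i ~ N(0, σ²)`,
`σ² = log(1 + CV²)`. Lognormal multiplicative noise is the natural choice
because estimation happens in log space — it makes log-OLS the exact MLE,
so recovery claims are clean: zero noise gives exact recovery for any
panel of ≥ 2 distinct weights, and at CV 20% the exponent estimate is
unbiased with Monte-Carlo error shrinking as the panel's weight span
grows. The synthetic human "observation" comes from the same law at
70 kg. Default noise CV is 0.2, a realistic between-study scatter for
preclinical clearance estimates. Seeding uses one root seed with
per-replicate streams spawned via `numpy.random.SeedSequence`, so any
replicate set is reproducible and replicates are mutually independent.

What the generator deliberately does **not** emulate: target-mediated
disposition, species-specific linker deconjugation, nonlinear
dose-dependence, or any divergence between total-antibody and conjugate
kinetics. Passing recovery tests therefore show the estimator and
strategy logic are correct under the model's own assumptions — they say
nothing about whether a real ADC obeys the power law, which is exactly
the question the empirical dataset addresses.

## Numerical and reporting choices

Predictions always use unrounded `(a, b)`. For comparison against the
printed reference tables (which carry rounded values and, for the
two-species predictions, were demonstrably computed from rounded
intermediates), agreement bands are: exponents ±0.006 (half a printed
ulp, with margin for float edges), coefficients max(1%, 0.05),
three-species predictions 1.5%, two-species predictions 2%, one-species
predictions 1%, ratios ±0.02. Printed cells that are internally
inconsistent with the published input data are flagged
`documented_discrepancy` and excluded from assertions; they are
enumerated with magnitudes in `docs/discrepancies.md`.

Reported rounding follows the published convention: exponents to 2
decimals; coefficients to one decimal when ≥ 10, else two.

## Problem sizes

The empirical analysis is desk-scale (13 series, ≤ 3 animal points per
fit; the full pipeline runs in well under a second). Monte-Carlo checks
use 400–1000 replicate panels, enough to pin the exponent's Monte-Carlo
standard error an order of magnitude below the effects being asserted.

## Known limitations

* No uncertainty intervals on human predictions — with n = 2–3 species a
  regression interval would be decorative rather than informative, and
  the reproduced analysis reports none.
* The ROE thresholds are conventions, not estimated quantities; the
  package applies them exactly and flags out-of-band exponents instead of
  extrapolating the rule.
* Clearance values are inputs; no concentration–time profiles are parsed
  and no NCA is performed.
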