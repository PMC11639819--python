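# Methods

## Scope and structure

`pedibca` reproduces the computational pipeline of a portable pediatric
body-composition analyzer as published, arithmetic included, rather than
a physiologically corrected variant of it. The package therefore
contains two kinds of code: faithful transcriptions of the device's
equations (which are kept exactly as printed even where their unit
bookkeeping or numerical output is questionable — see *Known
inconsistencies*), and standard statistical machinery (OLS, ICC,
Bland–Altman, t-tests) implemented or delegated the way any analyst
would.

Modules: `sensor_models` (raw-signal forward models), `estimation` (the
chain to the six parameters plus the CDC weight-status classifier),
`regression_models` (published coefficient sets, OLS refitting, stepwise
selection), `agreement_stats` (accuracy family and method-comparison
statistics), `synthetic_cohort` (virtual cohorts and the sensor-chain
inversion), and `io`/`cli` (files, configuration, provenance, the
`pedibca` command).

## Sensor models

* **Load cell.** Two-point calibration; the offset is defined as
  `slope × zero-load counts` so the zero-load reference maps to exactly
  0 kg and both reference points are reproduced bit-for-bit. Negative
  computed weights raise an invalid-reading error instead of clamping:
  a negative weight always indicates a calibration or sensor fault and
  silently clamping would hide it.
* **Optical chain.** All logarithms are base 10. The chain
  OD → T → verified V is an exact algebraic inverse of itself, which the
  property suite checks at 1e−12 relative tolerance. The photodiode
  responsivity defaults to 0.42 A/W at 970 nm (the detector datasheet
  value used in the device's own worked computation; the alternative
  0.57 V/µW figure quoted for the same part is not used). No ADC
  quantization is modeled for the photosensor; voltages are exact
  decimal inputs.
* **Impedance.** The device's printed relation defines the reciprocal of
  impedance, so two modes are exposed: `printed` (`Z = I/ΔV`, the
  literal equation) and `conventional` (`Z = ΔV/I`, Ohm's law). The
  conventional mode produces the ohm-scale magnitudes (≈400–700 Ω for a
  child at 50 kHz) that the fat-free-mass and muscle-mass equations
  require, and is what the synthetic inversion targets; the mode used is
  recorded by callers. Excitation defaults: 0.25 mA, 50 kHz.

## Estimation chain

Height is converted to metres only for BMI; every other equation
receives centimetres (uniform symbol usage across the published
equation set). The impedance magnitude feeds the fat-free-mass equation
and doubles as the "resistance" of the muscle-mass equation unless a
separate resistance value is supplied — the device measures a single
bipolar 50-kHz signal and never distinguishes the two numerically. The
water equation's unspecified logarithm is taken as base 10, consistent
with the only explicit logarithms in the system (the optical chain); a
`log_base="ln"` switch exists for sensitivity analysis.

Physiologically implausible outputs — negative bone mass, body fat
outside [0, 100]% — are flagged with a `PhysiologicalRangeWarning` but
not rejected, because the printed equations can and do produce them on
in-range inputs. The CDC weight-status classifier consumes a
BMI-for-age percentile (it never computes one from growth references)
with half-open boundaries where the upper class wins at exact cut
points (85 → overweight, 95 → obese); the source table's "between"
phrasing is ambiguous at the endpoints and this choice is the common
screening convention.

## Published regression models

The coefficient table is the canonical source. The equation listing in
the same publication differs in two cells (the BF model's BMI
coefficient is printed with opposite sign, the FFM model's BF
coefficient as 0.310 instead of 0.130); both variants are retrievable
(`source="equation_text"`), and the table values — which match the
publication's own concluding summary — are the default. The bone-mass
model's BF coefficient is an explicit 0.000, not an omitted term. The
reported MultipleR/R² pairs are stored verbatim as metadata even where
R² > R, which is impossible for OLS; they are never validated against
each other or recomputed.

Refitting uses statsmodels OLS. Stepwise selection is
forward-entry/backward-elimination on partial-F p-values with the
common enter-0.05 / remove-0.10 defaults, deterministic given the input
table: ties break by smallest p-value then alphabetical predictor name.

## Agreement statistics

`accuracy`, `mean_accuracy`, `mean_avg_error` and the symmetric percent
difference are implemented from their definitions. The pooled metrics
divide by 2 × number of parameters with seven parameters (weight plus
the six composition outputs), which exactly reproduces the published
94.77% and 0.884. The percent-difference denominator is the mean of
the two group means; this reproduces six of the nine published cells to
printed precision (two of those appear truncated rather than rounded,
so comparisons use a 1e−3 absolute tolerance). The other three cells
are internally inconsistent in the source and are stored verbatim, never
asserted.

Bland–Altman uses bias ± 1.96 × sample SD (n−1). ICC defaults to
ICC(2,1) — two-way random effects, absolute agreement, single measures —
computed by `pingouin.intraclass_corr` with its F-distribution 95% CI;
the form is configurable (`ICC3` for consistency). The test suite
cross-checks the ICC against an explicit ANOVA mean-squares oracle.
SEM = SD·√(1−ICC). t-tests, Shapiro–Wilk and Pearson correlations are
delegated to scipy; only their contracts are asserted.

## Synthetic cohorts

The generator emulates the validation study's design: two groups of 100
children (obese / normal weight status), half boys and half girls, with
the published per-group mean ± SD for age, weight, height and the six
composition parameters as defaults. Draws are independent truncated
normals per parameter (default bounds keep weights and heights positive,
body fat in (0, 60)% and the impedance/resistance inversions in-domain);
independence is an explicit modeling assumption — the study publishes no
subject-level data or covariance. An optional Gaussian-copula mode
accepts a target correlation matrix (the published obese-group matrix is
packaged, mirrored symmetric and eigenvalue-clipped to the nearest
correlation matrix) for stress tests; it is an extension, not part of
the study design.

Two sampling modes exist because the published group means do not
satisfy the device's own identities (BMI, BF% and BM are deterministic
functions of the other quantities in the device, and evaluating those
functions at the published means does not return the published BMI/BF/BM
means). `marginal` mode matches the printed per-parameter statistics and
is the default for summary-level work; `chain` mode samples only the
free quantities (age, sex, height, weight, FFM, TBW, MM) and derives the
rest through the device equations, which makes the sensor inversion an
exact round trip. The CLI's `simulate` uses chain mode so that
`estimate` on its output reproduces the generating cohort to 1e−9.

The inversion solves the FFM equation for impedance, the MM equation for
resistance, the TBW equation for optical current, and the calibration
for ADC counts. When the implied detector voltage (photocurrent ÷
responsivity) falls within (0, V₀] — V₀ defaults to 0.5 V, the device's
worked-example level — the optical chain is inverted all the way to
voltages; otherwise the frame carries the optical current directly,
because the published water equation routinely implies photocurrents
orders of magnitude outside the optical front-end's physical range (see
below), and the estimation chain accepts a direct current input.

The virtual device pair adds independent zero-mean Gaussian error per
device per parameter. Default error SDs (0.70 kg weight, 0.45 kg/m²
BMI, 0.60 %-points BF, 0.50 kg FFM, 0.40 kg TBW, 0.45 kg MM, 0.02 kg
BM) put each device's relative error in the low single-digit percent
range of the group means, consistent with the ±3% overall error band the
validation reports.

## Numerical and testing choices

All randomness flows through `numpy.random.default_rng` seeded per spec
or per CLI flag; no global RNG state. CSVs are RFC 4180 with "." decimal
separator, written at full precision; the 2-decimal (accuracy) and
3-decimal (means) rounding of the published tables is applied at
reporting time only. Problem sizes in the test and acceptance runs —
200 round-trip subjects, 10,000 Bland–Altman differences, 400 stepwise
null replicates at n = 500, a 10,000-subject cohort-mean check — were
chosen to make Monte-Carlo error negligible relative to each assertion's
tolerance while keeping the whole suite under a few seconds.

The stepwise type-I check is calibrated rather than knife-edge: with a
single null candidate at enter-p 0.05 the per-replicate entry
probability is exactly 0.05, so the suite asserts the observed rate over
400 replicates lies within ±3.2 binomial standard errors of the nominal
level ([0.015, 0.085]); a rate below the band fails too, since it would
indicate miscalibrated p-values, not conservatism.

## Known inconsistencies in the source, reproduced deliberately

* The photocurrent worked example multiplies volts by A/W and labels the
  result amperes (0.05 → 21 mA). Implemented numerically as printed;
  the units are not reconciled.
* The water equation's log term cannot produce the published TBW group
  means at physically plausible photocurrents; consequently single-
  subject TBW estimates at e.g. 21 mA are implausibly high. The
  synthetic module derives optical current by inversion rather than from
  physical optics for exactly this reason.
* Evaluating the BF% and BM equations at the published group means does
  not reproduce the published BF%/BM means (the published summary
  statistics and the device equations are mutually inconsistent).
* Two different obese body-fat means (31.309 and 30.309) appear in
  different published tables; both are stored verbatim in their
  respective packaged reference tables.
* The published "Relative Reliability" column contains values above 1
  (e.g. 1.78) that exceed any correlation bound and whose formula is
  unstated; it is stored verbatim and never computed.

## Limitations

Synthetic cohorts share none of a real pediatric population's joint
structure beyond (optionally) a single correlation matrix; passing tests
demonstrate software correctness — that the pipeline computes the
published equations and statistics exactly and reproducibly — not
clinical validity of those equations. Subject-level quantities of the
original study (per-child measurements, the reliability table, the
scatter behind the published Bland–Altman figures) cannot be recomputed
without the raw data and are covered instead by verbatim reference
storage and by the property-based suite on synthetic data.
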