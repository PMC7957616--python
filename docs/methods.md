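# Methods

## Scope and data

The package reanalyzes a licorice (*Glycyrrhiza uralensis*) extraction
study built around ultrasound-assisted deep-eutectic-solvent (DES)
extraction of six compounds, quantified by HPLC with a single-marker
(QAMS) scheme. No raw chromatograms or deposited datasets exist; the
inputs are the study's printed summary tables, embedded in
`licoqams.study_data`:

- per-injection relative correction factors (five injection volumes,
  five analytes against glycyrrhizic acid);
- five single-factor extraction-rate blocks (water content,
  liquid-to-material ratio, time, temperature, ultrasonic power), six
  compounds each, with replicate SDs and reported composite scores;
- the 17-run Box–Behnken design with measured composite scores;
- six linear calibration curves with linearity ranges, R², LOD and LOQ;
- three verification runs at the adopted optimum;
- the 24 candidate DES systems (hydrogen-bond acceptor/donor, molar
  ratio).

Two printed values were corrected on internal-consistency grounds and are
flagged in the module: the glycyrrhetinic-acid calibration slope is read
as 1.0e7 (its ambiguous digit grouping admits 1e6, but only 1e7 is
consistent with the measured correction factor 0.79 ≈ 8e6/1e7), and the
isoliquiritin apioside upper linearity bound is read as 0.086 µg/µL
(every range in the table spans stock/10 × (0.4, 2.0)).

## Quantification model

The detector is assumed linear in concentration, `area = s·C + b`, per
compound. The external-standard route inverts the compound's own line.
The QAMS route measures `f_m/k = A_k C_m / (A_m C_k)` per injection volume
from mixed standards, averages the series (the per-volume-then-average
convention matching the study's table, rather than a pooled regression),
and prices analyte concentrations off the marker's sample peak. Contents
in % w/w use the mass balance `C_m · V · 100 / (W · 1000)` with the
extract volume V a required input (100 mL default, the study's extraction
volume); the underlying formula in the study omits V, which cannot be
dimensionally complete without it.

Two consequences of the intercepts `b ≠ 0` are deliberate design points:

- QAMS ≡ ESM to machine precision holds only for proportional (zero
  intercept) responses; with the published intercepts QAMS carries a
  small method bias. The exact-identity tests therefore use a
  zero-intercept generator configuration, while the relative-error check
  runs with the full curves and quantifies the bias the method claims to
  keep under 5 %.
- The bias grows as `b/(s·C)`, so the QAMS/ESM comparison sample is
  generated with every analyte inside its validated linearity range
  (mid-range by default). Below the range the bias can exceed 5 % —
  which is precisely why validated ranges exist — and the comparison is
  not meaningful there.

Relative standard deviations use the n−1 (sample) standard deviation
throughout. LOD/LOQ follow the 3.3σ/s and 10σ/s convention; the study
prints values but no formula, and this is the common choice. Printed
correction-factor RSDs are not exactly recomputable from the 2-decimal
per-injection values, so tests assert the means only.

## Composite score

Index score = rate / block maximum per compound; Z = equal-weight (1/6)
mean of the six scores. The normalization block is one single-factor sweep
or the whole screening panel. Recomputed Z values match the reported 0.95
(30 % water) and 0.83 (40 % water) exactly at two decimals; some other
rows differ by ±0.01–0.03 because the study scored unrounded rates, so
tests pin only the exactly-reproducing rows. Ties in ranking keep input
order and warn. The three verification-run scores (0.92/0.92/0.93) are
carried as data: their normalization block is unpublished (one printed
rate exceeds every candidate maximum), so they cannot be recomputed and
the pipeline reports only their mean.

## Design of experiments

The 3-factor Box–Behnken design is generated in the fixed edge-block
order (AB, AC, BC pairs, then centers); fitting is order-invariant.
Coding is affine, `x = (natural − center)/step`, with centers 20 mL/g /
30 % / 40 min and steps 10. The full 10-term quadratic is fitted by
`numpy.linalg.lstsq`; the ANOVA uses drop-one-term partial SS (equal to
`β²Σx²` for the orthogonal linear and interaction columns), tests each
term and the model against the residual mean square, and tests lack of
fit against the pure-error mean square computed from replicate groups.
p-values are upper-tail F probabilities. Degenerate cases: a perfect fit
reports NaN F ratios rather than dividing by zero; designs without
replicates omit the lack-of-fit rows with a warning.

The stationary point solves `Hx = −g` with `H_ii = 2β_ii`,
`H_ij = β_ij`, classified by Hessian eigenvalue signs; a Hessian whose
smallest singular value is below 1e−8 of the coefficient scale is treated
as singular and routed to the box optimizer. `optimize_in_box` enumerates
the stationary points of the quadratic restricted to all 27 faces of the
coded cube (each coordinate free or fixed at ±1), which is exact for a
quadratic, and flags optima on the boundary. On the study design the
interior maximum decodes to 20.40 mL/g, 29.84 %, 41.19 min with predicted
Z 0.95, matching the reported optimum.

## Synthetic generator

One seeded `numpy.random.Generator` per `SyntheticGenerator` instance is
threaded through all operations; a fixed seed reproduces every output
byte for byte. It emulates:

- calibration points at five levels spanning each linearity range in the
  proportions of the 4/8/10/16/20 µL injection series (endpoints always
  present), with areas from the published lines;
- standard injections whose areas either follow the calibration lines or
  are back-solved from a given per-injection f series (used to
  reconstruct the published correction-factor table exactly);
- sample chromatograms inverted from known contents, warning outside
  validated ranges and flooring areas at zero (a real integrator cannot
  report signal below baseline);
- extraction tables: the five single-factor blocks exactly as printed,
  plus a synthetic 24-system screening panel in which only the ordinal
  structure is guaranteed (the screening figure prints no numbers): the
  choline chloride/1,3-butanediol family on top with its 1:5 system
  first, ±1 % jitter;
- Box–Behnken responses from arbitrary quadratic truths plus Gaussian
  noise.

Default noise levels are the study's measurement conditions:
multiplicative peak-area noise of 0.5 % RSD (mid-range of the reported
instrument-precision RSDs, 0.33–1.05 %) and response noise
σ = 0.0164, the square root of the published pure-error mean square.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: chromatographic peak shape, integration and
baseline error, retention drift, co-elution, matrix effects,
heteroscedastic detector noise, and between-day variation. Tests
demonstrate the *statistical machinery* is correct and self-consistent,
not that the instrument behaves linearly.

## Problem sizes and numerics

All headline computations are desk-scale (17-run OLS, 5-row score
blocks) and run in well under a second. Monte-Carlo checks use 1000
seeded refits at the replicate noise scale; the box-optimizer oracle is a
dense grid at step 0.02 over the coded cube. Tolerances: exact identities
at 1e−9..1e−12; SS/df additivity at 1e−10; printed values at their
display precision. Weights passed to the composite score must sum to 1
within 1e−9.

## Known limitations

- The reported validation RSDs and recoveries summarize unpublished
  replicates and serve only as generator noise targets.
- The verification-run composite scores are reproduced as data, not
  recomputed (see above).
- Only the 3-factor Box–Behnken design is supported; no weighted or
  nonlinear calibration; no peak detection from raw signals.
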