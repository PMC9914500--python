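# Methods

This note documents the models, the synthetic data they are exercised
on, and the numerical choices that were genuinely open.

## Data model

A spectrum is an absorbance trace on a strictly descending wavenumber
grid. The canonical grid is 4000, 3996, …, 700 cm⁻¹ — 826 points with
both endpoints on-grid. Instruments state range and resolution but not
endpoint conventions, so endpoint inclusion here is a package convention,
not a measured fact. Region selection is a filter with inclusive bounds
(an off-grid bound keeps the nearest in-range points; it never
interpolates); resampling, when explicitly requested, is linear
interpolation without extrapolation. Ascending input grids are
normalized to descending with a logged notice rather than rejected.

## Synthetic cohorts

The simulator exists so the full workflow can be exercised without
proprietary spectra. It emulates two things:

**Trait tables.** Each trait follows a truncated normal on the reference
cohort's printed min/max/mean/SD (e.g. moisture 15.8 ± 0.9 % in
[13.6, 19.7]). Three couplings make the table internally consistent and
spectrally recoverable:

* soluble solids = 94.5 − moisture + N(0, 0.2) °Brix (solids are the
  complement of water);
* water activity = 0.21 + 0.02·moisture + N(0, 0.004);
* pH = 4.02 − 0.028·(free acidity − 27.9) + N(0, 0.03).

All three are clipped to the reference bounds. The coupling noise levels
are simulator parameters: they bound the best achievable prediction R²
for the coupled traits (a model can never explain the independent noise),
and were chosen so that ceiling sits near 0.95–0.97, inside the
calibration band the package is meant to reproduce. The pH coupling is
chemically motivated (acid content drives pH); without it pH would leave
no spectral trace at all and a pH calibration would be meaningless.
Sucrose is drawn below 5 % for pure samples and uniformly from
5.1–12.6 % for adulterated ones, so class labels and the regulatory
sucrose rule agree by construction.

**Spectra.** Beer–Lambert additivity: absorbance = Σ_c conc_c ·
component_c + linear baseline + iid N(0, noise_sd). Components are sums
of Gaussian bands at the standard honey assignments (water 3285/1637,
C-H 2930, glucose 1411/1043/1020/918, fructose 1321/1254/1063/1020,
glycosidic C-O-C 1110, HMF carbonyl 1666 cm⁻¹). Pure-honey sucrose
carries {1020, 1110}; the adulterant syrup carries {1010, 1110-enhanced},
realizing the 1020→1010 shift compositionally — syrup adds a different
component; nothing warps the pure bands. Band centers are fixed by the
assignments; widths and heights are free parameters calibrated once so
that (a) the composite pure spectrum peaks at 1020 cm⁻¹ and a 10 %-sucrose
adulterated spectrum at the grid point nearest 1010 cm⁻¹, (b) the nine
trait models land in the published calibration band, and (c) each class's
spectra after 4 PCs leave a noise-dominated residual (see SIMCA below).
Defaults: noise_sd = 0.002 AU, baseline drift ≤ ±0.001 AU end-to-end
across the grid.

What the simulator does **not** emulate: instrument line-shape
convolution, ATR penetration-depth dispersion, atmospheric CO₂/H₂O
features, scattering baselines, wavenumber miscalibration, or
between-instrument variation. Passing tests therefore demonstrate the
correctness and internal consistency of the chemometric machinery under
the stated generative model — not that a real instrument will reach the
same figures.

## PLS1 calibration

NIPALS PLS1 on column-centered spectra and centered response; no SNV,
MSC or derivatives (mean centering only, matching the acquisition
pipeline being modeled). Key conventions:

* **SECV** uses divisor *n* (every sample is predicted once in LOO);
  **SEP** is bias-corrected with divisor *n−1*. R² values are squared
  Pearson correlations (references conflate correlation and
  determination coefficients; this choice is stated in the report).
* **LV selection**: smallest count whose SECV is within 2 % of the global
  minimum (parsimony tolerance; max 10 LVs). A plateau therefore
  resolves to its knee.
* **Outliers**: leverage from the score space, h = 1/n + Σₐ t²ₐ/(tᵀt)ₐ,
  flagged above 3(nLV+1)/n; studentized residuals flagged beyond |3|.
  At most two removal passes on calibration data, then a final refit.
* **RPD/RER**: both divide by SEP; RPD uses the calibration-set reference
  SD, and RER the calibration-set range. (The reference-table ranges and
  SEPs printed in the literature this mirrors are not mutually
  consistent, so the calibration range is used and recorded.) Band
  edges: RPD < 2 not usable, 2.0–2.4 rough screening, 2.5–2.9 screening,
  3.0–3.4 quality control, 3.5–4.0 process control, ≥ 4.1 all
  applications (gaps between printed bands are closed by extending the
  lower band upward); RER ≤ 4 not usable, then screening, > 10 quality
  control, > 15 quantification, with left-open boundaries.
* **Default regions**: fingerprint 750–1800 cm⁻¹ plus the C-H/O-H
  stretch window 2800–3600 cm⁻¹. The O-H stretch is included because
  moisture — and through it soluble solids and water activity — is
  encoded almost entirely in that band; per-trait regions are config
  entries.

Degenerate inputs: a response with variance ≤ 1e-12 raises; requesting
more LVs than the data's rank raises; score energies are compared
against 1e-12 of the total spectral energy.

## SIMCA authentication

Per-class PCA by SVD of the centered class matrix (default region
920–1650 cm⁻¹, 4 PCs per class, α = 0.05). A sample's distance to a
class is d = √(s᷂ᵢ²/s₀²) with s᷂ᵢ² = ‖e‖²/(J−n_pc); it is assigned to every
class with d² ≤ F₀.₉₅(J−n_pc, n−n_pc−1) — soft assignment: none, one or
several classes.

Two calibration choices here deserve the detail:

* **s₀² is a leave-one-out estimate** — the mean residual variance of
  each training sample under a class model refit without it. The naive
  alternative (pooled training residuals over (n−n_pc−1)(J−n_pc)) is
  biased low when channels far outnumber samples, because the fitted PCs
  absorb training noise: with 17 training samples, 183 channels and 4
  PCs, a controlled low-rank-plus-noise experiment shows new-sample
  distances averaging d² ≈ 1.4 against a nominal 95 % limit of 1.19,
  i.e. the "95 %" region rejects most genuine class members. The LOO
  estimate is unbiased for new samples and restores d² ≈ 1.
* **Denominator dof = n−n_pc−1**, the number of independent samples
  informing s₀², not the sample×channel product: spectral residuals are
  strongly correlated across wavenumbers, and pretending to
  (n−n_pc−1)(J−n_pc) independent dof collapses the confidence band far
  below the actual spread of per-sample residual variances. With both
  choices the acceptance region behaves the way SIMCA is used in
  authentication practice: essentially all genuine class members are
  accepted, while foreign samples — whose residuals are orders of
  magnitude larger — are rejected.

Diagnostics: interclass distance
ICD = √((S²(p→q)+S²(q→p))/(S²(p→p)+S²(q→q))) − 1 from cross-fitted mean
squared residuals (0 for identical classes; the −1 offset keeps the
conventional "> 3 ⇒ substantially different" reading); discriminating
power is the same ratio per wavenumber without the offset (≈ 1 for
indistinguishable classes, denominators floored at 1e-12 and logged);
modeling power is 1 − s_resid/s_total per wavenumber, clipped to [0, 1],
NaN where a wavenumber has no variance. Training-set "cross-validated
misclassification" is a leave-one-out class projection: the held-out
sample's own class model is refit without it and the sample is
misclassified when its nearest class is not its true class; held-out
performance instead uses the soft F-test assignment, counting a positive
as detected only when assigned exclusively to the positive class.
Per-class PC counts can be cross-validated (`select_n_pc`, LOO PRESS with
a plateau rule, capped at 10), but the two-class honey workflow defaults
to the conventional 4 PCs. The score-space-augmented distance is a
config extension point, off by default.

## Regulatory screen

Strict inequalities (a value exactly at its limit is compliant, per
"shall not exceed" wording); glucose+fructose exactly 60 g/100 g is
tolerated. Water activity above 0.6 is reported as spoilage risk, not
legal non-compliance. Missing traits skip their rule with a notice;
negative concentrations are rejected. Rule overlaps (e.g. sucrose- and
HMF-flagged) are reported explicitly.

## Pipeline and problem sizes

The end-to-end run uses the default cohort of 147 samples (21
adulterated), an 80/20 split (plain random for quantification — 118/29;
stratified per class for authentication — 101+17 / 25+4), LOO
cross-validation up to 10 LVs for each of the nine traits, up to two
outlier passes, and SIMCA with 4 PCs. A full run completes in well under
a minute on one CPU; `scripts/acceptance.py` repeats it from scratch
under a caller-supplied seed. All randomness flows through seeded
generators (cohort seed and split seed recorded in the provenance
block), so reports reproduce bit for bit.

## Known limitations

* Synthetic spectra are idealized (see above); absolute error figures
  (e.g. a moisture SEP of 0.01 %) reflect the generator's high
  signal-to-noise ratio, not instrument reality — read the regime
  (R² band, RPD bands, perfect class separation), not the decimals.
* Real per-trait wavenumber selections are study-specific and
  unpublished; the defaults here are broad windows, so published
  calibration tables cannot be reproduced number for number.
* PLS2, derivative/SNV preprocessing, variable-selection searches,
  DD-SIMCA and probabilistic class membership are out of scope.
* The ICD and discriminating-power formulas follow common chemometric
  definitions; commercial packages do not publish theirs, so their
  printed values (e.g. a specific ICD) are matched in regime (≫ 3), not
  numerically.
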