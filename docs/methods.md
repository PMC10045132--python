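# Methods

This note documents the models, estimators and numerical choices behind
`aptdki`, and what the synthetic-data generators do and do not emulate.

## CEST forward model and APTw quantification

**Model.** The saturated, normalised water signal is modelled as a sum of
Lorentzian lines, one per saturable proton pool:

    Z(Δω) = 1 − Σᵢ aᵢ · (wᵢ/2)² / ((wᵢ/2)² + (Δω − δᵢ − B0)²)

with amplitude `aᵢ ∈ [0, 1]`, FWHM `wᵢ` (ppm) and chemical shift `δᵢ` (amide
at +3.5 ppm; a broad water/background line at 0 ppm).  This steady-state
line-shape model stands in for a Bloch–McConnell simulation of the pulsed
saturation module.  The trade is deliberate: the analysis layer only ever
consumes Z-spectra, the water line is exactly symmetric so the ground-truth
`MTRasym(3.5 ppm)` is analytic (it equals the solute pools' asymmetric
contribution), and amplitudes map directly onto the APTw contrast being
recovered.  What is lost is any dependence of the line shapes on saturation
power/duration, exchange rates or relaxation — the phantom cannot say
anything about sequence optimisation, only about the *processing* chain.

**Acquisition scheme.** 63 frames: one unsaturated reference plus 62
saturated frames — a sparse positive far wing (80…10 ppm), symmetric pairs
through |Δω| ≤ 6 ppm with ±4, ±3.75, ±3.25, ±3, ±2.5, ±2 acquired twice and
the amide pair ±3.5 six times, and one on-resonance frame.  Repeats are
arithmetically averaged before normalisation (the simplest unbiased
estimator for repeated measurements), and the spectrum is divided by the
reference frame, making every downstream quantity invariant to a common
scale factor.

**B0 mapping.** The field map comes from a dual-echo gradient-echo phase
pair: `Δf [Hz] = wrap(φ₂ − φ₁) / (2π·ΔTE)` with ΔTE = 4.92 ms, converted to
ppm at 127.74 MHz (nominal 3.0 T, γ = 42.58 MHz/T — the field strength is
stated, the exact synthesiser frequency is a convention).  Wrapping confines
the phase difference to (−π, π], so fields beyond 1/(2·ΔTE) ≈ 101.6 Hz
(0.796 ppm) alias; no unwrapping is attempted.  The phantom flags such
voxels in its truth record, and the round-trip identity
(simulate → map) holds to < 10⁻¹⁰ ppm below that limit.

**Spectrum shifting.** The corrected value at nominal offset `w` is the
measured curve interpolated at `w + B0`, with a natural cubic spline built
on the averaged unique offsets of the densely sampled |Δω| ≤ 6 ppm region.
Extrapolation is never performed: shifted evaluation points outside the
sampled range yield NaN and the voxel is masked.  Offsets in the sparse far
wing pass through unshifted — a sub-ppm shift is negligible against their
tens-of-ppm spacing, and they do not enter the ±3.5 ppm evaluation.
Noise-free phantom tests bound the residual interpolation error at
< 0.02 percentage points of APTw across B0 ∈ ±0.5 ppm (the test asserts a
looser 0.5 pp).

**APTw.** `MTRasym(3.5 ppm) = Z(−3.5) − Z(+3.5)`, stored ×100 in percent,
clipped to ±100 %.  No B1 correction and no multi-pool (Lorentzian
difference) variant is provided; MTRasym is the sole readout.

## Diffusion-kurtosis fitting

**Model.** `S(b) = S0 · exp(−b·MD + b²·MD²·MK/6)` on the trace-weighted
series b = 0, 500, 1000, 1500, 2000 s/mm².  No directional tensor, IVIM or
stretched-exponential variants: the acquisition this emulates produces one
direction-averaged series.

**Estimator.** Two stages. (1) Ordinary least squares of `ln S` on
`(1, −b, b²)` — the model is exactly log-polynomial, so this is closed-form
and recovers noiseless parameters to ≤ 10⁻⁹ relative error.  MK is read off
as `6·c₂/MD²`. (2) Bound-constrained least squares in the signal domain
(`scipy.optimize.least_squares`, trust-region reflective, xtol 10⁻¹²)
initialised at (1); the stage returns whichever of initialiser/refinement
has the lower residual, so refinement can never degrade a voxel.  Bounds:
MD ∈ (10⁻⁵, 3.5] ×10⁻³ mm²/s, MK ∈ [0, 3] — standard physiological clamps;
any clip beyond numerical noise (10⁻⁹) is flagged in the QC map, never
silent.  Voxels with a non-positive sample are excluded (QC code 2) rather
than imputed.

**Noise.** The simulator applies Rician noise as the magnitude of a
complex Gaussian perturbation.  No noise-floor correction term is fitted;
at b = 2000 with low SNR this biases MD down and MK up, which the test
suite characterises (median bias < 5 % at σ = 2 % of S0, bias shrinking
monotonically as σ → 0) rather than removes.

## Synthetic cohort

One row per patient: three continuous markers (APTw %, MK, MD), age and
tumor size, seven binary covariates, binary nodal outcome.  Defaults encode
the emulated study: 17 node-positive / 44 node-negative; marker summaries
APTw 3.7 ± 1.1 vs 2.4 ± 1.0 %, MK 1.065 ± 0.185 vs 0.909 ± 0.189,
MD 0.989 ± 0.195 vs 1.193 ± 0.337 ×10⁻³ mm²/s; categorical counts per group
(e.g. deep invasion 16/17 vs 18/44) reproduced *exactly* by deterministic
assignment followed by an in-group shuffle — cross-tabs are therefore
design constants, not random variables, and the 2×2-determined odds ratios
are reproduced to printed precision on every draw.  Continuous markers are
per-group normals; the within-group correlation between the three markers
defaults to zero (no correlation structure is available to emulate) with a
Gaussian-copula option for sensitivity analyses.  Age and tumor size are
truncated normals respecting the reported ranges.  Binary covariates are
shuffled independently of the markers, so marker–covariate association
within outcome groups is absent by construction — a known simplification.

The screening ledger applies four exclusion rules (21 incomplete
histopathology, 9 non-cervical cancer, 10 sub-10 mm tumors, 4 artifact
cases) to 105 screened records, leaving 61.

**What passing tests show / don't show.** Green tests demonstrate that the
processing and inference chains are correct on data whose generating
process matches the models exactly (Lorentzian spectra, kurtosis signals,
normal markers, exact margins).  They do not certify performance on real
tissue, where line shapes are non-Lorentzian, diffusion is multi-
compartment, reader variability is structured, and marker distributions
are neither normal nor independent of covariates.

## ROI statistics and agreement

ROI means are arithmetic over finite voxels (NaN voxels counted and
reported); all-NaN ROIs raise with the patient and parameter named.  The
two readers' means are averaged for the final per-patient value.  Agreement
uses ICC(2,1) — two-way random effects, absolute agreement, single measure
— computed from the ANOVA mean squares with the McGraw–Wong F-based 95 %
interval, cross-checked in tests against `pingouin`.  Bands: < 0.40 low,
0.40–0.75 medium, > 0.75 high.  The ICC form had to be fixed by choice; for
two fixed readers rating all subjects, two-way random with absolute
agreement is the conventional default.  In the pipeline demo the second
reader's contour is the first shifted by one pixel — a lower bound on real
interreader variability, so demo ICCs run near 1.

## Cohort inference

- **Normality gate:** per-group one-sample Kolmogorov–Smirnov against a
  normal with the sample's moments, α = 0.05; both groups pass → pooled-
  variance Student's t; otherwise Mann–Whitney U (midranks).  A
  zero-variance group forces the rank branch with a note.  The test chosen
  is always reported.
- **Contingency:** χ² with continuity correction; Fisher's exact whenever
  any expected count < 5 (the conventional validity bound; the switching
  rule had to be fixed by choice).
- **Logistic regression:** `statsmodels` GLM/Binomial (IRLS, tol 10⁻⁸,
  ≤ 100 iterations).  Wald CIs `exp(β ± z₀.₉₇₅·SE)` — for binary predictors
  the fitted OR is the 2×2 cross-product ratio, and Wald intervals
  reproduce the printed intervals on those tables.  Complete separation
  (|β| > 15 or exploded SE) is flagged and the CI reported unbounded.
  Pipeline mode screens candidates univariately at p < 0.05; events-per-
  variable < 10 raises a flag.  In-sample (apparent) fit only; no
  cross-validation or shrinkage.
- **ROC/DeLong:** empirical AUC = normalised Mann–Whitney U with midranks
  (asserted identical to `scipy`'s U on every fixture).  Variance and
  paired comparisons via DeLong structural components; AUC CI on the
  log-odds scale.  Scores are auto-oriented so AUC ≥ 0.5 (MD, lower in the
  node-positive group, is negated; orientation and test direction are
  recorded).  Youden cutoff maximises sens + spec − 1; ties break toward
  the lower cutoff (more sensitive operating point).  The combined score is
  the in-sample linear predictor of the three-marker logistic fit.
- **Variance validation:** the DeLong variance is checked against a
  *stratified* bootstrap (cases and controls resampled separately, each
  replicate's AUC recomputed by brute-force pairwise comparison) with the
  standard n/(n−1) correction per stratum.  The naive joint bootstrap
  variance at n = 12 sits ~10–25 % below any consistent estimator because
  of plug-in shrinkage; the corrected stratified design targets the same
  estimand as DeLong and agrees within a few tenths of a percent.
- **Nomogram:** each predictor's contribution β·x is shifted to zero at its
  least-risky end and scaled so the strongest predictor spans 0–100 points;
  total points map back through the inverse logit.  The construction is
  exactly invertible — nomogram read-offs equal direct model predictions to
  10⁻⁶ on a grid, asserted in tests.

Significance is two-sided 0.05 throughout; no multiple-testing correction
is applied (matching the emulated analysis plan).

## Problem sizes and determinism

Phantom scenes default to 60 × 60 voxels with eight lesions (pipeline tests
use 40 × 40); the binormal AUC emulation uses 2000 replicate cohorts; the
bootstrap validation uses 10⁵ replicates at n = 12; noise-bias
characterisation uses 10⁴ voxels.  These sizes make every Monte-Carlo
estimate's error small against its tolerance while keeping a full run in
seconds to minutes on one core.  All stochastic paths accept a seed or
`numpy` Generator; the pipeline manifest records the seed and SHA-256
checksums of every artifact, and a repeated run with the same seed
reproduces the checksums bit-for-bit.

## Known limitations

- No Bloch–McConnell saturation physics, B1 correction, or phase
  unwrapping; wrapped-field voxels are flagged, not recovered.
- No Rician noise-floor correction in the DKI fit; high-b bias is
  characterised, not removed.
- Cohort realism stops at the printed margins and group moments; joint
  marker–covariate structure is absent by construction.
- Multivariate odds ratios, ICCs against human readers, and real-data
  AUC/cutoff values depend on raw data this package does not have; the
  pipeline reproduces the *procedures*, and only table-determined
  quantities are asserted numerically.
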