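# Methods

## Scope and data model

The package operates on flowthrough fractions of a protein A breakthrough
experiment. A `Spectrum` is a pair of equal-length vectors (wavenumber in
cm⁻¹, strictly increasing; intensity in detector counts); a `SpectraBlock`
stacks spectra on one shared axis with unique sample ids and optional
per-sample titers (mg/mL). All operators preserve the wavenumber axis
bit-for-bit unless they explicitly crop or resample, and file round trips
are bit-identical (numbers written at 17 significant digits, parsed with
exact string-to-double conversion).

## Spectral preprocessing

**SNV** subtracts the per-spectrum mean and divides by the per-spectrum
*sample* standard deviation (ddof = 1; the dominant chemometrics
convention, chosen so that independent recomputations match exactly). It
is exactly invariant to `a·x + b` for `a > 0`, which is what removes
multiplicative scatter.

**Savitzky–Golay** filtering uses local least-squares polynomials on a
uniform axis. Two choices are deliberate:

- *Derivative scaling is per cm⁻¹* (division by spacing^d), so derivative
  spectra are comparable across instruments with different channel spacing.
- *Edge policy*: the polynomial fitted to the first/last full window is
  evaluated at the edge points; no mirror padding, which would fabricate
  reflected features in derivative spectra. The processing log records
  this policy.

The axis must be uniform within 1% relative spacing; otherwise the filter
refuses and `resample_uniform` (linear interpolation) must be applied
explicitly — silent interpolation inside a filter is a provenance hazard.

**Rubber-band baseline** is the piecewise-linear interpolation of the
lower convex hull (monotone-chain construction, checked in the tests
against an O(n²) search). The corrected spectrum is zero at hull vertices,
non-negative elsewhere, and invariant to adding any linear trend.

**Crop** uses a closed interval in wavenumber.

Recipes are ordered step lists applied row-wise; three calibration presets
are provided (SNV only; SNV + SG(15, 1, 1); SNV + SG(25, 2, 2)) plus a
baseline-corrected second-derivative display recipe
(rubber band → SNV → SG(27, 2, 2)) for amide I inspection. Which
wavenumber range feeds the calibration is a configuration choice; the
default is the full spectrum, with `crop` available to isolate the amide I
window.

## PLS1 calibration

NIPALS with deflation on mean-centred data; channels are not autoscaled
(SNV already row-normalizes, and column autoscaling of derivative spectra
amplifies noise channels). For one response the weight update has a closed
fixed point; the loop still iterates to tolerance 1e-12 (max 1000
iterations) so the convergence contract is explicit and violations are
reported with the component index. If the deflated matrix is numerically
exhausted (score variance below 1e-12 of the first component's) the model
is truncated with a warning: fitting past the numerical rank produces
unbounded coefficient vectors that extrapolate catastrophically on new
data. Coefficients at truncation A are `W_A (P_Aᵀ W_A)⁻¹ q_A`.

**Cross-validation.** Leave-one-out with a full refit per fold, including
re-centering. RMSECV is the root mean square of the held-out errors.
Q² = 1 − PRESS/TSS with TSS about the full-sample mean of y (so 1 means
perfect prediction and ≈0 none). R² and RMSEC come from the full-data fit
and are monotone in the component count by construction.

**Component selection** formalizes "stop when RMSECV gains become
incremental": the smallest A whose relative RMSECV improvement to A+1
falls below `rel_tol` (default 1%, configurable). Ties break toward
smaller A. If RMSECV is already at a numerical floor (10⁻⁸ of the response
SD) the current A is accepted; if every improvement exceeds the tolerance
the rule returns A_max − 1, since the final component cannot be certified
as "no further gain" without looking beyond it.

**Assessment.** RMSEP is the RMSE on an independent test block at the
selected truncation; test-set Q² uses the test-set mean. Train/test
designation is explicit metadata, never inferred.

## Chromatography math

- Oversaturation load: `C_S = V_I · C_0 / V_c`.
- Standard curve: ordinary least squares `area = m·mass + b` with residual
  SD (ddof = 2); titer inversion `C_0 = ((S_A − b)/m)/I_V`. Negative
  fitted masses clip to zero with a warning rather than erroring, since
  baseline noise in blank fractions is expected.
- Beer–Lambert titer `c = A/(ε·l)`; the path length is a required input,
  never silently defaulted.
- Breakthrough ratios attach to the **fraction midpoint** volume
  (unbiased for linear segments). Ratios above 1.05 are flagged; small
  negatives clip to zero.
- `V_10%` is found by linear interpolation at the first upward crossing of
  the threshold (a sampled point exactly at the threshold wins; a first
  point already above it is an error). For noisy spectroscopic titer
  series a `sustained` crossing mode uses the *last* upward crossing — the
  boundary of the final exceedance run — which is robust to estimates
  jittering around the threshold in blank fractions; the two conventions
  coincide on monotone curves. The end-to-end workflow uses `sustained`
  for the Raman route only.
- The UV route subtracts the mean of an explicit pre-load baseline region,
  then converts the signal with ε·l against the known C₀
  (`beer_lambert` mode) or normalizes to the full-breakthrough plateau
  (`plateau` mode, top decile of the trace).

## Amide I decomposition

Three bands: β-sheet 1657–1688, α-helix 1630–1656, aromatic/tertiary
1598–1630 cm⁻¹ (overridable). Band magnitude is the trapezoidal integral
over the band interval with values interpolated at the exact edges, so a
shared boundary contributes half to each neighbour and nothing is double
counted; the 1656→1657 gap in the band definitions is assigned to the
β band. On second-derivative input the integrand is the absolute value of
the negative part (protein bands appear as negative lobes); on
baseline-corrected zeroth-order input the plain integral. Area integration
was chosen over peak heights because it is stable under small band-width
changes. Replicate stability across measurement groups is a one-way ANOVA
(scipy) on a chosen band's percentage.

## Method-precision metrics

%CV(SD) = 100·SD/mean over repeated determinations of one method (sample
SD). %CV(RMSE) = 100·RMSE/mean(reference) for paired determinations of two
methods; the first argument is the normalizing reference and the metric is
deliberately asymmetric. Both are invariant to a common positive
rescaling.

## Synthetic data generator

The generator emulates a breakthrough study on clarified harvest where no
real spectra are available. Per sample:

    I(w) = a·(titer·protein(w) + g_b·background(w) + g_l·baseline(w))
           + offset + N(0, σ²)

- **Protein**: three Gaussian amide I component bands at 1672 (β), 1643
  (α) and 1612 cm⁻¹ (aromatic) with integrated areas 50/30/20
  counts·cm⁻¹ per mg/mL (a 5:3:2 area ratio); band areas scale linearly
  with titer. A pseudo-Voigt line shape is available.
- **Background**: media/host-cell bands away from the amide window (850,
  1003, 1080, 1250, 1450 cm⁻¹), scaled per sample by g_b ~ U(0.9, 1.1).
- **Baseline**: a quadratic in normalized wavenumber (≈160–200 counts),
  scaled per sample by g_l ~ U(0.9, 1.1).
- **Scatter**: a ~ U(0.9, 1.1), offset ~ U(−2, 2) counts; detector noise
  σ = 1 count. With the band areas above this places the cross-validated
  titer error near 0.1 mg/mL on a 2.5 mg/mL load — the precision regime a
  well-run plate-based Raman assay operates in.
- **Breakthrough**: logistic `C(V) = C₀/(1+exp(−k(V−V_mid)))` with
  C₀ = 2.5 mg/mL, k = 0.3 /mL, collected as 2 mL fractions over 120 mL
  (60 fractions; a 96-well plate capacity is enforced). Closed forms:
  `V_10% = V_mid − ln 9 / k` and `DBC = (V_10% − V_0)·C₀/V_c` with
  V_c = 4.7 mL, V_0 = 1.2 mL. Study targets place DBC at 27.6/38.9 mg/mL
  (training runs at short/long residence time) and 37.0/37.5 mg/mL (test
  runs), capacities typical of protein A resins. The logistic shape was
  chosen for its smoothness and closed-form inverse; step and steeper
  variants are reachable through k. Optional per-cycle shrinkage of the
  bound mass emulates column ageing.
- **Assay models**: affinity peak areas `m·mass + b + N(0, σ_area)` with
  m = 1000 area/mg, b = 5, σ_area = 0.15 (≈0.6% titer CV at a 10 µL
  injection) and the 5–30 µL injection-volume standard-curve series; the
  UV trace is ε·l·C(V) plus a flat 0.02 AU baseline and 0.005 AU noise
  (ε = 1.44 mL·mg⁻¹·cm⁻¹, l = 0.2 cm).

Five latent variables vary independently per spectrum (titer, g_b, g_l,
a, offset); the generator reports this as its latent dimension. Identical
configurations (including the seed) produce byte-identical CSV outputs.

**What the generator does not emulate**: real amide line shapes and their
concentration-dependent shifts, fluorescence photobleaching dynamics,
cosmic-ray artefacts, detector response functions, correlated host-cell
protein composition drift, or plate-position effects. Passing tests
demonstrate that the algorithms are correct and the workflow is coherent
under a realistic noise model — not that any instrument will achieve these
exact error levels.

## Identifiability and the noise floor

SNV is invariant to global scaling, so
`SNV(t·p + g_b·b + g_l·l) = SNV(p + (g_b/t)·b + (g_l/t)·l)`: after
normalization the spectrum determines only the *ratios* of titer to the
component scales, and the titer direction lies exactly in the span of the
nuisance directions at first order. Titer is recovered only because the
scale factors are concentrated around 1 — an irreducible multiplicative
uncertainty on top of detector noise.

`propagated_noise_floor` quantifies this: it linearizes the generator in
the preprocessed space around a reference titer, estimates the
detector-noise covariance in that tangent space by Monte Carlo through the
full pipeline, and returns the posterior SD of titer under a flat titer
prior and the configured uniform priors on the nuisance scales. This is
the precision limit of any estimator linear in the processed spectrum;
model error (normalization curvature) comes on top. With the default
configuration and the first-derivative recipe the floor is ≈0.10 mg/mL,
and the observed RMSECV/RMSEP (≈0.12–0.14 mg/mL) sit within a factor of
1.5 of it.

A related consequence: on noiseless data the processed training matrix is
numerically rank-3 (titer, background and baseline directions; SNV removes
scatter and offset exactly), which is what the NIPALS rank guard detects.

## End-to-end study design

`run_synthetic_study` mirrors a platform-calibration experiment: train on
two runs of analyte A (shallow and deep breakthrough), test on a held-out
run of analyte A and on analyte B, whose amide areas are redistributed to
46/34/20 (same total Raman cross-section — a structurally similar but
distinct molecule). Training titers come from the simulated affinity assay
(peak areas inverted through a freshly fitted standard curve), not from
ground truth, so reference-method noise propagates into the calibration
exactly as it would in practice. Each test run yields DBC by the
spectroscopic, affinity-assay and UV routes, plus RMSEP against ground
truth and %CV(RMSE) route comparisons.

Problem sizes throughout (60 fractions/run, 120 training spectra, 1201
channels, 20-seed replication in the validation suite) were chosen so the
whole test suite and the acceptance script each complete in minutes on a
single CPU while keeping every statistical check adequately powered.

## Known limitations

- PLS1 only; multi-response PLS, variable selection and nonlinear
  calibration are out of scope.
- The UV and spectroscopic routes assume the load titer C₀ is known from
  an upstream measurement; uncertainty in C₀ is not propagated.
- The component-selection rule is one defensible formalization of an
  inherently qualitative criterion; the tolerance is exposed precisely
  because reasonable alternatives exist.
- ANOVA-based replicate stability assumes approximately normal
  within-group variation; it is a drift screen, not an equivalence test.
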