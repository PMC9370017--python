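# Methods

This note documents the models, parameter choices and numerical conventions
behind `nades_hydrospec`, and what the synthetic data can and cannot say
about real measurements.

## The measurement design being emulated

The package targets a standard-addition calibration of water in a Levulinic
Acid / L-Proline (2:1 mol/mol) NADES. Known masses of water are added to the
solvent — r grams per 100 g NADES, r in {0, 1, 2.5, 5, 7.5, 10, 20, 30, 40}
— giving nominal labels 100·r/(100+r) %w/w added water (0, 0.99, 2.44, 4.76,
6.98, 9.09, 16.67, 23.08, 28.57). Five replicate sets of all nine levels are
prepared independently; each of the 45 samples is measured as 3 deposits (or
vial repositionings) x 3 scans, i.e. 405 spectra per instrument.

Two facts shape everything downstream:

1. **The label is the *added* water, not the total.** Each preparation
   carries intrinsic water (modelled per set as Normal(1.07, 0.08) %w/w,
   the Karl Fischer mean ± repeatability). The spectral response is driven
   by total water; the regression target is the nominal added amount. The
   generator therefore computes the physical driver as
   `total% = added% + intrinsic% · (1 − added%/100)` (the intrinsic water is
   diluted as water is added) while the metadata carries the nominal label.
   Whether the instrument response should track total or added water is not
   decidable from the study description; total water is the physically
   sensible choice and is what this package uses.
2. **The sample, not the spectrum, is the statistical unit.** All splits are
   by (set, level) sample; predictions are averaged over a sample's nine
   spectra before any error metric. This matches the reported sample counts
   (12 calibration / 6 validation / 27 test) and prevents replicate leakage.
   A per-spectrum alternative would underestimate errors by letting
   near-identical replicates straddle the calibration/validation boundary.

## Synthetic spectra model

The clean signal at total water mass fraction f is a two-endmember mixture

    s(f) = f · S_water(f) + (1 − f) · S_NADES(f)

where each endmember is a sum of Gaussian or Lorentzian bands on the
instrument grid. Band positions follow the published assignments for water,
Levulinic Acid and L-Proline in each spectral range. Band *amplitudes and
widths are not published anywhere*; they are chosen (once, in a plain data
table in `synthetic_lalp.py`) so the clean spectra reproduce the described
qualitative balance: water and constituents both strong in ATR-IR; water
dominating NIR, with the 5200 cm⁻¹ combination band strong enough to
saturate; constituents dominating the Raman fingerprint with compact CH/C=O
bands. Selected Raman bands shift linearly in f (2929 → 2931, 772 → 778
cm⁻¹ over the added range 0–0.286) and the carbonyl band broadens,
implemented as `center + shift_per_fraction·f` and
`FWHM · (1 + broaden_per_fraction·f)` — the simplest model consistent with
two-point observations.

Instrument grids: ATR-IR 400–4000 cm⁻¹ at 4 cm⁻¹; benchtop NIR 4000–12800
cm⁻¹ at 8 cm⁻¹; handheld NIR 228 points linear in wavelength 900–1700 nm
(converted to cm⁻¹, hence a non-uniform wavenumber grid — typical of compact
dispersive devices); Raman 150–4000 cm⁻¹ at 2.5 cm⁻¹.

Measurement effects, each with its own named random substream off one
master seed (so disabling one source never reshuffles another):

| effect | model | default |
|---|---|---|
| intrinsic water | Normal per set, %w/w | 1.07 ± 0.08 |
| weighing error | Normal per sample, %w/w added | sd 0.002 |
| deposit gain | LogNormal per deposit | log-sd 0.002 (ATR) / 0.01 (NIR) / 0.05 (Raman) |
| baseline | per deposit, see below | scale 0 (ATR/NIR), 0.3 (Raman) |
| scan noise | additive Normal per channel | sd 0.001–0.003 intensity units |
| NIR saturation | hard clip at absorbance cap | 3.0 |

Noise sd is in absolute intensity units; band amplitudes are scaled so the
clean ATR-IR signal maxes near 1 absorbance, making "0.001 absorbance" and
"0.1 % of max signal" coincide there.

**Baselines.** Two families are available. `legendre` draws random
coefficients Normal(0, scale) on a low-order Legendre basis — a generic
smooth drift model. For Raman the default is `fluorescence`: a positive
convex decaying exponential `amp · exp(−k·u)` with lognormal amplitude and a
*random decay constant* k ∈ [1, 6] per deposit. The distinction matters: a
fixed-order polynomial family with random coefficients is a low-dimensional
linear nuisance subspace, which a linear regression absorbs with a few extra
latent variables, making baseline correction pointless; a family with a
random nonlinear shape parameter is not linearly absorbable, and it is also
the physically right shape for a fluorescence background. With the
fluorescence model the rubberband + vector-normalization plan strictly
outperforms raw spectra on Raman data, reproducing the ordering observed
with real instruments.

**The saturation cap (3.0)** is an arbitrary but typical detector ceiling;
only its existence (not its value) matters, since the benchtop-NIR plan
crops to 5400–9000 cm⁻¹ precisely to discard the saturated region.

## Preprocessing

* **Rubberband, order 1.** Baseline = piecewise-linear interpolation
  through the vertices of the lower convex hull of (wavenumber, intensity),
  computed by monotone chain in O(n log n) (O(n) on the already-sorted
  axis). Endpoints are always support points; collinear interior points are
  excluded (they do not change the baseline, and excluding them makes the
  support set unique). The corrected spectrum is exactly zero at support
  points and ≥ −1e-12 elsewhere. Only order 1 is supported — higher-order
  segments invite overcorrection and are rejected explicitly. The operation
  is idempotent and invariant to adding any affine function of wavenumber.
* **Vector normalization.** Division by the Euclidean norm; an all-zero
  spectrum is an error, not a silent NaN. Applied *after* rubberband in the
  Raman plan — normalizing first would rescale baseline-contaminated
  spectra.
* **Crop.** Inclusive channel window; empty intersections error.

Negative intensities (possible with synthetic noise) are left untouched
everywhere; the hull handles them naturally.

## PLSR

Single-response NIPALS with mean-centering only (no unit-variance scaling —
the standard choice for spectra, where channel variance is informative).
For univariate y the component loop is closed-form, so fitting is exact and
deterministic. The regression vector b = W(P'W)⁻¹q is assembled via a dense
solve of the small (A x A) system; per-LV coefficient paths reuse the same
factors, so a single NIPALS pass at max_lv serves all LV counts during
cross-validation.

Numerical guard: if ‖X'y‖ < 1e-12 before the requested number of components
is extracted, `fit_plsr` raises an error naming the achievable rank, rather
than emitting NaNs. The cross-validation path uses `fit_plsr_path`, which
stops at the achievable rank and freezes the coefficient vector for higher
LV counts — on noise-free data the response is fully explained after one or
two components and predictions cannot change beyond that point, so the LV
curve is still well-defined for all requested LVs.

## Validation protocol

* Training pool: SET_02 and SET_04 (18 samples); test: SET_01/03/05 (27).
* Per iteration (default 100): a random 12/6 calibration/validation sample
  split, one NIPALS fit at max_lv = 20 on the calibration spectra, per-LV
  validation predictions aggregated to sample means, per-iteration RMSECV
  and R² (squared Pearson correlation) per LV.
* Chosen LV = argmin of the mean RMSECV curve; ties resolve to the smallest
  LV (parsimony).
* Test evaluation refits at the chosen LV on each iteration's calibration
  subset, yielding RMSEP and R² distributions (reported mean ± SD) and
  iteration-mean per-sample predictions.
* Relative errors: RE% = 100·|pred − true|/true for test samples with
  true > 0 (the three 0 %w/w samples are excluded; 24 of 27 remain), binned
  into half-open intervals [0,1), [1,2.5), [2.5,5), [5,7.5), [7.5,10),
  [10,∞) — an RE of exactly 10.0 lands in the top bin.
* Iteration k draws its split from substream k of the protocol seed, so
  increasing `n_iterations` extends, never reshuffles, the split sequence.

R² is computed as the squared Pearson correlation of true vs predicted per
iteration and averaged; no algebraic definition was available to copy, and
this choice is invariant to affine miscalibration, which keeps it
interpretable as linearity.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of the measurement
campaign and the qualitative spectral phenomenology, not calibrated optical
physics: band intensities are not quantitative cross-sections, hydrogen-bond
network effects beyond linear peak shifts are absent, and temperature drift,
detector nonlinearity (other than the hard clip) and cosmic-ray artifacts
are not modelled. Pipeline error levels on synthetic data therefore
demonstrate correctness and stability of the *algorithms* under the study's
design, noise magnitudes and nuisance structure — they are not predictions
of any particular instrument's accuracy.

One structural limit is worth stating: under standard addition, per-set
intrinsic-water variability is spectrally indistinguishable from added
water. The test-set prediction error of a correct pipeline is bounded below
by Δi·(100−c)/c percent relative error at level c, where Δi is the
difference between the test set's intrinsic water and the calibration mean.
With the default 0.08 %w/w intrinsic sd this floor is ~2 % mean relative
error, concentrated at the lowest levels — visible in the worked example,
and in the large low-concentration relative errors that real standard-
addition studies report.

## Problem sizes and runtime

Default runs use the full 405-spectrum design, 100 Monte-Carlo iterations
and 20 LVs; one full ATR-IR validation takes ~1.5 s on one CPU (the NIPALS
fit on a 108 x 901 calibration matrix is the inner loop), and the complete
test suite a little over half a minute. These are the study-scale sizes; no
scaled-down surrogate is needed anywhere.
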