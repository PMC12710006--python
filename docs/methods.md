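# Methods

`canopyphot` estimates and maps leaf photosynthetic capacity — the maximum
Rubisco carboxylation rate Vcmax25 and the maximum electron transport rate
Jmax25, both normalized to 25 °C — from 5-band UAV canopy reflectance
(blue, green, red, red-edge, NIR). This note documents the models, the
synthetic study conditions, the numerical choices, and what the tests do and
do not demonstrate.

## FvCB model and A-Ci fitting

Net assimilation follows the Farquhar–von Caemmerer–Berry model without the
TPU limitation:

    A  = min(Ac, Aj) − Rd
    Ac = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko))
    Aj = J (Ci − Γ*) / (4 Ci + 8 Γ*)

with J the lower root of θJ² − (αQ + Jmax)J + αQ·Jmax = 0 (θ = 0.85,
α = 0.24, Q = 1500 µmol m⁻² s⁻¹, the acclimation irradiance of the rapid
protocol). All kinetic parameters scale with leaf temperature by the
Arrhenius form k(T) = k25·exp(Ea(T − 298.15)/(298.15·R·T)). Kinetic
constants and activation energies are the Bernacchi (2001) set:
Γ*25 = 42.75 and Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 and O = 210
mmol mol⁻¹; Ea = 65 330 (Vcmax), 43 540 (Jmax), 46 390 (Rd), 37 830 (Γ*),
79 430 (Kc), 36 380 (Ko) J mol⁻¹. The hard minimum of Ac and Aj is used
rather than a hyperbolic smoothing: it is the simplest continuous published
form and introduces no extra smoothing parameter.

Fitting minimizes Σ(Aᵢ − Â(Ciᵢ))² over (Vcmax25, Jmax25, Rd25) with
`scipy.optimize.least_squares`, bounds (1, 500) × (1, 1000) × (0, 10)
µmol m⁻² s⁻¹ and tolerances 1e-8. Because min(Ac, Aj) has a kink, the fit
is multi-started from (50, 100, 1), (100, 200, 1.5) and (25, 50, 0.5) and
the lowest-cost solution is kept; Rd25 is free (bounded), not fixed. The
per-point limitation state (Rubisco- vs RuBP-regeneration-limited) is
reported from the fitted parameters. Noise-free forward-simulated curves are
recovered to better than 1e-3 relative error across a 3×3×2 grid of
generating parameters, and the 25 °C normalization round-trips exactly by
construction of the Arrhenius form.

The rapid-ramp protocol records one sample every 5 s while the CO2 level
rises from 30 to 1830 µmol mol⁻¹ at 200 µmol mol⁻¹ min⁻¹ — 108 records,
sampled at t = 5 … 540 s so the final record lands exactly on the endpoint.
The synthetic instrument treats the ramped value as Ci directly (no
stomatal model is in scope) and adds Gaussian noise of sd 0.5 µmol m⁻² s⁻¹
to A — small relative to the A range yet large enough that recovery is a
real statistical test. Per-plant traits are arithmetic means of converged
leaf-level fits; plants with no converged fit are flagged, not silently
averaged.

## Synthetic study conditions

The generator emulates a five-level nitrogen-gradient field trial (N0–N4 =
0, 130, 260, 390, 520 kg/hm², default 3 replicate plots × 15 plants). A
latent leaf nitrogen per area drives everything:

* n_area ~ (1.0 + 0.002·rate) g m⁻² with lognormal within-treatment noise
  (σ = 0.15), so expected capacity rises monotonically N0→N4;
* Cab = 25·n_area µg cm⁻² (σ = 0.06); Vcmax25 = 45·n_area µmol m⁻² s⁻¹
  (σ = 0.08) — Cab and Vcmax are thus correlated proxies of N, not copies
  of each other;
* Jmax25 = 1.9·Vcmax25 (σ = 0.05, ratio clipped to [1.2, 2.5]), a mid-range
  physiological ratio that keeps both limitations active over the ramp;
  Rd25 = 0.015·Vcmax25;
* LAI = 1.8 + 0.0025·rate ± 0.5 (uniform), clipped to [1.5, 4.2]: canopy
  structure also responds to N, so structure-sensitive indices carry
  complementary information about N status.

Scenes use a Beer-law two-stream caricature:
ρ_b = ρ_soil,b·e^(−k_b·LAI) + ρ_leaf,b(Cab)·(1 − e^(−k_b·LAI)), with soil
(0.15, 0.17, 0.19, 0.21, 0.20) (flat, ρNIR ≈ ρR), extinction k =
(0.85, 0.75, 0.90, 0.65, 0.55), and leaf reflectance linear in Cab:
base (0.04, 0.13, 0.06, 0.35, 0.45) minus slopes (0, 0.0007, 0.0006,
0.004, 0) per µg cm⁻² — the red edge is the most pigment-sensitive band and
NIR is pigment-insensitive, reproducing the canonical vegetation ordering
ρNIR > ρRE > ρG > ρR. This is deliberately not a radiative-transfer model
(PROSPECT/SAIL are non-goals); it encodes exactly the LAI/soil confounding
that motivates ratio indices such as SCCCI = NDRE/NDVI, whose relative range
over LAI ∈ [1, 4] at fixed Cab is less than half that of NDRE (asserted as
a property test).

Three nuisance processes make the spectra realistically imperfect proxies:

* a per-plant band-neutral brightness factor (lognormal, σ = 0.06) for
  illumination/BRDF variability — it cancels in ratio indices but confounds
  raw bands and reciprocals;
* per-plant, per-band lognormal jitter of the leaf optics (σ = 0.10) for
  leaf-angle and structural variation unrelated to pigment content — it
  makes every index, including ratios, a *noisy* pigment proxy with
  partially independent errors, which is what gives a multivariate model
  genuine headroom over the single best index (on noise-free spectra one
  index saturates the achievable R² and PLSR could only tie it);
* i.i.d. Gaussian pixel noise (σ = 0.003 reflectance) plus a band-neutral
  ×0.3 shadow on a seeded 10 % of canopy pixels.

What the generator does **not** emulate: directional (BRDF) geometry,
mixed border pixels, registration error between bands, within-crown pigment
gradients, atmospheric variability, or any genetic structure across
varieties. Passing tests therefore demonstrate the pipeline's correctness
and its statistical behaviour under the stated conditions — not field-level
accuracy claims.

## Imaging

Radiometric calibration is the empirical-line method against a ≈50 %
reflectance panel: gain g_b = nominal_b/panel_DN_b per band, output clipped
to [0, 1.5] with clip counts logged. Vegetation segmentation thresholds the
excess-green index ExG = 2ρG − ρR − ρB at 0.07 (strict inequality); the
generator's soil spectrum evaluates to ExG = 0 and its shadow model scales
ExG by 0.3, so the threshold removes both soil and shadowed canopy — which
is the intended behaviour of the masking step, whose recovery target is the
illuminated-canopy mask. ROI reflectance is the arithmetic per-band mean
over masked pixels; per-plant ROIs are a 9×9 window around the plant marker
intersected with the ExG mask. GSD follows pinhole geometry
(altitude·pixel pitch/focal length); the default flight configuration
(30 m altitude, 3.75 µm pixel pitch, 5.4 mm focal length) resolves 2 cm per
pixel.

ExG is computed on calibrated reflectance, not on chromatic coordinates;
the chromatic-coordinate variant exists in the registry (`g`, `b`) for
users who prefer it.

## Index registry

32 indices are registered with explicit formulas (the set used in the main
analysis: NDVI, NDRE, SCCCI, CVI, CI_green, CI_RE, GNDVI, VIg, VARI, GRRI,
GBRI, IKAW, MGRVI, RGBVI, GLI, ExG, ExB, SIPI, MSAVI2, MCARI2, the five raw
bands, their reciprocals, and chromatic g and b). GBRI is green-over-blue.
Five index names whose formulas could not be verified (IPCA,
CI2, WI, NDI, VIre) are stubs raising `UnregisteredFormulaError` until the
user registers a definition — formulas are never guessed. Guarded
denominators return NaN (flagged missing) rather than raising mid-batch;
modeling drops flagged rows. The registry serializes to JSON so the full
63-index bank can be supplied as configuration.

## Modeling

Samples are split 2:1 into calibration/validation by a seeded unstratified
shuffle (sizes round(2N/3) and the remainder; 204 → 136/68). Metrics:
R² = 1 − SSres/SStot, r = |Pearson|, RMSE, bias = mean(predicted −
observed), rRMSE = 100·RMSE/mean(observed).

LASSO (scikit-learn coordinate descent, objective (1/2n)RSS + λ‖β‖₁) runs
on internally standardized columns over a geometric 100-point λ path from
λ_max = max|Xᵀy|/n down four decades. λ* minimizes the mean 10-fold CV MSE
(seeded unstratified folds); exact ties break toward the larger λ (sparser
model). On orthonormal designs the coefficients equal closed-form
soft-thresholding — asserted at 1e-6.

PLSR is NIPALS (scikit-learn `PLSRegression`) on centered/scaled data; the
component count minimizes 10-fold CV RMSE over 1..min(p, n−1), ties toward
fewer components. With all components on a full-rank design the predictions
equal OLS (asserted at 1e-8). VIP_j = sqrt(p·Σ_a SS_a (w_ja/‖w_a‖)² /
Σ_a SS_a) with SS_a = q_a²‖t_a‖²; mean squared VIP is exactly 1, and
indices with VIP > 1 are flagged influential. If LASSO selects fewer than
two indices (PLSR needs ≥ 2), the selection is padded with the best
univariate index. The univariate baseline picks the index with the best
*calibration* R² and reports its validation metrics — selection never
touches the validation set.

## Mapping

Trained models are linear in their index vector, so per-pixel prediction
computes each selected index per pixel (same registry code as the tabular
path) and applies the model; a pixel equal to the ROI-mean spectrum
reproduces the tabular prediction exactly for these linear models (for
ratio indices, a ROI's mean index is generally not the index of its mean
spectrum — the pixel/tabular consistency is exact only in the former
sense). Soil/shadow pixels (ExG ≤ 0.07), nodata and guard-failing pixels
are masked; predictions are not clipped to physiological ranges —
out-of-range pixel counts are reported in map metadata instead, so model
misbehaviour stays visible. Per-plot summaries report mean/min/max over
valid pixels; plots with no valid pixels are reported as missing.

## Problem sizes and determinism

Default synthetic experiments use 5 treatments × 3 plots × 15 plants = 225
plants (a realistic field-campaign sample size), 108-point A-Ci
curves, and a ~78×186-pixel scene at 2 cm GSD — sizes at which the full
pipeline (225 curve fits, LASSO path CV, PLSR CV, per-pixel mapping) runs
in well under a minute. Every random draw flows from explicit integer
seeds through `numpy.random.default_rng`/`SeedSequence`; identical
(config, seed) reproduces byte-identical artifacts, which the manifest's
file hashes make checkable.

## Known limitations

* The reflectance model is a caricature; absolute index values are not
  comparable to field spectra, only their ordering/correlation structure.
* Vcmax/Jmax identifiability degrades when Jmax25 approaches αQ·(saturation)
  or when the ramp covers only one limitation; the default grid keeps both
  limitations active.
* The Jmax:Vcmax generating distribution (1.9 ± 5 %) is a package choice
  from the common physiological range, not an empirical estimate.
* LASSO fold assignment and PLSR fold assignment are independent seeded
  partitions; whether they should share folds is unspecified, and the
  package does not force them to.
* Rd25 estimated from A-Ci ramps is weakly identified; it is bounded to
  [0, 10] µmol m⁻² s⁻¹ and should not be over-interpreted.
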