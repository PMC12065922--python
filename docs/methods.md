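# Methods

This note documents the models behind `paitwin`, the parameters that matter,
the numerical choices, and what the synthetic experiments do and do not show
about real data.

## Tissue phantoms

Phantoms are 2D label maps in the imaging plane (depth × lateral, probe at
depth 0): a flat coupling stack (coupling medium, membrane, ultrasound gel),
then dermis, subcutis and bulk tissue with gently undulating boundaries, and
one elliptical lymph node fully inside the bulk. Default grid 256×128 voxels
at 0.1 mm; the twin experiment uses 128×64 at 0.2 mm (see *Problem sizes*).
Voxel indices are 0-based, depth increases away from the probe, physical
positions are voxel centres in mm.

Optical absorption follows the linear mixing rule over chromophore
fractions; reduced scattering follows µs′(λ) = a·(λ/500 nm)^(−b). The
chromophore table (`data/chromophores.csv`) is literature-derived: whole
blood at 150 g Hb/L for the two hemoglobin endmembers, pure water, soft fat
and a melanosome power law, tabulated over 660–1100 nm with linear
interpolation and no extrapolation. Per-class compositions and acoustic
constants live in `data/tissue_properties.yaml` and are deliberately
editable; they follow the conventions of standard tissue-optics
compilations. Two values deserve comment:

- The dermis *melanin fraction* (0.002) is a layer-equivalent: melanosomes
  occupy ~1–2 % of a ~0.1 mm epidermis, and the model smears that pigment
  over the full ~2 mm dermis layer. Using the raw melanosome fraction for
  the whole layer would make skin nearly opaque at 700 nm and is physically
  wrong.
- The lymph-node BVF/sO₂ entries are placeholders; every phantom overrides
  them with a ground truth drawn from a disease state.

### Disease states

Node ground truth is Gaussian per state — malignant BVF 4±2 %, sO₂ 43±15 %;
benign 14±7 %, 73±15 %; intermediate 9±4.5 %, 58±15 % — with draws *clipped*
(not rejected) to [0.001, 1] for BVF and [0, 1] for sO₂. The clipping bias
at these parameters is below 0.3 percentage points (verified against the
closed-form clipped-normal mean). The 0.001 BVF floor keeps every node
weakly perfused so its sO₂ remains physically defined.

### Composition heterogeneity

Real tissue is granular: blood resides in discrete microvessels and the
other constituents fluctuate at sub-millimetre scale. A perfectly
homogeneous region is *invisible* to a band-limited detector except at its
edges, which would leave node interiors with a spectrum-less clutter floor
and destroy any sO₂ sensitivity. The builder therefore multiplies the
chromophore fractions by a shared random texture field (relative sd 0.3,
white at a fixed ~0.2 mm cell size so statistics do not depend on voxel
size, floored at 0.05, mean-preserving per class region). Because one field
scales all fractions, each voxel's *relative* composition — in particular
its sO₂ — is untouched, and region means remain exact, so the node ground
truth is preserved. Setting `bvf_heterogeneity=0` restores homogeneous
regions for contract tests.

## Device model

Full photon Monte Carlo and wave-equation acoustics are replaced by
desk-scale substitutes that preserve the mechanisms under study.

**Fluence.** Collimated illumination along depth; each column is attenuated
by exp(−∫µ_eff dz) with µ_eff = √(µa(µa+3µs′)), evaluated at voxel centres
(half of the voxel's own attenuation). This reduces exactly to Beer–Lambert
when µs′=0 and to the diffusion-theory √(3µaµs′) in the scattering-dominated
limit. A vectorised voxel Monte Carlo random walk (isotropic scattering at
rate µs′, continuous absorption weighting, track-length estimator) serves as
an independent cross-check; the two agree on decay rates within a factor ~2,
which is all the qualitative claims require. Limitations: no diffuse
buildup near the surface, no lateral spreading, no refractive-index steps.

**Acoustics.** Every voxel radiates the array's band-limited impulse
response (Gaussian-modulated cosine at 4 MHz, 100 % fractional −6 dB
bandwidth), delayed by distance/sos and scaled by 1/r; contributions
superpose linearly. Implementation: fractional-delay deposition onto the
time axis followed by one FFT convolution per element. Acoustic attenuation
(dB/MHz/cm at the centre frequency) is applied per voxel–element pair using
the attenuation averaged over the column above the voxel — a deliberate
simplification of the true ray average. Default array: 256 elements on a
40 mm-radius, 125° arc focused 10 mm deep, sampled at 40 MHz; all values are
configurable since not every device constant is public.

**Noise.** I.i.d. additive Gaussian noise per frame. The default sigma is
calibrated once per experiment configuration so that a mean-malignant node
at the deep end of the depth range has single-frame SNR ≈ 2 (peak node-only
channel amplitude divided by two) — a realistic regime in which malignant
nodes are noise-dominated and benign nodes are not.

## Image formation

The processing chain mirrors the clinical device: per-wavelength pulse
energy division; zero-phase order-4 Butterworth bandpass (default 1–7 MHz;
in-band gain within 0.1 %, stopband ≥ 20 dB); four-frame averaging;
delay-and-sum beamforming with linear delay interpolation, uniform element
weights and no apodization (delays beyond the recorded axis contribute
zero and are counted); Hilbert-envelope detection along beamformed depth
lines, in that order. Reconstruction reuses the projection speed of sound
by default (the "inverse crime" is accepted for unit testing; a mismatched
sos can be passed for realism studies).

## Spectral unmixing

Per pixel, the envelope amplitudes at the acquisition wavelengths inside
700–850 nm (the five-wavelength subset of the 11-wavelength protocol) are
decomposed onto whole-blood Hb/HbO₂ endmembers by non-negative least
squares; for two endmembers the NNLS solution is closed-form (unconstrained
solve if feasible, else the better single-endmember fit), vectorised over
all pixels and verified against `scipy.optimize.nnls`. sO₂ maps are masked
where tHb falls below a threshold (default 1 % of the image's 99th
percentile tHb) to suppress undefined ratios in background; the twin error
metric uses threshold 0 so that every node pixel counts. **No fluence
correction is applied before unmixing** — deliberately, so the spectral
coloring bias of the real chain is reproduced rather than removed. The mean
envelope amplitude at 1000 nm over an ROI serves as a water-content proxy,
water being a dominant absorber there.

## The twin experiment

One run: draw a ground truth from a disease state → generate a label map →
build the phantom → per wavelength, fluence → p₀ → projection → four noisy
frames → average → bandpass → DAS → envelope → unmix → mean |sO₂ − truth|
over node pixels. Everything derives from one seed per node, so runs are
exactly reproducible. The headline analysis (30 nodes per state, 90 runs)
reports per-run (BVF, error) pairs and their Spearman rank correlation; no
parametric fit is claimed.

Two oracle modes decompose the error:

- `noiseless=True`: the remaining error is spectral-coloring bias plus
  background clutter.
- `uniform_fluence=True`: unit fluence and only the node's *hemoglobin*
  absorption radiates. This isolates the estimator chain from coloring,
  clutter and non-hemoglobin cross-talk; since every wavelength image is
  then an exact scalar multiple of one spatial field, the chain inverts the
  saturation to machine precision, and with noise on the mode measures pure
  noise error. Restricting the oracle to the hemoglobin subspace is what
  makes "near-exact inversion" mathematically well-defined: a two-endmember
  unmixing basis cannot be inverted exactly in the presence of water or fat
  signal, and those cross-talk terms belong to the realistic runs.

Two regimes govern the depth dependence of coloring: shallow paths are
dominated by the melanin-bearing skin, which attenuates 700 nm more than
850 nm (red-shifting the fluence, biasing sO₂ upward), while bulk tissue
(water + oxygenated blood) attenuates 850 nm more (blue-shifting, biasing
downward). The net mean bias crosses zero around 15 mm; the monotone
depth-sweep property is therefore asserted in the bulk regime (12–17 mm).

## Mixed model and explained variation

Records follow y_ij = α + Σ_k x_ijk·β_k + δ_i + ε_ij with fixed effects for
treatment phase (pre/during/post), side, depth, ROI pixel count, smoking,
BMI and season, a subject random intercept δ_i ~ N(0, σ_δ²) and residual
ε_ij ~ N(0, σ_ε²), fitted by REML (statsmodels `MixedLM`, gradient tolerance
1e-8, continuous columns scaled to unit sd internally for conditioning and
transformed back). Categorical covariates are effect-coded so each term's
fitted contribution is invariant to the reference-level choice; with the
subject variance constrained to zero the fit reduces exactly to OLS.

The explained-variation decomposition assigns each fixed effect the
empirical variance of its fitted contribution X_k·β̂_k across records; the
covariance between contributions goes to an explicit *shared* term (≈ 0 for
the independent synthetic covariates); σ_δ² and σ_ε² give the subject and
residual shares; all shares are normalised by their sum, so the fractions
add to one exactly and are invariant to affine rescaling of the response.
This operative definition is validated by parameter recovery on synthetic
studies (generating three-way splits recovered within ±0.05 at 200
subjects; Wald type-I error ≈ 5 % under the null), not against any
patient-data split, which would require the unavailable clinical records.

The per-wavelength analysis fits one model per wavelength. The
water-mechanism experiment sets the treatment effect proportional to the
embedded water absorption and checks that the treatment's variance share
rises monotonically with wavelength over 680–1000 nm — the band where water
absorption itself rises monotonically. Real water absorption is not
monotone across the full 680–1100 nm protocol (a shoulder near 760 nm and a
dip after the ~975 nm peak at 1030/1064 nm), so the monotone claim is tested
exactly where its premise holds, and the premise is asserted alongside the
conclusion.

## Problem sizes and runtime

The twin experiment defaults to a 128×64 grid at 0.2 mm, a 128-element
array and the five unmixing wavelengths: this keeps a 90-run experiment
around one minute on a single CPU while leaving the axial/lateral point
spread (~0.2–0.4 mm) well below the node diameter (4–10 mm), so the
mechanisms are resolution-faithful. Phantom and array defaults outside the
experiment remain at full scale (256×128 at 0.1 mm, 256 elements).

## Known limitations

- 2D in-plane physics: no out-of-plane illumination or detection, no
  element directivity, no speed-of-sound heterogeneity in propagation.
- The fluence model has no near-surface diffuse buildup; absolute fluence
  at shallow depth is underestimated, though spectral ratios — the quantity
  that drives coloring — behave correctly.
- Acoustic attenuation is frequency-independent along simplified paths.
- The composition texture is statistically stationary white-cell noise, not
  a vascular tree; it reproduces the *amplitude* statistics band-limited
  detection needs, not vascular morphology.
- Synthetic study records have independent covariates and a single random
  intercept; real records violate both (confounding, repeated structures),
  so passing recovery tests demonstrates correctness of the estimator, not
  robustness to real-world confounding.
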