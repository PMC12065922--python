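# paitwin

Photoacoustic tissue/device digital twins for auditing oxygen-saturation
estimates in neck lymph nodes.

## The problem

Multispectral photoacoustic imaging (PAI) estimates tissue oxygen
saturation, sO₂ = HbO₂/(Hb+HbO₂), by linear spectral unmixing of images
acquired at several near-infrared wavelengths. In weakly perfused tissue —
notably malignant lymph nodes, whose blood volume fraction (BVF) is only a
few percent — the hemoglobin signal is faint and the estimate is corrupted
by detector noise, by background clutter, and by *spectral coloring*: the
overlying tissue filters light wavelength-dependently, so the apparent
spectrum at depth is distorted even without noise.

`paitwin` builds a complete simulation replica (digital twin) of the tissue
and of an arc-array photoacoustic scanner, with exact knowledge of the
ground truth, and uses it to quantify how the sO₂ estimation error grows as
node BVF falls. It also implements the accompanying statistical machinery: a
linear mixed model of longitudinal study records and the empirical
decomposition of explained signal variation.

## What is inside

- **`paitwin.phantoms`** — layered neck phantoms (coupling medium, membrane,
  gel, dermis, subcutis, bulk tissue, one elliptical lymph node) on a 2D
  imaging grid; voxel absorption from the mixing rule
  µa(λ) = BVF·[sO₂·µa_HbO₂ + (1−sO₂)·µa_Hb] + W·µa_water + F·µa_fat +
  M·µa_melanin and reduced scattering µs′(λ) = a·(λ/500 nm)^(−b). Node
  ground truth is drawn from three clinically informed disease states:
  malignant (BVF 4±2 %, sO₂ 43±15 %), benign (14±7 %, 73±15 %) and an
  intermediate state (9±4.5 %, 58±15 %).
- **`paitwin.forward`** — collimated-beam fluence with effective attenuation
  µ_eff = √(µa(µa+3µs′)) (exactly Beer–Lambert in the non-scattering limit),
  initial pressure p₀ = Γ·µa·φ, analytic band-limited projection onto a
  256-element, 4 MHz arc array, additive Gaussian noise; plus a voxel Monte
  Carlo fluence cross-check.
- **`paitwin.recon`** — the clinical processing chain: laser-energy
  correction, zero-phase bandpass, four-frame averaging, delay-and-sum
  beamforming, Hilbert-envelope detection.
- **`paitwin.unmixing`** — non-negative linear unmixing onto Hb/HbO₂
  endmembers over the five 700–850 nm acquisition wavelengths; sO₂, tHb and
  the 1000 nm water-proxy statistic.
- **`paitwin.twin`** — the end-to-end twin experiment (sample truth → build
  phantom → simulate → reconstruct → unmix → score), error-vs-BVF analysis,
  ROI summaries, relative-to-baseline series, tumor-to-muscle ratio.
- **`paitwin.lmm`** — `ExplainedVariationModel` / `ExplainedVariationResults`
  (statsmodels-style): REML mixed model with a subject random intercept and
  fixed effects for treatment phase, side, depth, ROI pixel count, smoking,
  BMI and season; the explained-variation decomposition; a synthetic
  study-record generator for parameter recovery.

## Worked example

```python
from paitwin.twin import (TwinExperimentConfig, run_twin, error_vs_bvf,
                          runs_to_frame)

cfg = TwinExperimentConfig()            # desk-scale twin, noise calibrated
runs = []
for k, state in enumerate(("malignant", "intermediate", "benign")):
    runs += run_twin(state, 10, seeds=100 + 1000 * k, config=cfg)

df, rho = error_vs_bvf(runs)
print(runs_to_frame(runs).groupby("state")[["bvf", "abs_so2_error"]].mean())
print("Spearman rho(BVF, error) = %.2f" % rho)
```

Output:

```
                bvf  abs_so2_error
state
benign        0.139          0.146
intermediate  0.095          0.168
malignant     0.038          0.195
Spearman rho(BVF, error) = -0.60
```

Each row is the mean over ten simulated scans of one disease state: the mean
node BVF and the mean absolute sO₂ error (estimated minus true saturation,
averaged over node pixels). Malignant nodes — lowest blood volume — carry
the largest error, and the rank correlation between BVF and error across all
thirty scans is strongly negative: exactly the mechanism that makes measured
sO₂ untrustworthy in low-BVF nodes.

The same pipeline is scriptable from the shell:

```sh
paitwin phantom --state malignant --seed 1 --out phantom.h5
paitwin simulate --phantom phantom.h5 --out channels.h5
paitwin reconstruct --channels channels.h5 --out msi.h5
paitwin unmix --msi msi.h5 --out unmix.h5
paitwin twin run --state all --n 30 --seed 0 --out runs.csv
paitwin lmm simulate --seed 0 --out records.csv
paitwin lmm decompose records.csv
```

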