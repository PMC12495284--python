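# redoxdmri

Desk-scale pipeline linking blood glutathione-cycle enzyme activities to
white-matter diffusion microstructure.

Peripheral redox markers — glutathione peroxidase (GPx) and glutathione
reductase (GR) activities in blood cells, and their ratio GPx/GR — have been
proposed as accessible proxies for brain oxidative status in
schizophrenia-spectrum disorders. Testing whether they track white-matter
microstructure requires a chain of quantitative steps: a biophysical signal
model, diffusion kurtosis imaging (DKI) fitting, inversion to tissue
parameters, harmonization of scanner and plate-reader batch effects, and
voxelwise association testing with permutation inference on a tract
skeleton. This package implements that chain end to end for researchers who
want to study, validate or extend each stage — with a synthetic-data module
standing in for patient data that cannot be shared.

## What is implemented

**Forward model** — two-compartment standard model with Watson orientation
dispersion (stick + zeppelin + Watson):

    S(b, g) = S0 ∫_{S²} W_κ(n·μ) [ f e^{−b Da (g·n)²}
              + (1−f) e^{−b De⊥ − b (De∥−De⊥)(g·n)²} ] dn

with axonal water fraction `f`, intra-axonal diffusivity `Da`, extra-axonal
diffusivities `De∥ ≥ De⊥` (µm²/ms), and Watson concentration `κ`
(orientation coherence `c2 = ⟨cos²ψ⟩ ∈ [1/3, 1]`). Rician noise is added at
a chosen SNR.

**DKI** — weighted linear least squares fit of the cumulant expansion

    ln S(b, g) = ln S0 − b gᵀD g + (b²/6) MD² W(g)

restricted to b ≤ 2500 s/mm², yielding the scalar maps MD, FA, MK (plus
AD, RD, AK, RK).

**WMTI-Watson** — per-voxel inversion of the five moment equations relating
the axially symmetrized (D, W) invariants to (f, Da, De∥, De⊥, κ), on the
in-vivo consensus branch Da ≥ De∥.

**Harmonization** — parametric empirical-Bayes location/scale batch removal
(ComBat family) with protected covariates and no reference batch, shared
between voxelwise scanner harmonization and plate-reader marker correction.

**Association testing** — Welch tests, Pearson χ², robust (Huber)
regression with sex / centred age / age² / delay covariates, a 60-day
MRI-to-blood delay filter, GPx/GR median split on the healthy-control
median, and voxelwise inference by Freedman–Lane permutations with
threshold-free cluster enhancement (TFCE, E = 0.5, H = 2), reporting both
FDR (Benjamini–Hochberg) and family-wise (max-TFCE null) corrected maps.

**Synthetic data** — multi-shell phantoms and a two-group cohort whose
marker moments, demographics, batch structure, and a planted HC-only
negative GR→MK slope in a contiguous skeleton cluster emulate the study
population.

## Worked example

Simulate 200 voxels of dispersed white matter at SNR 30, fit DKI, then
invert to tissue parameters:

```python
import numpy as np
from redoxdmri import (SMWatsonParams, default_scheme, watson_signal, add_noise,
                       Volume4D, DKIModel, WMTIWatsonModel)

params = SMWatsonParams(f=0.55, Da=2.1, De_par=1.7, De_perp=0.7, kappa=10.0)
scheme = default_scheme()
clean = watson_signal(params, scheme)
noisy = add_noise(np.tile(clean, (200, 1)), sigma=1/30, model="rician", rng=0)
vol = Volume4D(data=noisy.reshape(200, 1, 1, -1))

res = DKIModel(vol, scheme).fit()
print(res.summary())
wm = WMTIWatsonModel(res.tensors).fit(compute_alt=False)
print(wm.summary())
```

```
DKI weighted-LLS fit
  voxels fitted: 200 (200 valid)
  MD  (um^2/ms): 0.8640 +/- 0.0346
  FA           : 0.7573 +/- 0.0237
  MK           : 0.8842 +/- 0.0854
  clip-flagged voxels: 0
WMTI-Watson inversion (branch Da >= De_par)
  voxels converged: 194 / 200
  f       : 0.5232 +/- 0.0409
  Da      : 2.5524 +/- 0.2307 um^2/ms
  De_par  : 1.4571 +/- 0.1211 um^2/ms
  De_perp : 0.5937 +/- 0.0819 um^2/ms
  c2      : 0.8842 +/- 0.0148
```

The mean axonal fraction (0.52) sits close to the ground truth 0.55; the
upward bias in `Da` at SNR 30 is the well-known noise sensitivity of the
intra-axonal diffusivity in moment-based inversions (see
`docs/methods.md`). The orientation coherence `c2 ≈ 0.88` matches
`c2(κ=10) = 0.893`.

A command-line interface mirrors the library:
`redoxdmri simulate|fit-dki|fit-wmti|harmonize|associate --help`.

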