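# Methods

## Signal model and simulation

The forward model is the two-compartment standard model of white matter
with a Watson orientation distribution: an intra-axonal "stick" (fraction
`f`, axial diffusivity `Da`, zero radial diffusivity) and an extra-axonal
axially symmetric "zeppelin" (`De∥`, `De⊥`), both convolved with the Watson
density `W_κ(n·μ) ∝ exp(κ (n·μ)²)`. Parameters and units: `f` ∈ [0, 1],
diffusivities in µm²/ms, `κ` ≥ 0 dimensionless; b-values are converted from
s/mm² to ms/µm² internally so that all diffusivities stay in µm²/ms.

The spherical convolution is evaluated by a deterministic product
quadrature about the symmetry axis: 64 Gauss–Legendre nodes in cos ψ on
[0, 1] (the integrand is antipodally symmetric) × 64 equally spaced
azimuths, with the Watson density folded into the weights and the weights
normalized to unit sum so that `S(b=0) = S0` holds exactly. Above
`κ = 1024` the quadrature can no longer resolve the density peak and the
coherent (δ-function ODF) limit is substituted; this keeps the function
total over `κ ∈ [0, ∞)`. Agreement with an importance-weighted Monte-Carlo
oracle (10⁶ uniform orientations) is ~1e-4 relative, limited by the
Monte-Carlo sampling itself.

Watson moments use the Dawson-function identity
`M(1/2, 3/2, κ) = e^κ D(√κ)/√κ`, giving closed forms
`c2 = (√κ/D(√κ) − 1)/(2κ)` and the corresponding `c4`, stable over the
whole κ range with a Taylor series below κ = 1e-4. `c2` is strictly
increasing with `c2(0) = 1/3` and `c2 → 1` as `κ → ∞`.

Rician noise follows the magnitude-MRI model
`√((S + ε₁)² + ε₂²)`, ε ~ N(0, σ²); the default phantom SNR is 30 at b=0,
a typical clinical diffusion SNR. The default synthetic acquisition is
b = {0×6, 1000×30, 2000×45, 2500×60} s/mm² with golden-spiral direction
sets — a desk-scale multi-shell scheme covering exactly the b ≤ 2500 range
the DKI fit consumes. Acquisitions with jittered b-values are clustered
into shells with a 50 s/mm² tolerance.

## DKI fit

The cumulant expansion `ln S = ln S0 − b·gᵀDg + (b²/6)·MD²·W(g)` is linear
in its 22 coefficients (ln S0, 6 of D, 15 of MD²·W). Estimation is two-pass
weighted linear least squares: pass 1 unweighted on log-signals, pass 2
weighted by the squared predicted signals of pass 1 — the standard variance
stabilization for log-transformed data. Voxels with any non-positive or
non-finite signal, a singular design, or non-positive fitted MD are flagged
invalid rather than raising.

Scalars: MD, FA, AD, RD from the eigen-decomposition of D. MK is the
weighted average of the directional apparent kurtosis
`K(g) = MD² W(g)/D(g)²` over a fixed deterministic 256-point spherical
quadrature (16 Gauss–Legendre polar nodes × 16 azimuths); the weighted rule
keeps MD/FA/MK rotation-invariant to better than 1e-6 for in-model
signals, which an equal-weight point set of the same size does not achieve.
Directional kurtosis is clipped to the plausibility window [−3/7, 10]
before averaging and voxels with more than 25 % clipped directions are
flagged. No positivity constraints are imposed during the fit itself.

The quadratic cumulant truncation biases fitted tensors at finite b
(O(b) in W, O(b²) for symmetric diffusivity mixtures). Tests that compare
against analytic cumulants therefore fit in the small-b regime (shells at
scale s = 25–100 s/mm²) and extrapolate s → 0 (Richardson), which agrees
with the closed forms to ~1e-5.

## WMTI-Watson inversion

The model cumulants are available analytically: with Watson orientation
moments `⟨n⊗n⟩` and `⟨n⊗4⟩` expressed through c2 and c4,

    D = f Da ⟨nnᵀ⟩ + (1−f)(De⊥ I + (De∥−De⊥)⟨nnᵀ⟩)
    W = (3/MD²) sym( ⟨D_i ⊗ D_i⟩ − D ⊗ D )

(the covariance of the compartment tensors, fully symmetrized). The
inversion consumes five axially symmetrized invariants per voxel — D∥, D⊥,
apparent kurtosis along and perpendicular to the principal axis, and the
spherical mean of W — and solves the five moment equations by bounded
least squares. The parametrization (f, Da, De∥/Da, De⊥/De∥, κ) enforces
the branch `Da ≥ De∥` and the ordering `De⊥ ≤ De∥` through box bounds
alone; multi-start over f₀ ∈ {0.3, 0.5, 0.7} × κ₀ ∈ {3, 10, 40} with early
exit on machine-precision roots makes the noise-free round trip exact
(< 0.1 % error over the tested grid). The alternative branch `Da < De∥` is
solved as well and stored in a diagnostics channel, never reported.

Reporting bounds: f ∈ [0.01, 0.99], diffusivities ∈ [0.01, 4] µm²/ms,
κ ∈ [0.1, 128]; a voxel is `converged` only when the residual norm is
below 1e-6 and all bounds hold. Voxels with FA < 0.1 have no trusted
principal axis and are flagged non-convergent (the downstream analysis is
skeleton-restricted, where FA is high). Eigenvalue ties are broken by the
deterministic LAPACK ordering and flagged degenerate.

At SNR 30 the moment-based inversion recovers f with median error < 0.05;
`Da` is the least stable parameter (upward bias of ~0.3–0.5 µm²/ms),
consistent with the known shallow likelihood of the intra-axonal
diffusivity in cumulant-based estimation.

## Harmonization

Parametric empirical-Bayes ComBat: per feature g and subject j in batch i,
`y = α_g + X β_g + γ_ig + δ_ig ε`. Features are standardized against the
batch-size-weighted grand mean and pooled residual variance, batch
locations get a normal prior and scales an inverse-gamma prior with
method-of-moments hyperparameters, updated by the standard iterative
conditional scheme (tolerance 1e-4, max 100 iterations). No reference
batch: data are re-centred on the weighted grand mean, and each feature's
sample grand mean is restored exactly after adjustment. Protected
covariates are group, sex, age and age² for imaging features and group,
sex, age for blood markers — the variables the downstream models test or
adjust for. Zero-variance features pass through unadjusted; single-batch
designs return the input unchanged.

A known property of the EB step, verified here against the Bioconductor
reference implementation (which matches this one to ~1e-6 after
de-meaning): shrinkage of the per-feature batch locations toward their
across-feature mean leaves a residual batch gap of order
`(1−w) × (sampling noise of a batch mean)`, where the shrinkage weight `w`
is essentially independent of the per-batch sample size. With 200+200
subjects and a uniform planted 0.5-SD shift this residual is ~9 % of the
shift on average, and roughly a third of features retain gaps above 10 %
of the planted size. Exact per-feature removal is not a property of EB
ComBat; only its no-shrinkage limit has it.

## Association testing

Subjects whose MRI-to-blood delay exceeds 60 days are excluded (inclusive
boundary: exactly 60 is kept). All designs contain sex, centred age,
centred age², and delay; the predictor (GPx, GR, or their ratio) is
centred. Tested terms: the predictor slope, the slope-by-group contrast
(interaction term of a pooled model), or the three-way
predictor × ratio-class × group interaction with all lower-order terms.
The ratio split classifies every subject against the healthy-control
median ratio; ties go to "high" for determinism.

Reported slopes use Huber M-estimation (c = 1.345, zero-centred MAD scale,
IRLS tolerance 1e-8), vectorized across voxels. Permutation inference uses
OLS t-statistics inside the loop for tractability: Freedman–Lane
permutation of reduced-model residuals, TFCE of the |t| map (two-sided)
over the skeleton's 26-connectivity graph with E = 0.5, H = 2 and 100
integration steps (computed by an incremental union-find sweep over
descending thresholds), and two corrected maps per analysis:

* `p_fdr` — Benjamini–Hochberg across skeleton voxels of the per-voxel
  permutation p-values `(b+1)/(n_perm+1)` of the TFCE statistic; this is
  the significance map used for cluster reporting.
* `p_fwe` — from the permutation null of the maximum TFCE over the
  skeleton; exact under exchangeability, and the quantity whose
  false-positive rate is calibrated (the FDR map is conservative under the
  strong spatial dependence of TFCE combined with the discreteness of
  permutation p-values, with family-wise rates well below nominal under a
  global null).

Clusters are connected components of the significant set with voxel count
and peak |t|.

## Synthetic cohort

The generator reproduces the study population margins: 86 HC / 82 PT; GPx
16.7 ± 6.6 vs 16.3 ± 6.2 and GR 2.5 ± 0.7 vs 2.3 ± 0.7 nmoles
NADPH/min/g hemoglobin; GPx–GR correlation 0.38 (the latent correlation is
inflated to compensate for the variance taken up by systematic terms);
higher GPx in HC females (+4 units, centred within group so the marginal
moments stay on target); GPx declining by 0.1 unit/year of age; sex,
scanner (Prisma/Trio) and plate-reader (Infinite/SPARK) frequencies from
the published contingency tables; group ages 28.1 ± 8.6 / 29.8 ± 9.6;
half-normal MRI-to-blood delays with group means 17.9 / 36.7 days so the
60-day filter excludes a realistic fraction. Batch effects: +0.25 SD on
SPARK marker readings, +0.3 within-voxel SD on Trio skeleton metrics.

Skeleton metrics (MD, FA, MK, f) are baseline voxel maps plus subject
offsets plus voxel noise with plausible white-matter skeleton values
(e.g. MK 0.95 with 0.05 voxel noise). The planted effect multiplies none
of this: inside one contiguous 200-voxel cluster, HC subjects receive
`MK −= 0.043 · (GR − mean GR_HC)` (a standardized slope of ≈ 0.6) and PT
subjects a flat 0.02 MK deficit with no GR dependence — the qualitative
pattern the analysis is meant to detect.

The skeleton template is a one-voxel-thick spherical shell with
26-connectivity (radius 34 → ~15k voxels at full scale; radius 12 → ~1.8k
voxels, used for permutation-heavy runs). It mimics the sparsity and
surface-like connectivity of a tract skeleton, not its anatomy: passing
tests show the statistical machinery is calibrated and sensitive on data
with the assumed generative structure, not that real registration,
projection, or physiological confounds are handled.

## Problem sizes in tests and the acceptance script

Round-trip grid: 4 values per axis over f ∈ [0.3, 0.7], Da ∈ [1.5, 2.5],
De∥ ∈ [1.0, 2.0], De⊥ ∈ [0.3, 0.9], κ ∈ {4, 10, 25, 64}, restricted to
Da ≥ De∥ and De⊥ ≤ De∥ (832 points). Null calibration: 200 replicates of
the full simulate → delay-filter → harmonize → associate pipeline on the
1.8k-voxel skeleton with 500 permutations each; the family-wise rate is
compared to the binomial 95 % interval around 0.05. Planted-effect runs
use 500 permutations — detection of the planted effect is far from the
decision boundary, so the permutation resolution is not limiting. These
sizes were chosen as the smallest at which each property is measured
stably.

## Known limitations

* No time-dependent diffusion, exchange, dot or free-water compartment;
  no fiber crossings beyond Watson dispersion.
* The DKI fit has no positivity constraints and no outlier rejection; it
  consumes preprocessed data.
* EB ComBat's shrinkage floor (above) bounds how completely a uniform
  batch shift can be removed.
* The permutation loop tests OLS t-statistics; robust slopes are reported
  but not permuted.
* The synthetic skeleton is geometric, not anatomical; no registration or
  projection errors are simulated, and clinical scores are not simulated.
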