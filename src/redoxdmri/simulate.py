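"""Synthetic diffusion signals, phantoms and cohorts.

The patient data behind this analysis cannot be shared, so everything
downstream is exercised on synthetic inputs with the same statistical
structure:

* noise-free and Rician-noised multi-shell signals from the two-compartment
  stick + zeppelin + Watson standard model;
* a two-group cohort (healthy controls HC, patients PT) whose blood-marker
  marginals match the study population (GPx ~ 16.7 +/- 6.6 vs 16.3 +/- 6.2,
  GR ~ 2.5 +/- 0.7 vs 2.3 +/- 0.7 nmoles NADPH/min/g hemoglobin, GPx-GR
  correlation ~ 0.38, higher GPx in HC females, GPx declining with age);
* scanner and plate-reader batch shifts for the harmonization stage;
* a planted negative GR-MK slope present in controls only, concentrated in
  a contiguous skeleton cluster, which the association pipeline must find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CohortTable, GradientScheme, Volume4D
from .skeleton import SkeletonDataset, SkeletonTemplate, contiguous_cluster
from .watson import watson_norm

__all__ = [
    "SMWatsonParams",
    "PhantomSpec",
    "CohortSimSpec",
    "sphere_directions",
    "default_scheme",
    "watson_signal",
    "add_noise",
    "build_phantom",
    "simulate_cohort",
    "KAPPA_COHERENT",
]

# above this concentration the quadrature can no longer resolve the ODF
# peak; the coherent (delta-function) limit is substituted
KAPPA_COHERENT = 1024.0


@dataclass
class SMWatsonParams:
    """Ground-truth standard-model parameters of one tissue population.

    f          intra-axonal (axonal) water fraction, in [0, 1]
    Da         intra-axonal axial diffusivity (um^2/ms)
    De_par     extra-axonal axial diffusivity (um^2/ms)
    De_perp    extra-axonal radial diffusivity (um^2/ms)
    kappa      Watson concentration (>= 0; dispersion decreases with kappa)
    mu         principal orientation (unit 3-vector)
    S0         non-weighted signal (arbitrary units)
    """

    f: float
    Da: float
    De_par: float
    De_perp: float
    kappa: float
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    S0: float = 1.0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.Da < 0 or self.De_par < 0 or self.De_perp < 0:
            raise ValueError("diffusivities must be non-negative")
        if self.De_perp > self.De_par:
            raise ValueError("De_perp must not exceed De_par")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        n = np.linalg.norm(self.mu)
        if abs(n - 1.0) > 1e-6:
            if n == 0:
                raise ValueError("mu must be a unit vector")
            self.mu = self.mu / n
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass
class PhantomSpec:
    """Layout of a multi-region phantom volume."""

    shape: tuple[int, int, int]
    regions: list[tuple[np.ndarray, SMWatsonParams]]  # (bool mask, params)
    snr: float = 30.0  # S0-to-sigma ratio at b=0
    noise_model: str = "rician"  # rician | gaussian | none

    def __post_init__(self):
        if self.noise_model not in {"rician", "gaussian", "none"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise ValueError("snr must be positive unless noise_model='none'")
        occupancy = np.zeros(self.shape, dtype=int)
        for mask, _ in self.regions:
            if mask.shape != tuple(self.shape):
                raise ValueError("region mask shape mismatch")
            occupancy += mask.astype(int)
        if np.any(occupancy > 1):
            raise ValueError("region masks overlap")


def sphere_directions(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the golden-spiral (Fibonacci)
    construction — a deterministic stand-in for repulsion-optimized sets."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme() -> GradientScheme:
    """Desk-scale multi-shell scheme: b = 0 x6, 1000 x30, 2000 x45, 2500 x60
    s/mm^2 — covering the b <= 2500 range the DKI fit consumes."""
    bvals = np.concatenate(
        [np.zeros(6), np.full(30, 1000.0), np.full(45, 2000.0), np.full(60, 2500.0)]
    )
    bvecs = np.concatenate(
        [np.zeros((6, 3)), sphere_directions(30), sphere_directions(45), sphere_directions(60)]
    )
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# Gauss-Legendre x trapezoid quadrature over the half-sphere (the Watson
# density and the diffusion kernel are both antipodally symmetric)
_N_POLAR = 64
_N_AZIMUTH = 64
_GL_T, _GL_W = np.polynomial.legendre.leggauss(_N_POLAR)
_COS_PSI = 0.5 * (_GL_T + 1.0)  # map [-1,1] -> [0,1]
_W_PSI = 0.5 * _GL_W
_PHI = 2.0 * np.pi * np.arange(_N_AZIMUTH) / _N_AZIMUTH


def _orthonormal_basis(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return e1, e2


def _kernel(b: np.ndarray, x2: np.ndarray, p: SMWatsonParams) -> np.ndarray:
    """Per-orientation compartment signal; x2 = (g . n)^2, b in ms/um^2."""
    intra = p.f * np.exp(-b * p.Da * x2)
    extra = (1.0 - p.f) * np.exp(-b * p.De_perp - b * (p.De_par - p.De_perp) * x2)
    return intra + extra


def watson_signal(params: SMWatsonParams, scheme: GradientScheme) -> np.ndarray:
    """Noise-free standard-model signal for each volume of ``scheme``.

    S(b, g) = S0 * int_{S^2} W_kappa(n . mu)
              [ f e^{-b Da (g.n)^2} + (1-f) e^{-b De_perp - b (De_par - De_perp)(g.n)^2} ] dn

    evaluated by Gauss-Legendre (order 64) x trapezoid (64 azimuths)
    quadrature about the symmetry axis; above kappa = 1024 the coherent
    delta-function ODF limit is substituted.  b-values are converted from
    s/mm^2 to ms/um^2 so that diffusivities are in um^2/ms.
    """
    b = np.asarray(scheme.bvals, dtype=float) * 1e-3  # s/mm^2 -> ms/um^2
    g = np.asarray(scheme.bvecs, dtype=float)
    p = params
    if p.kappa > KAPPA_COHERENT:
        x2 = (g @ p.mu) ** 2
        return p.S0 * _kernel(b, x2, p)

    e1, e2 = _orthonormal_basis(p.mu)
    t = _COS_PSI  # (P,)
    s = np.sqrt(1.0 - t**2)
    # orientation samples n(t, phi), shape (P, A, 3)
    n = (
        t[:, None, None] * p.mu[None, None, :]
        + s[:, None, None]
        * (np.cos(_PHI)[None, :, None] * e1 + np.sin(_PHI)[None, :, None] * e2)
    )
    # quadrature weights carrying the Watson density, normalized to sum 1 so
    # that S(b=0) = S0 exactly
    w = np.exp(p.kappa * t**2) * _W_PSI
    w = np.repeat(w[:, None], _N_AZIMUTH, axis=1) / _N_AZIMUTH
    w /= w.sum()
    x = np.einsum("vk,pak->vpa", g, n)  # (N, P, A)
    sig = np.einsum("pa,vpa->v", w, _kernel(b[:, None, None], x**2, p))
    return p.S0 * sig


def add_noise(signal: np.ndarray, sigma: float, model: str = "rician", rng=None) -> np.ndarray:
    """Corrupt a signal with Rician (magnitude-MRI) or Gaussian noise.

    Rician: each sample becomes sqrt((S + e1)^2 + e2^2) with e1, e2
    independent N(0, sigma^2) — the magnitude of a complex Gaussian
    perturbation.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if model == "none" or sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(rng)
    if model == "rician":
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        return np.sqrt((signal + e1) ** 2 + e2**2)
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    raise ValueError(f"unknown noise model {model!r}")


def build_phantom(spec: PhantomSpec, scheme: GradientScheme, seed: int) -> Volume4D:
    """Fill each region of the phantom with its model signal plus noise.

    Voxels outside all regions are masked out (and left at zero).
    """
    data = np.zeros(tuple(spec.shape) + (len(scheme),), dtype=float)
    mask = np.zeros(spec.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    for region_mask, params in spec.regions:
        sig = watson_signal(params, scheme)
        data[region_mask] = sig
        mask |= region_mask
        if spec.noise_model != "none":
            sigma = params.S0 / spec.snr
            idx = np.where(region_mask)
            noisy = add_noise(
                np.broadcast_to(sig, (len(idx[0]), len(scheme))), sigma, spec.noise_model, rng
            )
            data[idx] = noisy
    return Volume4D(data=data, mask=mask)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class GroupMoments:
    """Group-wise marginal mean/SD for one blood marker."""

    mean: float
    sd: float


@dataclass
class CohortSimSpec:
    """Study-population parameters of the synthetic cohort.

    Defaults reproduce the published cohort margins: group sizes 86/82,
    GPx 16.7 +/- 6.6 (HC) and 16.3 +/- 6.2 (PT), GR 2.5 +/- 0.7 and
    2.3 +/- 0.7 nmoles NADPH/min/g hemoglobin, GPx-GR correlation 0.38,
    female-HC GPx excess, a mild GPx decline with age, scanner
    (Prisma/Trio) and plate-reader (Infinite/SPARK) frequencies from the
    published contingency tables, and MRI-blood delays with a long tail so
    that the 60-day exclusion bites.
    """

    n_hc: int = 86
    n_pt: int = 82
    gpx: dict = field(default_factory=lambda: {"HC": GroupMoments(16.7, 6.6), "PT": GroupMoments(16.3, 6.2)})
    gr: dict = field(default_factory=lambda: {"HC": GroupMoments(2.5, 0.7), "PT": GroupMoments(2.3, 0.7)})
    rho_gpx_gr: float = 0.38
    sex_effect: float = 4.0  # additive GPx shift for HC females (nmol/min/g Hb)
    age_slope: float = -0.10  # GPx change per year of age
    female_frac: dict = field(default_factory=lambda: {"HC": 32 / 86, "PT": 18 / 82})
    age_mean: dict = field(default_factory=lambda: {"HC": 28.1, "PT": 29.8})
    age_sd: dict = field(default_factory=lambda: {"HC": 8.6, "PT": 9.6})
    delay_mean: dict = field(default_factory=lambda: {"HC": 17.9, "PT": 36.7})
    trio_frac: dict = field(default_factory=lambda: {"HC": 18 / 86, "PT": 22 / 82})
    spark_frac: dict = field(default_factory=lambda: {"HC": 20 / 86, "PT": 7 / 82})
    # batch effects (applied before harmonization is supposed to remove them)
    plate_shift_sd: float = 0.25  # additive marker shift on SPARK, in marker SDs
    scanner_shift_sd: float = 0.3  # additive metric shift on Trio, in within-voxel SDs
    # planted association: HC-only negative GR->MK slope inside one cluster
    planted_slope: float = 0.043  # MK units per GR unit (~0.6 standardized)
    planted_metric: str = "MK"
    cluster_size: int = 200
    pt_deficit: float = 0.02  # group-level MK deficit in PT inside the cluster
    seed: int = 0

    def __post_init__(self):
        if self.n_hc < 2 or self.n_pt < 2:
            raise ValueError("group sizes must be >= 2")
        if not abs(self.rho_gpx_gr) < 1:
            raise ValueError("|rho_gpx_gr| must be < 1")
        for d in (self.gpx, self.gr):
            for m in d.values():
                if m.sd <= 0:
                    raise ValueError("marker SDs must be positive")


# per-metric baseline mean, across-voxel SD of the mean map, between-subject
# SD, and within-subject voxel noise SD — plausible skeleton-averaged values
_METRIC_MODEL = {
    "MD": dict(mean=0.80, voxel_sd=0.05, subj_sd=0.03, noise_sd=0.04),
    "FA": dict(mean=0.55, voxel_sd=0.08, subj_sd=0.03, noise_sd=0.04),
    "MK": dict(mean=0.95, voxel_sd=0.06, subj_sd=0.03, noise_sd=0.05),
    "f": dict(mean=0.40, voxel_sd=0.05, subj_sd=0.02, noise_sd=0.03),
}


def simulate_cohort(
    spec: CohortSimSpec, template: SkeletonTemplate
) -> tuple[CohortTable, SkeletonDataset, np.ndarray]:
    """Draw a synthetic cohort and its skeleton metric matrices.

    Returns ``(cohort, skeleton_dataset, cluster_voxels)`` where
    ``cluster_voxels`` indexes the contiguous skeleton cluster carrying the
    planted HC-only GR-MK association.  Fixing ``spec.seed`` makes the
    output bit-reproducible.
    """
    import pandas as pd

    if spec.cluster_size > template.n_voxels:
        raise ValueError("designated cluster exceeds the skeleton")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in (("HC", spec.n_hc), ("PT", spec.n_pt)):
        female = rng.random(n) < spec.female_frac[group]
        age = np.clip(rng.normal(spec.age_mean[group], spec.age_sd[group], n), 18, 65)
        scanner = np.where(rng.random(n) < spec.trio_frac[group], "Trio", "Prisma")
        plate = np.where(rng.random(n) < spec.spark_frac[group], "SPARK", "Infinite")
        delay = np.abs(rng.normal(0.0, spec.delay_mean[group] * np.sqrt(np.pi / 2), n))

        gm, rm = spec.gpx[group], spec.gr[group]
        # systematic GPx structure (sex, age), centred within group so the
        # marginal moments stay on target
        eff = np.zeros(n)
        if group == "HC":
            eff += spec.sex_effect * (female - female.mean())
        eff += spec.age_slope * (age - age.mean())
        resid_var = gm.sd**2 - eff.var()
        if resid_var <= 0:
            raise ValueError("sex/age effects exceed the target GPx variance")
        resid_sd = np.sqrt(resid_var)
        # correlate the residual parts so the observed GPx-GR correlation
        # lands on target despite the systematic-variance dilution
        rho_z = min(0.99, spec.rho_gpx_gr * gm.sd / resid_sd)
        z = rng.multivariate_normal([0, 0], [[1, rho_z], [rho_z, 1]], size=n)
        gpx = gm.mean + eff + resid_sd * z[:, 0]
        gr = np.maximum(0.3, rm.mean + rm.sd * z[:, 1])
        # plate-reader batch effect on the measured activities
        shift = spec.plate_shift_sd * (plate == "SPARK")
        gpx = gpx + shift * gm.sd
        gr = gr + shift * rm.sd
        gpx = np.maximum(0.5, gpx)
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"{group}{i:03d}",
                    group=group,
                    age=age[i],
                    sex="F" if female[i] else "M",
                    scanner=scanner[i],
                    plate=plate[i],
                    gpx=gpx[i],
                    gr=gr[i],
                    delay=delay[i],
                )
            )
    cohort = CohortTable(pd.DataFrame(rows))
    df = cohort.df
    n_sub, n_vox = len(df), template.n_voxels
    cluster = contiguous_cluster(template, spec.cluster_size)

    is_hc = (df["group"] == "HC").to_numpy()
    is_trio = (df["scanner"] == "Trio").to_numpy()
    gr_all = df["gr"].to_numpy()
    gr_hc_mean = gr_all[is_hc].mean()

    metrics = {}
    for name, mm in _METRIC_MODEL.items():
        base = mm["mean"] + mm["voxel_sd"] * rng.standard_normal(n_vox)
        subj = mm["subj_sd"] * rng.standard_normal(n_sub)
        mat = base[None, :] + subj[:, None] + mm["noise_sd"] * rng.standard_normal((n_sub, n_vox))
        mat += (spec.scanner_shift_sd * mm["noise_sd"]) * is_trio[:, None]
        if name == spec.planted_metric and spec.planted_slope != 0:
            effect = np.zeros(n_sub)
            effect[is_hc] = -spec.planted_slope * (gr_all[is_hc] - gr_hc_mean)
            effect[~is_hc] = -spec.pt_deficit
            mat[:, cluster] += effect[:, None]
        metrics[name] = mat
    dataset = SkeletonDataset(subjects=list(df["subject_id"]), template=template, metrics=metrics)
    return cohort, dataset, cluster
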