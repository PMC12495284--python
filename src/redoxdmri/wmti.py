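"""WMTI-Watson: biophysical inversion of the DKI tensors.

The two-compartment standard model with a Watson orientation distribution
(stick + zeppelin + Watson) has five scalar parameters per voxel: axonal
water fraction f, intra-axonal diffusivity Da, extra-axonal axial and
radial diffusivities De_par and De_perp, and the orientation coherence
c2 = <cos^2 psi> (equivalently the Watson concentration kappa).  Its
second- and fourth-order signal cumulants (D, W) are available in closed
form, so the inversion solves five moment equations in five unknowns from
the axially-symmetrized DKI invariants.

The moment equations admit two algebraic branches distinguished by the
sign of Da - De_par; the in-vivo consensus branch Da >= De_par is
hard-selected here (the alternative branch is solved too and kept as a
diagnostics channel, never reported as the estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import least_squares

from .dki import DKITensors, d6_to_tensor, tensor_to_w15, w15_to_tensor
from .simulate import SMWatsonParams
from .watson import c2 as watson_c2
from .watson import c4 as watson_c4
from .watson import fourth_moment_tensor, second_moment_tensor

__all__ = [
    "WMTIWMaps",
    "sm_cumulants",
    "axial_symmetrize",
    "invert_wmti_watson",
    "WMTIWatsonModel",
    "WMTIResults",
    "FA_FLOOR",
    "BOUNDS",
]

FA_FLOOR = 0.1  # below this no principal axis is trusted
RESIDUAL_TOL = 1e-6
# reporting bounds: f, diffusivities (um^2/ms), kappa
BOUNDS = dict(f=(0.01, 0.99), diff=(0.01, 4.0), kappa=(0.1, 128.0))
_DEGENERATE_TOL = 1e-6  # relative eigenvalue tie tolerance


def _sym4(t: np.ndarray) -> np.ndarray:
    """Full symmetrization of a rank-4 tensor (average over 24 orderings)."""
    out = np.zeros_like(t)
    for perm in permutations(range(4)):
        out += np.transpose(t, perm)
    return out / 24.0


def sm_cumulants(params: SMWatsonParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact (D, W) cumulant tensors of the stick+zeppelin+Watson model.

    D is the orientation-averaged compartment tensor; W is defined so the
    DKI expansion matches the exact signal to O(b^2) at b -> 0:

        W = (3 / MD^2) * sym( <D_i (x) D_i> - D (x) D )

    with the average over compartments and Watson orientations.
    """
    p = params
    m2 = second_moment_tensor(p.mu, p.kappa)
    m4 = fourth_moment_tensor(p.mu, p.kappa)
    de = p.De_par - p.De_perp
    eye = np.eye(3)

    D = p.f * p.Da * m2 + (1.0 - p.f) * (p.De_perp * eye + de * m2)

    dd = np.einsum("ij,kl->ijkl", eye, eye)
    d_m2 = np.einsum("ij,kl->ijkl", eye, m2) + np.einsum("kl,ij->ijkl", eye, m2)
    M = p.f * p.Da**2 * m4 + (1.0 - p.f) * (
        p.De_perp**2 * dd + p.De_perp * de * d_m2 + de**2 * m4
    )
    C = M - np.einsum("ij,kl->ijkl", D, D)
    md = np.trace(D) / 3.0
    W = 3.0 * _sym4(C) / md**2
    return D, W


@dataclass
class AxialInvariants:
    """Axially-symmetrized per-voxel representation the inversion consumes."""

    D_par: np.ndarray
    D_perp: np.ndarray
    K_par: np.ndarray  # apparent kurtosis along the principal axis
    K_perp: np.ndarray  # apparent kurtosis perpendicular to it
    W_mean: np.ndarray  # spherical mean of W(g) (dimensionless)
    axis: np.ndarray  # (V, 3) principal axis
    degenerate: np.ndarray  # eigenvalue tie flag


def _w_sphere_mean(w15: np.ndarray) -> np.ndarray:
    """Analytic spherical mean of W(g): (W_xxxx+W_yyyy+W_zzzz
    + 2 W_xxyy + 2 W_xxzz + 2 W_yyzz) / 5."""
    w = w15_to_tensor(np.atleast_2d(w15))
    out = (
        w[:, 0, 0, 0, 0] + w[:, 1, 1, 1, 1] + w[:, 2, 2, 2, 2]
        + 2 * (w[:, 0, 0, 1, 1] + w[:, 0, 0, 2, 2] + w[:, 1, 1, 2, 2])
    ) / 5.0
    return out


def axial_symmetrize(tensors: DKITensors) -> AxialInvariants:
    """Project general (D, W) voxels onto the axially symmetric form.

    D_par is the principal-eigenvalue component, D_perp the mean of the
    two transverse eigenvalues; the kurtosis invariants are the apparent
    kurtosis along and perpendicular to the principal axis and the
    spherical mean of W.  The projection is exact (zero information loss)
    when the input is already axially symmetric.  Voxels whose top
    eigenvalues tie within tolerance are flagged degenerate; the axis
    tie-break follows the deterministic LAPACK eigenvector ordering.
    """
    D = d6_to_tensor(tensors.d6)
    evals, evecs = np.linalg.eigh(D)
    d_par = evals[:, 2]
    d_perp = evals[:, :2].mean(axis=1)
    axis = evecs[:, :, 2]
    md = evals.mean(axis=1)
    degenerate = (evals[:, 2] - evals[:, 1]) <= _DEGENERATE_TOL * np.maximum(np.abs(md), 1e-12)

    W = w15_to_tensor(tensors.w15)
    k_par = np.empty(len(D))
    k_perp = np.empty(len(D))
    for v in range(len(D)):
        e1 = axis[v]
        w_e1 = np.einsum("ijkl,i,j,k,l->", W[v], e1, e1, e1, e1)
        with np.errstate(invalid="ignore", divide="ignore"):
            k_par[v] = md[v] ** 2 * w_e1 / d_par[v] ** 2 if d_par[v] > 0 else np.nan
        # W(g) averaged over the transverse plane: use the two transverse
        # eigenvectors and the analytic in-plane average
        u, w_vec = evecs[v, :, 1], evecs[v, :, 0]
        wu = np.einsum("ijkl,i,j,k,l->", W[v], u, u, u, u)
        ww = np.einsum("ijkl,i,j,k,l->", W[v], w_vec, w_vec, w_vec, w_vec)
        wuw = np.einsum("ijkl,i,j,k,l->", W[v], u, u, w_vec, w_vec)
        # mean over the circle g = u cos a + w sin a of W(g):
        # <cos^4> = 3/8, <sin^4> = 3/8, <cos^2 sin^2> = 1/8 (x6 cross term)
        w_perp = 0.375 * wu + 0.375 * ww + 0.75 * wuw
        with np.errstate(invalid="ignore", divide="ignore"):
            k_perp[v] = md[v] ** 2 * w_perp / d_perp[v] ** 2 if d_perp[v] > 0 else np.nan
    return AxialInvariants(
        D_par=d_par, D_perp=d_perp, K_par=k_par, K_perp=k_perp,
        W_mean=_w_sphere_mean(tensors.w15), axis=axis, degenerate=degenerate,
    )


def _forward_invariants(f, Da, De_par, De_perp, kappa):
    """Closed-form (D_par, D_perp, K_par, K_perp, W_mean) of the model."""
    m2 = watson_c2(kappa)
    m4 = watson_c4(kappa)
    de = De_par - De_perp
    d_par = f * Da * m2 + (1 - f) * (De_perp + de * m2)
    t2 = (1 - m2) / 2.0  # <n_x^2>
    d_perp = f * Da * t2 + (1 - f) * (De_perp + de * t2)
    md = (d_par + 2 * d_perp) / 3.0

    # <(axial apparent diffusivity)^2> along the symmetry axis
    m_zzzz = f * Da**2 * m4 + (1 - f) * (De_perp**2 + 2 * De_perp * de * m2 + de**2 * m4)
    k_par = 3.0 * (m_zzzz - d_par**2) / d_par**2

    w4x = 3.0 * (1 - 2 * m2 + m4) / 8.0  # <n_x^4>
    m_xxxx = f * Da**2 * w4x + (1 - f) * (De_perp**2 + 2 * De_perp * de * t2 + de**2 * w4x)
    k_perp = 3.0 * (m_xxxx - d_perp**2) / d_perp**2

    # spherical means: <(g.n)^4>_g = 1/5 for any n; zeppelin average is free
    # of n; the mean tensor is axially symmetric (d_par, d_perp)
    m_sph = f * Da**2 / 5.0 + (1 - f) * (
        De_perp**2 + 2.0 * De_perp * de / 3.0 + de**2 / 5.0
    )
    dde = d_par - d_perp
    d2_sph = d_perp**2 + 2.0 * d_perp * dde / 3.0 + dde**2 / 5.0
    w_mean = 3.0 * (m_sph - d2_sph) / md**2
    return d_par, d_perp, k_par, k_perp, w_mean


@dataclass
class WMTIWMaps:
    """Per-voxel WMTI-Watson parameter maps (flat over voxels)."""

    f: np.ndarray
    Da: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    kappa: np.ndarray
    c2: np.ndarray
    converged: np.ndarray
    residual: np.ndarray
    # alternative (Da < De_par) branch, diagnostics only
    alt_f: np.ndarray | None = None
    alt_Da: np.ndarray | None = None
    alt_residual: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.f)


def _solve_voxel(target: np.ndarray, d_par: float, d_perp: float, branch_plus: bool = True):
    """Bounded least squares on the five moment equations for one voxel.

    Parametrization guarantees the branch and ordering constraints:
    x = (f, Da, rp, rr, kappa) with De_par = rp*Da (rp <= 1 on the plus
    branch) and De_perp = rr*De_par (rr <= 1).  On the minus branch the
    roles of Da and De_par swap: x1 = De_par, Da = rp*De_par.
    """
    scale = np.array([max(abs(target[0]), 0.1), max(abs(target[0]), 0.1), 1.0, 1.0, 1.0])

    def resid(x):
        f, a, rp, rr, kap = x
        if branch_plus:
            Da, De_par = a, rp * a
        else:
            Da, De_par = rp * a, a
        De_perp = rr * De_par
        fwd = np.array(_forward_invariants(f, Da, De_par, De_perp, kap))
        return (fwd - target) / scale

    lo = np.array([BOUNDS["f"][0], BOUNDS["diff"][0], 1e-3, 0.0, BOUNDS["kappa"][0]])
    hi = np.array([BOUNDS["f"][1], BOUNDS["diff"][1], 1.0, 1.0, BOUNDS["kappa"][1]])
    best = None
    a0 = float(np.clip(1.5 * d_par, 0.5, 3.9))
    rp0 = float(np.clip(d_par / a0, 0.05, 0.95))
    rr0 = float(np.clip(2.0 * d_perp / max(rp0 * a0, 0.05), 0.05, 0.95))
    # multi-start over f and kappa; stop early once a machine-precision
    # root of the moment equations is found
    for f0 in (0.5, 0.3, 0.7):
        for k0 in (10.0, 40.0, 3.0):
            x0 = np.clip([f0, a0, rp0, rr0, k0], lo, hi)
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            # ties broken toward larger f
            if best is None or sol.cost < best.cost - 1e-15 or (
                abs(sol.cost - best.cost) <= 1e-15 and sol.x[0] > best.x[0]
            ):
                best = sol
            if best is not None and best.cost < 1e-16:
                return best
    return best


def invert_wmti_watson(tensors: DKITensors, compute_alt: bool = True) -> WMTIWMaps:
    """Voxel-wise inversion of the DKI tensors to WMTI-Watson parameters.

    Consumes the axially-symmetrized invariants; a voxel converges iff the
    residual norm is below 1e-6 and every parameter lies inside its
    reporting bounds (f in [0.01, 0.99], diffusivities in [0.01, 4]
    um^2/ms, kappa in [0.1, 128]).  Voxels with FA below 0.1 have no
    trusted principal axis and are flagged non-convergent.
    """
    inv = axial_symmetrize(tensors)
    V = tensors.n_voxels
    out = {k: np.full(V, np.nan) for k in ("f", "Da", "De_par", "De_perp", "kappa", "c2", "residual")}
    alt = {k: np.full(V, np.nan) for k in ("f", "Da", "residual")}
    converged = np.zeros(V, dtype=bool)

    # FA from the axial representation
    md = (inv.D_par + 2 * inv.D_perp) / 3.0
    num = (inv.D_par - md) ** 2 + 2 * (inv.D_perp - md) ** 2
    den = inv.D_par**2 + 2 * inv.D_perp**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)

    for v in range(V):
        if not tensors.valid[v] or not np.isfinite(fa[v]) or fa[v] < FA_FLOOR or inv.degenerate[v]:
            continue
        target = np.array([inv.D_par[v], inv.D_perp[v], inv.K_par[v], inv.K_perp[v], inv.W_mean[v]])
        if not np.all(np.isfinite(target)):
            continue
        sol = _solve_voxel(target, inv.D_par[v], inv.D_perp[v], branch_plus=True)
        if sol is None:
            continue
        f, a, rp, rr, kap = sol.x
        res = float(np.linalg.norm(sol.fun))
        out["f"][v], out["Da"][v] = f, a
        out["De_par"][v], out["De_perp"][v] = rp * a, rr * rp * a
        out["kappa"][v] = kap
        out["c2"][v] = watson_c2(kap)
        out["residual"][v] = res
        in_bounds = (
            BOUNDS["f"][0] <= f <= BOUNDS["f"][1]
            and BOUNDS["diff"][0] <= a <= BOUNDS["diff"][1]
            and BOUNDS["kappa"][0] <= kap <= BOUNDS["kappa"][1]
        )
        converged[v] = in_bounds and res < RESIDUAL_TOL
        if compute_alt:
            sol2 = _solve_voxel(target, inv.D_par[v], inv.D_perp[v], branch_plus=False)
            if sol2 is not None:
                alt["f"][v] = sol2.x[0]
                alt["Da"][v] = sol2.x[2] * sol2.x[1]
                alt["residual"][v] = float(np.linalg.norm(sol2.fun))

    return WMTIWMaps(
        f=out["f"], Da=out["Da"], De_par=out["De_par"], De_perp=out["De_perp"],
        kappa=out["kappa"], c2=out["c2"], converged=converged, residual=out["residual"],
        alt_f=alt["f"], alt_Da=alt["Da"], alt_residual=alt["residual"],
    )


def cumulants_to_tensors(params: SMWatsonParams) -> DKITensors:
    """Pack exact model cumulants of one parameter set as a 1-voxel
    :class:`DKITensors` (convenience for round-trip testing)."""
    from .dki import tensor_to_d6

    D, W = sm_cumulants(params)
    return DKITensors(
        lnS0=np.array([np.log(params.S0)]),
        d6=tensor_to_d6(D)[None, :],
        w15=tensor_to_w15(W)[None, :],
        residual_norm=np.zeros(1),
        valid=np.ones(1, dtype=bool),
    )


class WMTIWatsonModel:
    """statsmodels-style wrapper: WMTIWatsonModel(tensors).fit() -> results."""

    def __init__(self, tensors: DKITensors):
        self.tensors = tensors

    def fit(self, compute_alt: bool = True) -> "WMTIResults":
        return WMTIResults(self, invert_wmti_watson(self.tensors, compute_alt=compute_alt))


class WMTIResults:
    def __init__(self, model: WMTIWatsonModel, maps: WMTIWMaps):
        self.model = model
        self.maps = maps

    def summary(self) -> str:
        m, ok = self.maps, self.maps.converged
        def fmt(x):
            return f"{np.nanmean(x[ok]):.4f} +/- {np.nanstd(x[ok]):.4f}" if ok.any() else "n/a"
        return "\n".join([
            "WMTI-Watson inversion (branch Da >= De_par)",
            f"  voxels converged: {int(ok.sum())} / {m.n_voxels}",
            f"  f       : {fmt(m.f)}",
            f"  Da      : {fmt(m.Da)} um^2/ms",
            f"  De_par  : {fmt(m.De_par)} um^2/ms",
            f"  De_perp : {fmt(m.De_perp)} um^2/ms",
            f"  c2      : {fmt(m.c2)}",
        ])
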