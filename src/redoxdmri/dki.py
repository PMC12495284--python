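"""Diffusion kurtosis imaging: voxel-wise weighted-LLS tensor estimation.

Signal model (cumulant expansion of the log-signal to order b^2):

    ln S(b, g) = ln S0 - b g^T D g + (b^2/6) MD^2 W(g),
    W(g) = sum_ijkl W_ijkl g_i g_j g_k g_l,

with D the 3x3 diffusion tensor (um^2/ms, 6 unique components) and W the
fully symmetric rank-4 kurtosis tensor (dimensionless, 15 unique
components).  The fit is linear in (ln S0, D, MD^2 W): 22 coefficients.

Estimation is the standard two-pass weighted linear least squares: an
unweighted log-linear pass provides predicted signals whose squares weight
the second pass (the optimal weighting for log-transformed Rician-free
data).  Fits are restricted to b <= 2500 s/mm^2, where the quadratic
cumulant truncation is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .io import GradientScheme, Volume4D

__all__ = ["DKITensors", "ScalarMaps", "DKIModel", "DKIResults", "fit_dki_wlls", "dki_scalars",
           "BMAX_DEFAULT", "KMIN", "KMAX"]

BMAX_DEFAULT = 2500.0  # s/mm^2
# plausibility window for directional apparent kurtosis; -3/7 is the lower
# bound attainable by any probability distribution of diffusivities along a
# direction, 10 a generous in-vivo ceiling
KMIN, KMAX = -3.0 / 7.0, 10.0
CLIP_FRACTION_FLAG = 0.25

# unique component orders
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
_W_IDX = list(combinations_with_replacement(range(3), 4))  # 15 sorted quadruples


def _w_mult() -> np.ndarray:
    from math import factorial

    mult = []
    for quad in _W_IDX:
        counts = [quad.count(a) for a in range(3)]
        mult.append(factorial(4) // (factorial(counts[0]) * factorial(counts[1]) * factorial(counts[2])))
    return np.array(mult, dtype=float)


_W_MULT = _w_mult()


def d_quadratic(d6: np.ndarray, g: np.ndarray) -> np.ndarray:
    """g^T D g for stacked unique components d6 (..., 6) and directions (M, 3)."""
    basis = np.stack([g[:, i] * g[:, j] for i, j in _D_IDX], axis=1) * _D_MULT  # (M, 6)
    return d6 @ basis.T


def w_quartic(w15: np.ndarray, g: np.ndarray) -> np.ndarray:
    """W(g) for stacked unique components w15 (..., 15) and directions (M, 3)."""
    basis = np.stack(
        [g[:, a] * g[:, b] * g[:, c] * g[:, d] for a, b, c, d in _W_IDX], axis=1
    ) * _W_MULT
    return w15 @ basis.T


def d6_to_tensor(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique components to full symmetric (..., 3, 3)."""
    out = np.zeros(d6.shape[:-1] + (3, 3))
    for comp, (i, j) in enumerate(_D_IDX):
        out[..., i, j] = d6[..., comp]
        out[..., j, i] = d6[..., comp]
    return out


def tensor_to_d6(d: np.ndarray) -> np.ndarray:
    return np.stack([d[..., i, j] for i, j in _D_IDX], axis=-1)


def w15_to_tensor(w15: np.ndarray) -> np.ndarray:
    """Expand (..., 15) unique components to full symmetric (..., 3,3,3,3)."""
    out = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    from itertools import permutations

    for comp, quad in enumerate(_W_IDX):
        for perm in set(permutations(quad)):
            out[(...,) + perm] = w15[..., comp]
    return out


def tensor_to_w15(w: np.ndarray) -> np.ndarray:
    return np.stack([w[(...,) + quad] for quad in _W_IDX], axis=-1)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(N, 22) design: [1, -b q2(g) (6 cols), (b^2/6) q4(g) (15 cols)].

    b is converted to ms/um^2, so the D block is in um^2/ms and the W block
    carries MD^2 * W (dimensionless times (um^2/ms)^2).
    """
    b = scheme.bvals * 1e-3
    g = scheme.bvecs
    q2 = np.stack([g[:, i] * g[:, j] for i, j in _D_IDX], axis=1) * _D_MULT
    q4 = np.stack([g[:, a] * g[:, b_] * g[:, c] * g[:, d] for a, b_, c, d in _W_IDX], axis=1) * _W_MULT
    return np.concatenate(
        [np.ones((len(b), 1)), -b[:, None] * q2, (b[:, None] ** 2 / 6.0) * q4], axis=1
    )


@dataclass
class DKITensors:
    """Per-voxel DKI fit over the masked voxels of a volume.

    Arrays are flat over voxels (first axis); ``voxel_index`` maps back to
    the spatial grid.  ``w15`` holds the dimensionless kurtosis tensor W
    (the raw b^2 coefficients divided by the fitted MD^2).
    """

    lnS0: np.ndarray  # (V,)
    d6: np.ndarray  # (V, 6) um^2/ms
    w15: np.ndarray  # (V, 15) dimensionless
    residual_norm: np.ndarray  # (V,)
    valid: np.ndarray  # (V,) bool
    voxel_index: np.ndarray | None = None  # (V, 3) int coordinates
    shape: tuple | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.lnS0)

    @property
    def D(self) -> np.ndarray:
        return d6_to_tensor(self.d6)

    @property
    def W(self) -> np.ndarray:
        return w15_to_tensor(self.w15)

    @property
    def md(self) -> np.ndarray:
        return self.d6[:, :3].mean(axis=1)


@dataclass
class ScalarMaps:
    """Scalar invariants of the DKI tensors (flat over voxels)."""

    MD: np.ndarray  # um^2/ms
    FA: np.ndarray
    MK: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    AK: np.ndarray
    RK: np.ndarray
    valid: np.ndarray
    clip_flagged: np.ndarray  # > 25% of design directions clipped


def _check_scheme(scheme: GradientScheme, n_volumes: int) -> None:
    if np.any(scheme.bvals > BMAX_DEFAULT + scheme.shell_tolerance):
        raise ValueError(
            f"scheme contains b = {scheme.bvals.max():g} s/mm^2; the DKI cumulant "
            f"fit requires truncation at b <= {BMAX_DEFAULT:g} s/mm^2 "
            "(apply truncate_shells first)"
        )
    if n_volumes != len(scheme):
        raise ValueError("volume count does not match scheme length")
    if len(scheme) < 22:
        raise ValueError(f"{len(scheme)} volumes < 22 coefficients; fit underdetermined")
    nonzero_shells = scheme.shells()
    nonzero_shells = nonzero_shells[nonzero_shells > scheme.shell_tolerance]
    if len(nonzero_shells) < 2:
        raise ValueError("need >= 2 nonzero shells to separate D from W")


def fit_dki_wlls(volume: Volume4D, scheme: GradientScheme) -> DKITensors:
    """Two-pass weighted linear least squares DKI fit on masked voxels.

    Pass 1 is an unweighted fit of the log-signals; pass 2 re-solves with
    weights equal to the squared predicted signals of pass 1.  Voxels with
    any non-positive signal are flagged invalid rather than raising.
    """
    _check_scheme(scheme, volume.n_volumes)
    A = design_matrix(scheme)
    coords = np.argwhere(volume.mask)
    Y = volume.data[volume.mask]  # (V, N)
    V = len(Y)
    n_par = A.shape[1]
    lnS0 = np.zeros(V)
    d6 = np.zeros((V, 6))
    c15 = np.zeros((V, 15))
    resid = np.full(V, np.nan)
    valid = np.all(Y > 0, axis=1) & np.all(np.isfinite(Y), axis=1)

    if np.any(valid):
        logY = np.log(Y[valid])  # (Vv, N)
        beta1, *_ = np.linalg.lstsq(A, logY.T, rcond=None)  # (22, Vv)
        pred = A @ beta1  # (N, Vv) log-predictions
        w = np.exp(2.0 * pred).T  # (Vv, N) squared predicted signals
        # batched weighted normal equations, chunked to bound memory
        beta2 = np.empty_like(beta1.T)  # (Vv, 22)
        idx = np.flatnonzero(valid)
        chunk = 20000
        ok = np.ones(len(idx), dtype=bool)
        for s in range(0, len(idx), chunk):
            sl = slice(s, min(s + chunk, len(idx)))
            wv = w[sl]
            AtWA = np.einsum("ni,vn,nj->vij", A, wv, A, optimize=True)
            AtWy = np.einsum("ni,vn,vn->vi", A, wv, logY[sl], optimize=True)
            try:
                beta2[sl] = np.linalg.solve(AtWA, AtWy[..., None])[..., 0]
            except np.linalg.LinAlgError:
                for t, (M, y_) in enumerate(zip(AtWA, AtWy)):
                    try:
                        beta2[sl][t] = np.linalg.solve(M, y_)
                    except np.linalg.LinAlgError:
                        beta2[sl][t] = 0.0
                        ok[sl][t] = False
        lnS0[idx] = beta2[:, 0]
        d6[idx] = beta2[:, 1:7]
        c15[idx] = beta2[:, 7:]
        r = logY - beta2 @ A.T
        resid[idx] = np.linalg.norm(r, axis=1)
        valid[idx] &= ok & np.all(np.isfinite(beta2), axis=1)

    md = d6[:, :3].mean(axis=1)
    w15 = np.zeros_like(c15)
    pos = md > 1e-12
    w15[pos] = c15[pos] / md[pos, None] ** 2
    valid &= pos
    return DKITensors(
        lnS0=lnS0, d6=d6, w15=w15, residual_norm=resid, valid=valid,
        voxel_index=coords, shape=volume.data.shape[:3],
    )


# fixed deterministic 256-point spherical quadrature (16 Gauss-Legendre
# polar nodes x 16 azimuths) for the mean-kurtosis average
def _mk_design(n_polar: int = 16, n_azimuth: int = 16) -> tuple[np.ndarray, np.ndarray]:
    t, wt = np.polynomial.legendre.leggauss(n_polar)
    phi = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    ct = t[:, None]
    st = np.sqrt(1.0 - ct**2)
    g = np.stack(
        [
            (st * np.cos(phi)[None, :]).ravel(),
            (st * np.sin(phi)[None, :]).ravel(),
            np.broadcast_to(ct, (n_polar, n_azimuth)).ravel(),
        ],
        axis=1,
    )
    w = np.broadcast_to(wt[:, None] / (2.0 * n_azimuth), (n_polar, n_azimuth)).ravel()
    return g, w / w.sum()


def _perp_circle(e1: np.ndarray, n: int = 64) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, helper)
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    ang = np.pi * np.arange(n) / n
    return np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v


def dki_scalars(tensors: DKITensors) -> ScalarMaps:
    """Scalar maps from fitted tensors.

    MD = tr(D)/3; FA from the eigenvalues of D; MK is the average over a
    fixed 256-direction spherical quadrature of the apparent kurtosis
    K(g) = MD^2 W(g) / D(g)^2, with directional values clipped to the
    plausibility window [-3/7, 10] before averaging (voxels with > 25%
    clipped directions are flagged); AD/RD from sorted eigenvalues; AK/RK
    along / averaged perpendicular to the principal eigenvector.
    """
    V = tensors.n_voxels
    D = tensors.D
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    e1 = evecs[:, :, -1]  # principal
    MD = evals.mean(axis=1)
    AD = evals[:, 0]
    RD = evals[:, 1:].mean(axis=1)
    denom = (evals**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        FA = np.sqrt(1.5 * ((evals - MD[:, None]) ** 2).sum(axis=1) / np.where(denom > 0, denom, np.nan))

    gset, gw = _mk_design()
    Dg = d_quadratic(tensors.d6, gset)  # (V, M)
    Wg = w_quartic(tensors.w15, gset)
    mk_valid = tensors.valid & np.all(Dg > 0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (MD[:, None] ** 2) * Wg / Dg**2
    clipped = (K < KMIN) | (K > KMAX)
    clip_frac = clipped.mean(axis=1)
    K = np.clip(K, KMIN, KMAX)
    MK = np.where(mk_valid, K @ gw, np.nan)

    AK = np.full(V, np.nan)
    RK = np.full(V, np.nan)
    for v in range(V):
        if not mk_valid[v]:
            continue
        ax = e1[v][None, :]
        Dv = d_quadratic(tensors.d6[v], ax)[0]
        if Dv <= 0:
            continue
        AK[v] = MD[v] ** 2 * w_quartic(tensors.w15[v], ax)[0] / Dv**2
        circ = _perp_circle(e1[v])
        Dp = d_quadratic(tensors.d6[v], circ)
        if np.any(Dp <= 0):
            continue
        RK[v] = (MD[v] ** 2 * w_quartic(tensors.w15[v], circ) / Dp**2).mean()

    return ScalarMaps(
        MD=MD, FA=np.clip(FA, 0.0, 1.0), MK=MK, AD=AD, RD=RD, AK=AK, RK=RK,
        valid=mk_valid, clip_flagged=clip_frac > CLIP_FRACTION_FLAG,
    )


class DKIModel:
    """Voxel-wise DKI model for a masked 4-D volume.

    Parameters
    ----------
    volume : Volume4D
        Preprocessed diffusion data with mask.
    scheme : GradientScheme
        Must already be truncated to b <= 2500 s/mm^2 and span at least two
        nonzero shells with >= 22 volumes.

    ``fit()`` returns a :class:`DKIResults`.
    """

    def __init__(self, volume: Volume4D, scheme: GradientScheme):
        _check_scheme(scheme, volume.n_volumes)
        self.volume = volume
        self.scheme = scheme

    def fit(self) -> "DKIResults":
        tensors = fit_dki_wlls(self.volume, self.scheme)
        return DKIResults(self, tensors)


class DKIResults:
    """Fitted DKI tensors with scalar-map derivation and diagnostics."""

    def __init__(self, model: DKIModel, tensors: DKITensors):
        self.model = model
        self.tensors = tensors
        self._scalars: ScalarMaps | None = None

    @property
    def scalars(self) -> ScalarMaps:
        if self._scalars is None:
            self._scalars = dki_scalars(self.tensors)
        return self._scalars

    def predict(self) -> np.ndarray:
        """Model-predicted signals per masked voxel (V, N)."""
        A = design_matrix(self.model.scheme)
        md2 = self.tensors.md**2
        beta = np.concatenate(
            [self.tensors.lnS0[:, None], self.tensors.d6, self.tensors.w15 * md2[:, None]], axis=1
        )
        return np.exp(beta @ A.T)

    def to_map(self, values: np.ndarray) -> np.ndarray:
        """Scatter a flat per-voxel array back onto the 3-D grid (NaN fill)."""
        out = np.full(self.tensors.shape, np.nan)
        out[tuple(self.tensors.voxel_index.T)] = values
        return out

    def summary(self) -> str:
        sc = self.scalars
        ok = sc.valid
        lines = [
            "DKI weighted-LLS fit",
            f"  voxels fitted: {self.tensors.n_voxels} ({int(ok.sum())} valid)",
            f"  MD  (um^2/ms): {np.nanmean(sc.MD[ok]):.4f} +/- {np.nanstd(sc.MD[ok]):.4f}",
            f"  FA           : {np.nanmean(sc.FA[ok]):.4f} +/- {np.nanstd(sc.FA[ok]):.4f}",
            f"  MK           : {np.nanmean(sc.MK[ok]):.4f} +/- {np.nanstd(sc.MK[ok]):.4f}",
            f"  clip-flagged voxels: {int(sc.clip_flagged.sum())}",
        ]
        return "\n".join(lines)
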