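"""Watson distribution utilities.

The Watson distribution is the axially symmetric distribution on the unit
sphere with density proportional to exp(kappa * (n . mu)^2).  Its
normalization constant involves the confluent hypergeometric function
M(1/2, 3/2, kappa) = integral_0^1 exp(kappa t^2) dt, which we evaluate
through the Dawson function identity

    M(1/2, 3/2, k) = e^k * dawsn(sqrt k) / sqrt k      (k > 0),

numerically stable for every kappa of interest (no overflow, no
series/asymptotic switching).

Orientation moments used throughout the package:

    c2(kappa) = <cos^2 psi>  in [1/3, 1]
    c4(kappa) = <cos^4 psi>  in [1/5, 1]

where psi is the angle between an orientation sample and the Watson axis.
"""

from __future__ import annotations

import numpy as np
from scipy.special import dawsn

__all__ = ["watson_norm", "c2", "c4", "second_moment_tensor", "fourth_moment_tensor"]

# below this kappa the closed forms become 0/0; Taylor series take over
_SMALL_KAPPA = 1e-4


def watson_norm(kappa):
    """M(1/2,3/2,kappa) = integral_0^1 exp(kappa t^2) dt (Kummer function).

    The sphere-normalized Watson density is
    exp(kappa (n.mu)^2) / (4 pi M(1/2,3/2,kappa)).
    """
    kappa = np.asarray(kappa, dtype=float)
    out = np.ones_like(kappa)
    big = kappa > _SMALL_KAPPA
    neg = kappa < -_SMALL_KAPPA
    small = ~big & ~neg
    if np.any(big):
        k = kappa[big]
        s = np.sqrt(k)
        out[big] = np.exp(k) * dawsn(s) / s
    if np.any(neg):
        # M(1/2,3/2,-x^2) = sqrt(pi) erf(x) / (2x); kept for completeness
        from scipy.special import erf

        x = np.sqrt(-kappa[neg])
        out[neg] = np.sqrt(np.pi) * erf(x) / (2 * x)
    if np.any(small):
        k = kappa[small]
        out[small] = 1.0 + k / 3.0 + k**2 / 10.0 + k**3 / 42.0
    return out if out.ndim else float(out)


def c2(kappa):
    """Mean squared cosine <cos^2 psi> of the Watson distribution.

    Strictly increasing in kappa; c2(0) = 1/3, c2 -> 1 as kappa -> inf.
    """
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    big = kappa > _SMALL_KAPPA
    small = ~big
    if np.any(big):
        k = kappa[big]
        s = np.sqrt(k)
        # c2 = (e^k / M - 1) / (2k), with e^k / M = sqrt(k)/dawsn(sqrt k)
        out[big] = (s / dawsn(s) - 1.0) / (2.0 * k)
    if np.any(small):
        k = kappa[small]
        # Taylor: 1/3 + 4k/45 + 8k^2/945 - ...
        out[small] = 1.0 / 3.0 + 4.0 * k / 45.0 + 8.0 * k**2 / 945.0
    return out if out.ndim else float(out)


def c4(kappa):
    """Mean fourth-power cosine <cos^4 psi> of the Watson distribution."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    big = kappa > _SMALL_KAPPA
    small = ~big
    if np.any(big):
        k = kappa[big]
        s = np.sqrt(k)
        r = s / dawsn(s)  # e^k / M
        cc2 = (r - 1.0) / (2.0 * k)
        # integral_0^1 t^4 e^{kt^2} dt = (e^k - 3 N2)/(2k) with N2 = c2 * M
        out[big] = (r - 3.0 * cc2) / (2.0 * k)
    if np.any(small):
        k = kappa[small]
        # Taylor: 1/5 + 8k/105 + ...
        out[small] = 1.0 / 5.0 + 8.0 * k / 105.0 + 344.0 * k**2 / 33075.0
    return out if out.ndim else float(out)


def second_moment_tensor(mu: np.ndarray, kappa: float) -> np.ndarray:
    """<n n^T> for Watson orientations about axis ``mu``."""
    mu = np.asarray(mu, dtype=float)
    m2 = c2(kappa)
    eye = np.eye(3)
    return (1.0 - m2) / 2.0 * eye + (3.0 * m2 - 1.0) / 2.0 * np.outer(mu, mu)


def fourth_moment_tensor(mu: np.ndarray, kappa: float) -> np.ndarray:
    """<n_i n_j n_k n_l> (fully symmetric 3x3x3x3) for Watson orientations.

    For an axially symmetric distribution the fourth moment decomposes as

        alpha * S(delta delta) + beta * S(delta u u) + gamma * u u u u

    with S the sum over distinct index pairings, and

        alpha = (1 - 2 c2 + c4)/8
        beta  = (6 c2 - 5 c4 - 1)/8
        gamma = (3 - 30 c2 + 35 c4)/8.
    """
    mu = np.asarray(mu, dtype=float)
    m2, m4 = c2(kappa), c4(kappa)
    alpha = (1.0 - 2.0 * m2 + m4) / 8.0
    beta = (6.0 * m2 - 5.0 * m4 - 1.0) / 8.0
    gamma = (3.0 - 30.0 * m2 + 35.0 * m4) / 8.0

    d = np.eye(3)
    uu = np.outer(mu, mu)
    dd = (
        np.einsum("ij,kl->ijkl", d, d)
        + np.einsum("ik,jl->ijkl", d, d)
        + np.einsum("il,jk->ijkl", d, d)
    )
    du = (
        np.einsum("ij,kl->ijkl", d, uu)
        + np.einsum("ik,jl->ijkl", d, uu)
        + np.einsum("il,jk->ijkl", d, uu)
        + np.einsum("kl,ij->ijkl", d, uu)
        + np.einsum("jl,ik->ijkl", d, uu)
        + np.einsum("jk,il->ijkl", d, uu)
    )
    uuuu = np.einsum("i,j,k,l->ijkl", mu, mu, mu, mu)
    return alpha * dd + beta * du + gamma * uuuu
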