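"""Single-compartment signal kernels and Watson orientation dispersion.

Attenuations are unitless, normalised to 1 at b = 0.  Angles enter through
``cos_angle``, the cosine between the compartment symmetry axis and the
gradient direction.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import legvander
from scipy.optimize import brentq
from scipy.special import spherical_jn

from .protocol import GYROMAGNETIC_RATIO
from .tissue import ParameterError, PRIOR_RANGES

# ---------------------------------------------------------------------------
# Gaussian compartments

def stick_attenuation(b, cos_angle, D_a_in):
    """Zero-radius cylinder: exp(-b * D * cos^2 theta)."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(cos_angle, dtype=float)
    if np.any(np.abs(c) > 1 + 1e-12):
        raise ParameterError("|cos_angle| must be <= 1")
    return np.exp(-b * np.asarray(D_a_in, float) * c**2)


def zeppelin_attenuation(b, cos_angle, D_a_ex, D_r_ex):
    """Axially symmetric tensor: exp(-b [D_r + (D_a - D_r) cos^2 theta])."""
    D_a = np.asarray(D_a_ex, float)
    D_r = np.asarray(D_r_ex, float)
    if np.any(D_a <= 0) or np.any(D_r <= 0):
        raise ParameterError("zeppelin diffusivities must be positive")
    c = np.asarray(cos_angle, dtype=float)
    if np.any(np.abs(c) > 1 + 1e-12):
        raise ParameterError("|cos_angle| must be <= 1")
    b = np.asarray(b, dtype=float)
    return np.exp(-b * (D_r + (D_a - D_r) * c**2))


def ball_attenuation(b, D_ball):
    """Free isotropic diffusion: exp(-b * D)."""
    return np.exp(-np.asarray(b, float) * np.asarray(D_ball, float))


# ---------------------------------------------------------------------------
# Restricted sphere under the Gaussian phase distribution approximation

@lru_cache(maxsize=8)
def bessel_prime_roots(n_roots: int = 30) -> np.ndarray:
    """First ``n_roots`` positive roots of d/dx [ j_1(x) ] (j_1: spherical
    Bessel).  The first is ~2.0816.  Roots are bracketed by scanning; a
    failure to bracket raises."""
    f = lambda x: spherical_jn(1, x, derivative=True)
    roots = []
    x = 1.0
    step = 0.05
    while len(roots) < n_roots:
        x2 = x + step
        if x2 > 500.0:
            raise RuntimeError("failed to bracket requested Bessel roots")
        if f(x) * f(x2) < 0:
            roots.append(brentq(f, x, x2, xtol=1e-12))
        x = x2
    return np.asarray(roots)


def sphere_gpd_attenuation(
    G, delta_small, delta_big, D_sph, R_sph,
    gamma: float = GYROMAGNETIC_RATIO, n_roots: int = 30,
):
    """PGSE signal for diffusion restricted in an impermeable sphere (GPD).

    Uses the classic root expansion over alpha_m = mu_m / R with mu_m the
    positive roots of j_1'(x):

        ln E = -2 (gamma G)^2 * sum_m
               [2 a d - 2 + 2 e^{-a d} + 2 e^{-a D} - e^{-a (D-d)} - e^{-a (D+d)}]
               / (D_s^2 alpha_m^6 (alpha_m^2 R^2 - 2))

    with a = alpha_m^2 D_s, d = delta, D = Delta.  G in T/m, timings in ms,
    D_sph in um^2/ms, R_sph in um.
    """
    D = np.asarray(D_sph, dtype=float)
    R = np.asarray(R_sph, dtype=float)
    if np.any(D <= 0):
        raise ParameterError("D_sph must be positive")
    if np.any(R < 0):
        raise ParameterError("R_sph must be non-negative")
    G = np.asarray(G, dtype=float)
    gamma_g = gamma * 1e-3 * G * 1e-6  # rad / (ms um)

    mu = bessel_prime_roots(n_roots)  # (k,)
    Rb = R[..., None]
    Db = D[..., None]
    # avoid division by zero in the dot limit R -> 0; masked below
    Rsafe = np.where(Rb > 0, Rb, 1.0)
    alpha2 = (mu / Rsafe) ** 2  # (..., k)
    a = alpha2 * Db  # 1/ms
    d, Dt = delta_small, delta_big
    num = (
        2 * a * d - 2
        + 2 * np.exp(-a * d) + 2 * np.exp(-a * Dt)
        - np.exp(-a * (Dt - d)) - np.exp(-a * (Dt + d))
    )
    den = Db**2 * alpha2**3 * (mu**2 - 2.0)
    series = np.sum(num / den, axis=-1)
    ln_e = -2.0 * gamma_g**2 * series
    out = np.exp(ln_e)
    return np.where(R > 0, out, 1.0)


# ---------------------------------------------------------------------------
# Watson dispersion

def odi_to_kappa(odi):
    """ODI = (2/pi) arctan(1/kappa)  =>  kappa = 1/tan(pi/2 * ODI)."""
    odi = np.asarray(odi, dtype=float)
    return 1.0 / np.tan(np.pi / 2.0 * odi)


def kappa_to_odi(kappa):
    return (2.0 / np.pi) * np.arctan(1.0 / np.asarray(kappa, dtype=float))


def _check_odi(odi):
    lo, hi = PRIOR_RANGES["ODI"]
    if np.any(np.asarray(odi) < lo - 1e-12) or np.any(np.asarray(odi) > hi + 1e-12):
        raise ParameterError(f"ODI must lie in [{lo}, {hi}]")


# Legendre-series (Funk-Hecke) machinery.  Both the Watson density
# exp(kappa t^2) and the stick/zeppelin kernels exp(-bD t^2) are even
# Gaussians in t = cos(theta), so one primitive computes the Legendre
# projections of exp(u t^2):
#
#     g_l(u) = int_{-1}^{1} e^{u t^2} P_l(t) dt   (even l only)
#
# and the convolved signal of kernel K with a normalised Watson density is
#
#     S(c) = sum_{even l} (2l+1)/2 * g_l(u_K) * g_l(kappa)/g_0(kappa) * P_l(c)

LMAX_RESPONSE = 60  # truncation; enough for kappa ~ 64 (ODI = 0.01)
_N_QUAD = 128


@lru_cache(maxsize=4)
def _gauss_nodes(lmax: int, n_quad: int):
    x, w = np.polynomial.legendre.leggauss(n_quad)
    t = 0.5 * (x + 1.0)  # map to [0, 1]; even integrand doubles
    w = 0.5 * w
    P = legvander(t, lmax)[:, ::2]  # even degrees 0, 2, ..., lmax
    return t, w, P


def legendre_gauss_coeffs(u, lmax: int = LMAX_RESPONSE) -> np.ndarray:
    """g_l(u) for even l = 0..lmax; ``u`` may be an array (batched)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    t, w, P = _gauss_nodes(lmax, _N_QUAD)
    E = np.exp(np.multiply.outer(u, t * t))  # (..., n_quad)
    return 2.0 * E @ (w[:, None] * P)  # (..., n_even)


def watson_response(odi, lmax: int = LMAX_RESPONSE) -> np.ndarray:
    """Normalised Legendre response of the Watson density,
    r_l = g_l(kappa)/g_0(kappa); r_0 = 1, r_l -> 1 as ODI -> 0."""
    _check_odi(odi)
    kappa = odi_to_kappa(odi)
    g = legendre_gauss_coeffs(kappa, lmax)
    return g / g[..., :1]


def legendre_polynomials(x, lmax: int = LMAX_RESPONSE) -> np.ndarray:
    """P_l(x) for even l = 0..lmax, stacked on the last axis."""
    x = np.asarray(x, dtype=float)
    return legvander(x.ravel(), lmax)[:, ::2].reshape(x.shape + (-1,))


def watson_convolve(
    kernel, odi, fibre_dir, directions,
    n_theta: int = 64, n_phi: int = 48,
):
    """Average ``kernel`` over fibre orientations drawn from a Watson density.

    ``kernel(cos_angle)`` maps the cosine between a fibre orientation and a
    gradient direction to an attenuation.  The integral over the sphere uses
    a product quadrature about ``fibre_dir``: Gauss-Legendre nodes in
    cos(theta) on [0, 1] (doubled to the antipodal hemisphere by evenness)
    times a uniform azimuth grid -- an antipodally symmetric point set of
    2 * n_theta * n_phi >= 300 points.

    Returns one attenuation per row of ``directions``.
    """
    _check_odi(odi)
    kappa = float(odi_to_kappa(odi))
    mu = np.asarray(fibre_dir, dtype=float)
    mu = mu / np.linalg.norm(mu)
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))

    x, w = np.polynomial.legendre.leggauss(n_theta)
    t = 0.5 * (x + 1.0)
    wt = 0.5 * w * np.exp(kappa * (t * t - 1.0))  # exp offset for stability
    phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)

    # orthonormal frame about mu (any perpendicular pair; the phi average
    # removes the dependence on the choice)
    a = np.array([1.0, 0.0, 0.0])
    if abs(mu @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)

    st = np.sqrt(np.maximum(0.0, 1.0 - t * t))
    # nodes (n_theta, n_phi, 3)
    nodes = (
        t[:, None, None] * mu
        + st[:, None, None] * np.cos(phi)[None, :, None] * e1
        + st[:, None, None] * np.sin(phi)[None, :, None] * e2
    )
    weights = np.repeat(wt[:, None], n_phi, axis=1)
    weights = weights / weights.sum()

    cosang = np.clip(nodes.reshape(-1, 3) @ dirs.T, -1.0, 1.0)
    vals = kernel(cosang)  # (n_nodes, n_dirs)
    return weights.reshape(-1) @ vals
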