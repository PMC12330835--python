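"""Forward signal model: noise-free dMRI attenuation of the extended
white-matter standard model for a given acquisition protocol.

The per-voxel signal on a shell with b-value b and direction g is

    S(g) = f_in  * (stick    (x) Watson)(mu . g)
         + f_ex  * (zeppelin (x) Watson)(mu . g)
         + f_sph * E_sphere(b)
         + f_dot * 1
         + f_ball * exp(-b D_ball)

with (x) the spherical convolution with a Watson orientation density of mean
axis mu.  b = 0 volumes carry attenuation exactly 1.  The convolution is
evaluated through the Legendre (Funk-Hecke) series, which makes the signal an
exact function of mu . g and therefore exactly rotation equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import compartments as cp
from .protocol import AcquisitionProtocol
from .tissue import TissueParams, params_to_array


@dataclass(frozen=True)
class RawSignal:
    """Per-volume attenuations (b=0 normalised to 1) plus their protocol."""

    values: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape[-1] != self.protocol.n_volumes:
            raise ValueError("signal length does not match protocol volumes")
        object.__setattr__(self, "values", vals)


def _shell_anisotropic_coeffs(batch: dict, b: float, lmax: int) -> np.ndarray:
    """Legendre coefficients (even l) of f_in*stick + f_ex*zeppelin, each
    convolved with the voxel's Watson density.  Shape (n, n_even)."""
    g_stick = cp.legendre_gauss_coeffs(-b * batch["D_a_in"], lmax)
    g_zep = cp.legendre_gauss_coeffs(-b * (batch["D_a_ex"] - batch["D_r_ex"]), lmax)
    zep_scale = np.exp(-b * batch["D_r_ex"])
    watson = cp.watson_response(batch["ODI"], lmax)
    ell = np.arange(0, lmax + 1, 2)
    pref = (2 * ell + 1) / 2.0
    return pref * watson * (
        batch["f_in"][:, None] * g_stick
        + (batch["f_ex"] * zep_scale)[:, None] * g_zep
    )


def batch_signals(
    batch: dict, protocol: AcquisitionProtocol, lmax: int = cp.LMAX_RESPONSE
) -> np.ndarray:
    """Noise-free signals for a batch of parameter sets.

    ``batch`` is a dict of arrays as produced by
    :func:`cbench.tissue.sample_params_batch`; returns (n, n_volumes).
    """
    n = batch["f_in"].shape[0]
    out = np.empty((n, protocol.n_volumes))
    out[:, : protocol.n_b0] = 1.0

    grads = protocol.gradient_amplitudes()
    col = protocol.n_b0
    for shell, G in zip(protocol.shells, grads):
        b = shell.b_value
        iso = (
            batch["f_dot"]
            + batch["f_ball"] * cp.ball_attenuation(b, batch["D_ball"])
            + batch["f_sph"]
            * cp.sphere_gpd_attenuation(
                G, protocol.delta_small, protocol.delta_big,
                batch["D_sph"], batch["R_sph"], protocol.gyromagnetic_ratio,
            )
        )
        coeffs = _shell_anisotropic_coeffs(batch, b, lmax)  # (n, L)
        cosang = batch["fibre_dir"] @ shell.directions.T  # (n, ndir)
        P = cp.legendre_polynomials(cosang, lmax)  # (n, ndir, L)
        aniso = np.einsum("nl,ndl->nd", coeffs, P)
        out[:, col : col + shell.n_directions] = aniso + iso[:, None]
        col += shell.n_directions
    return out


def model_signal(params: TissueParams, protocol: AcquisitionProtocol) -> RawSignal:
    """Noise-free signal of one voxel (see module docstring)."""
    params.validate()
    vals = batch_signals(params_to_array(params), protocol)[0]
    return RawSignal(values=vals, protocol=protocol)
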