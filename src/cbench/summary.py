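"""Rotationally invariant summary measures of the dMRI signal.

Per shell two scalars are kept: the l = 0 measure (the directional mean
signal) and the l = 2 measure (the root-mean-square of the five degree-2
real spherical-harmonic coefficients), so two-shell data yield a length-4
summary vector per voxel.

The spherical-harmonic fit is *mean-anchored*: the l = 0 coefficient is set
from the directional mean and the l >= 2 coefficients are fitted by least
squares to the demeaned signal.  This makes the l0 measure equal the
directional mean exactly on any input, and leaves the l2 measure exactly
unchanged by an isotropic offset.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

from .protocol import AcquisitionProtocol, volume_order

Y00 = 1.0 / (2.0 * np.sqrt(np.pi))


class InsufficientDirectionsError(ValueError):
    """Fewer directions than spherical-harmonic coefficients."""


def _even_degrees(lmax: int) -> list[int]:
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be an even non-negative integer")
    return list(range(0, lmax + 1, 2))


def n_coefficients(lmax: int) -> int:
    return sum(2 * l + 1 for l in _even_degrees(lmax))


def real_sh_basis(directions: np.ndarray, lmax: int = 2) -> np.ndarray:
    """Real, antipodally symmetric SH design matrix (n_dirs, n_coeffs).

    Column order: (0,0), (2,-2), (2,-1), (2,0), (2,1), (2,2), (4,-4), ...
    Real basis from the complex one: m = 0 -> Y_l0; m > 0 ->
    sqrt(2) (-1)^m Re(Y_lm); m < 0 -> sqrt(2) (-1)^m Im(Y_l|m|).
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    for l in _even_degrees(lmax):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.stack(cols, axis=1)


def fit_spherical_harmonics(
    signals: np.ndarray, directions: np.ndarray, lmax: int = 2
) -> np.ndarray:
    """Mean-anchored real SH coefficients of per-direction signals.

    ``signals`` may be (n_dirs,) or (n_vox, n_dirs); returns matching
    (..., n_coeffs).  Raises :class:`InsufficientDirectionsError` when the
    direction count is below the coefficient count.
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    ncoef = n_coefficients(lmax)
    if dirs.shape[0] < ncoef:
        raise InsufficientDirectionsError(
            f"{dirs.shape[0]} directions < {ncoef} coefficients for lmax={lmax}"
        )
    sig = np.asarray(signals, dtype=float)
    squeeze = sig.ndim == 1
    sig = np.atleast_2d(sig)
    if sig.shape[1] != dirs.shape[0]:
        raise ValueError("signals and directions length mismatch")

    mean = sig.mean(axis=1)
    coeffs = np.zeros((sig.shape[0], ncoef))
    coeffs[:, 0] = mean / Y00
    if lmax >= 2:
        basis = real_sh_basis(dirs, lmax)[:, 1:]
        resid = sig - mean[:, None]
        sol, *_ = np.linalg.lstsq(basis, resid.T, rcond=None)
        coeffs[:, 1:] = sol.T
    return coeffs[0] if squeeze else coeffs


def summarise(coeffs: np.ndarray, lmax: int = 2, l2_sqrt: bool = True) -> np.ndarray:
    """Rotation-invariant measures from one shell's SH coefficients.

    Returns [l0, l2] where l0 = c00 * Y00 (the mean signal) and
    l2 = sqrt(mean(c_2m^2)) (or the mean of squares with ``l2_sqrt=False``;
    the square root makes the measure scale linearly with signal amplitude).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] < n_coefficients(2) or lmax < 2:
        raise ValueError("summary measures need degrees 0 and 2")
    l0 = coeffs[..., 0] * Y00
    sq = np.mean(coeffs[..., 1:6] ** 2, axis=-1)
    l2 = np.sqrt(sq) if l2_sqrt else sq
    return np.stack([l0, l2], axis=-1)


def measure_names(protocol: AcquisitionProtocol) -> list[str]:
    names = []
    for sh in protocol.shells:
        tag = f"b{sh.b_value:g}"
        names += [f"{tag}_l0", f"{tag}_l2"]
    return names


def summary_vectors(
    signals: np.ndarray, protocol: AcquisitionProtocol,
    lmax: int = 2, l2_sqrt: bool = True,
) -> np.ndarray:
    """Per-voxel summary vectors from per-volume signals.

    ``signals``: (..., n_volumes) raw attenuations in protocol volume order.
    Returns (..., 2 * n_shells): [shell1_l0, shell1_l2, shell2_l0, ...].
    """
    sig = np.asarray(signals, dtype=float)
    squeeze = sig.ndim == 1
    sig = np.atleast_2d(sig)
    order = volume_order(protocol)
    out = np.empty((sig.shape[0], 2 * len(protocol.shells)))
    for k, shell in enumerate(protocol.shells):
        block = sig[:, order[f"shell{k}"]]
        coeffs = fit_spherical_harmonics(block, shell.directions, lmax)
        out[:, 2 * k : 2 * k + 2] = summarise(coeffs, lmax, l2_sqrt)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# File-level interfaces (NIfTI volumes + TSV tables)

def summaries_from_nifti(
    image_path, protocol: AcquisitionProtocol, mask_path=None, lmax: int = 2
):
    """Summary-measure table from a 4D NIfTI in protocol volume order.

    Returns ``(table, voxel_indices)`` where ``table`` is a pandas DataFrame
    with one row per voxel inside the (optional) mask and one column per
    summary measure, and ``voxel_indices`` the (n, 3) voxel coordinates.
    """
    import nibabel as nib
    import pandas as pd

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != protocol.n_volumes:
        raise ValueError("image volume count does not match protocol")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    vox = np.argwhere(mask)
    sig = data[mask]
    b0 = sig[:, volume_order(protocol)["b0"]]
    if b0.shape[1]:
        scale = np.clip(b0.mean(axis=1), 1e-12, None)
        sig = sig / scale[:, None]
    table = pd.DataFrame(summary_vectors(sig, protocol, lmax),
                         columns=measure_names(protocol))
    return table, vox


def write_summary_nifti(table, voxel_indices, shape3d, affine, out_path):
    """Write a summary table back to a 4D NIfTI (one volume per measure)."""
    import nibabel as nib

    vol = np.zeros(tuple(shape3d) + (table.shape[1],))
    idx = tuple(np.asarray(voxel_indices).T)
    vol[idx] = np.asarray(table)
    nib.save(nib.Nifti1Image(vol, affine), str(out_path))


def write_summary_tsv(table, voxel_indices, out_path):
    """Summary table keyed by voxel index, as TSV."""
    import pandas as pd

    vox = np.asarray(voxel_indices)
    df = pd.DataFrame(vox, columns=["i", "j", "k"]).join(table.reset_index(drop=True))
    df.to_csv(out_path, sep="\t", index=False)
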