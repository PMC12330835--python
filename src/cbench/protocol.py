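"""Acquisition protocols for pulsed-gradient spin-echo (PGSE) diffusion MRI.

Internal unit system: lengths in um, times in ms, b-values in ms/um^2,
diffusivities in um^2/ms, gradient amplitude in T/m, gyromagnetic ratio in
rad s^-1 T^-1.  With these units b*D is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GYROMAGNETIC_RATIO = 2.675e8
"""Proton gyromagnetic ratio in rad s^-1 T^-1."""

# minimum directions to fit all even-degree real SH coefficients at lmax=2
_MIN_DIRS_LMAX2 = 6


class ProtocolError(ValueError):
    """Invalid acquisition protocol (timing, b-value or direction set)."""


@dataclass(frozen=True)
class Shell:
    """One diffusion-weighted shell: a b-value and its gradient directions."""

    b_value: float  # ms/um^2
    directions: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if dirs.shape[1] != 3:
            raise ProtocolError("directions must be (n, 3)")
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ProtocolError("shell directions must have unit norm (1e-6)")
        if self.b_value < 0:
            raise ProtocolError("b-value must be non-negative")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """A multi-shell PGSE protocol with shared pulse timing.

    Parameters
    ----------
    shells:
        Diffusion-weighted shells (b > 0).
    n_b0:
        Number of unweighted (b = 0) volumes.
    delta_small:
        Gradient pulse duration delta (ms).
    delta_big:
        Gradient pulse separation Delta (ms).
    gyromagnetic_ratio:
        In rad s^-1 T^-1.
    """

    shells: tuple[Shell, ...]
    n_b0: int = 0
    delta_small: float = 14.0
    delta_big: float = 24.0
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO

    def __post_init__(self):
        if not (0 < self.delta_small <= self.delta_big):
            raise ProtocolError("require 0 < delta <= Delta")
        if self.n_b0 < 0:
            raise ProtocolError("n_b0 must be >= 0")
        shells = tuple(self.shells)
        for sh in shells:
            if sh.n_directions < _MIN_DIRS_LMAX2:
                raise ProtocolError(
                    f"shell b={sh.b_value}: {sh.n_directions} directions < "
                    f"{_MIN_DIRS_LMAX2} needed for lmax=2"
                )
        object.__setattr__(self, "shells", shells)

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + sum(s.n_directions for s in self.shells)

    @property
    def b_values(self) -> np.ndarray:
        """Per-volume b-values; b=0 volumes first."""
        return np.concatenate(
            [np.zeros(self.n_b0)]
            + [np.full(s.n_directions, s.b_value) for s in self.shells]
        )

    @property
    def directions(self) -> np.ndarray:
        """Per-volume gradient directions; b=0 volumes carry zero vectors."""
        return np.concatenate(
            [np.zeros((self.n_b0, 3))] + [s.directions for s in self.shells]
        )

    def gradient_amplitudes(self) -> np.ndarray:
        """Per-shell gradient amplitudes (T/m)."""
        return np.array(
            [
                gradient_from_b(
                    s.b_value, self.delta_small, self.delta_big,
                    self.gyromagnetic_ratio,
                )
                for s in self.shells
            ]
        )


def gradient_from_b(
    b: float,
    delta_small: float,
    delta_big: float,
    gamma: float = GYROMAGNETIC_RATIO,
) -> float:
    """Invert the PGSE relation b = gamma^2 G^2 delta^2 (Delta - delta/3).

    Parameters are b in ms/um^2, timings in ms, gamma in rad s^-1 T^-1.
    Returns the gradient amplitude G in T/m.
    """
    if not (0 < delta_small <= delta_big):
        raise ProtocolError("require 0 < delta <= Delta")
    if b < 0:
        raise ProtocolError("b-value must be non-negative")
    gamma_ms = gamma * 1e-3  # rad ms^-1 T^-1
    # G in T/um so that (gamma_ms * G * delta)^2 * (Delta - delta/3) = b
    g_per_um = np.sqrt(b / (delta_big - delta_small / 3.0)) / (gamma_ms * delta_small)
    return float(g_per_um * 1e6)  # T/m


def fibonacci_sphere(n: int, hemisphere: bool = True, seed: int | None = None) -> np.ndarray:
    """Quasi-uniform unit vectors from a Fibonacci spiral.

    With ``hemisphere=True`` points are kept on z >= 0, mimicking the
    antipodal ambiguity of diffusion gradients.
    """
    i = np.arange(n, dtype=float) + 0.5
    if hemisphere:
        z = i / n  # cos(theta) in (0, 1)
    else:
        z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if seed is not None:
        # random overall rotation so repeated shells are not identical
        rng = np.random.default_rng(seed)
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        pts = pts @ q.T
    return pts


def two_shell_protocol(
    b_values: tuple[float, float] = (7.0, 10.0),
    n_directions: int = 90,
    n_b0: int = 18,
    delta_small: float = 14.0,
    delta_big: float = 24.0,
    seed: int = 0,
) -> AcquisitionProtocol:
    """The ex-vivo style two-shell protocol used throughout this package.

    Defaults mirror the acquisition the package emulates: b = 7 and
    10 ms/um^2, 90 directions per shell, 18 unweighted volumes, Delta = 24 ms,
    delta = 14 ms.
    """
    shells = tuple(
        Shell(b, fibonacci_sphere(n_directions, seed=seed + k))
        for k, b in enumerate(b_values)
    )
    return AcquisitionProtocol(
        shells=shells, n_b0=n_b0, delta_small=delta_small, delta_big=delta_big
    )


def read_bvals_bvecs(
    bval_path, bvec_path, delta_small: float, delta_big: float,
    b0_threshold: float = 0.05,
) -> AcquisitionProtocol:
    """Build a protocol from FSL-style bval/bvec text files.

    b-values whose magnitudes exceed 100 are assumed to be in s/mm^2 and are
    divided by 1000 to give ms/um^2.  Timing comes from the caller (JSON
    config upstream).  Volumes with b below ``b0_threshold`` count as b=0.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ProtocolError("bval/bvec volume counts differ")
    if np.max(np.abs(bvals)) > 100:
        bvals = bvals / 1000.0
    is_b0 = bvals <= b0_threshold
    shells = []
    for b in np.unique(np.round(bvals[~is_b0], 6)):
        sel = ~is_b0 & (np.round(bvals, 6) == b)
        dirs = bvecs[sel]
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        shells.append(Shell(float(b), dirs))
    return AcquisitionProtocol(
        shells=tuple(shells), n_b0=int(is_b0.sum()),
        delta_small=delta_small, delta_big=delta_big,
    )


def volume_order(protocol: AcquisitionProtocol) -> dict:
    """Slices of the per-volume axis: 'b0' plus one slice per shell."""
    out = {"b0": slice(0, protocol.n_b0)}
    start = protocol.n_b0
    for k, sh in enumerate(protocol.shells):
        out[f"shell{k}"] = slice(start, start + sh.n_directions)
        start += sh.n_directions
    return out
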