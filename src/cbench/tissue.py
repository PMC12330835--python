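"""Tissue parameters of the extended white-matter standard model.

The model pools signal from five compartments: dispersed sticks
(intra-axonal), dispersed zeppelins (extra-axonal), a GPD sphere
(intra-soma), a dot (stationary water) and optionally a ball (free water,
used when modelling numerical-substrate data).  Signal fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """Tissue parameters outside their physical / prior bounds."""


#: Prior ranges for every model parameter (uniform). Units: fractions and ODI
#: are unitless, diffusivities um^2/ms, radius um.
PRIOR_RANGES: dict[str, tuple[float, float]] = {
    "f_in": (0.0, 1.0),
    "f_ex": (0.0, 1.0),
    "f_sph": (0.0, 0.10),
    "f_dot": (0.0, 0.10),
    "f_ball": (0.0, 0.10),
    "ODI": (0.01, 0.50),
    "D_a_in": (0.50, 1.5),
    "D_a_ex": (0.50, 1.5),
    "D_r_ex": (0.50, 1.5),
    "D_sph": (0.50, 1.5),
    "D_ball": (0.50, 2.5),
    "R_sph": (0.01, 10.0),
}

FRACTION_NAMES = ("f_in", "f_ex", "f_sph", "f_dot", "f_ball")

_FRACTION_TOL = 1e-9


@dataclass
class TissueParams:
    """One voxel's biophysical parameter vector.

    ``fibre_dir`` is the mean fibre orientation (unit 3-vector); all other
    fields are scalars with the units of :data:`PRIOR_RANGES`.
    """

    f_in: float = 0.55
    f_ex: float = 0.35
    f_sph: float = 0.04
    f_dot: float = 0.03
    f_ball: float = 0.03
    ODI: float = 0.1
    D_a_in: float = 1.0
    D_a_ex: float = 1.0
    D_r_ex: float = 0.8
    D_sph: float = 1.0
    D_ball: float = 1.5
    R_sph: float = 5.0
    fibre_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.fibre_dir = np.asarray(self.fibre_dir, dtype=float)
        n = np.linalg.norm(self.fibre_dir)
        if not np.isfinite(n) or n == 0:
            raise ParameterError("fibre_dir must be a nonzero 3-vector")
        self.fibre_dir = self.fibre_dir / n

    def validate(self, check_ranges: bool = False) -> "TissueParams":
        fr = np.array([getattr(self, f) for f in FRACTION_NAMES])
        if np.any(fr < -_FRACTION_TOL) or np.any(fr > 1 + _FRACTION_TOL):
            raise ParameterError("signal fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > _FRACTION_TOL:
            raise ParameterError(
                f"signal fractions must sum to 1 (got {fr.sum()!r})"
            )
        for name in ("D_a_in", "D_a_ex", "D_r_ex", "D_sph", "D_ball"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.R_sph < 0:
            raise ParameterError("R_sph must be non-negative")
        if check_ranges:
            for name, (lo, hi) in PRIOR_RANGES.items():
                v = getattr(self, name)
                if not (lo - _FRACTION_TOL <= v <= hi + _FRACTION_TOL):
                    raise ParameterError(f"{name}={v} outside prior range [{lo}, {hi}]")
        return self

    def to_dict(self) -> dict:
        out = {f: float(getattr(self, f)) for f in PRIOR_RANGES}
        out["fibre_dir"] = self.fibre_dir.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TissueParams":
        return cls(**d)


def scalar_names() -> list[str]:
    """Names of the scalar model parameters, in canonical order."""
    return list(PRIOR_RANGES)


@dataclass(frozen=True)
class PriorSet:
    """Uniform prior ranges per parameter, defaulting to the model's table.

    ``with_ball`` selects the simulation variant (ball compartment included)
    versus the ex-vivo variant (no free-water ball).
    """

    ranges: dict = field(default_factory=lambda: dict(PRIOR_RANGES))
    with_ball: bool = True

    def range(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    def width(self, name: str) -> float:
        lo, hi = self.ranges[name]
        return hi - lo

    @property
    def fraction_names(self) -> tuple[str, ...]:
        if self.with_ball:
            return FRACTION_NAMES
        return tuple(f for f in FRACTION_NAMES if f != "f_ball")


def params_to_array(params: TissueParams) -> dict[str, np.ndarray]:
    """Promote a single parameter set to a length-1 batch."""
    batch = {f: np.array([float(getattr(params, f))]) for f in PRIOR_RANGES}
    batch["fibre_dir"] = params.fibre_dir[None, :]
    return batch


def sample_params_batch(
    priors: PriorSet, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` parameter sets from the priors as a dict of arrays.

    Fractions: f_sph, f_dot (and f_ball in the simulation variant) are drawn
    uniformly from their ranges, f_in uniformly on [0, 1], and f_ex takes the
    remainder; draws with a negative remainder are resampled.  Fibre
    orientations are uniform on the sphere.
    """
    out = {k: np.empty(n) for k in PRIOR_RANGES}
    if not priors.with_ball:
        out["f_ball"][:] = 0.0

    small = [f for f in ("f_sph", "f_dot", "f_ball") if priors.with_ball or f != "f_ball"]
    filled = 0
    attempts = 0
    while filled < n:
        m = max(n - filled, 16)
        draw = {f: rng.uniform(*priors.range(f), size=m) for f in small}
        f_in = rng.uniform(*priors.range("f_in"), size=m)
        rest = sum(draw.values())
        f_ex = 1.0 - f_in - rest
        lo_ex, hi_ex = priors.range("f_ex")
        ok = (f_ex >= lo_ex) & (f_ex <= hi_ex)
        k = min(int(ok.sum()), n - filled)
        sl = slice(filled, filled + k)
        idx = np.flatnonzero(ok)[:k]
        for f in small:
            out[f][sl] = draw[f][idx]
        out["f_in"][sl] = f_in[idx]
        out["f_ex"][sl] = f_ex[idx]
        filled += k
        attempts += 1
        if attempts > 10_000:
            raise ParameterError("fraction sampling failed: empty feasible region")

    for name in ("ODI", "D_a_in", "D_a_ex", "D_r_ex", "D_sph", "D_ball", "R_sph"):
        out[name] = rng.uniform(*priors.range(name), size=n)
    if not priors.with_ball:
        out["f_ball"] = np.zeros(n)

    v = rng.standard_normal((n, 3))
    out["fibre_dir"] = v / np.linalg.norm(v, axis=1, keepdims=True)
    return out


def sample_params(priors: PriorSet, rng_seed: int) -> TissueParams:
    """Draw one parameter set (reproducible for a fixed seed)."""
    batch = sample_params_batch(priors, 1, np.random.default_rng(rng_seed))
    kwargs = {k: float(batch[k][0]) for k in PRIOR_RANGES}
    return TissueParams(fibre_dir=batch["fibre_dir"][0], **kwargs).validate()
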