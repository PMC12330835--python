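"""Forward-model voxel cohorts with covariate-linked parameter trends.

A cohort emulates a voxel population in which exactly one candidate change
(a :class:`~cbench.changes.ChangeSpec`) varies linearly with a continuous
covariate, on top of voxel-to-voxel baseline variability drawn from the
priors, with Rician noise at a stated SNR (relative to the b=0 signal).
It stands in for the ex-vivo voxel table when testing the GLM + inference
stages end to end with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .changes import ChangeSpec, apply_change, _feasible
from .forward import batch_signals
from .protocol import AcquisitionProtocol, volume_order
from .summary import measure_names, summary_vectors
from .tissue import PriorSet, sample_params_batch


@dataclass
class CohortSpec:
    """Defines a synthetic voxel cohort.

    One baseline parameter set is drawn from the priors per cohort; voxels
    scatter around it with a small uniform parameter jitter (fraction
    ``jitter`` of each prior width) and random fibre orientations, mimicking
    a homogeneous tissue region rather than the full prior volume.  With
    ``jitter = 0`` all voxels share the exact baseline (and orientation).

    ``slope`` is the total change |Dnu| across the covariate span [0, 1]
    along ``trend`` (applied centred, so voxels at x = 0.5 sit at their
    baseline).  ``snr`` is the Rician SNR at b = 0; ``np.inf`` disables
    noise.  Default SNR 150 matches the simulation regime this cohort
    emulates.
    """

    n_voxels: int = 2000
    trend: ChangeSpec | None = None
    slope: float | None = None  # default: 5% of the touched prior width
    snr: float = 150.0
    jitter: float = 0.02
    priors: PriorSet = field(default_factory=PriorSet)
    #: fixed centre values; by default the soma radius is pinned at the
    #: glia-representative 5 um rather than drawn from its (very wide)
    #: prior -- a cohort whose "soma" have sub-micron radii is not a soma
    #: study, the sphere is then exactly degenerate with the dot
    centre_overrides: dict = field(default_factory=lambda: {"R_sph": 5.0})
    covariate_name: str = "x"
    rng_seed: int = 0

    def resolved_slope(self) -> float:
        if self.slope is not None:
            return self.slope
        if self.trend is None:
            return 0.0
        w = max(self.priors.width(p) for p in self.trend.signs)
        return 0.05 * w


def add_rician_noise(signals: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex-Gaussian-corrupted signal, sigma = 1/SNR."""
    if not np.isfinite(snr):
        return np.asarray(signals, dtype=float)
    sig = 1.0 / snr
    s = np.asarray(signals, dtype=float)
    re = s + rng.normal(0.0, sig, s.shape)
    im = rng.normal(0.0, sig, s.shape)
    return np.hypot(re, im)


def _cohort_batch(spec: CohortSpec, rng: np.random.Generator):
    """Per-voxel parameter batch + covariate values for a cohort."""
    slope = spec.resolved_slope()
    priors = spec.priors
    n = spec.n_voxels

    centre = sample_params_batch(priors, 1, rng)
    for p, v in (spec.centre_overrides or {}).items():
        centre[p][0] = v
    scalars = [k for k in centre if k != "fibre_dir"]
    fractions = ("f_in", "f_ex", "f_sph", "f_dot", "f_ball")
    # pull the centre far enough from the bounds that jitter + trend fit
    for p in scalars:
        lo, hi = priors.range(p)
        margin = 0.0 if p in fractions else spec.jitter * priors.width(p)
        if spec.trend is not None and p in spec.trend.signs:
            margin += slope / 2.0
        if lo + margin > hi - margin:
            raise ValueError(f"trend/jitter span exceeds the {p} prior range")
        centre[p][0] = np.clip(centre[p][0], lo + margin, hi - margin)
    # restore sum-to-one after clipping by rescaling the untouched fractions
    touched = set(spec.trend.signs) if spec.trend is not None else set()
    ft = [f for f in fractions if f in touched]
    fu = [f for f in fractions if f not in touched]
    rest = 1.0 - sum(centre[f][0] for f in ft)
    tot_u = sum(centre[f][0] for f in fu)
    if tot_u > 0:
        for f in fu:
            centre[f][0] *= rest / tot_u

    batch = {}
    for p in scalars:
        # fractions stay at the cohort centre (their variation enters via
        # the trend); the remaining scalars carry the per-voxel jitter
        if p in fractions:
            batch[p] = np.full(n, centre[p][0])
        else:
            w = spec.jitter * priors.width(p)
            batch[p] = centre[p][0] + rng.uniform(-w, w, size=n)
    if spec.jitter > 0:
        v = rng.standard_normal((n, 3))
        batch["fibre_dir"] = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        batch["fibre_dir"] = np.repeat(centre["fibre_dir"], n, axis=0)

    x = rng.uniform(0.0, 1.0, size=n)
    if spec.trend is not None and slope != 0.0:
        batch = apply_change(batch, spec.trend, slope * (x - 0.5))
        if not np.all(_feasible(batch, spec.trend, priors)):
            raise ValueError("cohort trend leaves the parameter bounds")
    return batch, x, slope


def make_cohort(
    spec: CohortSpec, protocol: AcquisitionProtocol
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (summary table Y, covariate table, ground-truth record).

    Rician noise is applied to the raw per-volume signals before
    summarisation, and signals are renormalised by the mean noisy b=0
    volume, as a measured dataset would be.
    """
    rng = np.random.default_rng(spec.rng_seed)
    batch, x, slope = _cohort_batch(spec, rng)
    raw = batch_signals(batch, protocol)
    noisy = add_rician_noise(raw, spec.snr, rng)
    b0 = noisy[:, volume_order(protocol)["b0"]]
    if b0.shape[1]:
        noisy = noisy / np.clip(b0.mean(axis=1), 1e-12, None)[:, None]
    Y = pd.DataFrame(summary_vectors(noisy, protocol),
                     columns=measure_names(protocol))
    cov = pd.DataFrame({spec.covariate_name: x})
    truth = {
        "trend": None if spec.trend is None else spec.trend.name,
        "slope": slope,
        "snr": spec.snr,
        "rng_seed": spec.rng_seed,
        "params": batch,
    }
    return Y, cov, truth


def make_confound_cohort(
    n_voxels: int,
    protocol: AcquisitionProtocol,
    amplitude: float = 0.05,
    snr: float = 150.0,
    priors: PriorSet | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """A cohort whose signal trend no candidate change model can produce.

    The covariate multiplicatively scales the highest-b shell only (a
    relaxation-like confound outside the diffusion model), leaving the other
    shell untouched -- no single tissue-parameter change does that.  Used to
    exercise the chi-squared misfit diagnostics.  The voxel population is
    the same homogeneous trend-free cohort :func:`make_cohort` builds.
    """
    priors = priors or PriorSet()
    rng = np.random.default_rng(rng_seed)
    batch, x, _ = _cohort_batch(
        CohortSpec(n_voxels=n_voxels, trend=None, snr=snr, priors=priors,
                   rng_seed=rng_seed),
        rng,
    )
    raw = batch_signals(batch, protocol)
    order = volume_order(protocol)
    k_hi = int(np.argmax([s.b_value for s in protocol.shells]))
    raw[:, order[f"shell{k_hi}"]] *= (1.0 - amplitude * (x - 0.5))[:, None]
    noisy = add_rician_noise(raw, snr, rng)
    b0 = noisy[:, order["b0"]]
    if b0.shape[1]:
        noisy = noisy / np.clip(b0.mean(axis=1), 1e-12, None)[:, None]
    Y = pd.DataFrame(summary_vectors(noisy, protocol),
                     columns=measure_names(protocol))
    cov = pd.DataFrame({"confound": x})
    return Y, cov, {"mechanism": "high-shell scaling", "amplitude": amplitude}
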