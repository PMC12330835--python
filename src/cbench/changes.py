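"""Change specifications, training-set generation and change-model fitting.

A *change model* answers: "if parameter (or signed fraction pair) nu were
perturbed at a voxel whose baseline summary vector is S, in which direction
would S move?"  It is a regression N(mu_i(S), Sigma_i(S)) trained on pairs
generated from the forward model: sample parameters from the priors, perturb
along the spec, and record the finite-difference change vector

    dS/dnu_hat ~= [M(nu + Dnu) - M(nu)] / |Dnu|

computed in summary-measure space (the signals are assumed to change
linearly with the parameter over the magnitude prior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import PolynomialFeatures
from sklearn.utils.validation import check_is_fitted

from .forward import batch_signals
from .protocol import AcquisitionProtocol
from .summary import summary_vectors
from .tissue import (
    FRACTION_NAMES,
    PriorSet,
    TissueParams,
    params_to_array,
    sample_params_batch,
)

MAGNITUDE_PRIOR_FRACTION = (0.01, 0.1)
"""Magnitude prior as a fraction of the touched parameters' prior width."""


class ChangeSpecError(ValueError):
    pass


class TrainingConfigError(RuntimeError):
    """Priors and spec incompatible (rejection rate above 90%)."""


@dataclass(frozen=True)
class ChangeSpec:
    """A named signed unit direction in parameter space.

    ``signs`` maps parameter name -> +1/-1.  Single-parameter specs touch
    exactly one parameter; fraction-pair specs touch two signal fractions
    with opposite signs so the sum-to-one constraint is preserved.
    """

    name: str
    signs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.signs:
            raise ChangeSpecError("empty change spec")
        touched = list(self.signs)
        frac = [p for p in touched if p in FRACTION_NAMES]
        if frac:
            if set(frac) != set(touched):
                raise ChangeSpecError("cannot mix fractions with other parameters")
            if abs(sum(self.signs[p] for p in frac)) > 1e-12:
                raise ChangeSpecError("fraction-pair signs must sum to zero")
        elif len(touched) != 1:
            raise ChangeSpecError("non-fraction specs must touch exactly one parameter")
        for s in self.signs.values():
            if s not in (+1, -1, +1.0, -1.0):
                raise ChangeSpecError("signs must be +1 or -1")

    @classmethod
    def single(cls, param: str, sign: float = +1.0) -> "ChangeSpec":
        suffix = "" if sign > 0 else "-"
        return cls(name=f"{suffix}{param}" if sign < 0 else param,
                   signs={param: float(np.sign(sign))})

    @classmethod
    def fraction_pair(cls, up: str, down: str) -> "ChangeSpec":
        return cls(name=f"{up}-{down}", signs={up: +1.0, down: -1.0})

    def flipped(self) -> "ChangeSpec":
        signs = {p: -s for p, s in self.signs.items()}
        parts = self.name.split("-")
        if len(parts) == 2 and all(p in FRACTION_NAMES for p in parts):
            name = f"{parts[1]}-{parts[0]}"
        else:
            name = self.name[1:] if self.name.startswith("-") else f"-{self.name}"
        return ChangeSpec(name=name, signs=signs)

    def magnitude_range(self, priors: PriorSet) -> tuple[float, float]:
        w = max(priors.width(p) for p in self.signs)
        lo, hi = MAGNITUDE_PRIOR_FRACTION
        return (lo * w, hi * w)


def default_roster(priors: PriorSet) -> list[ChangeSpec]:
    """Single-parameter specs plus all ordered fraction pairs of the variant."""
    singles = ["ODI", "D_a_in", "D_a_ex", "D_r_ex", "D_sph", "R_sph"]
    if priors.with_ball:
        singles.append("D_ball")
    roster = [ChangeSpec.single(p) for p in singles]
    fracs = priors.fraction_names
    for up in fracs:
        for down in fracs:
            if up != down:
                roster.append(ChangeSpec.fraction_pair(up, down))
    return roster


def apply_change(batch: dict, spec: ChangeSpec, magnitudes: np.ndarray) -> dict:
    """Perturbed copy of a parameter batch: p -> p + sign * magnitude."""
    out = {k: (v.copy() if k in spec.signs else v) for k, v in batch.items()}
    for p, s in spec.signs.items():
        out[p] = batch[p] + s * np.asarray(magnitudes)
    return out


def _feasible(batch: dict, spec: ChangeSpec, priors: PriorSet) -> np.ndarray:
    ok = np.ones(batch["f_in"].shape[0], dtype=bool)
    for p in spec.signs:
        lo, hi = priors.range(p)
        ok &= (batch[p] >= lo) & (batch[p] <= hi)
    return ok


@dataclass(frozen=True)
class TrainingSample:
    baseline: np.ndarray  # summary vector S
    change: np.ndarray  # dS / dnu_hat
    magnitude: float


class TrainingData:
    """Arrays of (baseline summary, change vector, magnitude) triples.

    Sequence-like: ``len(td)``, ``td[i] -> TrainingSample``.
    """

    def __init__(self, baselines, changes, magnitudes, spec: ChangeSpec):
        self.baselines = np.asarray(baselines)
        self.changes = np.asarray(changes)
        self.magnitudes = np.asarray(magnitudes)
        self.spec = spec
        if not np.all(np.isfinite(self.changes)):
            raise ValueError("non-finite change vectors")

    def __len__(self):
        return self.baselines.shape[0]

    def __getitem__(self, i):
        return TrainingSample(self.baselines[i], self.changes[i],
                              float(self.magnitudes[i]))


def change_vector(
    params: TissueParams,
    spec: ChangeSpec,
    magnitude: float,
    protocol: AcquisitionProtocol,
    priors: PriorSet | None = None,
) -> TrainingSample:
    """Finite-difference change vector for one voxel (summary space)."""
    priors = priors or PriorSet()
    batch = params_to_array(params)
    pert = apply_change(batch, spec, np.array([magnitude]))
    if not _feasible(pert, spec, priors)[0]:
        raise ChangeSpecError(
            f"perturbation of {spec.name} by {magnitude} leaves the prior range"
        )
    s0 = summary_vectors(batch_signals(batch, protocol), protocol)
    s1 = summary_vectors(batch_signals(pert, protocol), protocol)
    return TrainingSample(s0[0], (s1 - s0)[0] / magnitude, magnitude)


def generate_training_set(
    spec: ChangeSpec,
    n_samples: int,
    priors: PriorSet,
    protocol: AcquisitionProtocol,
    rng_seed: int,
) -> TrainingData:
    """Exactly ``n_samples`` accepted (S, dS) pairs; rejections resampled.

    Perturbations that would leave a parameter's prior range are rejected and
    redrawn (never clipped), keeping the finite difference unbiased.  A
    rejection rate above 90% raises :class:`TrainingConfigError`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    lo, hi = spec.magnitude_range(priors)
    kept_base: list[dict] = []
    kept_mag: list[np.ndarray] = []
    n_kept = 0
    n_drawn = 0
    while n_kept < n_samples:
        m = max(n_samples - n_kept, 64)
        batch = sample_params_batch(priors, m, rng)
        mags = rng.uniform(lo, hi, size=m)
        pert = apply_change(batch, spec, mags)
        ok = _feasible(pert, spec, priors)
        n_drawn += m
        take = np.flatnonzero(ok)[: n_samples - n_kept]
        if take.size:
            kept_base.append({k: v[take] for k, v in batch.items()})
            kept_mag.append(mags[take])
            n_kept += take.size
        if n_drawn >= 2000 and n_kept < 0.1 * n_drawn:
            raise TrainingConfigError(
                f"rejection rate {1 - n_kept / n_drawn:.0%} for spec {spec.name}"
            )
    base = {k: np.concatenate([b[k] for b in kept_base]) for k in kept_base[0]}
    mags = np.concatenate(kept_mag)
    pert = apply_change(base, spec, mags)
    s0 = summary_vectors(batch_signals(base, protocol), protocol)
    s1 = summary_vectors(batch_signals(pert, protocol), protocol)
    return TrainingData(s0, (s1 - s0) / mags[:, None], mags, spec)


# ---------------------------------------------------------------------------
# Regression

class ChangeModelRegressor(RegressorMixin, BaseEstimator):
    """Predicts the change-vector distribution N(mu(S), Sigma(S)).

    The mean is a degree-``mean_degree`` polynomial regression of the change
    vectors on the baseline summaries.  The covariance is the empirical
    covariance of the residuals plus a degree-``cov_degree`` linear
    correction of the residual outer products, projected to positive
    semidefinite at prediction time.

    Attributes (after fit): ``mean_coef_`` ((p, m)), ``cov_coef_``
    ((p_cov, m, m)), ``n_features_in_``.
    """

    def __init__(self, mean_degree: int = 2, cov_degree: int = 1,
                 ridge: float = 1e-10):
        self.mean_degree = mean_degree
        self.cov_degree = cov_degree
        self.ridge = ridge

    def _poly(self, degree):
        return PolynomialFeatures(degree=degree, include_bias=True)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be 2-D with matching rows")
        self._poly_mean = self._poly(self.mean_degree).fit(X)
        F = self._poly_mean.transform(X)
        if X.shape[0] < 10 * F.shape[1]:
            raise ValueError(
                "need at least 10x more samples than regression coefficients"
            )
        gram = F.T @ F
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e14:
            raise np.linalg.LinAlgError("singular design in change-model regression")
        coef, *_ = np.linalg.lstsq(F, y, rcond=None)
        self.mean_coef_ = coef
        resid = y - F @ coef

        self._poly_cov = self._poly(self.cov_degree).fit(X)
        Fc = self._poly_cov.transform(X)
        outer = resid[:, :, None] * resid[:, None, :]  # (n, m, m)
        ccoef, *_ = np.linalg.lstsq(
            Fc, outer.reshape(len(X), -1), rcond=None
        )
        self.cov_coef_ = ccoef.reshape(Fc.shape[1], y.shape[1], y.shape[1])
        self.n_features_in_ = X.shape[1]
        self.n_targets_ = y.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "mean_coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._poly_mean.transform(X) @ self.mean_coef_

    def predict_cov(self, X):
        """Per-row covariance predictions, projected to PSD."""
        check_is_fitted(self, "cov_coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Fc = self._poly_cov.transform(X)
        cov = np.einsum("np,pij->nij", Fc, self.cov_coef_)
        cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
        vals, vecs = np.linalg.eigh(cov)
        floor = self.ridge * np.maximum(vals.max(axis=1, keepdims=True), 1e-300)
        vals = np.maximum(vals, floor)
        return np.einsum("nij,nj,nkj->nik", vecs, vals, vecs)


@dataclass
class ChangeModel:
    """A trained change model: spec + mu/Sigma regressor + magnitude prior."""

    spec: ChangeSpec
    regressor: ChangeModelRegressor
    magnitude_range: tuple[float, float]

    @property
    def name(self) -> str:
        return self.spec.name

    def predict_mu(self, S) -> np.ndarray:
        return self.regressor.predict(S)

    def predict_sigma(self, S) -> np.ndarray:
        return self.regressor.predict_cov(S)


def train_change_model(
    samples: TrainingData,
    priors: PriorSet | None = None,
    mean_degree: int = 2,
    cov_degree: int = 1,
) -> ChangeModel:
    """Fit the mu/Sigma regressors on generated training pairs."""
    reg = ChangeModelRegressor(mean_degree=mean_degree, cov_degree=cov_degree)
    reg.fit(samples.baselines, samples.changes)
    priors = priors or PriorSet()
    return ChangeModel(
        spec=samples.spec,
        regressor=reg,
        magnitude_range=samples.spec.magnitude_range(priors),
    )


def train_roster(
    roster: list[ChangeSpec],
    priors: PriorSet,
    protocol: AcquisitionProtocol,
    n_samples: int = 20_000,
    rng_seed: int = 0,
) -> dict[str, ChangeModel]:
    """Train every spec in the roster; reproducible for a fixed seed."""
    seeds = np.random.SeedSequence(rng_seed).spawn(len(roster))
    models = {}
    for spec, ss in zip(roster, seeds):
        data = generate_training_set(
            spec, n_samples, priors, protocol,
            rng_seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        models[spec.name] = train_change_model(data, priors)
    return models


# ---------------------------------------------------------------------------
# Serialisation: JSON metadata + npz coefficient arrays

def save_models(models: dict[str, ChangeModel], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {}
    arrays = {}
    for i, (name, cm) in enumerate(models.items()):
        key = f"m{i}"
        meta[key] = {
            "name": name,
            "signs": cm.spec.signs,
            "magnitude_range": list(cm.magnitude_range),
            "mean_degree": cm.regressor.mean_degree,
            "cov_degree": cm.regressor.cov_degree,
            "n_features": cm.regressor.n_features_in_,
        }
        arrays[f"{key}_mean"] = cm.regressor.mean_coef_
        arrays[f"{key}_cov"] = cm.regressor.cov_coef_
    (out / "models.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    np.savez(out / "coefficients.npz", **arrays)


def load_models(in_dir) -> dict[str, ChangeModel]:
    src = Path(in_dir)
    meta = json.loads((src / "models.json").read_text())
    arrays = np.load(src / "coefficients.npz")
    models = {}
    for key in sorted(meta, key=lambda k: int(k[1:])):
        m = meta[key]
        reg = ChangeModelRegressor(
            mean_degree=m["mean_degree"], cov_degree=m["cov_degree"]
        )
        X0 = np.zeros((1, m["n_features"]))
        reg._poly_mean = reg._poly(reg.mean_degree).fit(X0)
        reg._poly_cov = reg._poly(reg.cov_degree).fit(X0)
        reg.mean_coef_ = arrays[f"{key}_mean"]
        reg.cov_coef_ = arrays[f"{key}_cov"]
        reg.n_features_in_ = m["n_features"]
        reg.n_targets_ = reg.mean_coef_.shape[1]
        spec = ChangeSpec(name=m["name"], signs=m["signs"])
        models[m["name"]] = ChangeModel(
            spec=spec, regressor=reg,
            magnitude_range=tuple(m["magnitude_range"]),
        )
    return models
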