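"""GLM stage: baseline summaries, per-covariate change directions, effect
sizes and bootstrap noise covariances.

The model is Y = X beta with X = [1 | x_1 ... x_q] (intercept prepended).
Covariates are demeaned (not rescaled) before the fit so the intercept row
equals the across-voxel mean summary vector; the covariate rows beta_l are
unchanged by the demeaning.  beta is computed with the pseudoinverse of X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


class CollinearityError(ValueError):
    """Rank-deficient design matrix; names the offending covariates."""


@dataclass
class GLMResult:
    """Fitted GLM coefficients and (optionally) effect sizes / noise.

    ``beta_mean``: (m,), ``beta``: (q, m), ``delta``: (q,),
    ``sigma``: (q, m, m).
    """

    beta_mean: np.ndarray
    beta: np.ndarray
    covariate_names: list[str]
    n: int
    delta: np.ndarray | None = None
    sigma: np.ndarray | None = None
    measure_names: list[str] | None = None
    meta: dict = field(default_factory=dict)


def _as_design(X_covariates) -> tuple[np.ndarray, list[str]]:
    if X_covariates is None:
        return np.zeros((0, 0)), []
    if isinstance(X_covariates, pd.DataFrame):
        names = [str(c) for c in X_covariates.columns]
        X = X_covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X_covariates, dtype=float))
        if X.shape[0] == 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates contain missing/non-finite values")
    return X, names


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending covariates: ones whose removal restores full rank
        bad = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j - 1])
        raise CollinearityError(
            f"design matrix is rank deficient; offending covariates: {bad or names}"
        )


def fit_glm(Y: np.ndarray, X_covariates=None) -> GLMResult:
    """beta = pinv([1 | x]) Y; first row is the baseline beta_mean.

    ``X_covariates=None`` fits an intercept-only model (column means)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X, names = _as_design(X_covariates)
    if X.size and X.shape[0] != Y.shape[0]:
        raise ValueError("Y and covariates row counts differ")
    if Y.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > q + 1 voxels")
    Xc = X - X.mean(axis=0) if X.size else np.zeros((Y.shape[0], 0))
    design = np.column_stack([np.ones(Y.shape[0]), Xc])
    _check_rank(design, names)
    beta = np.linalg.pinv(design) @ Y
    return GLMResult(
        beta_mean=beta[0], beta=beta[1:], covariate_names=names, n=len(Y),
    )


def effect_size(x_l, mode: str = "percentile") -> float:
    """Covariate effect size delta_l.

    ``mode='percentile'``: 99.9th minus 0.1th percentile (linear
    interpolation between order statistics), the real-data convention.
    ``mode='range'``: max minus min, the simulated-data convention.
    Constant covariates give 0 with a warning (inference is skipped for
    them upstream).
    """
    x = np.asarray(x_l, dtype=float).ravel()
    if np.ptp(x) == 0:
        warnings.warn("constant covariate: effect size 0, inference skipped")
        return 0.0
    if mode == "range":
        return float(np.ptp(x))
    if mode != "percentile":
        raise ValueError(f"unknown effect-size mode {mode!r}")
    if x.size < 1000:
        warnings.warn(
            f"only {x.size} values: extreme percentiles (0.1/99.9) are unstable"
        )
    lo, hi = np.percentile(x, [0.1, 99.9], method="linear")
    return float(hi - lo)


def bootstrap_noise_cov(
    Y: np.ndarray,
    X_covariates,
    n_iter: int = 5000,
    subsample_size: int = 1000,
    rng_seed: int = 0,
    chunk: int = 250,
) -> np.ndarray:
    """Noise covariance of each beta_l by voxel bootstrap.

    Each iteration resamples ``subsample_size`` voxels with replacement,
    refits the GLM, and records beta_l; sigma_l is the covariance of beta_l
    across iterations.  Returns (q, m, m); deterministic given the seed.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X, names = _as_design(X_covariates)
    n, q = X.shape
    m = Y.shape[1]
    if subsample_size > n:
        raise ValueError("subsample_size cannot exceed the voxel count")
    if subsample_size < q + 2:
        raise ValueError("subsample smaller than q + 2")
    rng = np.random.default_rng(rng_seed)
    betas = np.empty((n_iter, q, m))
    done = 0
    while done < n_iter:
        k = min(chunk, n_iter - done)
        idx = rng.integers(0, n, size=(k, subsample_size))
        Xb = X[idx]  # (k, s, q)
        Xb = Xb - Xb.mean(axis=1, keepdims=True)
        Yb = Y[idx]  # (k, s, m)
        D = np.concatenate([np.ones((k, subsample_size, 1)), Xb], axis=2)
        G = np.einsum("ksp,ksq->kpq", D, D)
        R = np.einsum("ksp,ksm->kpm", D, Yb)
        try:
            sol = np.linalg.solve(G, R)  # (k, q+1, m)
        except np.linalg.LinAlgError:
            sol = np.stack([np.linalg.pinv(d) @ y for d, y in zip(D, Yb)])
        betas[done : done + k] = sol[:, 1:, :]
        done += k
    centred = betas - betas.mean(axis=0)
    sigma = np.einsum("klm,kln->lmn", centred, centred) / (n_iter - 1)
    return sigma


class SummaryGLM(BaseEstimator):
    """Estimator wrapping the full GLM stage.

    ``fit(X, Y)`` computes beta_mean_, beta_, delta_ (per
    ``effect_size_mode``) and sigma_ (bootstrap, unless ``n_boot=0``).
    """

    def __init__(self, effect_size_mode: str = "percentile",
                 n_boot: int = 5000, subsample_size: int = 1000,
                 rng_seed: int = 0):
        self.effect_size_mode = effect_size_mode
        self.n_boot = n_boot
        self.subsample_size = subsample_size
        self.rng_seed = rng_seed

    def fit(self, X, Y):
        res = fit_glm(Y, X)
        Xarr, _ = _as_design(X)
        res.delta = np.array(
            [effect_size(Xarr[:, j], self.effect_size_mode)
             for j in range(Xarr.shape[1])]
        )
        if self.n_boot:
            res.sigma = bootstrap_noise_cov(
                Y, X, n_iter=self.n_boot,
                subsample_size=min(self.subsample_size, Xarr.shape[0]),
                rng_seed=self.rng_seed,
            )
        res.meta = {"rng_seed": self.rng_seed, "n_boot": self.n_boot,
                    "subsample_size": self.subsample_size,
                    "effect_size_mode": self.effect_size_mode}
        self.result_ = res
        self.beta_mean_ = res.beta_mean
        self.beta_ = res.beta
        self.delta_ = res.delta
        self.sigma_ = res.sigma
        self.covariate_names_ = res.covariate_names
        return self


def glm_from_noise_instances(beta_samples: np.ndarray) -> np.ndarray:
    """sigma_l from repeated noise realisations: covariance of beta_l across
    instances.  ``beta_samples``: (n_instances, q, m) -> (q, m, m)."""
    b = np.asarray(beta_samples, dtype=float)
    centred = b - b.mean(axis=0)
    return np.einsum("klm,kln->lmn", centred, centred) / (b.shape[0] - 1)
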