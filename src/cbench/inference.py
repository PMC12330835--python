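"""Bayesian inference over candidate parameter changes.

For each continuous covariate l the GLM provides a baseline y = beta_mean,
a measured change Dy = beta_l * delta_l and a noise covariance sigma_l.
Each trained change model i supplies mu_i(y) and Sigma_i(y), and the
likelihood of the measured change under a change of magnitude s = |Dnu| is

    P(Dy | y, nu_i, s) = N(Dy; s mu_i(y), s^2 Sigma_i(y) + sigma_l)

marginalised over s with a uniform magnitude prior (fixed-order
Gauss-Legendre quadrature in the log-density domain) and normalised across
models to give the posterior probability of each candidate change.  A
chi-squared pattern distance (the Mahalanobis distance of Dy to its
best-fitting scaled prediction) is reported alongside as a goodness-of-fit
diagnostic: probabilities are normalised so they always sum to one, even
when no candidate pattern actually matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .changes import ChangeModel
from .glm import GLMResult

QUAD_ORDER = 64
RIDGE = 1e-10  # x mean diagonal, added before inversion


@dataclass
class MeasuredChange:
    """One covariate's measured change in summary space."""

    y: np.ndarray  # baseline (m,)
    delta_y: np.ndarray  # beta_l * delta_l (m,)
    sigma: np.ndarray  # noise covariance (m, m)
    name: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.delta_y = np.asarray(self.delta_y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = self.y.shape[0]
        if self.delta_y.shape != (m,) or self.sigma.shape != (m, m):
            raise ValueError("inconsistent dimensions in MeasuredChange")


def measured_changes_from_glm(result: GLMResult) -> list[MeasuredChange]:
    if result.delta is None or result.sigma is None:
        raise ValueError("GLMResult lacks effect sizes or noise covariances")
    out = []
    for l, name in enumerate(result.covariate_names):
        # Dy = beta_l * delta_l, so the noise covariance of Dy is the
        # bootstrap covariance of beta_l scaled by delta_l^2
        out.append(
            MeasuredChange(
                y=result.beta_mean,
                delta_y=result.beta[l] * result.delta[l],
                sigma=result.sigma[l] * result.delta[l] ** 2,
                name=name,
            )
        )
    return out


def _log_mvnormal(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Hand-rolled multivariate normal log density via Cholesky."""
    m = x.shape[0]
    cov = cov + RIDGE * (np.trace(cov) / m) * np.eye(m)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # regularise harder; flagged by caller via -inf fallbacks elsewhere
        L = np.linalg.cholesky(cov + 1e-8 * (np.trace(cov) / m + 1e-300) * np.eye(m))
    u = np.linalg.solve(L, x - mean)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (u @ u + logdet + m * np.log(2 * np.pi)))


def change_likelihood(
    measured: MeasuredChange, model: ChangeModel, magnitude: float
) -> float:
    """Density of the measured change at one magnitude (non-log)."""
    return float(np.exp(log_change_likelihood(measured, model, magnitude)))


def log_change_likelihood(
    measured: MeasuredChange, model: ChangeModel, magnitude: float
) -> float:
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    mu = model.predict_mu(measured.y[None])[0]
    sig = model.predict_sigma(measured.y[None])[0]
    cov = magnitude**2 * sig + measured.sigma
    return _log_mvnormal(measured.delta_y, magnitude * mu, cov)


def marginal_likelihood(
    measured: MeasuredChange,
    model: ChangeModel,
    magnitude_prior: tuple[float, float] | None = None,
    order: int = QUAD_ORDER,
) -> float:
    """integral of the likelihood over the magnitude prior (Gauss-Legendre)."""
    return float(np.exp(log_marginal_likelihood(
        measured, model, magnitude_prior, order)))


def log_marginal_likelihood(
    measured: MeasuredChange,
    model: ChangeModel,
    magnitude_prior: tuple[float, float] | None = None,
    order: int = QUAD_ORDER,
) -> float:
    a, b = magnitude_prior if magnitude_prior is not None else model.magnitude_range
    if not (np.isfinite(a) and np.isfinite(b) and b > a):
        raise ValueError("magnitude prior must be a bounded interval")
    x, w = np.polynomial.legendre.leggauss(order)
    s = 0.5 * (b - a) * x + 0.5 * (b + a)
    logw = np.log(0.5 * (b - a) * w)

    mu = model.predict_mu(measured.y[None])[0]
    sig = model.predict_sigma(measured.y[None])[0]
    logf = np.array(
        [_log_mvnormal(measured.delta_y, si * mu, si**2 * sig + measured.sigma)
         for si in s]
    )
    return float(logsumexp(logf + logw))


def posterior(
    measured: MeasuredChange,
    models: list[ChangeModel] | dict[str, ChangeModel],
    magnitude_prior: tuple[float, float] | None = None,
    order: int = QUAD_ORDER,
) -> dict:
    """Normalised probabilities over candidate change models.

    Returns ``{"probabilities": {name: p}, "argmax": name,
    "chi2": {name: d}, "underflow": bool}``.  When every marginal
    underflows the posterior is uniform and flagged.
    """
    if isinstance(models, dict):
        models = list(models.values())
    if len(models) < 2:
        raise ValueError("need at least 2 candidate change models")
    names = [m.name for m in models]
    logm = np.array(
        [log_marginal_likelihood(measured, m, magnitude_prior, order)
         for m in models]
    )
    # underflow: every marginal would round to 0.0 outside the log domain
    finite = logm[np.isfinite(logm)]
    underflow = finite.size == 0 or finite.max() < -744.0
    if underflow:
        probs = np.full(len(models), 1.0 / len(models))
    else:
        probs = np.exp(logm - logsumexp(logm))
        probs = probs / probs.sum()
    chi2 = {m.name: chi2_pattern_distance(measured, m) for m in models}
    return {
        "probabilities": dict(zip(names, probs)),
        "argmax": names[int(np.argmax(probs))],
        "chi2": chi2,
        "underflow": underflow,
    }


def chi2_pattern_distance(
    measured: MeasuredChange, model: ChangeModel,
    magnitude_bounds: tuple[float, float] | None = None,
) -> float:
    """Mahalanobis distance of Dy to its best-fitting scaled prediction.

    Minimised over the (non-negative) change magnitude s, with the total
    covariance s^2 Sigma(y) + sigma_l as the metric.  Zero iff Dy is an
    exact non-negative scaling of mu(y) under the metric.
    """
    mu = model.predict_mu(measured.y[None])[0]
    sig = model.predict_sigma(measured.y[None])[0]
    m = measured.y.shape[0]

    def dist(s):
        cov = s**2 * sig + measured.sigma
        cov = cov + RIDGE * (np.trace(cov) / m) * np.eye(m)
        r = measured.delta_y - s * mu
        return float(r @ np.linalg.solve(cov, r))

    hi = magnitude_bounds[1] if magnitude_bounds else model.magnitude_range[1]
    res = minimize_scalar(dist, bounds=(0.0, hi), method="bounded")
    return float(min(res.fun, dist(0.0), dist(hi)))


def infer_table(
    result: GLMResult,
    models: dict[str, ChangeModel],
    order: int = QUAD_ORDER,
) -> pd.DataFrame:
    """Posterior table: one row per (covariate, change model).

    Columns: covariate, model, probability, chi2.  Covariates with zero
    effect size are skipped.
    """
    rows = []
    for mc in measured_changes_from_glm(result):
        if not np.any(mc.delta_y):
            continue
        post = posterior(mc, models, order=order)
        for name in post["probabilities"]:
            rows.append(
                {
                    "covariate": mc.name,
                    "model": name,
                    "probability": post["probabilities"][name],
                    "chi2": post["chi2"][name],
                }
            )
    return pd.DataFrame(rows)


class ChangeInference(BaseEstimator):
    """Estimator facade: fit on trained change models, predict posteriors."""

    def __init__(self, order: int = QUAD_ORDER):
        self.order = order

    def fit(self, models: dict[str, ChangeModel], y=None):
        if len(models) < 2:
            raise ValueError("need at least 2 change models")
        self.models_ = dict(models)
        return self

    def predict_proba(self, measured: list[MeasuredChange]) -> np.ndarray:
        names = list(self.models_)
        out = np.empty((len(measured), len(names)))
        for i, mc in enumerate(measured):
            post = posterior(mc, self.models_, order=self.order)
            out[i] = [post["probabilities"][n] for n in names]
        return out

    def predict(self, measured: list[MeasuredChange]) -> list[str]:
        names = list(self.models_)
        probs = self.predict_proba(measured)
        return [names[i] for i in np.argmax(probs, axis=1)]

    def table(self, result: GLMResult) -> pd.DataFrame:
        return infer_table(result, self.models_, order=self.order)
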