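"""Plot helpers: posterior bar charts and pattern-of-change panels."""

from __future__ import annotations

import numpy as np

from .glm import GLMResult
from .inference import measured_changes_from_glm


def plot_posterior_bars(table, covariate=None, ax=None):
    """Bar chart of inferred probabilities for one covariate.

    ``table``: DataFrame with covariate/model/probability columns (as
    produced by :func:`cbench.inference.infer_table`).
    """
    import matplotlib.pyplot as plt

    if covariate is None:
        covariate = table["covariate"].iloc[0]
    sub = table[table["covariate"] == covariate]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.4 * len(sub)), 3))
    order = sub.sort_values("probability", ascending=False)
    ax.bar(order["model"], order["probability"], color="#4878a8")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    ax.set_title(f"Δ{covariate}")
    ax.tick_params(axis="x", rotation=90)
    return ax


def plot_change_patterns(result: GLMResult, models: dict, covariate: str,
                         model_names=None, axes=None):
    """Measured vs predicted pattern-of-change panels.

    Left panel: the measured change Dy per summary measure for the chosen
    covariate.  Remaining panels: each change model's predicted direction
    mu(beta_mean) with +-1 sd from its predicted covariance.
    """
    import matplotlib.pyplot as plt

    mc = next(
        m for m in measured_changes_from_glm(result) if m.name == covariate
    )
    names = model_names or list(models)
    if axes is None:
        _, axes = plt.subplots(
            1, len(names) + 1, figsize=(2.2 * (len(names) + 1), 2.6),
            sharey=False,
        )
    labels = result.measure_names or [f"m{i}" for i in range(len(mc.y))]
    xs = np.arange(len(mc.y))
    err = np.sqrt(np.diag(mc.sigma))
    axes[0].bar(xs, mc.delta_y, yerr=err, color="#555555")
    axes[0].set_title(f"Measured\nΔ{covariate}")
    for ax, nm in zip(axes[1:], names):
        cm = models[nm]
        mu = cm.predict_mu(mc.y[None])[0]
        sd = np.sqrt(np.diag(cm.predict_sigma(mc.y[None])[0]))
        ax.bar(xs, mu, yerr=sd, color="#4878a8")
        ax.set_title(f"Predicted\nΔ{nm}")
    for ax in axes:
        ax.set_xticks(xs)
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_yticks([])
    return axes
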