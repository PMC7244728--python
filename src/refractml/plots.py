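"""Optional figure outputs for evaluation reports.

Thin matplotlib wrappers over the statistics in :mod:`refractml.evaluation`;
each function draws onto a provided or fresh Axes and returns it, so figures
compose and test headlessly.
"""

from __future__ import annotations

import numpy as np

from .evaluation import bland_altman, confidence_ellipse, density_summary

__all__ = ["plot_error_density", "plot_astigmatic_errors", "plot_bland_altman"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_error_density(errors_by_method: dict[str, np.ndarray], ax=None):
    """Gaussian KDE of the signed prediction error, one curve per method."""
    ax = _get_ax(ax)
    for method, errors in errors_by_method.items():
        d = density_summary(np.asarray(errors))
        ax.plot(d["x"], d["density"], label=method)
    ax.set_xlabel("prediction error (D)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_astigmatic_errors(
    errors_by_method: dict[str, tuple[np.ndarray, np.ndarray]],
    level: float = 0.95,
    ax=None,
):
    """(J0, J45) error scatter with the covariance confidence ellipse."""
    from matplotlib.patches import Ellipse

    ax = _get_ax(ax)
    for method, (j0, j45) in errors_by_method.items():
        pts = ax.scatter(j0, j45, s=6, alpha=0.4, label=method)
        e = confidence_ellipse(np.asarray(j0), np.asarray(j45), level=level)
        ax.add_patch(
            Ellipse(
                e.center, 2 * e.semi_axes[0], 2 * e.semi_axes[1],
                angle=e.orientation_deg, fill=False,
                edgecolor=pts.get_facecolor()[0],
            )
        )
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("J0 error (D)")
    ax.set_ylabel("J45 error (D)")
    ax.set_aspect("equal")
    ax.legend()
    return ax


def plot_bland_altman(predicted: np.ndarray, subjective: np.ndarray, ax=None):
    """Difference-vs-mean agreement plot with bias and 95% limits."""
    ax = _get_ax(ax)
    predicted = np.asarray(predicted, dtype=float)
    subjective = np.asarray(subjective, dtype=float)
    ba = bland_altman(predicted, subjective)
    mean = (predicted + subjective) / 2.0
    ax.scatter(mean, predicted - subjective, s=6, alpha=0.5)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="r", linestyle=style, lw=1)
    ax.set_xlabel("mean of prediction and subjective (D)")
    ax.set_ylabel("prediction − subjective (D)")
    return ax
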