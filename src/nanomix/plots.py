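"""Plot renderings (QQ diagnostics, fitted mixture profiles).

Plots are artifacts for human inspection, not test surfaces.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import QQDiagnostic
from .em import MixtureModel, mixture_pdf
from .measurements import MeasurementSet


def plot_qq(qq: QQDiagnostic, path, title: str = "") -> None:
    """QQ scatter with the identity reference line (the red line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(qq.theoretical, qq.observed, s=14, color="black", zorder=3)
    span = [min(qq.theoretical.min(), qq.observed.min()),
            max(qq.theoretical.max(), qq.observed.max())]
    ax.plot(span, span, color="red", lw=1.5, label="perfect fit")
    ax.set_xlabel("theoretical mixture quantile")
    ax.set_ylabel("observed quantile")
    ax.set_title(title or f"QQ (R² = {qq.r_squared:.4f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mixture(data: MeasurementSet, model: MixtureModel, path, bins: int = 20) -> None:
    """Histogram of the sample with the fitted mixture density overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(data.values, bins=bins, density=True, alpha=0.5, color="steelblue")
    grid = np.linspace(data.values.min(), data.values.max(), 400)
    ax.plot(grid, mixture_pdf(grid, model), color="black", lw=1.5)
    for w, m, s in zip(model.weights, model.means, model.sigmas):
        component = w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        ax.plot(grid, component, lw=1.0, ls="--")
    ax.set_xlabel(data.unit)
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
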