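"""Optional matplotlib renderings of diagrams and study results."""

from __future__ import annotations

import numpy as np

from .inference import SnrStudyResult, TwoGroupResult
from .persistence import PersistenceDiagram

__all__ = ["plot_diagram", "plot_snr_curves", "plot_bootstrap_boxes"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_diagram(pd: PersistenceDiagram, ax=None, inf_factor: float = 1.05):
    """Birth/death scatter, one colour per homology dimension; essential
    classes are drawn at ``inf_factor`` times the largest finite death."""
    ax = _axes(ax)
    finite = pd.deaths[np.isfinite(pd.deaths)]
    top = (finite.max() if finite.size else 1.0) * inf_factor
    for k in sorted(set(pd.dims.tolist())):
        sel = pd.dims == k
        deaths = np.where(np.isfinite(pd.deaths[sel]), pd.deaths[sel], top)
        ax.scatter(pd.births[sel], deaths, s=14, label=f"dim {k}")
    lim = max(top, 1e-9)
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.legend()
    return ax


def plot_snr_curves(res: SnrStudyResult, ax=None):
    ax = _axes(ax)
    for k, m in sorted(res.mean_total_persistence.items()):
        ax.plot(res.snr_grid, m, marker="o", label=f"$P_{k}$")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("signal-to-noise ratio")
    ax.set_ylabel("mean total persistence")
    ax.legend()
    return ax


def plot_bootstrap_boxes(res: TwoGroupResult, k: int, ax=None):
    ax = _axes(ax)
    labels = sorted(res.summaries[k])
    ax.boxplot(
        [res.summaries[k][label].boot_means for label in labels],
        tick_labels=labels,
    )
    ax.set_ylabel(f"bootstrap mean total persistence (dim {k})")
    return ax
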