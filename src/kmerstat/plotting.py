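"""Plotting of fitted histogram models (static overlay and DE animation)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .histogram import KmerHistogram
from .mixture import FitResult, MixtureModel, _Encoding

__all__ = ["plot_model", "animate_fit"]

_COMPONENT_NAMES = {0: "error", 1: "heterozygous", 2: "homozygous"}


def _draw(ax, model: MixtureModel, hist: KmerHistogram, log: bool) -> None:
    x = np.arange(1, hist.c + 1)
    target = hist.normalized()
    ax.bar(x, target, width=1.0, color="0.85", label="histogram")
    pmfs = model.component_pmfs()
    w = model.weights
    for i in range(len(model.components)):
        name = _COMPONENT_NAMES.get(i, f"component {i}") if model.p == 2 else f"component {i}"
        ax.plot(x, w[i] * pmfs[i], lw=1.2, ls="--", label=f"{name} ({model.components[i].family})")
    ax.plot(x, w @ pmfs, lw=1.8, color="k", label="mixture F")
    if log:
        ax.set_yscale("log")
        ax.set_ylim(bottom=max(target[target > 0].min() / 10, 1e-12))
    ax.set_xlabel("k-mer count")
    ax.set_ylabel("fraction of distinct k-mers")
    ax.legend(fontsize=8)


def plot_model(
    fit: FitResult | MixtureModel,
    hist: KmerHistogram,
    path=None,
    log: bool = False,
):
    """Static overlay of the histogram, the components, and the mixture.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    model = fit.model if isinstance(fit, FitResult) else fit
    fig, ax = plt.subplots(figsize=(7, 4.2))
    _draw(ax, model, hist, log)
    if isinstance(fit, FitResult):
        ax.set_title(f"Err = {fit.err:.4f} after {fit.n_generations} generations")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def animate_fit(fit: FitResult, hist: KmerHistogram, path, log: bool = False):
    """Animate the per-generation best solutions of the DE search (GIF).

    One frame per recorded generation; requires the fit's solution trace.
    """
    from matplotlib.animation import FuncAnimation, PillowWriter

    if not fit.trace_solutions:
        raise ValueError("fit has no recorded per-generation solutions")
    enc = _Encoding(hist.c, fit.model.p)
    fig, ax = plt.subplots(figsize=(7, 4.2))

    def render(frame):
        ax.clear()
        model = enc.decode(fit.trace_solutions[frame])
        _draw(ax, model, hist, log)
        ax.set_title(f"generation {frame + 1}: objective = {fit.trace[frame]:.4f}")

    anim = FuncAnimation(fig, render, frames=len(fit.trace_solutions))
    anim.save(path, writer=PillowWriter(fps=10))
    plt.close(fig)
    return len(fit.trace_solutions)
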