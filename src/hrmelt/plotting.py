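"""Melt-curve plot panels: derivative, normalized, difference."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .curve_analysis import DerivativeCurve, DifferenceCurve, NormalizedCurve

__all__ = ["plot_derivative", "plot_normalized", "plot_difference"]


def _panel(title: str, ylabel: str):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.set_title(title)
    ax.set_xlabel("Temperature (°C)")
    ax.set_ylabel(ylabel)
    return fig, ax


def plot_derivative(curves: Mapping[str, DerivativeCurve] | Sequence[DerivativeCurve]):
    fig, ax = _panel("Derivative melt plot", "-dF/dT")
    items = curves.items() if isinstance(curves, Mapping) else ((None, c) for c in curves)
    for label, c in items:
        ax.plot(c.temperatures_c, c.minus_df_dt, lw=0.8, label=label)
    if isinstance(curves, Mapping):
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_normalized(curves: Mapping[str, NormalizedCurve] | Sequence[NormalizedCurve]):
    fig, ax = _panel("Normalized melt curves", "Fluorescence (%)")
    items = curves.items() if isinstance(curves, Mapping) else ((None, c) for c in curves)
    for label, c in items:
        ax.plot(c.temperatures_c, c.values, lw=0.8, label=label)
    if isinstance(curves, Mapping):
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_difference(curves: Mapping[str, DifferenceCurve] | Sequence[DifferenceCurve]):
    fig, ax = _panel("Difference plot", "Δ fluorescence (%)")
    items = curves.items() if isinstance(curves, Mapping) else ((None, c) for c in curves)
    for label, c in items:
        ax.plot(c.temperatures_c, c.delta_values, lw=0.8, label=label)
    ax.axhline(0.0, color="k", lw=0.5)
    if isinstance(curves, Mapping):
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
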