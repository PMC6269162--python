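"""Diagnostic plots: melt fits with derivative overlays, binding isotherms."""

from __future__ import annotations

import numpy as np

from . import binding as binding_mod
from . import meltfit, thermo


def plot_melt_fit(norm, deriv, result, ax=None):
    """Overlay the normalised melt, its derivative and the fitted model.

    Returns the matplotlib axes (fraction on the left axis, df/dT on a
    twin right axis).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(norm.temperature, norm.fraction, ".", ms=2, color="0.5", label="data")
    transitions = tuple(
        thermo.Transition(tm=t.tm, dh=t.dh, amplitude=t.amplitude) for t in result.transitions
    )
    model = thermo.UnfoldingModel(transitions=transitions)
    ax.plot(
        norm.temperature,
        thermo.fraction_unfolded(model, norm.temperature),
        "-",
        color="C0",
        label="fit",
    )
    ax2 = ax.twinx()
    ax2.plot(deriv.temperature, deriv.dfdT, "-", color="C1", alpha=0.6, label="df/dT")
    for t in result.transitions:
        ax.axvline(t.tm, color="C3", ls=":", lw=0.8)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("fraction unfolded")
    ax2.set_ylabel("df/dT (°C$^{-1}$)")
    ax.legend(loc="upper left", frameon=False)
    return ax


def plot_binding_fit(series, hill, ax=None):
    """Binding isotherm: θ against free tropomyosin with the Hill fit curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.free, series.theta, "o", color="0.3", label="data")
    grid = np.linspace(0.0, float(np.max(series.free)) * 1.05, 200)
    ax.plot(
        grid,
        binding_mod.hill_curve(grid, hill.k50, hill.n_hill, hill.theta_max),
        "-",
        color="C0",
        label=f"Hill fit (K$_{{50}}$ = {hill.k50:.2f} μM)",
    )
    ax.axvline(hill.k50, color="C3", ls=":", lw=0.8)
    ax.set_xlabel("free Tpm (μM)")
    ax.set_ylabel("fractional saturation θ")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(frameon=False)
    return ax
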