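"""Plot helpers: fit overlays, SLD profiles and 2D marginal posteriors."""

from __future__ import annotations

import numpy as np

from .composition import WedgeStructure
from .inference import FitSummary
from .io import ScatteringPattern

__all__ = ["plot_fit", "plot_sld_profile", "plot_marginal_2d"]


def plot_fit(pattern: ScatteringPattern, model_intensity, ax=None):
    """Overlay data (with error bars) and model intensity on log-log axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        pattern.q, pattern.intensity, yerr=pattern.sigma,
        fmt=".", ms=3, alpha=0.5, label="data",
    )
    ax.plot(pattern.q, np.asarray(model_intensity), "-", lw=1.5, label="model")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$q$ ($\mathrm{\AA}^{-1}$)")
    ax.set_ylabel("intensity (arb. u.)")
    ax.legend()
    return ax


def plot_sld_profile(wedge: WedgeStructure, a: float, ax=None):
    """Radial electron-density contrast profile of the wedge unit cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = [0.0, wedge.R_W, wedge.r_H_out, wedge.r_BB_out, a / 2.0]
    vals = [0.0, wedge.sld["H"], wedge.sld["BB"], wedge.sld["HC"]]
    ax.stairs(vals, edges, fill=True, alpha=0.4)
    ax.axvline(wedge.R_0, ls="--", c="k", lw=0.8, label=r"$R_0$ (neutral plane)")
    ax.set_xlabel(r"$r$ ($\mathrm{\AA}$)")
    ax.set_ylabel(r"$\Delta\rho$ (e$/\mathrm{\AA}^3$)")
    ax.legend()
    return ax


def plot_marginal_2d(summary: FitSummary, name_i: str, name_j: str, bins=40, ax=None):
    """2D marginal posterior density of a parameter pair, MAP and mean marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h, xe, ye = summary.marginal_2d(name_i, name_j, bins=bins)
    ax.pcolormesh(xe, ye, h.T, shading="auto")
    ax.plot(
        getattr(summary.map_params, name_i),
        getattr(summary.map_params, name_j),
        "r+", ms=12, label="MAP",
    )
    ax.plot(
        summary.expectation[name_i], summary.expectation[name_j],
        "o", mfc="none", mec="lime", ms=10, label="mean",
    )
    ax.set_xlabel(name_i)
    ax.set_ylabel(name_j)
    ax.legend()
    return ax
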