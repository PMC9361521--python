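"""Diagnostic plots for the main result objects (matplotlib, optional use)."""

from __future__ import annotations

import numpy as np

from .io import ScatteringCurve
from .saxs import GuinierResult, PairDistribution, dimensionless_kratky

__all__ = ["plot_curve", "plot_kratky", "plot_pr", "plot_itc_fit"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_curve(curve: ScatteringCurve, ax=None, label=None, log=True):
    """log I(q) vs q with error band."""
    ax = _axes(ax)
    ax.errorbar(curve.q, curve.I, yerr=curve.sigma, fmt=".", ms=2, label=label)
    if log:
        ax.set_yscale("log")
    ax.set_xlabel(r"q ($\AA^{-1}$)")
    ax.set_ylabel("I(q)")
    if label:
        ax.legend()
    return ax


def plot_kratky(curve: ScatteringCurve, g: GuinierResult, ax=None, label=None):
    """Dimensionless Kratky plot with the globular reference point."""
    ax = _axes(ax)
    xy = dimensionless_kratky(curve, g)
    ax.plot(xy[:, 0], xy[:, 1], label=label)
    ax.axvline(np.sqrt(3.0), ls="--", lw=0.7, color="grey")
    ax.axhline(3.0 / np.e, ls="--", lw=0.7, color="grey")
    ax.set_xlabel(r"$qR_g$")
    ax.set_ylabel(r"$(qR_g)^2\, I/I(0)$")
    if label:
        ax.legend()
    return ax


def plot_pr(pr: PairDistribution, ax=None, label=None):
    ax = _axes(ax)
    ax.plot(pr.r, pr.p, label=label)
    ax.set_xlabel(r"r ($\AA$)")
    ax.set_ylabel("P(r)")
    ax.axhline(0.0, lw=0.5, color="grey")
    if label:
        ax.legend()
    return ax


def plot_itc_fit(titration, fit, ax=None):
    """Measured injection heats with the fitted one-site model overlaid."""
    from .itc import one_site_heats

    ax = _axes(ax)
    idx = np.arange(1, titration.injections.size + 1)
    ax.plot(idx, titration.heats, "o", ms=4, label="data")
    model = one_site_heats((fit.kd, fit.n, fit.dH, fit.dilution_offset), titration)
    ax.plot(idx, model, "-", label="one-site fit")
    ax.set_xlabel("injection")
    ax.set_ylabel(r"heat ($\mu$cal)")
    ax.legend()
    return ax
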