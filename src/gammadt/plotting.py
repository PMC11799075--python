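"""Plot helpers for spectra and loss curves (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .phantom import IncidentSpectrum

__all__ = ["plot_spectra", "plot_loss_curves"]


def plot_spectra(spectra: dict[str, IncidentSpectrum], ax=None, log=True):
    """Overlay incident spectra, one line per filter configuration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, spec in spectra.items():
        ax.step(spec.centers, spec.total, where="mid", label=name)
    ax.set_xlabel("energy (keV)")
    ax.set_ylabel("incident rate (photons/s per bin)")
    if log:
        ax.set_yscale("log")
    ax.legend(title="filter")
    return ax


def plot_loss_curves(timecourse: pd.DataFrame, detector: int | None = None, ax=None):
    """Dead-time loss versus time after administration per configuration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    df = timecourse
    if detector is not None and "detector" in df.columns:
        df = df[df["detector"] == detector]
    for name, grp in df.groupby("config"):
        g = grp.sort_values("time_h")
        ax.plot(g["time_h"], g["loss_percent"], marker="o", label=name)
    ax.set_xlabel("time after administration (h)")
    ax.set_ylabel("dead-time loss (%)")
    ax.legend(title="filter")
    return ax
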