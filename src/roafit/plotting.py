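"""Minimal plotting helpers (Raman/ROA panels)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spectra import SpectrumPair


def plot_pair(
    experiment: SpectrumPair,
    fit: SpectrumPair | None = None,
    path: str | Path = "spectra.png",
    title: str = "",
) -> None:
    """Two stacked panels (Raman, ROA); optional overlay of a fitted pair."""
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for ax, chan in zip(axes, ("raman", "roa")):
        exp_s = getattr(experiment, chan)
        ax.plot(exp_s.wavenumbers, exp_s.values, "k-", lw=1, label="experiment")
        if fit is not None:
            fit_s = getattr(fit, chan)
            ax.plot(fit_s.wavenumbers, fit_s.values, "r-", lw=1, label="best fit")
        ax.set_ylabel(f"I ({chan.upper()})")
        ax.legend(frameon=False, fontsize=8)
    axes[1].set_xlabel(r"wavenumber (cm$^{-1}$)")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
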