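"""Rendering of spectral maps and averaged spectra to PNG.

Figures are built directly on an Agg canvas (no pyplot global state) so
output is deterministic and headless-safe.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .spectral import AveragedSpectrum, SpectralMap


def plot_spectral_map(spectral_map: SpectralMap, path: str | Path) -> None:
    """Frequency x column heat map of spectral power (DC bin excluded)."""
    fig = Figure(figsize=(6, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    power = spectral_map.power[1:]  # DC row dwarfs everything when drift remains
    freqs = spectral_map.freqs
    im = ax.imshow(
        power,
        origin="lower",
        aspect="auto",
        extent=(0, power.shape[1], freqs[1], freqs[-1]),
        cmap="inferno",
    )
    ax.set_xlabel("pixel column x")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"spectral map: {spectral_map.signal_label}")
    fig.colorbar(im, ax=ax, label="power (px$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)


def plot_average_spectrum(spectrum: AveragedSpectrum, path: str | Path) -> None:
    """Column-averaged power spectrum as a line plot (DC bin excluded)."""
    fig = Figure(figsize=(6, 3.2))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.plot(spectrum.freqs[1:], spectrum.power[1:], lw=1.2)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (px$^2$)")
    ax.set_title(f"averaged spectrum: {spectrum.signal_label}")
    ax.set_xlim(0, float(np.max(spectrum.freqs)))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
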