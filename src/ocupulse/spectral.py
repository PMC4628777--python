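"""Temporal FFT spectral maps, averaged spectra and physiological peaks.

Each column's detrended position signal is Fourier-transformed; the
one-sided power ``|F_k|^2 / n^2`` is laid out as a (frequency bin, column)
spectral map.  With this normalization a unit-amplitude sinusoid at an
exact bin reads 0.25 px^2 (amplitude^2 / 4) regardless of n, and Parseval's
identity holds per column with folding weights 2 on interior bins.  The
column-averaged spectrum is the quantity on which physiological peaks —
respiratory (~0.25 Hz), cardiac (~1-1.5 Hz) and its harmonics — are
detected and a cardiac fundamental is estimated from the harmonic comb.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows as _windows

from .exceptions import ConfigurationError, ContractError

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "respiratory": (0.1, 0.6),
    "cardiac": (0.75, 2.0),
    "harmonic": (2.0, 7.0),
}

WINDOWS = ("rect", "hann")


@dataclass
class SpectralMap:
    """One-sided power vs (frequency bin, column) for one signal, px^2 units."""

    power: np.ndarray  # (n_bins, width)
    freqs: np.ndarray  # (n_bins,) Hz, freqs[0] = 0
    signal_label: str  # "cornea" | "iris" | "depth"
    n_frames: int = 0  # temporal length the map was computed from

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class AveragedSpectrum:
    """Per-bin mean of a spectral map over columns."""

    power: np.ndarray
    freqs: np.ndarray
    signal_label: str = ""


@dataclass(frozen=True)
class Peak:
    frequency: float  # Hz
    power: float  # px^2
    band: str  # respiratory | cardiac | harmonic | other


@dataclass
class PeakSet:
    peaks: list[Peak]
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def by_band(self, band: str) -> list[Peak]:
        return [p for p in self.peaks if p.band == band]


def parseval_weights(n_bins: int, n_frames: int) -> np.ndarray:
    """Folding weights: 1 for DC and (even n) Nyquist, 2 for interior bins."""
    w = np.full(n_bins, 2.0)
    w[0] = 1.0
    if n_frames % 2 == 0:
        w[-1] = 1.0
    return w


def power_spectrum_map(series, window: str = "rect") -> SpectralMap:
    """One-sided temporal power spectrum of every column of a series.

    The series must already be detrended (mean removal at minimum).  The
    window ('rect' or 'hann') is compensated for coherent gain so both read
    a sinusoid's peak as amplitude^2/4 at an exact bin.
    """
    if window not in WINDOWS:
        raise ConfigurationError(f"unknown window {window!r} (use {'|'.join(WINDOWS)})")
    v = np.asarray(series.values, dtype=float)
    n = v.shape[1]
    if n < 4:
        raise ValueError(f"need at least 4 frames for a spectrum; got {n}")
    mu = v.mean(axis=1)
    rms = np.sqrt((v**2).mean(axis=1))
    # absolute floor keeps numerically-zero columns (constant input after
    # detrending) from tripping the relative check
    bad = (np.abs(mu) > 1e-6 * rms) & (np.abs(mu) > 1e-9)
    if np.any(bad):
        x = int(np.flatnonzero(bad)[0])
        raise ContractError(
            f"series not detrended: column {x} has |temporal mean| {abs(mu[x]):.3g} "
            f"> 1e-6 x RMS {rms[x]:.3g}"
        )
    if window == "rect":
        w = np.ones(n)
    else:
        w = _windows.hann(n, sym=False)
        w = w / w.mean()  # coherent-gain compensation
    F = np.fft.rfft(v * w[None, :], axis=1)  # (width, n_bins)
    power = (np.abs(F) ** 2) / float(n) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / series.frame_rate)
    label = getattr(series, "label", "signal")
    return SpectralMap(power=power.T, freqs=freqs, signal_label=label, n_frames=n)


def average_spectrum(spectral_map: SpectralMap) -> AveragedSpectrum:
    """Arithmetic mean of the spectral map over columns, per frequency bin."""
    return AveragedSpectrum(
        power=spectral_map.power.mean(axis=1),
        freqs=spectral_map.freqs,
        signal_label=spectral_map.signal_label,
    )


def _refine_parabolic(power: np.ndarray, freqs: np.ndarray, k: int) -> float:
    """Sub-bin frequency by 3-point parabolic interpolation in log-power."""
    if k <= 0 or k >= power.size - 1:
        return float(freqs[k])
    p = power[k - 1 : k + 2]
    # a negligible neighbour (e.g. the DC bin after mean detrending) makes the
    # log-parabola degenerate; report the bin centre instead
    if np.any(p <= 0) or p.min() < 1e-9 * p[1]:
        return float(freqs[k])
    y = np.log(p)
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0:
        return float(freqs[k])
    delta = float(np.clip(0.5 * (y[0] - y[2]) / denom, -0.5, 0.5))
    df = freqs[1] - freqs[0]
    return float(freqs[k] + delta * df)


def detect_peaks(
    spectrum: AveragedSpectrum,
    bands: dict[str, tuple[float, float]] | None = None,
    subbin: str = "parabolic",
    min_rel_power: float = 0.05,
) -> PeakSet:
    """Strict local maxima of the averaged spectrum, labelled by band.

    For the respiratory and cardiac bands only the highest local maximum is
    reported; other bands (e.g. the harmonic band) keep every local maximum
    whose power is at least ``min_rel_power`` of that band's top peak.  The
    DC bin is never eligible; with ``subbin='parabolic'`` the reported
    frequency is refined by 3-point parabolic interpolation in log-power.
    """
    if subbin not in ("none", "parabolic"):
        raise ConfigurationError(f"unknown subbin mode {subbin!r}")
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    p = np.asarray(spectrum.power, dtype=float)
    f = np.asarray(spectrum.freqs, dtype=float)
    nyq = f[-1]
    for name, (lo, hi) in bands.items():
        if not (0.0 < lo < hi):
            raise ConfigurationError(f"band {name!r} edges must satisfy 0 < lo < hi; got ({lo}, {hi})")
    interior = np.arange(1, p.size - 1)
    is_max = (p[interior] > p[interior - 1]) & (p[interior] > p[interior + 1])
    maxima = interior[is_max]
    peaks: list[Peak] = []
    for name, (lo, hi) in bands.items():
        hi = min(hi, nyq + 1e-12)
        in_band = maxima[(f[maxima] >= lo) & (f[maxima] < hi)]
        if in_band.size == 0:
            continue
        if name in ("respiratory", "cardiac"):
            chosen = [in_band[int(np.argmax(p[in_band]))]]
        else:
            top = p[in_band].max()
            chosen = [k for k in in_band if p[k] >= min_rel_power * top]
        for k in sorted(chosen):
            freq = _refine_parabolic(p, f, int(k)) if subbin == "parabolic" else float(f[k])
            peaks.append(Peak(frequency=freq, power=float(p[k]), band=name))
    peaks.sort(key=lambda pk: pk.frequency)
    return PeakSet(peaks=peaks, bands=bands)


def estimate_fundamental(
    peaks: PeakSet, tolerance_hz: float = 0.15
) -> tuple[float, list[int | None]]:
    """Cardiac fundamental that best explains the peak comb as harmonics.

    Candidates are every peak frequency divided by an integer, kept when the
    quotient falls in the cardiac band; the winner maximizes the number of
    peaks lying within ``tolerance_hz`` of an integer multiple of it (ties:
    lowest candidate).  Returns the fundamental and, per peak, its harmonic
    order k (None when the peak is not within tolerance of k x fundamental).
    If no candidate explains at least two peaks, the cardiac-band peak is
    returned alone with all flags None.
    """
    lo, hi = peaks.bands.get("cardiac", DEFAULT_BANDS["cardiac"])
    freqs = [pk.frequency for pk in peaks.peaks]
    if not freqs:
        raise ValueError("PeakSet is empty: need at least one cardiac- or harmonic-band peak")
    candidates: list[float] = []
    for fpk in freqs:
        k_min = max(1, int(np.ceil(fpk / hi)))
        k_max = max(k_min, int(np.floor(fpk / lo)))
        for k in range(k_min, k_max + 1):
            f0 = fpk / k
            if lo <= f0 < hi:
                candidates.append(f0)
    cardiac_peaks = peaks.by_band("cardiac")
    fallback = cardiac_peaks[0].frequency if cardiac_peaks else None

    def orders_for(f0: float) -> list[int | None]:
        out: list[int | None] = []
        for fpk in freqs:
            k = max(1, int(round(fpk / f0)))
            out.append(k if abs(fpk - k * f0) <= tolerance_hz else None)
        return out

    best_f0, best_orders, best_count = None, None, -1
    for f0 in sorted(set(candidates)):
        orders = orders_for(f0)
        count = sum(o is not None for o in orders)
        if count > best_count:
            best_f0, best_orders, best_count = f0, orders, count
    if best_count < 2:
        if fallback is None:
            if best_f0 is None:
                raise ValueError("no cardiac-band candidate fundamental")
            return best_f0, [None] * len(freqs)
        return fallback, [None] * len(freqs)
    assert best_f0 is not None and best_orders is not None
    return best_f0, best_orders


def spectral_map_to_dataframe(spectral_map: SpectralMap) -> pd.DataFrame:
    """Long-format export: (frequency, column, power)."""
    n_bins, width = spectral_map.power.shape
    k, x = np.meshgrid(np.arange(n_bins), np.arange(width), indexing="ij")
    return pd.DataFrame(
        {
            "frequency": spectral_map.freqs[k.ravel()],
            "column": x.ravel(),
            "power": spectral_map.power.ravel(),
        }
    )


def averaged_spectrum_to_dataframe(spectrum: AveragedSpectrum) -> pd.DataFrame:
    return pd.DataFrame({"frequency": spectrum.freqs, "power": spectrum.power})
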