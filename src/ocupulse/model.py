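"""Model/Results façade over the analysis pipeline.

:class:`OcularPulseModel` binds a B-scan sequence to the analysis settings;
``fit()`` runs preprocessing, surface segmentation, depth dynamics and
spectral analysis, returning an :class:`OcularPulseResults` that carries the
position series, spectra, detected physiological peaks, the estimated
cardiac fundamental and a ``summary()`` table — in the spirit of the
model/results split used by statistical modelling packages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import dynamics, scan_io, segmentation, spectral
from .config import RunConfig
from .preprocess import RoiSpec, crop_rotate, denoise
from .scan_io import BScanSequence

SIGNALS = ("cornea", "iris", "depth")


class OcularPulseModel:
    """Pulsatile-microfluctuation analysis of an anterior-segment B-scan sequence.

    Parameters mirror :class:`~ocupulse.config.RunConfig`; ``zones=None``
    auto-initializes the cornea/iris search zones from frame 0.

    Examples
    --------
    >>> from ocupulse.config import load_fixture
    >>> from ocupulse.synthetic_scan import generate_sequence
    >>> fx = load_fixture("subject_default")
    >>> seq, gt = generate_sequence(fx.geometry, fx.motion, fx.noise,
    ...                             fx.n_frames, fx.frame_rate, seed=42)
    >>> res = OcularPulseModel(seq).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, sequence: BScanSequence, *, config: RunConfig | None = None, **overrides: Any):
        config = RunConfig() if config is None else RunConfig.from_dict(config.to_dict())
        for key, value in overrides.items():
            if not hasattr(config, key):
                raise TypeError(f"unknown analysis setting {key!r}")
            setattr(config, key, value)
        self.sequence = sequence
        self.config = config

    @classmethod
    def from_path(cls, path: str | Path, **kwargs: Any) -> "OcularPulseModel":
        """Build a model from a sequence on disk (TIFF stack or frame directory)."""
        return cls(scan_io.read_sequence(path), **kwargs)

    def fit(self) -> "OcularPulseResults":
        """Run the full pipeline and return the fitted results."""
        cfg = self.config
        seq = self.sequence
        if cfg.roi is not None:
            seq = crop_rotate(seq, cfg.roi if isinstance(cfg.roi, RoiSpec) else RoiSpec(**cfg.roi))
        if cfg.denoise_method != "none":
            seq = denoise(seq, cfg.denoise_method, cfg.denoise_radius)
        zones = cfg.zones
        if zones is None:
            zones = segmentation.initialize_zones(
                seq.frames[0], smooth_sigma=cfg.smooth_sigma, dilate=cfg.zone_dilate
            )
        traces = []
        for frame in seq.frames:
            edges_c = segmentation.detect_edges(frame, cfg.smooth_sigma, "bright_to_dark")
            edges_i = segmentation.detect_edges(frame, cfg.smooth_sigma, "dark_to_bright")
            traces.append(
                segmentation.trace_surfaces(frame, edges_c, edges_i, zones, cfg.min_confidence)
            )
        column_range = segmentation.select_valid_range(traces, min_width=cfg.min_width)
        cornea, iris = dynamics.build_series(traces, column_range, seq.frame_rate)
        depth = dynamics.compute_depth(cornea, iris)
        series = {"cornea": cornea, "iris": iris, "depth": depth}
        detrended = {k: dynamics.detrend(s, cfg.detrend_mode) for k, s in series.items()}
        bands = {k: tuple(v) for k, v in cfg.bands.items()}
        maps, avg, peak_sets, fundamentals = {}, {}, {}, {}
        for name, s in detrended.items():
            m = spectral.power_spectrum_map(s, window=cfg.window)
            a = spectral.average_spectrum(m)
            ps = spectral.detect_peaks(a, bands=bands, subbin=cfg.subbin)
            maps[name], avg[name], peak_sets[name] = m, a, ps
            try:
                fundamentals[name] = spectral.estimate_fundamental(
                    ps, tolerance_hz=cfg.fundamental_tolerance_hz
                )
            except ValueError:
                fundamentals[name] = None
        return OcularPulseResults(
            model=self,
            preprocessed=seq,
            zones=zones,
            traces=traces,
            column_range=column_range,
            series=series,
            detrended=detrended,
            spectral_maps=maps,
            averaged_spectra=avg,
            peak_sets=peak_sets,
            fundamentals=fundamentals,
        )


@dataclass
class OcularPulseResults:
    """Fitted pipeline outputs for one sequence."""

    model: OcularPulseModel
    preprocessed: BScanSequence
    zones: tuple[tuple[int, int], tuple[int, int]]
    traces: list
    column_range: segmentation.ColumnRange
    series: dict[str, Any]
    detrended: dict[str, Any]
    spectral_maps: dict[str, spectral.SpectralMap]
    averaged_spectra: dict[str, spectral.AveragedSpectrum]
    peak_sets: dict[str, spectral.PeakSet]
    fundamentals: dict[str, tuple[float, list] | None] = field(default_factory=dict)

    @property
    def cornea_series(self):
        return self.series["cornea"]

    @property
    def iris_series(self):
        return self.series["iris"]

    @property
    def depth_series(self):
        return self.series["depth"]

    def peak_frequency(self, signal: str, band: str) -> float | None:
        """Frequency (Hz) of the reported peak of ``band`` for ``signal``."""
        for pk in self.peak_sets[signal].peaks:
            if pk.band == band:
                return pk.frequency
        return None

    def summary(self) -> str:
        """Human-readable overview of the fitted quantities."""
        seq = self.preprocessed
        cfg = self.model.config
        lines = [
            "Ocular pulsatile microfluctuation analysis",
            "=" * 58,
            f"frames: {seq.n_frames}   frame rate: {seq.frame_rate:g} Hz   "
            f"duration: {seq.duration:.2f} s",
            f"frame size: {seq.n_rows} x {seq.n_cols} px   "
            f"window: {cfg.window}   detrend: {cfg.detrend_mode}",
            f"search zones (rows): cornea {self.zones[0]}, iris {self.zones[1]}",
            f"valid column range: [{self.column_range.start}, {self.column_range.stop}) "
            f"({self.column_range.width} columns)",
            f"mean depth D: {self.depth_series.values.mean():.2f} px",
            "",
            f"{'signal':8s} {'band':12s} {'freq (Hz)':>10s} {'power (px^2)':>13s}",
            "-" * 48,
        ]
        for name in SIGNALS:
            for pk in self.peak_sets[name].peaks:
                lines.append(f"{name:8s} {pk.band:12s} {pk.frequency:10.3f} {pk.power:13.4g}")
        lines.append("")
        for name in SIGNALS:
            fund = self.fundamentals.get(name)
            if fund is None:
                continue
            f0, orders = fund
            ks = sorted({k for k in orders if k is not None})
            lines.append(
                f"{name}: cardiac fundamental {f0:.3f} Hz"
                + (f", harmonic orders {ks}" if ks else "")
            )
        return "\n".join(lines)

    def peaks_record(self) -> dict:
        """JSON-serializable record of peaks and fundamentals per signal."""
        rec: dict[str, Any] = {}
        for name in SIGNALS:
            ps = self.peak_sets[name]
            entry: dict[str, Any] = {
                "peaks": [
                    {"frequency": pk.frequency, "power": pk.power, "band": pk.band}
                    for pk in ps.peaks
                ],
                "bands": {k: list(v) for k, v in ps.bands.items()},
            }
            fund = self.fundamentals.get(name)
            if fund is not None:
                f0, orders = fund
                entry["fundamental_hz"] = f0
                entry["harmonic_orders"] = [o for o in orders]
            rec[name] = entry
        return rec
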