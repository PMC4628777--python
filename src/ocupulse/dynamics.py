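"""Per-column temporal position signals and the inter-surface depth D.

Within the selected column range, the traced sub-pixel rows of each surface
are assembled into an (x, t) matrix — no interpolation or smoothing — and
the depth D of the cornea-iris gap is their elementwise difference in
pixels.  Detrending (mean or linear) prepares the signals for spectral
analysis so the DC component and slow drift do not mask physiological peaks.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InternalConsistencyError, OrderingViolationError
from .segmentation import ColumnRange, SurfaceTrace


@dataclass
class SurfaceSeries:
    """Sub-pixel axial position of one surface: values[x, t] in px."""

    values: np.ndarray  # (width, n_frames)
    frame_rate: float
    label: str  # "cornea" | "iris"


@dataclass
class DepthSeries:
    """Inter-surface gap D: values[x, t] in px (positive when raw)."""

    values: np.ndarray  # (width, n_frames)
    frame_rate: float
    label: str = "depth"


def build_series(
    traces: Sequence[tuple[SurfaceTrace, SurfaceTrace]],
    column_range: ColumnRange,
    frame_rate: float,
) -> tuple[SurfaceSeries, SurfaceSeries]:
    """Stack per-frame traces into (x, t) matrices over ``column_range``.

    Every column of the range must be valid in every frame — guaranteed when
    the range comes from :func:`~ocupulse.segmentation.select_valid_range`.
    """
    sl = column_range.slice
    width = column_range.width
    n_frames = len(traces)
    cornea = np.empty((width, n_frames))
    iris = np.empty((width, n_frames))
    for t, (ct, it) in enumerate(traces):
        if not (ct.valid[sl].all() and it.valid[sl].all()):
            bad = int(np.flatnonzero(~(ct.valid[sl] & it.valid[sl]))[0]) + column_range.start
            raise InternalConsistencyError(
                f"column {bad} inside the selected range is invalid in frame {t}; "
                "range selection contract broken"
            )
        cornea[:, t] = ct.rows[sl]
        iris[:, t] = it.rows[sl]
    return (
        SurfaceSeries(cornea, frame_rate, label="cornea"),
        SurfaceSeries(iris, frame_rate, label="iris"),
    )


def compute_depth(cornea: SurfaceSeries, iris: SurfaceSeries) -> DepthSeries:
    """Depth D = iris - cornea, elementwise in px; strictly positive."""
    if cornea.values.shape != iris.values.shape:
        raise ValueError(
            f"shape mismatch: cornea {cornea.values.shape} vs iris {iris.values.shape}"
        )
    if cornea.frame_rate != iris.frame_rate:
        raise ValueError("frame_rate mismatch between surface series")
    depth = iris.values - cornea.values
    if np.any(depth <= 0):
        x, t = np.unravel_index(int(np.argmin(depth)), depth.shape)
        raise OrderingViolationError(
            f"non-positive depth D={depth[x, t]:.3f} px at (x={x}, t={t}): iris not below cornea"
        )
    return DepthSeries(depth, cornea.frame_rate)


def detrend(series, mode: str = "mean"):
    """Remove the per-column temporal mean (``mean``) or least-squares line (``linear``).

    Returns a new series of the same type; idempotent for its own mode.
    """
    v = series.values
    n = v.shape[1]
    if mode == "mean":
        if n < 2:
            raise ValueError("mean detrend needs at least 2 frames")
        out = v - v.mean(axis=1, keepdims=True)
    elif mode == "linear":
        if n < 3:
            raise ValueError("linear detrend needs at least 3 frames")
        t = np.arange(n, dtype=float)
        tc = t - t.mean()
        slope = (v @ tc) / (tc @ tc)
        out = v - v.mean(axis=1, keepdims=True) - slope[:, None] * tc[None, :]
    else:
        raise ValueError(f"unknown detrend mode {mode!r} (use mean|linear)")
    return dataclasses.replace(series, values=out)


def series_to_dataframe(series) -> pd.DataFrame:
    """Long-format export: (column, frame, value)."""
    width, n_frames = series.values.shape
    x, t = np.meshgrid(np.arange(width), np.arange(n_frames), indexing="ij")
    return pd.DataFrame(
        {"column": x.ravel(), "frame": t.ravel(), "value": series.values.ravel()}
    )
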