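"""Region-of-interest selection, rotation and optional denoising.

One ROI and rotation is applied to every frame of a sequence, mirroring the
semiautomatic workflow in which the operator picks the area of interest once
and the cornea is rotated into the upper part of the image.  Keeping a
single spec per sequence preserves column identity across frames, which the
temporal analysis relies on.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import rotate as _sk_rotate

from .exceptions import ConfigurationError
from .scan_io import BScanSequence


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest: half-open 0-based ranges plus a rotation.

    ``rotation_deg`` is counter-clockwise positive, applied about the ROI
    centre with bilinear interpolation before cropping.
    """

    row_range: tuple[int, int]
    col_range: tuple[int, int]
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        if not (r1 > r0 and c1 > c0):
            raise ValueError(f"empty ROI: rows [{r0},{r1}), cols [{c0},{c1})")


def crop_rotate(seq: BScanSequence, roi: RoiSpec) -> BScanSequence:
    """Rotate every frame about the ROI centre, then crop to the ROI."""
    r0, r1 = roi.row_range
    c0, c1 = roi.col_range
    if r0 < 0 or c0 < 0 or r1 > seq.n_rows or c1 > seq.n_cols:
        raise ValueError(
            f"ROI rows [{r0},{r1}) cols [{c0},{c1}) exceeds frame bounds "
            f"{seq.n_rows}x{seq.n_cols}"
        )
    if roi.rotation_deg == 0.0:
        out = seq.frames[:, r0:r1, c0:c1].copy()
    else:
        centre = ((c0 + c1 - 1) / 2.0, (r0 + r1 - 1) / 2.0)  # (col, row)
        out = np.empty((seq.n_frames, r1 - r0, c1 - c0))
        for j in range(seq.n_frames):
            rot = _sk_rotate(
                seq.frames[j], roi.rotation_deg, center=centre,
                order=1, mode="edge", preserve_range=True,
            )
            out[j] = rot[r0:r1, c0:c1]
    return BScanSequence(out, seq.frame_rate, source_id=seq.source_id)


def denoise(seq: BScanSequence, method: str = "none", radius: float = 1.0) -> BScanSequence:
    """Frame-wise denoising: ``none`` (identity), ``median`` or ``gaussian``.

    ``radius`` is the median footprint radius or the Gaussian sigma, in px.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0; got {radius}")
    if method == "none":
        return seq
    if method == "median":
        if radius == 0:
            return seq
        footprint = disk(int(round(radius))).astype(bool)
        out = np.stack([ndimage.median_filter(f, footprint=footprint) for f in seq.frames])
    elif method == "gaussian":
        if radius == 0:
            return seq
        out = np.stack([ndimage.gaussian_filter(f, sigma=radius) for f in seq.frames])
    else:
        raise ConfigurationError(f"unknown denoise method {method!r} (use none|median|gaussian)")
    return dataclasses.replace(seq, frames=out)
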