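"""Reading and writing B-scan sequences with acquisition metadata.

A sequence lives on disk as a 16-bit grayscale multipage TIFF (or a
directory of lexicographically ordered PNG/TIFF frames) accompanied by a
JSON sidecar ``<name>.meta.json`` that carries the frame rate.  Metadata is
kept in a sidecar rather than TIFF tags so that it is bit-exact,
human-inspectable and immune to TIFF dialect quirks.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

from .exceptions import DimensionMismatchError, MetadataError

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class BScanSequence:
    """An ordered stack of grayscale B-scan frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, n_rows, n_cols)
        Intensities in [0, 1]; row index increases downward (axial depth).
    frame_rate : float
        Acquisition rate in Hz.
    source_id : str
        Free-text provenance label.
    """

    frames: np.ndarray
    frame_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise DimensionMismatchError(
                f"frames must be a 3-d stack (n_frames, n_rows, n_cols); got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError(f"a sequence needs at least 2 frames; got {self.frames.shape[0]}")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive; got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_rows(self) -> int:
        return self.frames.shape[1]

    @property
    def n_cols(self) -> int:
        return self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Sequence duration in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate


def sidecar_path(path: Path | str) -> Path:
    """Path of the JSON metadata sidecar for a sequence file or directory."""
    return Path(path).with_suffix(".meta.json")


def write_sequence(seq: BScanSequence, path: Path | str) -> None:
    """Write ``seq`` as a 16-bit grayscale multipage TIFF plus JSON sidecar.

    Output bytes are deterministic for identical input.
    """
    path = Path(path)
    arr = np.round(np.clip(seq.frames, 0.0, 1.0) * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "frame_rate": seq.frame_rate,
        "n_frames": seq.n_frames,
        "n_rows": seq.n_rows,
        "n_cols": seq.n_cols,
        "source_id": seq.source_id,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _rescale(img: np.ndarray, name: str) -> np.ndarray:
    if img.ndim != 2:
        raise DimensionMismatchError(f"{name}: expected a 2-d grayscale frame; got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return img.astype(float) / float(info.max)
    return img.astype(float)


def _read_meta(path: Path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists() and path.is_dir():
        sp = path / "meta.json"
    if not sp.exists():
        raise MetadataError(f"missing metadata sidecar for {path} (expected {sidecar_path(path)})")
    try:
        meta = json.loads(sp.read_text())
    except json.JSONDecodeError as e:
        raise MetadataError(f"invalid JSON in sidecar {sp}: {e}") from e
    if "frame_rate" not in meta:
        raise MetadataError(f"sidecar {sp} lacks required key 'frame_rate'")
    fr = meta["frame_rate"]
    if not isinstance(fr, (int, float)) or not fr > 0:
        raise MetadataError(f"sidecar {sp}: frame_rate must be a positive number; got {fr!r}")
    return meta


def read_sequence(path: Path | str) -> BScanSequence:
    """Read a B-scan sequence from a multipage TIFF or a frame directory.

    Integer intensities are rescaled to [0, 1] by the container bit depth.
    Frame order is TIFF page order, or lexicographic file-name order for a
    directory.  A missing or invalid sidecar is an error, never a default.
    """
    path = Path(path)
    meta = _read_meta(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise IOError(f"no PNG/TIFF frames found in directory {path}")
        frames = []
        for p in files:
            try:
                img = iio.imread(p)
            except Exception as e:  # noqa: BLE001 - rewrap with the offending frame name
                raise IOError(f"cannot read frame {p}: {e}") from e
            frames.append(_rescale(np.asarray(img), p.name))
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise DimensionMismatchError(f"frames in {path} have mixed sizes: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            stack = tifffile.imread(path)
        except Exception as e:  # noqa: BLE001
            raise IOError(f"cannot read TIFF {path}: {e}") from e
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise DimensionMismatchError(f"{path}: expected grayscale pages; got shape {stack.shape}")
        if np.issubdtype(stack.dtype, np.integer):
            info = np.iinfo(stack.dtype)
            stack = stack.astype(float) / float(info.max)
        else:
            stack = stack.astype(float)
    if stack.shape[0] < 2:
        raise ValueError(f"{path}: a sequence needs at least 2 frames; got {stack.shape[0]}")
    n_frames = meta.get("n_frames")
    if n_frames is not None and n_frames != stack.shape[0]:
        raise MetadataError(
            f"sidecar says n_frames={n_frames} but {stack.shape[0]} frames were read from {path}"
        )
    return BScanSequence(stack, float(meta["frame_rate"]), source_id=str(meta.get("source_id", path.name)))
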