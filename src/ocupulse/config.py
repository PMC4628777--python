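"""Run configuration and named simulator fixtures.

A :class:`RunConfig` gathers every tunable of the analysis pipeline with its
default; it round-trips losslessly through YAML.  Simulator fixtures are
YAML files bundling geometry, motion, noise and acquisition parameters;
``subject_default`` and ``motion_subject3`` ship with the package.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .preprocess import RoiSpec
from .spectral import DEFAULT_BANDS
from .synthetic_scan import (
    Breathing,
    Cardiac,
    IrisStep,
    LateralDrift,
    MotionSpec,
    NoiseSpec,
    ScanGeometry,
)

BUILTIN_FIXTURES = ("subject_default", "motion_subject3")


@dataclass
class SimFixture:
    """A complete simulator configuration."""

    geometry: ScanGeometry
    motion: MotionSpec
    noise: NoiseSpec
    n_frames: int = 90
    frame_rate: float = 22.7


def _geometry_from_dict(d: dict) -> ScanGeometry:
    d = dict(d)
    step = d.pop("iris_step", None)
    if step is not None:
        step = IrisStep(step_col=int(step["step_col"]), step_height=float(step["step_height"]))
    return ScanGeometry(iris_step=step, **d)


def _motion_from_dict(d: dict) -> MotionSpec:
    d = dict(d)
    breathing = Breathing(**d.pop("breathing", {}))
    card = dict(d.pop("cardiac", {}))
    if "harmonic_amplitudes" in card:
        card["harmonic_amplitudes"] = tuple(float(a) for a in card["harmonic_amplitudes"])
    cardiac = Cardiac(**card)
    drift = LateralDrift(**d.pop("lateral_drift", {}))
    return MotionSpec(breathing=breathing, cardiac=cardiac, lateral_drift=drift, **d)


def load_fixture(name_or_path: str | Path) -> SimFixture:
    """Load a simulator fixture by built-in name or YAML file path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    elif str(name_or_path) in BUILTIN_FIXTURES:
        text = resources.files("ocupulse.fixtures").joinpath(f"{name_or_path}.yaml").read_text()
    else:
        raise ConfigurationError(
            f"unknown fixture {name_or_path!r}: not a YAML file and not one of {BUILTIN_FIXTURES}"
        )
    raw = yaml.safe_load(text)
    try:
        acq = raw.get("acquisition", {})
        return SimFixture(
            geometry=_geometry_from_dict(raw.get("geometry", {})),
            motion=_motion_from_dict(raw.get("motion", {})),
            noise=NoiseSpec(**raw.get("noise", {})),
            n_frames=int(acq.get("n_frames", 90)),
            frame_rate=float(acq.get("frame_rate", 22.7)),
        )
    except (TypeError, KeyError, ValueError) as e:
        raise ConfigurationError(f"invalid fixture {name_or_path}: {e}") from e


@dataclass
class RunConfig:
    """All analysis-pipeline settings; every field but ``input`` has a default."""

    input: str = ""
    roi: RoiSpec | None = None
    denoise_method: str = "none"
    denoise_radius: float = 1.0
    smooth_sigma: float = 1.5
    zones: tuple[tuple[int, int], tuple[int, int]] | None = None  # None = auto from frame 0
    zone_dilate: int = 12
    min_confidence: float = 0.3
    min_width: int = 16
    detrend_mode: str = "mean"
    window: str = "rect"
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    subbin: str = "parabolic"
    fundamental_tolerance_hz: float = 0.15
    seed: int = 0
    out_dir: str = "ocupulse_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.roi is not None:
            d["roi"] = {
                "row_range": list(self.roi.row_range),
                "col_range": list(self.roi.col_range),
                "rotation_deg": self.roi.rotation_deg,
            }
        if self.zones is not None:
            d["zones"] = [list(z) for z in self.zones]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        roi = d.get("roi")
        if roi is not None:
            d["roi"] = RoiSpec(
                row_range=tuple(roi["row_range"]),
                col_range=tuple(roi["col_range"]),
                rotation_deg=float(roi.get("rotation_deg", 0.0)),
            )
        zones = d.get("zones")
        if zones is not None:
            d["zones"] = tuple(tuple(int(v) for v in z) for z in zones)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
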