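"""Synthetic anterior-segment B-scan sequences with known ground truth.

The simulator renders the iridocorneal region as two tissue bands on a dark
background: a corneal band whose posterior boundary is a quadratic profile,
and an iris region whose anterior boundary is a sloped (optionally stepped)
profile that runs to the bottom of the frame.  The cornea is rendered dimmer
than the iris, reproducing the lower corneal signal-to-noise ratio seen in
anterior-segment OCT.  Both structures move axially with a shared pulsatile
signal — a respiratory sinusoid plus a cardiac fundamental with harmonics —
scaled by per-structure gains, and the whole scene may drift laterally.
Speckle is modelled as per-pixel multiplicative gamma noise inside the
tissue bands, the standard coherent-imaging approximation.

Boundaries are anti-aliased by linear partial-pixel coverage so that the
sub-pixel ground truth returned alongside every sequence is meaningful for
segmentation-accuracy tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import BoundaryCrossingError
from .scan_io import BScanSequence

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class IrisStep:
    """Step-like relief on the anterior iris surface.

    Columns at and beyond ``step_col`` are displaced by ``step_height`` pixels
    (negative raises the surface toward the cornea).
    """

    step_col: int
    step_height: float


@dataclass(frozen=True)
class ScanGeometry:
    """Static geometry of the rendered field, in pixel units.

    Row 0 is the top of the frame; rows increase with depth.  The posterior
    corneal boundary is ``cornea_apex_row + cornea_curvature * (x - xc)^2``
    (``xc`` = centre column); the anterior iris boundary is
    ``iris_base_row + iris_slope * x`` plus the optional step.
    """

    n_rows: int = 200
    n_cols: int = 160
    cornea_apex_row: float = 40.0
    cornea_thickness: float = 12.0
    cornea_curvature: float = 0.002
    iris_base_row: float = 120.0
    iris_slope: float = 0.15
    iris_step: IrisStep | None = None
    band_intensity_cornea: float = 0.25
    band_intensity_iris: float = 0.55
    background_intensity: float = 0.05

    def __post_init__(self) -> None:
        if self.n_rows < 32 or self.n_cols < 16:
            raise ValueError(f"frame too small: {self.n_rows}x{self.n_cols} (need >= 32x16)")
        if not (0.0 < self.band_intensity_cornea < self.band_intensity_iris <= 1.0):
            raise ValueError(
                "band intensities must satisfy 0 < cornea < iris <= 1 "
                f"(got cornea={self.band_intensity_cornea}, iris={self.band_intensity_iris})"
            )
        if not (0.0 <= self.background_intensity < self.band_intensity_cornea):
            raise ValueError("background intensity must lie below the corneal band intensity")
        if self.cornea_thickness <= 0:
            raise ValueError("cornea_thickness must be positive")
        x = np.arange(self.n_cols, dtype=float)
        gap = self.iris_anterior_profile(x) - self.cornea_posterior_profile(x)
        if np.any(gap <= 0):
            raise ValueError("static geometry has no positive cornea-iris gap in some column")

    def cornea_posterior_profile(self, x: np.ndarray) -> np.ndarray:
        """Row of the posterior corneal boundary at (possibly fractional) column x."""
        xc = 0.5 * (self.n_cols - 1)
        return self.cornea_apex_row + self.cornea_curvature * (np.asarray(x, float) - xc) ** 2

    def iris_anterior_profile(self, x: np.ndarray) -> np.ndarray:
        """Row of the anterior iris boundary at (possibly fractional) column x."""
        x = np.asarray(x, float)
        rows = self.iris_base_row + self.iris_slope * x
        if self.iris_step is not None:
            rows = rows + np.where(x >= self.iris_step.step_col, self.iris_step.step_height, 0.0)
        return rows


@dataclass(frozen=True)
class Breathing:
    frequency: float = 0.25  # Hz
    amplitude: float = 2.0  # px
    phase: float = 0.0  # rad


@dataclass(frozen=True)
class Cardiac:
    frequency: float = 1.25  # Hz, fundamental
    phase: float = 0.0  # rad, shared by all harmonics
    harmonic_amplitudes: tuple[float, ...] = (1.0,)  # px, one per multiple k=1,2,...


@dataclass(frozen=True)
class LateralDrift:
    amplitude: float = 0.0  # px
    frequency: float = 0.0  # Hz


@dataclass(frozen=True)
class MotionSpec:
    """Pulsatile motion: a common axial signal scaled per structure.

    The common signal is
    ``s(t) = A_b sin(2π f_b t + φ_b) + Σ_k A_k sin(2π k f_c t + φ_c)``;
    the cornea moves by ``cornea_gain * s(t)`` and the iris by
    ``iris_gain * s(t)``.  Lateral drift is a slow sinusoidal shift of the
    whole scene.
    """

    breathing: Breathing = field(default_factory=Breathing)
    cardiac: Cardiac = field(default_factory=Cardiac)
    cornea_gain: float = 1.0
    iris_gain: float = 1.0
    lateral_drift: LateralDrift = field(default_factory=LateralDrift)

    def __post_init__(self) -> None:
        if self.breathing.frequency < 0 or self.cardiac.frequency < 0 or self.lateral_drift.frequency < 0:
            raise ValueError("frequencies must be >= 0")
        if (
            self.breathing.amplitude < 0
            or any(a < 0 for a in self.cardiac.harmonic_amplitudes)
            or self.lateral_drift.amplitude < 0
        ):
            raise ValueError("amplitudes must be >= 0")
        if self.cornea_gain <= 0 or self.iris_gain <= 0:
            raise ValueError("cornea_gain and iris_gain must be positive")

    @property
    def highest_frequency(self) -> float:
        """Highest injected axial frequency (Hz), for aliasing checks."""
        n_h = len(self.cardiac.harmonic_amplitudes)
        return max(self.breathing.frequency, self.cardiac.frequency * n_h)

    @property
    def max_axial_amplitude(self) -> float:
        return self.breathing.amplitude + sum(self.cardiac.harmonic_amplitudes)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: multiplicative gamma speckle plus additive Gaussian.

    ``speckle_looks`` is the gamma shape parameter (number of incoherent
    looks); larger values give smoother speckle, ``None`` disables it.
    """

    speckle_looks: int | None = 4
    additive_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1 (or None to disable)")
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be >= 0")


@dataclass
class GroundTruth:
    """True sub-pixel surface positions for every (column, frame).

    ``depth[x, t] = iris_rows[x, t] - cornea_rows[x, t]`` is the gap D in
    pixels, the quantity the analysis pipeline estimates.
    """

    cornea_rows: np.ndarray  # (n_cols, n_frames)
    iris_rows: np.ndarray  # (n_cols, n_frames)
    depth: np.ndarray  # (n_cols, n_frames)
    motion: MotionSpec
    geometry: ScanGeometry


def motion_displacement(motion: MotionSpec, t):
    """Axial cornea/iris and lateral displacements (px) at time ``t`` (s).

    ``t`` may be a scalar or an array; the result broadcasts accordingly.
    Deterministic in (motion, t).
    """
    t = np.asarray(t, dtype=float)
    b = motion.breathing
    s = b.amplitude * np.sin(TWO_PI * b.frequency * t + b.phase)
    c = motion.cardiac
    for k, amp in enumerate(c.harmonic_amplitudes, start=1):
        s = s + amp * np.sin(TWO_PI * k * c.frequency * t + c.phase)
    lat = motion.lateral_drift.amplitude * np.sin(TWO_PI * motion.lateral_drift.frequency * t)
    return motion.cornea_gain * s, motion.iris_gain * s, lat


def _coverage_below(boundary: np.ndarray, n_rows: int) -> np.ndarray:
    """Fraction of each pixel (row r, column x) lying below ``boundary[x]``.

    Linear partial-pixel coverage with pixel r centred at integer row r
    (cell [r-0.5, r+0.5)): the fraction below a boundary at row b is
    clip(r + 0.5 - b, 0, 1).  A boundary at an integer row therefore leaves
    that very pixel half-covered, so sub-pixel ground truth lives on the
    same grid the tracer samples.
    """
    r1 = np.arange(n_rows, dtype=float)[:, None] + 0.5
    return np.clip(r1 - boundary[None, :], 0.0, 1.0)


def render_frame(
    geometry: ScanGeometry,
    displacements: tuple[float, float, float],
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one anti-aliased, speckled frame at the given displacements.

    ``displacements`` is (d_axial_cornea, d_axial_iris, d_lateral) in px.
    """
    d_c, d_i, d_lat = (float(v) for v in displacements)
    if not all(np.isfinite([d_c, d_i, d_lat])):
        raise ValueError("displacements must be finite")
    if max(abs(d_c), abs(d_i)) >= geometry.n_rows / 4:
        raise ValueError(
            f"axial displacement {max(abs(d_c), abs(d_i)):.1f} px exceeds n_rows/4 = {geometry.n_rows / 4:.1f}"
        )
    # Lateral drift: evaluate the boundary profiles at shifted column
    # coordinates; profiles extend smoothly past the frame edge, which acts
    # as replicate padding for the rendered content.
    x = np.arange(geometry.n_cols, dtype=float) - d_lat
    p_cornea = geometry.cornea_posterior_profile(x) + d_c
    top_cornea = p_cornea - geometry.cornea_thickness
    q_iris = geometry.iris_anterior_profile(x) + d_i
    gap = q_iris - p_cornea
    if np.any(gap <= 0):
        col = int(np.argmin(gap))
        raise BoundaryCrossingError(
            f"displaced cornea ({p_cornea[col]:.2f}) not above iris ({q_iris[col]:.2f}) at column {col}"
        )
    cov_cornea = _coverage_below(top_cornea, geometry.n_rows) - _coverage_below(p_cornea, geometry.n_rows)
    cov_iris = _coverage_below(q_iris, geometry.n_rows)
    bg = geometry.background_intensity
    tissue = (geometry.band_intensity_cornea - bg) * cov_cornea + (geometry.band_intensity_iris - bg) * cov_iris
    if noise.speckle_looks is not None:
        looks = float(noise.speckle_looks)
        tissue = tissue * rng.gamma(looks, 1.0 / looks, size=tissue.shape)
    frame = bg + tissue
    if noise.additive_sigma > 0:
        frame = frame + rng.normal(0.0, noise.additive_sigma, size=frame.shape)
    return np.clip(frame, 0.0, 1.0)


def generate_sequence(
    geometry: ScanGeometry,
    motion: MotionSpec,
    noise: NoiseSpec,
    n_frames: int = 90,
    frame_rate: float = 22.7,
    seed: int = 0,
) -> tuple[BScanSequence, GroundTruth]:
    """Render a full sequence and its ground truth, reproducible from ``seed``.

    Frame t is rendered at time t / frame_rate.  Raises if the injected
    cardiac comb would alias (highest harmonic at or above Nyquist).
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2; got {n_frames}")
    if not frame_rate > 0:
        raise ValueError(f"frame_rate must be positive; got {frame_rate}")
    nyquist = frame_rate / 2.0
    n_h = len(motion.cardiac.harmonic_amplitudes)
    if motion.cardiac.frequency * n_h >= nyquist:
        raise ValueError(
            f"aliasing: cardiac harmonic {n_h} at {motion.cardiac.frequency * n_h:.2f} Hz "
            f"is at or above Nyquist ({nyquist:.2f} Hz)"
        )
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) / frame_rate
    d_c, d_i, d_lat = motion_displacement(motion, times)
    frames = np.empty((n_frames, geometry.n_rows, geometry.n_cols))
    cornea_rows = np.empty((geometry.n_cols, n_frames))
    iris_rows = np.empty((geometry.n_cols, n_frames))
    cols = np.arange(geometry.n_cols, dtype=float)
    for j in range(n_frames):
        try:
            frames[j] = render_frame(geometry, (d_c[j], d_i[j], d_lat[j]), noise, rng)
        except BoundaryCrossingError as e:
            raise BoundaryCrossingError(f"frame {j}: {e}") from e
        xs = cols - d_lat[j]
        cornea_rows[:, j] = geometry.cornea_posterior_profile(xs) + d_c[j]
        iris_rows[:, j] = geometry.iris_anterior_profile(xs) + d_i[j]
    gt = GroundTruth(
        cornea_rows=cornea_rows,
        iris_rows=iris_rows,
        depth=iris_rows - cornea_rows,
        motion=motion,
        geometry=geometry,
    )
    seq = BScanSequence(frames, frame_rate, source_id=f"synthetic(seed={seed})")
    return seq, gt
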