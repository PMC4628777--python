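"""Simulator: motion closed form, rendering forward model, ground truth."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocupulse.exceptions import BoundaryCrossingError
from ocupulse.synthetic_scan import (
    Breathing,
    Cardiac,
    IrisStep,
    LateralDrift,
    MotionSpec,
    NoiseSpec,
    ScanGeometry,
    generate_sequence,
    motion_displacement,
    render_frame,
)

NOISELESS = NoiseSpec(speckle_looks=None, additive_sigma=0.0)


def simple_motion(**kw):
    base = dict(
        breathing=Breathing(0.25, 2.0, 0.0),
        cardiac=Cardiac(1.25, 0.0, (1.0,)),
        lateral_drift=LateralDrift(0.0, 0.0),
    )
    base.update(kw)
    return MotionSpec(**base)


class TestMotionDisplacement:
    def test_zero_at_origin_with_zero_phases(self):
        d_c, d_i, d_lat = motion_displacement(simple_motion(), 0.0)
        assert d_c == 0.0 and d_i == 0.0 and d_lat == 0.0

    def test_closed_form_at_one_second(self):
        # 2 sin(2π·0.25·1) + 1 sin(2π·1.25·1) = 2 sin(π/2) + sin(2.5π) = 3
        d_c, d_i, _ = motion_displacement(simple_motion(), 1.0)
        assert d_c == pytest.approx(3.0, abs=1e-12)
        assert d_i == pytest.approx(3.0, abs=1e-12)

    def test_gain_scales_cornea_only(self):
        motion = simple_motion(cornea_gain=0.8)
        d_c, d_i, _ = motion_displacement(motion, 1.0)
        assert d_c == pytest.approx(2.4, abs=1e-12)
        assert d_i == pytest.approx(3.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        t=st.floats(0.0, 10.0, allow_nan=False),
        g_c=st.floats(0.1, 3.0),
        g_i=st.floats(0.1, 3.0),
    )
    def test_gains_scale_common_signal_linearly(self, t, g_c, g_i):
        base = simple_motion()
        scaled = simple_motion(cornea_gain=g_c, iris_gain=g_i)
        d_c0, d_i0, _ = motion_displacement(base, t)
        d_c, d_i, _ = motion_displacement(scaled, t)
        assert d_c == pytest.approx(g_c * d_c0, rel=1e-12, abs=1e-12)
        assert d_i == pytest.approx(g_i * d_i0, rel=1e-12, abs=1e-12)

    def test_vectorized_over_time(self):
        t = np.linspace(0, 3.96, 90)
        d_c, d_i, d_lat = motion_displacement(simple_motion(), t)
        assert d_c.shape == t.shape
        scalar = [motion_displacement(simple_motion(), ti)[0] for ti in t]
        np.testing.assert_allclose(d_c, scalar, atol=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            simple_motion(cornea_gain=0.0)
        with pytest.raises(ValueError):
            simple_motion(breathing=Breathing(0.25, -1.0, 0.0))
        with pytest.raises(ValueError):
            simple_motion(cardiac=Cardiac(-1.0, 0.0, (1.0,)))


class TestRenderFrame:
    def test_noiseless_iris_band_intensity(self):
        geom = ScanGeometry()
        rng = np.random.default_rng(0)
        frame = render_frame(geom, (0.0, 0.0, 0.0), NOISELESS, rng)
        q = geom.iris_anterior_profile(np.arange(geom.n_cols))
        for x in (0, 50, 159):
            below = np.arange(geom.n_rows) > np.ceil(q[x])
            assert np.allclose(frame[below, x], geom.band_intensity_iris)
        # background above the cornea is flat
        assert np.allclose(frame[:20], geom.background_intensity)

    def test_pure_translation_shifts_boundary(self):
        geom = ScanGeometry()
        rng = np.random.default_rng(0)
        f0 = render_frame(geom, (0.0, 0.0, 0.0), NOISELESS, rng)
        f3 = render_frame(geom, (3.0, 0.0, 0.0), NOISELESS, rng)
        # an integer-pixel cornea shift reproduces the static band 3 rows lower
        np.testing.assert_allclose(f3[23:63], f0[20:60], atol=1e-12)

    def test_same_rng_seed_is_bit_identical(self):
        geom = ScanGeometry()
        noise = NoiseSpec(speckle_looks=4, additive_sigma=0.01)
        f1 = render_frame(geom, (1.0, 1.0, 0.5), noise, np.random.default_rng(3))
        f2 = render_frame(geom, (1.0, 1.0, 0.5), noise, np.random.default_rng(3))
        assert np.array_equal(f1, f2)

    def test_boundary_crossing_rejected(self):
        geom = ScanGeometry()
        gap = geom.iris_base_row - geom.cornea_apex_row
        with pytest.raises(ValueError):
            # huge displacement also violates the |d| < n_rows/4 precondition
            render_frame(geom, (gap + 10, 0.0, 0.0), NOISELESS, np.random.default_rng(0))
        with pytest.raises(BoundaryCrossingError):
            render_frame(geom, (45.0, -30.0, 0.0), NOISELESS, np.random.default_rng(0))

    def test_antialiasing_centroid_recovers_subpixel_boundary(self):
        geom = ScanGeometry()
        rng = np.random.default_rng(0)
        for d in (0.0, 0.3, 0.77):
            frame = render_frame(geom, (0.0, d, 0.0), NOISELESS, rng)
            q = geom.iris_anterior_profile(np.arange(geom.n_cols)) + d
            grad = np.gradient(frame, axis=0)
            rows = np.arange(geom.n_rows)
            zone = (rows[:, None] > 100) & (rows[:, None] < 170)
            g = np.where(zone, np.maximum(grad, 0), 0.0)
            centroid = (g * rows[:, None]).sum(axis=0) / g.sum(axis=0)
            assert np.abs(centroid - q).max() < 0.25


class TestGenerateSequence:
    def test_default_acquisition_duration(self, fx_default):
        seq, _ = generate_sequence(
            fx_default.geometry, fx_default.motion, NOISELESS,
            fx_default.n_frames, fx_default.frame_rate, seed=0,
        )
        assert seq.n_frames == 90
        assert round(seq.duration, 2) == 3.96

    def test_zero_motion_frames_identical_and_depth_constant(self):
        geom = ScanGeometry()
        still = simple_motion(
            breathing=Breathing(0.25, 0.0, 0.0), cardiac=Cardiac(1.25, 0.0, (0.0,))
        )
        seq, gt = generate_sequence(geom, still, NOISELESS, n_frames=2, frame_rate=22.7, seed=0)
        assert np.array_equal(seq.frames[0], seq.frames[1])
        assert np.ptp(gt.depth, axis=1).max() == 0.0

    def test_ground_truth_cardiac_bin_dominates(self, fx_default):
        _, gt = generate_sequence(
            fx_default.geometry,
            simple_motion(breathing=Breathing(0.25, 0.0, 0.0)),
            NOISELESS, 90, 22.7, seed=5,
        )
        trace = gt.cornea_rows[80] - gt.cornea_rows[80].mean()
        # brute-force DFT of the ground-truth trace
        n = trace.size
        k = np.arange(n // 2 + 1)
        dft = np.array([np.sum(trace * np.exp(-2j * np.pi * kk * np.arange(n) / n)) for kk in k])
        freqs = k * 22.7 / n
        assert abs(freqs[np.argmax(np.abs(dft[1:]) ** 2) + 1] - 1.25) <= 22.7 / 90 / 2

    def test_seed_reproducibility(self, fx_default):
        a = generate_sequence(fx_default.geometry, fx_default.motion, fx_default.noise, 10, 22.7, seed=9)
        b = generate_sequence(fx_default.geometry, fx_default.motion, fx_default.noise, 10, 22.7, seed=9)
        assert np.array_equal(a[0].frames, b[0].frames)
        assert np.array_equal(a[1].depth, b[1].depth)

    def test_depth_invariant_under_common_axial_motion(self, fx_default):
        _, gt = generate_sequence(
            fx_default.geometry, fx_default.motion, NOISELESS, 90, 22.7, seed=0
        )
        assert fx_default.motion.cornea_gain == fx_default.motion.iris_gain
        assert np.var(gt.depth, axis=1).max() < 1e-20

    def test_static_profile_at_t0_with_zero_phases(self, fx_default):
        _, gt = generate_sequence(fx_default.geometry, fx_default.motion, NOISELESS, 4, 22.7, seed=0)
        x = np.arange(fx_default.geometry.n_cols)
        np.testing.assert_allclose(gt.cornea_rows[:, 0], fx_default.geometry.cornea_posterior_profile(x))

    def test_aliasing_rejected(self):
        geom = ScanGeometry()
        comb = simple_motion(cardiac=Cardiac(2.0, 0.0, (1.0, 0.5, 0.3, 0.2, 0.1, 0.1)))
        with pytest.raises(ValueError, match="alias"):
            generate_sequence(geom, comb, NOISELESS, 90, 22.7, seed=0)

    def test_lateral_drift_over_step_modulates_depth(self):
        geom = ScanGeometry(iris_step=IrisStep(step_col=80, step_height=-6.0))
        drifting = simple_motion(
            breathing=Breathing(0.25, 0.0, 0.0),
            cardiac=Cardiac(1.25, 0.0, (0.0,)),
            lateral_drift=LateralDrift(2.0, 0.5),
        )
        _, gt = generate_sequence(geom, drifting, NOISELESS, 90, 22.7, seed=0)
        # the drifting step dominates depth modulation; far columns only see
        # the gentle slope/curvature of the smooth profiles
        assert np.ptp(gt.depth[80]) > 4.0
        assert np.ptp(gt.depth[80]) > 3.0 * np.ptp(gt.depth[10])


class TestGeometryValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(band_intensity_cornea=0.7, band_intensity_iris=0.5),
            dict(n_rows=16),
            dict(cornea_apex_row=150.0, iris_base_row=100.0),
            dict(background_intensity=0.4),
        ],
    )
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(ValueError):
            ScanGeometry(**kw)
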