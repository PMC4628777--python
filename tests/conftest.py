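"""Shared synthetic fixtures for the test suite.

Everything is generated at test time from the simulator; session scope keeps
the expensive 90-frame renders to one per configuration.
"""
from __future__ import annotations

import dataclasses

import pytest

from ocupulse.config import load_fixture
from ocupulse.model import OcularPulseModel
from ocupulse.synthetic_scan import NoiseSpec, generate_sequence

NOISELESS = NoiseSpec(speckle_looks=None, additive_sigma=0.0)


@pytest.fixture(scope="session")
def fx_default():
    return load_fixture("subject_default")


@pytest.fixture(scope="session")
def fx_subject3():
    return load_fixture("motion_subject3")


@pytest.fixture(scope="session")
def noiseless_run(fx_default):
    """(sequence, ground truth) for the default motion without any noise."""
    return generate_sequence(
        fx_default.geometry, fx_default.motion, NOISELESS,
        fx_default.n_frames, fx_default.frame_rate, seed=7,
    )


@pytest.fixture(scope="session")
def speckled_run(fx_default):
    """(sequence, ground truth) for the default motion with default speckle."""
    return generate_sequence(
        fx_default.geometry, fx_default.motion, fx_default.noise,
        fx_default.n_frames, fx_default.frame_rate, seed=7,
    )


@pytest.fixture(scope="session")
def subject3_results(fx_subject3):
    """Fitted pipeline results for the subject-3 motion fixture, seed 42."""
    seq, gt = generate_sequence(
        fx_subject3.geometry, fx_subject3.motion, fx_subject3.noise,
        fx_subject3.n_frames, fx_subject3.frame_rate, seed=42,
    )
    return OcularPulseModel(seq).fit(), gt


@pytest.fixture(scope="session")
def unequal_gain_motion(fx_default):
    """Default motion with cornea gain 0.8 vs iris gain 1.0."""
    return dataclasses.replace(fx_default.motion, cornea_gain=0.8, iris_gain=1.0)
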