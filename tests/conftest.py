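"""Shared fixtures: small, fast synthetic walks with exact ground truth."""

import logging

import numpy as np
import pytest

from imugait import SyntheticGaitSpec, generate_leg, generate_pair

logging.getLogger("imugait").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def slow_spec():
    """Slow-gait conditions (2.8 s / 0.69 m strides), 8 strides for speed."""
    return SyntheticGaitSpec(
        n_strides=8, stride_time=2.8, stride_displacement=0.69, seed=11
    )


@pytest.fixture(scope="session")
def brisk_spec():
    """Brisk-gait conditions (1.4 s / 1.17 m strides), 8 strides."""
    return SyntheticGaitSpec(
        n_strides=8, stride_time=1.4, stride_displacement=1.17, seed=12
    )


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free slow gait: every pipeline error is algorithmic."""
    return SyntheticGaitSpec(
        n_strides=8,
        stride_time=2.8,
        stride_displacement=0.69,
        accel_noise_sd=0.0,
        gyro_noise_sd=0.0,
        gyro_bias=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def clean_pair(clean_spec):
    return generate_pair(clean_spec)


@pytest.fixture(scope="session")
def slow_pair(slow_spec):
    return generate_pair(slow_spec)


@pytest.fixture(scope="session")
def brisk_leg(brisk_spec):
    return generate_leg(brisk_spec, "left")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
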