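"""Shared fixtures: simulated trials and a stride template.

Session-scoped because trial simulation and template building are the
expensive common setup for the end-to-end tests.
"""

import dataclasses

import numpy as np
import pytest

import sdatw
from sdatw.synthgait import noise_sd_for_snr


def strides_from_truth(rec, truth):
    """Labeled stride segments (k x 6 matrices) from generator truth."""
    return [
        np.hstack([rec.acc[a:b], rec.gyro[a:b]]) for a, b in truth.stride_intervals
    ]


@pytest.fixture(scope="session")
def template_trial():
    """A 20-stride trial reserved for building the template."""
    return sdatw.simulate_walk(sdatw.WalkSpec(n_strides=20, seed=11))


@pytest.fixture(scope="session")
def stride_template(template_trial):
    rec, truth = template_trial
    return sdatw.build_template(strides_from_truth(rec, truth), fraction=0.30)


@pytest.fixture(scope="session")
def clean_walk():
    """A 60-stride noise-free walking trial with ground truth."""
    return sdatw.simulate_walk(sdatw.WalkSpec(n_strides=60, seed=5))


@pytest.fixture(scope="session")
def noisy_walk():
    """The same trial conditions with additive noise at power SNR 10."""
    spec = sdatw.WalkSpec(n_strides=60, seed=5)
    spec = dataclasses.replace(spec, noise_sd=noise_sd_for_snr(spec, 10.0))
    return sdatw.simulate_walk(spec)


@pytest.fixture(scope="session")
def gyro_z_scheme():
    return sdatw.ChannelScheme("gyro", ("Z",))
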