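import logging

import numpy as np
import pytest

import twinfecg as tf
from twinfecg.core import MATERNAL, NoiseParams, Scenario

logging.getLogger("twinfecg").setLevel(logging.ERROR)

FS = 500.0


@pytest.fixture(scope="session")
def geometry():
    return tf.default_geometry()


@pytest.fixture(scope="session")
def twin_sim():
    """Default twin scenario, 120 s, with ground truth."""
    return tf.simulate_recording(tf.default_twin_scenario(duration=120.0, seed=11))


@pytest.fixture(scope="session")
def twin_pipeline(twin_sim):
    return tf.run_pipeline(twin_sim.recording, geometry=twin_sim.scenario.geometry)


@pytest.fixture(scope="session")
def maternal_only_sim():
    base = tf.default_twin_scenario(duration=60.0, seed=21)
    scenario = Scenario(
        geometry=base.geometry,
        sources=[base.maternal_source()],
        duration=60.0,
        sampling_rate=FS,
        noise=base.noise,
        seed=21,
    )
    return tf.simulate_recording(scenario)


def noise_free() -> NoiseParams:
    return NoiseParams(baseline_amplitude_uv=0.0, powerline_amplitude_uv=0.0,
                       broadband_sd_uv=0.0)


@pytest.fixture(scope="session")
def clean_twin_fetal():
    """Noise-free fetal-only mixture with ground-truth trains.

    Returns (recording, annotation_A, annotation_B, simulation).
    """
    sc = tf.default_twin_scenario(duration=90.0, seed=31, noise=noise_free())
    sim = tf.simulate_recording(sc)
    rec = tf.Recording(
        sim.clean["fetusA"].samples + sim.clean["fetusB"].samples, FS
    )
    return rec, sim.annotation("fetusA"), sim.annotation("fetusB"), sim
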