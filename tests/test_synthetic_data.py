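"""Simulator: RR series, dipole waveform, lead field, full rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twinfecg as tf
from twinfecg.core import Scenario, NoiseParams, DipoleSource, WaveParams
from twinfecg.synthetic_data import LEAD_FIELD_GAIN

from conftest import FS, noise_free


class TestGenerateRRSeries:
    def test_zero_variability_is_uniform(self):
        beats = tf.generate_rr_series(mean_hr=120, sd_hr=0, duration=10)
        assert beats.size == 20
        assert np.allclose(np.diff(beats), 0.5)

    def test_seed_determinism(self):
        a = tf.generate_rr_series(140, 5, 600, seed=1)
        b = tf.generate_rr_series(140, 5, 600, seed=1)
        assert np.array_equal(a, b)

    def test_monte_carlo_mean_rate(self):
        beats = tf.generate_rr_series(140, 5, 600, seed=2)
        rates = 60.0 / np.diff(beats)
        assert abs(rates.mean() - 140) < 2.0

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(mean_hr=140, sd_hr=5, duration=-1), "duration"),
            (dict(mean_hr=10, sd_hr=5, duration=10), "mean_hr"),
            (dict(mean_hr=500, sd_hr=5, duration=10), "mean_hr"),
            (dict(mean_hr=140, sd_hr=-1, duration=10), "sd_hr"),
        ],
    )
    def test_rejects_bad_parameters(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            tf.generate_rr_series(**kwargs)

    @given(
        mean_hr=st.floats(60, 200),
        sd_hr=st.floats(0, 10),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_beats_strictly_increasing_within_duration(self, mean_hr, sd_hr, seed):
        beats = tf.generate_rr_series(mean_hr, sd_hr, 30.0, seed=seed)
        assert np.all(np.diff(beats) > 0)
        assert beats[0] >= 0 and beats[-1] < 30.0
        # truncation keeps implied rates physiological
        rates = 60.0 / np.diff(beats)
        assert np.all((rates >= 30 - 1e-9) & (rates <= 300 + 1e-9))


class TestDipoleWaveform:
    def test_zero_amplitudes_give_zero_vector(self):
        params = {
            "R": WaveParams(np.zeros(3), 0.0, 0.1),
            "T": WaveParams(np.zeros(3), np.pi / 2, 0.3),
        }
        phases = np.linspace(-np.pi, np.pi, 101, endpoint=False)
        assert np.allclose(tf.dipole_waveform(params, phases), 0.0)

    def test_single_wave_peak_equals_amplitude(self):
        amp = np.array([1.0, 0.2, -0.4])
        params = {"R": WaveParams(amp, 0.0, 0.1)}
        assert np.allclose(tf.dipole_waveform(params, 0.0), amp)

    def test_cycle_integral_matches_gaussian_closed_form(self):
        # Oracle: integral over one full cycle of a (wrapped) Gaussian
        # is amplitude * width * sqrt(2*pi), summed over waves per axis.
        params = tf.heart_waveform()
        expected = sum(
            w.amplitude * w.width * np.sqrt(2 * np.pi) for w in params.values()
        )
        phases = np.linspace(-np.pi, np.pi, 20001, endpoint=False)
        values = tf.dipole_waveform(params, phases)
        integral = values.sum(axis=0) * (2 * np.pi / phases.size)
        assert np.allclose(integral, expected, rtol=0.05)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError, match="width"):
            WaveParams(np.ones(3), 0.0, 0.0)


def _two_electrode_geometry():
    positions = np.array(
        [[2.0, 0.0, 0.0], [-2.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, -10.0, 0.0]]
    )
    deriv = np.array([[1.0, -1.0, 0.0, 0.0]])
    return tf.ElectrodePatchGeometry(
        electrode_positions=positions, ground_index=3, reference_index=2,
        derivation_matrix=deriv,
    )


class TestLeadField:
    def test_symmetric_source_orthogonal_dipole_cancels(self):
        geom = _two_electrode_geometry()
        L = tf.lead_field(np.array([0.0, 0.0, -1.0]), np.eye(3), geom)
        # dipole along z is orthogonal to neither pole direction's x
        # separation; x-dipole column must cancel exactly by symmetry
        assert abs(L[0, 1]) < 1e-12  # y-dipole: same y-projection at both poles
        # moving the source off-centre breaks the cancellation
        L2 = tf.lead_field(np.array([1.0, 0.0, -1.0]), np.eye(3), geom)
        assert abs(L2[0, 0]) > abs(L[0, 0]) - 1e-12

    def test_inverse_square_distance_scaling(self, geometry):
        src = np.array([0.0, 5.0, 0.0])
        L1 = tf.lead_field(src, np.eye(3), geometry)
        scaled = tf.ElectrodePatchGeometry(
            electrode_positions=src + 2.0 * (geometry.electrode_positions - src),
            ground_index=geometry.ground_index,
            reference_index=geometry.reference_index,
            derivation_matrix=geometry.derivation_matrix,
        )
        L2 = tf.lead_field(src, np.eye(3), scaled)
        assert np.allclose(L2, L1 / 4.0, rtol=1e-12)

    def test_dipole_toward_electrode_is_positive(self):
        # channel = e1 minus a far-away reference; a dipole pointing at
        # e1 must deflect the channel positively
        positions = np.array([[0.0, 0.0, 5.0], [0.0, 80.0, 0.0], [0.0, -80.0, 0.0]])
        geom = tf.ElectrodePatchGeometry(
            electrode_positions=positions, ground_index=2, reference_index=1,
            derivation_matrix=np.array([[1.0, -1.0, 0.0]]),
        )
        L = tf.lead_field(np.zeros(3), np.eye(3), geom)
        assert L[0, 2] > 0  # z-dipole points at e1
        assert L[0, 2] > 10 * abs(L[0, 0])

    def test_source_on_electrode_rejected(self, geometry):
        with pytest.raises(ValueError, match="singular"):
            tf.lead_field(geometry.electrode_positions[0], np.eye(3), geometry)

    def test_midline_channel_opposite_twin_polarity(self, twin_sim):
        """The two fetuses deflect the midline channel in opposite directions."""
        midline = 3  # channel derived from the lower-midline electrode
        signs = []
        for lab in ("fetusA", "fetusB"):
            ann = twin_sim.annotation(lab)
            vals = twin_sim.clean[lab].samples[midline, ann.r_samples[5:15]]
            signs.append(np.sign(np.median(vals)))
        assert signs[0] == -signs[1] != 0


class TestSimulateRecording:
    def test_noise_free_single_source_equals_projection(self):
        base = tf.default_twin_scenario(duration=10.0, seed=1, noise=noise_free())
        src = base.maternal_source()
        scenario = Scenario(
            geometry=base.geometry, sources=[src], duration=10.0,
            sampling_rate=FS, noise=noise_free(), seed=1,
        )
        sim = tf.simulate_recording(scenario)
        assert np.allclose(sim.recording.samples, sim.clean["maternal"].samples,
                           atol=1e-12)

    def test_maternal_dominates_variance(self, twin_sim):
        var = {k: np.sum(v.samples**2) for k, v in twin_sim.clean.items()}
        total = sum(var.values())
        assert var["maternal"] / total > 0.9

    def test_nearest_channel_carries_largest_fetal_qrs(self, twin_sim):
        amp = np.abs(twin_sim.clean["fetusA"].samples).max(axis=1)
        assert np.argmax(amp) == 2  # channel above the right-side fetus

    def test_additivity_of_clean_components_and_noise(self, twin_sim):
        total = sum(r.samples for r in twin_sim.clean.values()) + twin_sim.noise.samples
        assert np.array_equal(total, twin_sim.recording.samples)

    def test_seed_determinism(self):
        a = tf.simulate_recording(tf.default_twin_scenario(duration=5.0, seed=9))
        b = tf.simulate_recording(tf.default_twin_scenario(duration=5.0, seed=9))
        assert np.array_equal(a.recording.samples, b.recording.samples)
        c = tf.simulate_recording(tf.default_twin_scenario(duration=5.0, seed=10))
        assert not np.array_equal(a.recording.samples, c.recording.samples)

    def test_electrode_permutation_invariance(self):
        sc = tf.default_twin_scenario(duration=5.0, seed=4)
        sim = tf.simulate_recording(sc)
        perm = np.array([3, 1, 0, 2, 5, 4, 6, 7])
        geom = sc.geometry
        geom_p = tf.ElectrodePatchGeometry(
            electrode_positions=geom.electrode_positions[perm],
            ground_index=int(np.argwhere(perm == geom.ground_index)[0, 0]),
            reference_index=int(np.argwhere(perm == geom.reference_index)[0, 0]),
            derivation_matrix=geom.derivation_matrix[:, perm],
        )
        sc_p = Scenario(
            geometry=geom_p, sources=sc.sources, duration=5.0,
            sampling_rate=sc.sampling_rate, noise=sc.noise, seed=4,
        )
        sim_p = tf.simulate_recording(sc_p)
        assert np.allclose(sim.recording.samples, sim_p.recording.samples, atol=1e-9)

    def test_scenario_validation(self):
        base = tf.default_twin_scenario(duration=5.0)
        with pytest.raises(ValueError, match="duration"):
            Scenario(geometry=base.geometry, sources=base.sources, duration=0.0)
        with pytest.raises(ValueError, match="maternal"):
            Scenario(geometry=base.geometry, sources=base.fetal_sources(), duration=5.0)
        with pytest.raises(ValueError, match="powerline"):
            Scenario(geometry=base.geometry, sources=base.sources, duration=5.0,
                     sampling_rate=80.0)
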