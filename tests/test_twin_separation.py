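"""Linear-combination twin separation and fetal QRS detection."""

import numpy as np
import pytest

import twinfecg as tf
from twinfecg.core import Scenario, TwinsNotSeparableError
from twinfecg.fhr_output import evaluate_against_truth
from twinfecg.synthetic_data import fetal_orientation, heart_waveform
from twinfecg.twin_separation import (
    check_twin_distinctness,
    cluster_candidate_trains,
    derive_combination_weights,
    detect_candidate_beats,
    detect_fetal_qrs,
    enhance_fetus,
    _ensemble_qrs_matrix,
)

from conftest import FS, noise_free


@pytest.fixture(scope="module")
def twin_residual(twin_sim):
    pre = tf.preprocess_recording(twin_sim.recording)
    residual, _, _ = tf.suppress_maternal(pre)
    return residual


class TestCandidates:
    def test_single_fetus_best_channel_sensitivity(self):
        sc = tf.single_fetus_scenario(duration=60.0, seed=41, noise=noise_free())
        sim = tf.simulate_recording(sc)
        rec = tf.Recording(sim.clean["fetusA"].samples, FS)
        cands = detect_candidate_beats(rec)
        truth = sim.annotation("fetusA")
        best = max(
            evaluate_against_truth(c, truth, FS).sensitivity for c in cands
        )
        assert best >= 0.95

    def test_noise_channel_flagged_low_confidence(self):
        rng = np.random.default_rng(0)
        rec = tf.Recording(rng.normal(0, 5, size=(1, 30000)), FS)
        cands = detect_candidate_beats(rec)
        assert cands[0].confidence == "low"

    def test_twin_residual_contains_two_rate_clusters(self, twin_residual):
        cands = detect_candidate_beats(twin_residual)
        trains = cluster_candidate_trains(cands, FS)
        assert len(trains) == 2
        rates = sorted(
            60.0 * FS / np.median(np.diff(t.r_samples)) for t in trains
        )
        assert 130 < rates[0] < 150 < rates[1] < 165


class TestWeights:
    def test_noise_free_null_constraint(self, clean_twin_fetal):
        rec, ann_a, ann_b, sim = clean_twin_fetal
        weights, _ = derive_combination_weights(rec, trains=[ann_a, ann_b])
        # oracle: each fetus's CLEAN ensemble QRS (no cross-contamination)
        M_a = _ensemble_qrs_matrix(
            tf.Recording(sim.clean["fetusA"].samples, FS), ann_a.r_samples
        )
        M_b = _ensemble_qrs_matrix(
            tf.Recording(sim.clean["fetusB"].samples, FS), ann_b.r_samples
        )
        # other twin's ensemble QRS in each enhanced signal <= 1% of own
        own = np.abs(weights.w_A @ M_a).max()
        other = np.abs(weights.w_A @ M_b).max()
        assert other <= 0.01 * own
        own_b = np.abs(weights.w_B @ M_b).max()
        other_b = np.abs(weights.w_B @ M_a).max()
        assert other_b <= 0.01 * own_b

    def test_single_fetus_matched_filter(self):
        sc = tf.single_fetus_scenario(duration=60.0, seed=43, noise=noise_free())
        sim = tf.simulate_recording(sc)
        rec = tf.Recording(sim.clean["fetusA"].samples, FS)
        ann = sim.annotation("fetusA")
        weights, _ = derive_combination_weights(rec, trains=[ann])
        assert weights.w_B is None
        src = sc.fetal_sources()[0]
        L = tf.lead_field(src.position, src.orientation, sc.geometry)
        mixing = L @ heart_waveform()["R"].amplitude
        cos = abs(weights.w_A @ mixing) / np.linalg.norm(mixing)
        assert cos >= 0.99

    def test_identical_mixing_vectors_not_separable(self):
        base = tf.default_twin_scenario(duration=60.0, seed=44, noise=noise_free())
        fa, fb = base.fetal_sources()
        fb_same = tf.DipoleSource(
            label="fetusB", position=fa.position, orientation=fa.orientation,
            waveform_params=fb.waveform_params, mean_hr=fb.mean_hr, sd_hr=fb.sd_hr,
        )
        sc = Scenario(
            geometry=base.geometry, sources=[base.maternal_source(), fa, fb_same],
            duration=60.0, sampling_rate=FS, noise=noise_free(), seed=44,
        )
        sim = tf.simulate_recording(sc)
        rec = tf.Recording(
            sim.clean["fetusA"].samples + sim.clean["fetusB"].samples, FS
        )
        with pytest.raises(TwinsNotSeparableError, match="not separable"):
            derive_combination_weights(
                rec, trains=[sim.annotation("fetusA"), sim.annotation("fetusB")]
            )


class TestEnhance:
    def test_one_hot_weights_select_channel(self, twin_residual):
        w = np.zeros(6)
        w[2] = 1.0
        out = enhance_fetus(twin_residual, w)
        assert np.array_equal(out.samples[0], twin_residual.samples[2])

    def test_negated_weights_negate_output(self, twin_residual):
        w = np.arange(1.0, 7.0)
        a = enhance_fetus(twin_residual, w).samples
        b = enhance_fetus(twin_residual, -w).samples
        assert np.array_equal(a, -b)

    def test_dimension_mismatch_rejected(self, twin_residual):
        with pytest.raises(ValueError, match="channel count"):
            enhance_fetus(twin_residual, np.ones(4))

    def test_enhanced_snr_beats_best_single_channel(self, twin_sim, twin_residual):
        """Own-QRS-to-background ratio of the combination tops any channel."""
        weights, trains = derive_combination_weights(twin_residual)
        clean_a = tf.preprocess_recording(twin_sim.clean["fetusA"]).samples
        background = twin_residual.samples - clean_a  # noise + co-twin + leftover
        # identify which weight corresponds to fetus A via rate
        rates = [60.0 * FS / np.median(np.diff(t.r_samples)) for t in trains]
        w = weights.w_A if rates[0] < rates[1] else weights.w_B
        snr_w = np.std(w @ clean_a) / np.std(w @ background)
        best_single = max(
            np.std(clean_a[ch]) / np.std(background[ch]) for ch in range(6)
        )
        assert snr_w >= best_single


class TestFetalQrsDetection:
    def test_clean_enhanced_signal_high_accuracy(self):
        sc = tf.single_fetus_scenario(duration=60.0, seed=45, noise=noise_free())
        sim = tf.simulate_recording(sc)
        rec = tf.Recording(sim.clean["fetusA"].samples, FS)
        ann = sim.annotation("fetusA")
        weights, _ = derive_combination_weights(rec, trains=[ann])
        enhanced = enhance_fetus(rec, weights.w_A)
        det = detect_fetal_qrs(enhanced)
        m = evaluate_against_truth(det, ann, FS, tolerance_ms=4.0)
        assert m.sensitivity >= 0.99
        assert m.ppv >= 0.99

    def test_polarity_symmetry(self, twin_residual):
        weights, _ = derive_combination_weights(twin_residual)
        enhanced = enhance_fetus(twin_residual, weights.w_A)
        flipped = tf.Recording(-enhanced.samples, FS)
        a = detect_fetal_qrs(enhanced).r_samples
        b = detect_fetal_qrs(flipped).r_samples
        assert np.array_equal(a, b)

    def test_broadband_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(1)
        rec = tf.Recording(rng.normal(0, 5, size=(1, 30000)), FS)
        det = detect_fetal_qrs(rec)
        assert det.confidence == "low"


class TestDistinctness:
    def test_identical_trains_flagged(self):
        beats = tf.BeatAnnotation("fetusA", np.arange(10, 30000, 200))
        rep = check_twin_distinctness(beats, beats, FS)
        assert rep.coincidence_fraction == 1.0
        assert rep.flagged

    def test_independent_trains_near_analytic_rate(self):
        a = tf.BeatAnnotation(
            "fetusA", (tf.generate_rr_series(140, 4, 600, seed=1) * FS).astype(int)
        )
        b = tf.BeatAnnotation(
            "fetusB", (tf.generate_rr_series(155, 4, 600, seed=2) * FS).astype(int)
        )
        rep = check_twin_distinctness(a, b, FS, tolerance_ms=30.0)
        analytic = 2 * 0.030 * (155 / 60.0)  # 2*tol*rate of the other train
        assert rep.coincidence_fraction <= 3 * analytic
        assert not rep.flagged

    def test_empty_train_warns_not_flags(self):
        a = tf.BeatAnnotation("fetusA", np.array([], dtype=int))
        b = tf.BeatAnnotation("fetusB", np.arange(0, 10000, 200))
        rep = check_twin_distinctness(a, b, FS)
        assert rep.coincidence_fraction == 0.0
        assert not rep.flagged
        assert "empty" in rep.warning


class TestSeparationEndToEnd:
    def test_f1_and_labels_on_default_scenario(self, twin_sim, twin_pipeline):
        for lab in ("fetusA", "fetusB"):
            m = evaluate_against_truth(
                twin_pipeline.fetal_beats[lab], twin_sim.annotation(lab), FS
            )
            f1 = 2 * m.sensitivity * m.ppv / (m.sensitivity + m.ppv)
            assert f1 >= 0.95, f"{lab}: F1={f1:.3f}"
        assert not twin_pipeline.distinctness.flagged
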