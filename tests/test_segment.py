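"""Segmentation: features, emission training, Viterbi decoding, framing."""

import numpy as np
import pytest

from pcglvdd.preprocess import preprocess, resample
from pcglvdd.segment import (
    FEATURE_RATE,
    SegmenterModel,
    _duration_tables,
    _viterbi,
    extract_envelope_features,
    extract_frames,
    resample_states,
    segment_states,
    train_segmenter,
)
from pcglvdd.synth import default_config, simulate_recording
from pcglvdd.types import STATES, STATE_INDEX, DegenerateSignalError, Recording, StateSequence


@pytest.fixture(scope="module")
def trained(clean_cohort):
    return train_segmenter(clean_cohort[:4])


class TestFeatures:
    def test_row_count_and_normalization(self, clean_cohort):
        rec = resample(clean_cohort[0], 1000.0)
        f = extract_envelope_features(rec)
        assert f.shape == (int(rec.duration * FEATURE_RATE), 4)
        np.testing.assert_allclose(f.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(f.std(axis=0), 1, atol=1e-9)

    def test_zero_recording_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            extract_envelope_features(Recording(np.zeros(4000), 1000.0, "z"))

    def test_envelope_peaks_track_sounds(self, clean_recording):
        rec = preprocess(clean_recording)
        f = extract_envelope_features(rec)
        env = f[:, 0]
        step = rec.sampling_rate / FEATURE_RATE
        for c in clean_recording.true_s1_centers[1:-1]:
            row = int(round(c / 8 / step))
            lo = max(row - 1, 0)
            window = env[lo:row + 2]          # +-20 ms around the true center
            near = env[max(row - 15, 0):row + 15]
            assert window.max() >= 0.8 * near.max()


class TestTraining:
    def test_duration_priors_plausible(self, trained):
        s1 = trained.duration_means[STATE_INDEX["S1"]]
        s2 = trained.duration_means[STATE_INDEX["S2"]]
        assert 0.05 <= s1 <= 0.2
        assert 0.03 <= s2 <= 0.15

    def test_heldout_emission_accuracy(self, clean_cohort, trained):
        from pcglvdd.segment import _labelled_rows

        feats, labs = _labelled_rows(clean_cohort[5], FEATURE_RATE)
        pred = trained.emission_log_proba(feats).argmax(axis=1)
        assert np.mean(pred == labs) >= 0.7

    def test_training_deterministic(self, clean_cohort):
        a = train_segmenter(clean_cohort[:3])
        b = train_segmenter(clean_cohort[:3])
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_too_few_recordings(self, clean_cohort):
        with pytest.raises(ValueError):
            train_segmenter(clean_cohort[:1])

    def test_model_json_roundtrip(self, trained, tmp_path):
        p = tmp_path / "model.json"
        trained.to_json(p)
        back = SegmenterModel.from_json(p)
        np.testing.assert_allclose(back.coef, trained.coef)
        np.testing.assert_allclose(back.duration_means, trained.duration_means)


def brute_force_decode(logB, model):
    """Exhaustive search over duration-feasible cyclic run sequences."""
    T = logB.shape[0]
    support, logp, logsf = _duration_tables(model, T)
    E = np.vstack([np.zeros((1, 4)), np.cumsum(logB, axis=0)])
    best = (-np.inf, None)

    def extend(t, s, score, runs):
        nonlocal best
        for d, lp, lsf in zip(support[s], logp[s], logsf[s]):
            if t + d > T:
                break
            em = E[t + d, s] - E[t, s]
            if t + d == T:
                # final run: complete (full duration probability) or truncated
                # (survival of a longer intended duration), whichever is better
                tot = score + em + max(lp, lsf)
                if tot > best[0]:
                    best = (tot, runs + [(s, int(d))])
            else:
                extend(t + d, (s + 1) % 4, score + em + lp, runs + [(s, int(d))])

    for s0 in range(4):
        extend(0, s0, 0.0, [])
    path = np.concatenate([[s] * d for s, d in best[1]])
    return best[0], path.astype(np.int8)


def test_viterbi_equals_bruteforce_on_toy_inputs():
    model = SegmenterModel(
        coef=np.eye(4), intercept=np.zeros(4),
        duration_means=np.array([0.06, 0.08, 0.06, 0.10]),
        duration_sds=np.array([0.02, 0.02, 0.02, 0.02]),
        feature_rate=50.0)
    rng = np.random.default_rng(4)
    for trial in range(3):
        T = 12  # short toy grid keeps exhaustive enumeration tractable
        logB = np.log(rng.dirichlet(np.ones(4), size=T))
        path = _viterbi(logB, model)
        _, brute_path = brute_force_decode(logB, model)
        np.testing.assert_array_equal(path, brute_path)


class TestDecoding:
    def test_state_accuracy_on_clean_input(self, clean_cohort, trained):
        rec = clean_cohort[4]
        pr = preprocess(rec)
        states = segment_states(pr, trained)
        truth = resample_states(rec.true_states, 1000.0)
        n = min(len(states), len(truth))
        assert np.mean(states.labels[:n] == truth.labels[:n]) >= 0.9
        states.check_cyclic()

    def test_s1_onsets_within_20ms(self, clean_cohort, trained):
        rec = clean_cohort[5]
        states = segment_states(preprocess(rec), trained)
        detected = states.onsets("S1")
        ratio = 1000.0 / rec.sampling_rate
        errs = [np.abs(detected - t * ratio).min() for t in rec.true_s1_onsets[1:-1]]
        assert np.median(errs) <= 20

    def test_short_recording_rejected(self, trained):
        with pytest.raises(ValueError):
            segment_states(Recording(np.zeros(500), 1000.0, "s"), trained)

    def test_accuracy_degrades_with_noise(self, clean_cohort, trained):
        accs = {}
        for snr in (30.0, 0.0):
            vals = []
            for seed in (50, 51, 52):
                rec = simulate_recording(
                    default_config("control", duration=20.0, noise_snr=snr, seed=seed), "n")
                states = segment_states(preprocess(rec), trained)
                truth = resample_states(rec.true_states, 1000.0)
                n = min(len(states), len(truth))
                vals.append(np.mean(states.labels[:n] == truth.labels[:n]))
            accs[snr] = np.mean(vals)
        assert accs[30.0] > accs[0.0]


class TestFraming:
    def test_frame_count_at_60bpm(self):
        # 300 s at exactly 60 bpm: 1.6 s frame + ~2 skipped periods -> ~4 s cadence
        fs = 1000.0
        n = int(300 * fs)
        labels = np.full(n, STATE_INDEX["diastole"], dtype=np.int8)
        onsets = np.arange(0, n, 1000)
        for o in onsets:
            labels[o:o + 100] = STATE_INDEX["S1"]
            labels[o + 100:o + 350] = STATE_INDEX["systole"]
            labels[o + 350:o + 430] = STATE_INDEX["S2"]
        states = StateSequence(labels, fs)
        rec = Recording(np.ones(n), fs, "r", "control")
        frames = extract_frames(rec, states)
        assert 70 <= len(frames) <= 78
        assert all(len(f) == 1600 for f in frames)
        starts = np.array([f.start_index for f in frames])
        assert np.all(np.diff(starts) >= 1600)  # never overlapping

    def test_frames_start_on_s1_onsets(self, clean_cohort, trained):
        rec = preprocess(clean_cohort[0])
        states = segment_states(rec, trained)
        frames = extract_frames(rec, states)
        onsets = set(states.onsets("S1").tolist())
        assert frames and all(f.start_index in onsets for f in frames)

    def test_short_recording_yields_no_frames(self):
        labels = np.zeros(1000, dtype=np.int8)
        states = StateSequence(labels, 1000.0)
        rec = Recording(np.ones(1000), 1000.0, "r")
        assert extract_frames(rec, states) == []

    def test_no_onsets_warns(self):
        labels = np.full(3000, STATE_INDEX["diastole"], dtype=np.int8)
        rec = Recording(np.ones(3000), 1000.0, "r")
        with pytest.warns(UserWarning):
            assert extract_frames(rec, StateSequence(labels, 1000.0)) == []
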