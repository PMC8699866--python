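"""Four-state heart-sound segmentation and S1-onset framing.

A hidden semi-Markov model with logistic-regression emissions (LR-HSMM
style): envelope features are extracted at 50 Hz, a multinomial logistic
regression scores each feature frame against the four cardiac states, and a
duration-constrained Viterbi decoder finds the best state path under the
fixed cyclic order S1 -> systole -> S2 -> diastole with Gaussian state-
duration penalties. Detected S1 onsets anchor 1.6 s analysis frames
(about two cardiac periods), with roughly two periods skipped between
frames to avoid overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pywt
from scipy import signal as sps
from scipy.signal import hilbert
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

from .types import STATES, STATE_INDEX, DegenerateSignalError, Frame, Recording, StateSequence
from .synth import SimulatedRecording
from .preprocess import resample

__all__ = [
    "SegmenterModel",
    "extract_envelope_features",
    "train_segmenter",
    "segment_states",
    "extract_frames",
    "resample_states",
]

FEATURE_RATE = 50.0  # Hz
FEATURE_NAMES = ("homomorphic", "hilbert", "band_power", "wavelet")


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    b, a = sps.butter(order, cutoff / (fs / 2), btype="low")
    return sps.filtfilt(b, a, x)


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    b, a = sps.butter(order, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return sps.filtfilt(b, a, x)


def extract_envelope_features(rec: Recording, feature_rate: float = FEATURE_RATE) -> np.ndarray:
    """Four z-normalized envelope features at ``feature_rate`` rows per second.

    Columns: homomorphic envelope, analytic (Hilbert) envelope, 20-200 Hz
    band power envelope, and a wavelet-detail envelope. The recording must be
    at 1000 Hz.
    """
    if rec.sampling_rate != 1000.0:
        raise ValueError("features are defined on 1000 Hz recordings")
    x = rec.samples
    step = int(round(rec.sampling_rate / feature_rate))
    if x.size < 2 * step:
        raise ValueError("recording shorter than one feature window")
    if not np.any(x):
        raise DegenerateSignalError("all-zero recording has no envelopes")

    analytic = np.abs(hilbert(x))
    homomorphic = np.exp(_lowpass(np.log(analytic + 1e-12), rec.sampling_rate, 8.0, order=1))
    band = _bandpass(x, rec.sampling_rate, 20.0, 200.0)
    band_power = np.sqrt(np.clip(_lowpass(band**2, rec.sampling_rate, 8.0), 0, None))
    # db6 detail level 3 covers ~62.5-125 Hz at 1000 Hz, a heart-sound band
    coeffs = pywt.wavedec(x, "db6", level=3, mode="symmetric")
    kept = [np.zeros_like(c) for c in coeffs]
    kept[1] = coeffs[1]
    detail = pywt.waverec(kept, "db6", mode="symmetric")[: x.size]
    wavelet_env = np.sqrt(np.clip(_lowpass(detail**2, rec.sampling_rate, 8.0), 0, None))

    n_rows = x.size // step
    idx = np.arange(n_rows) * step
    feats = np.stack([homomorphic[idx], analytic[idx], band_power[idx], wavelet_env[idx]], axis=1)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateSignalError("constant envelope feature; signal is degenerate")
    return (feats - mu) / sd


def resample_states(states: StateSequence, target_rate: float) -> StateSequence:
    """Nearest-index downsampling of per-sample state labels."""
    n_out = int(round(len(states) * target_rate / states.sampling_rate))
    src = np.minimum((np.arange(n_out) * states.sampling_rate / target_rate).astype(np.int64),
                     len(states) - 1)
    return StateSequence(states.labels[src], target_rate)


@dataclass
class SegmenterModel:
    """Trained emission model plus per-state Gaussian duration priors (seconds)."""

    coef: np.ndarray  # (4, n_features)
    intercept: np.ndarray  # (4,)
    duration_means: np.ndarray  # (4,) seconds, indexed by STATE_INDEX
    duration_sds: np.ndarray  # (4,)
    feature_rate: float = FEATURE_RATE

    def emission_log_proba(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.coef.T + self.intercept
        z -= z.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return logp

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "duration_means": self.duration_means.tolist(),
            "duration_sds": self.duration_sds.tolist(),
            "feature_rate": self.feature_rate,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmenterModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["coef"]), np.asarray(d["intercept"]),
                   np.asarray(d["duration_means"]), np.asarray(d["duration_sds"]),
                   d["feature_rate"])


def _labelled_rows(rec: SimulatedRecording, feature_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    r = rec if rec.sampling_rate == 1000.0 else resample(rec, 1000.0)
    if rec.true_states is None:
        raise ValueError("training requires simulator ground truth")
    states_1k = (rec.true_states if rec.sampling_rate == 1000.0
                 else resample_states(rec.true_states, 1000.0))
    feats = extract_envelope_features(
        Recording(r.samples, 1000.0, rec.subject_id, rec.class_label), feature_rate)
    lab = resample_states(states_1k, feature_rate).labels[: feats.shape[0]]
    feats = feats[: lab.size]
    return feats, lab


def train_segmenter(recordings: Sequence[SimulatedRecording],
                    feature_rate: float = FEATURE_RATE) -> SegmenterModel:
    """Fit the emission model and duration priors from labelled recordings.

    Deterministic: the logistic regression is fitted with lbfgs from a fixed
    initialisation, so identical inputs give identical weights.
    """
    if len(recordings) < 2:
        raise ValueError("need at least two labelled recordings")
    rows, labs = [], []
    durations: List[List[float]] = [[] for _ in STATES]
    for rec in recordings:
        f, l = _labelled_rows(rec, feature_rate)
        rows.append(f)
        labs.append(l)
        if rec.true_states is not None:
            for start, end, state in rec.true_states.runs()[1:-1]:  # drop clipped edge runs
                durations[state].append((end - start) / rec.sampling_rate)
    X = np.concatenate(rows)
    y = np.concatenate(labs)
    if np.unique(y).size < len(STATES):
        raise ValueError("training labels must cover all four states")
    lr = LogisticRegression(max_iter=500, C=10.0)
    lr.fit(X, y)
    coef = np.zeros((len(STATES), X.shape[1]))
    intercept = np.zeros(len(STATES))
    for cls_idx, c in enumerate(lr.classes_):
        coef[int(c)] = lr.coef_[cls_idx]
        intercept[int(c)] = lr.intercept_[cls_idx]
    means = np.array([np.mean(d) if d else 0.1 for d in durations])
    sds = np.array([max(np.std(d), 0.01) if len(d) > 1 else 0.02 for d in durations])
    return SegmenterModel(coef, intercept, means, sds, feature_rate)


def _duration_tables(model: SegmenterModel, T: int):
    """Per-state duration support (frames), normalized log-probabilities and
    log survival, all on the feature-rate grid."""
    dt = 1.0 / model.feature_rate
    dur_support: List[np.ndarray] = []
    dur_logp: List[np.ndarray] = []
    dur_logsf: List[np.ndarray] = []
    for s in range(len(STATES)):
        mu, sd = model.duration_means[s], model.duration_sds[s]
        dmax = max(1, int(np.ceil((mu + 3 * sd) / dt)))
        dmax = min(dmax, T)
        d = np.arange(1, dmax + 1)
        lp = norm.logpdf(d * dt, mu, sd)
        lp -= np.log(np.exp(lp - lp.max()).sum()) + lp.max()  # normalize over support
        dur_support.append(d)
        dur_logp.append(lp)
        dur_logsf.append(norm.logsf(d * dt, mu, sd))
    return dur_support, dur_logp, dur_logsf


def _viterbi(logB: np.ndarray, model: SegmenterModel) -> np.ndarray:
    """Duration-constrained Viterbi over the fixed cyclic state order.

    ``logB``: (T, 4) emission log-probabilities at the feature rate. Returns
    the frame-level state path. The first and last runs may be truncated
    (recordings start and end mid-cycle); the last run pays a duration
    survival penalty instead of the full Gaussian.
    """
    T = logB.shape[0]
    n_states = len(STATES)
    prev_state = [(s - 1) % n_states for s in range(n_states)]
    dur_support, dur_logp, dur_logsf = _duration_tables(model, T)

    E = np.vstack([np.zeros((1, n_states)), np.cumsum(logB, axis=0)])  # E[t] = sum logB[:t]

    delta = np.full((T + 1, n_states), -np.inf)
    delta[0, :] = 0.0
    back_d = np.zeros((T + 1, n_states), dtype=np.int32)
    for t in range(1, T + 1):
        for s in range(n_states):
            d = dur_support[s]
            ok = d <= t
            if not ok.any():
                continue
            dd = d[ok]
            scores = (delta[t - dd, prev_state[s]]
                      + dur_logp[s][ok]
                      + (E[t, s] - E[t - dd, s]))
            k = int(np.argmax(scores))
            delta[t, s] = scores[k]
            back_d[t, s] = dd[k]

    # termination: allow a truncated final run with a survival penalty
    best = (-np.inf, 0, 0)  # score, state, trunc_d
    for s in range(n_states):
        d = dur_support[s]
        ok = d <= T
        dd = d[ok]
        scores = (delta[T - dd, prev_state[s]]
                  + dur_logsf[s][ok]
                  + (E[T, s] - E[T - dd, s]))
        k = int(np.argmax(scores))
        if float(scores[k]) >= float(delta[T, s]):
            entry = (float(scores[k]), s, int(dd[k]))
        else:
            entry = (float(delta[T, s]), s, int(back_d[T, s]))
        if entry[0] > best[0]:
            best = entry

    path = np.empty(T, dtype=np.int8)
    t, s, d = T, best[1], best[2]
    while t > 0:
        path[t - d:t] = s
        t -= d
        s = prev_state[s]
        d = int(back_d[t, s])
        if d == 0 and t > 0:  # initial truncated run
            path[:t] = s
            break
    return path


def segment_states(rec: Recording, model: SegmenterModel) -> StateSequence:
    """Maximum a-posteriori four-state path, upsampled to sample resolution."""
    if rec.sampling_rate != 1000.0:
        raise ValueError("segment_states expects a 1000 Hz recording")
    if rec.duration < 2.0:
        raise ValueError("recording too short to segment (need >= 2 s)")
    feats = extract_envelope_features(rec, model.feature_rate)
    logB = model.emission_log_proba(feats)
    path = _viterbi(logB, model)
    step = int(round(rec.sampling_rate / model.feature_rate))
    labels = np.repeat(path, step)
    if labels.size < len(rec):
        labels = np.concatenate([labels, np.full(len(rec) - labels.size, path[-1], dtype=np.int8)])
    return StateSequence(labels[: len(rec)], rec.sampling_rate)


def extract_frames(rec: Recording, states: StateSequence,
                   frame_seconds: float = 1.6, skip_periods: float = 2.0) -> List[Frame]:
    """Cut fixed-length frames starting at detected S1 onsets.

    After each frame, the next frame starts at the first S1 onset at least
    ``skip_periods`` mean cardiac periods after the frame's end. Tail frames
    that would run past the recording are discarded.
    """
    frame_len = int(round(frame_seconds * rec.sampling_rate))
    onsets = states.onsets("S1")
    if onsets.size == 0:
        warnings.warn("no S1 onsets detected; returning no frames")
        return []
    mean_cycle = float(np.mean(np.diff(onsets))) if onsets.size > 1 else frame_len / 2
    frames: List[Frame] = []
    cursor = 0
    for onset in onsets:
        if onset < cursor:
            continue
        if onset + frame_len > len(rec):
            break
        frames.append(Frame(rec.samples[onset:onset + frame_len], int(onset),
                            subject_id=rec.subject_id, class_label=rec.class_label,
                            sampling_rate=rec.sampling_rate))
        cursor = onset + frame_len + int(round(skip_periods * mean_cycle))
    return frames
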