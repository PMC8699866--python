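"""Synthetic phonocardiogram (PCG) simulator.

Generates heart-sound recordings with known per-sample state labels so the
whole analysis chain (denoising, segmentation, framing, spectrogram imaging,
augmentation, classification) can be exercised and validated without clinical
data. Each cardiac cycle is S1 -> systole -> S2 -> diastole; S1 and S2 are
Gaussian-enveloped band-limited chirps, and the two simulated cohorts differ
in the upper edge of the S2 band: the LVDD-like class caps S2 content near
150 Hz while the control-like class extends to about 200 Hz, mirroring the
spectral signature that separates the groups on real spectrograms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.io import wavfile

from .types import STATE_INDEX, CLASS_INDEX, Recording, StateSequence

__all__ = [
    "PCGSimConfig",
    "SimulatedRecording",
    "default_config",
    "simulate_recording",
    "simulate_cohort",
    "write_cohort",
]


@dataclass
class PCGSimConfig:
    """Parameters of the PCG simulator.

    The defaults emulate the acquisition protocol the pipeline targets:
    five-minute apex recordings sampled at 8000 Hz, an elderly cohort heart
    rate around 70 bpm, and heart-sound energy confined to 20-200 Hz. The
    S2 band upper edge is the class-separating parameter: ~150 Hz for the
    ``lvdd`` class, ~200 Hz for ``control``.
    """

    sampling_rate: float = 8000.0
    duration: float = 300.0
    heart_rate_mean: float = 70.0
    heart_rate_sd: float = 5.0
    s1_band: Tuple[float, float] = (30.0, 110.0)
    s2_band: Tuple[float, float] = (50.0, 200.0)
    s1_s2_amplitude_ratio: float = 1.25
    systole_fraction: float = 0.35
    noise_snr: float = 15.0  # dB; np.inf disables noise
    class_label: str = "control"
    seed: int = 0
    # cycle-to-cycle period jitter, as a fraction of the mean period
    period_jitter: float = 0.03
    s1_duration_range: Tuple[float, float] = (0.07, 0.14)
    s2_duration_range: Tuple[float, float] = (0.05, 0.10)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sampling_rate <= 2 * self.s2_band[1]:
            raise ValueError("sampling_rate must exceed twice the S2 band upper edge")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must lie in (0, 1)")
        if self.heart_rate_mean <= 0:
            raise ValueError("heart_rate_mean must be positive")
        if self.class_label not in CLASS_INDEX:
            raise ValueError(f"unknown class label {self.class_label!r}")


@dataclass
class SimulatedRecording(Recording):
    """A :class:`Recording` carrying simulator ground truth."""

    true_states: Optional[StateSequence] = None
    true_s1_onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    true_s2_centers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    true_s1_centers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def default_config(class_label: str, **overrides) -> PCGSimConfig:
    """Config with the class-appropriate S2 band (LVDD ~150 Hz, control ~200 Hz)."""
    s2_high = 150.0 if class_label == "lvdd" else 200.0
    cfg = PCGSimConfig(class_label=class_label, s2_band=(50.0, s2_high))
    return replace(cfg, **overrides) if overrides else cfg


def _burst(fs: float, dur: float, band: Tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Gaussian-enveloped chirp sweeping from near the band top down to its bottom."""
    n = max(int(round(dur * fs)), 8)
    t = np.arange(n) / fs
    f_hi = 0.95 * band[1]
    f_lo = band[0]
    # linear downward sweep; integrate instantaneous frequency for the phase
    inst_f = f_hi + (f_lo - f_hi) * (t / t[-1])
    phase = 2 * np.pi * np.cumsum(inst_f) / fs + rng.uniform(0, 2 * np.pi)
    env = np.exp(-0.5 * ((t - t[-1] / 2) / (dur / 5.0)) ** 2)
    return env * np.sin(phase)


def simulate_recording(config: PCGSimConfig, subject_id: str = "sim") -> SimulatedRecording:
    """Simulate one PCG recording with per-sample ground-truth states.

    Deterministic for a fixed ``(config, subject_id)``: all randomness comes
    from ``config.seed``.
    """
    fs = config.sampling_rate
    n_total = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)

    samples = np.zeros(n_total, dtype=np.float64)
    labels = np.full(n_total, STATE_INDEX["diastole"], dtype=np.int8)
    s1_onsets: List[int] = []
    s1_centers: List[int] = []
    s2_centers: List[int] = []

    period_mean = 60.0 / config.heart_rate_mean
    t0 = 0.0
    while t0 < config.duration:
        jitter_sd = config.period_jitter * period_mean
        period = float(np.clip(period_mean + jitter_sd * rng.standard_normal(),
                               period_mean - 3 * jitter_sd, period_mean + 3 * jitter_sd))
        s1_dur = rng.uniform(*config.s1_duration_range)
        s2_dur = rng.uniform(*config.s2_duration_range)
        sys_end = config.systole_fraction * period

        i0 = int(round(t0 * fs))
        if i0 >= n_total:
            break
        i_s1_end = int(round((t0 + s1_dur) * fs))
        i_sys_end = int(round((t0 + sys_end) * fs))
        i_s2_end = int(round((t0 + sys_end + s2_dur) * fs))
        i_cycle_end = int(round((t0 + period) * fs))

        s1 = config.s1_s2_amplitude_ratio * _burst(fs, s1_dur, config.s1_band, rng)
        s2 = _burst(fs, s2_dur, config.s2_band, rng)
        for start, wave in ((i0, s1), (i_sys_end, s2)):
            stop = min(start + wave.size, n_total)
            if stop > start:
                samples[start:stop] += wave[: stop - start]

        labels[i0:min(i_s1_end, n_total)] = STATE_INDEX["S1"]
        labels[min(i_s1_end, n_total):min(i_sys_end, n_total)] = STATE_INDEX["systole"]
        labels[min(i_sys_end, n_total):min(i_s2_end, n_total)] = STATE_INDEX["S2"]
        labels[min(i_s2_end, n_total):min(i_cycle_end, n_total)] = STATE_INDEX["diastole"]

        s1_onsets.append(i0)
        s1_centers.append(i0 + int(round(s1_dur * fs / 2)))
        s2_centers.append(i_sys_end + int(round(s2_dur * fs / 2)))
        t0 += period

    if np.isfinite(config.noise_snr):
        p_signal = float(np.mean(samples**2))
        noise_sd = np.sqrt(p_signal / (10.0 ** (config.noise_snr / 10.0)))
        samples = samples + noise_sd * rng.standard_normal(n_total)

    onsets = np.asarray([i for i in s1_onsets if i < n_total], dtype=np.int64)
    return SimulatedRecording(
        samples=samples,
        sampling_rate=fs,
        subject_id=subject_id,
        class_label=config.class_label,
        true_states=StateSequence(labels, fs),
        true_s1_onsets=onsets,
        true_s1_centers=np.asarray([i for i in s1_centers if i < n_total], dtype=np.int64),
        true_s2_centers=np.asarray([i for i in s2_centers if i < n_total], dtype=np.int64),
    )


def simulate_cohort(
    n_lvdd: int,
    n_control: int,
    base_config: Optional[PCGSimConfig] = None,
    seed: int = 0,
) -> List[SimulatedRecording]:
    """Simulate a two-group cohort with per-subject heart rates.

    Subject heart rates are drawn from N(heart_rate_mean, heart_rate_sd),
    clipped to a plausible 45-120 bpm resting range. Each subject gets a
    fresh seed derived from ``seed`` so cohorts are reproducible.
    """
    if n_lvdd < 1 or n_control < 1:
        raise ValueError("each group needs at least one subject")
    rng = np.random.default_rng(seed)
    recordings: List[SimulatedRecording] = []
    for label, n in (("lvdd", n_lvdd), ("control", n_control)):
        for k in range(n):
            hr = float(np.clip(
                (base_config.heart_rate_mean if base_config else 70.0)
                + (base_config.heart_rate_sd if base_config else 5.0) * rng.standard_normal(),
                45.0, 120.0))
            cfg = base_config if base_config is not None else default_config(label)
            s2_high = 150.0 if label == "lvdd" else 200.0
            cfg = replace(
                cfg,
                class_label=label,
                s2_band=(cfg.s2_band[0], s2_high),
                heart_rate_mean=hr,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            recordings.append(simulate_recording(cfg, subject_id=f"{label}_{k:03d}"))
    return recordings


def write_cohort(recordings: Sequence[SimulatedRecording], out_dir: str | Path) -> Path:
    """Write WAV files, a manifest CSV and ground-truth boundary CSVs.

    Returns the manifest path. Layout: ``<out_dir>/<subject_id>.wav`` plus
    ``manifest.csv`` (subject_id, path, label) and ``boundaries.csv``
    (subject_id, state, start_sample, end_sample).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as mf, open(out / "boundaries.csv", "w", newline="") as bf:
        mw = csv.writer(mf)
        bw = csv.writer(bf)
        mw.writerow(["subject_id", "path", "label"])
        bw.writerow(["subject_id", "state", "start_sample", "end_sample"])
        for rec in recordings:
            wav_path = out / f"{rec.subject_id}.wav"
            peak = np.max(np.abs(rec.samples))
            scaled = rec.samples / peak if peak > 0 else rec.samples
            wavfile.write(wav_path, int(rec.sampling_rate), scaled.astype(np.float32))
            mw.writerow([rec.subject_id, wav_path.name, rec.class_label])
            if rec.true_states is not None:
                from .types import STATES
                for start, end, state in rec.true_states.runs():
                    bw.writerow([rec.subject_id, STATES[state], start, end])
    return manifest


def read_manifest(manifest_path: str | Path) -> List[Recording]:
    """Load recordings listed in a manifest CSV written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    recs: List[Recording] = []
    with open(manifest_path, newline="") as f:
        for row in csv.DictReader(f):
            rate, data = wavfile.read(manifest_path.parent / row["path"])
            if data.dtype.kind == "i":
                data = data / float(np.iinfo(data.dtype).max)
            recs.append(Recording(np.asarray(data, dtype=np.float64), float(rate),
                                  subject_id=row["subject_id"], class_label=row["label"] or None))
    return recs
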