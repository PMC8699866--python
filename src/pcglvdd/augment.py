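"""Non-generative audio augmentation of heart-sound frames.

Five techniques expand the dataset before spectrogram imaging: positive and
negative pitch shift, slow and fast time stretch, and silence trimming.
Each augmented signal is re-fitted to exactly the original frame length so
downstream imaging sees a uniform input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .spectro import SpectrogramConfig, frame_to_image
from .types import Frame, SpectrogramImage

__all__ = [
    "AudioAugmentConfig",
    "TECHNIQUES",
    "time_stretch",
    "pitch_shift",
    "trim_silence",
    "augment_audio",
    "augment_nongenerative_dataset",
]

TECHNIQUES = ("pitch_up", "pitch_down", "stretch_slow", "stretch_fast", "trim_silence")


@dataclass
class AudioAugmentConfig:
    pitch_semitones: float = 2.0
    stretch_rates: tuple[float, float] = (0.9, 1.1)
    trim_threshold_db: float = -40.0

    def __post_init__(self) -> None:
        slow, fast = self.stretch_rates
        if not (0 < slow < 1 < fast):
            raise ValueError("stretch rates must satisfy 0 < slow < 1 < fast")


def _stft_cols(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    n_cols = 1 + max(0, (x.size - n_fft)) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_cols)[:, None]
    win = np.hanning(n_fft)
    return np.fft.rfft(x[idx] * win, axis=1).T


def _istft(cols: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    win = np.hanning(n_fft)
    n_cols = cols.shape[1]
    out = np.zeros(n_fft + hop * (n_cols - 1))
    wsum = np.zeros_like(out)
    frames = np.fft.irfft(cols.T, n=n_fft, axis=1)
    for t in range(n_cols):
        out[t * hop:t * hop + n_fft] += frames[t] * win
        wsum[t * hop:t * hop + n_fft] += win**2
    good = wsum > 1e-8
    out[good] /= wsum[good]
    return out


def time_stretch(x: np.ndarray, rate: float, n_fft: int = 256, hop: int = 64) -> np.ndarray:
    """Phase-vocoder time stretch: output duration = len(x) / rate, pitch preserved."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = np.asarray(x, dtype=np.float64)
    D = _stft_cols(x, n_fft, hop)
    n_bins, n_cols = D.shape
    steps = np.arange(0, n_cols - 1, rate)
    phase_adv = 2 * np.pi * hop * np.arange(n_bins) / n_fft
    out = np.empty((n_bins, steps.size), dtype=complex)
    phase = np.angle(D[:, 0])
    for k, t in enumerate(steps):
        i = int(t)
        frac = t - i
        mag = (1 - frac) * np.abs(D[:, i]) + frac * np.abs(D[:, min(i + 1, n_cols - 1)])
        out[:, k] = mag * np.exp(1j * phase)
        dphi = np.angle(D[:, min(i + 1, n_cols - 1)]) - np.angle(D[:, i]) - phase_adv
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase = phase + phase_adv + dphi
    return _istft(out, n_fft, hop)


def pitch_shift(x: np.ndarray, semitones: float, n_fft: int = 256, hop: int = 64) -> np.ndarray:
    """Shift pitch by 2^(semitones/12) while keeping the duration (approximately)."""
    r = 2.0 ** (semitones / 12.0)
    # resample to change pitch (and duration), then stretch the duration back
    from fractions import Fraction
    frac = Fraction(1 / r).limit_denominator(1000)
    resampled = sps.resample_poly(np.asarray(x, dtype=np.float64), frac.numerator, frac.denominator)
    return time_stretch(resampled, rate=1.0 / r, n_fft=n_fft, hop=hop)


def trim_silence(x: np.ndarray, threshold_db: float = -40.0, window: int = 32) -> np.ndarray:
    """Drop leading/trailing samples whose local RMS is below threshold re peak."""
    x = np.asarray(x, dtype=np.float64)
    rms = np.sqrt(np.convolve(x**2, np.ones(window) / window, mode="same"))
    peak = rms.max()
    if peak == 0:
        return x.copy()
    keep = np.flatnonzero(20 * np.log10(rms / peak + 1e-12) > threshold_db)
    if keep.size == 0:
        return x.copy()
    return x[keep[0]:keep[-1] + 1]


def fit_length(x: np.ndarray, n: int) -> np.ndarray:
    """Center-crop or reflection-pad a signal to exactly ``n`` samples."""
    if x.size == n:
        return x
    if x.size > n:
        off = (x.size - n) // 2
        return x[off:off + n]
    pad = n - x.size
    return np.pad(x, (pad // 2, pad - pad // 2), mode="reflect")


def augment_audio(frame: Frame, technique: str,
                  cfg: Optional[AudioAugmentConfig] = None) -> Frame:
    """Apply one augmentation technique; output has the input frame's length."""
    cfg = cfg or AudioAugmentConfig()
    x = frame.samples
    if technique == "pitch_up":
        y = pitch_shift(x, +cfg.pitch_semitones)
    elif technique == "pitch_down":
        y = pitch_shift(x, -cfg.pitch_semitones)
    elif technique == "stretch_slow":
        y = time_stretch(x, cfg.stretch_rates[0])
    elif technique == "stretch_fast":
        y = time_stretch(x, cfg.stretch_rates[1])
    elif technique == "trim_silence":
        y = trim_silence(x, cfg.trim_threshold_db)
    else:
        raise ValueError(f"unknown augmentation technique {technique!r}")
    return Frame(fit_length(y, len(frame)), frame.start_index,
                 subject_id=frame.subject_id, class_label=frame.class_label,
                 sampling_rate=frame.sampling_rate)


def augment_nongenerative_dataset(
    frames: Sequence[Frame],
    cfg: Optional[AudioAugmentConfig] = None,
    spectro_cfg: Optional[SpectrogramConfig] = None,
) -> List[SpectrogramImage]:
    """All five techniques applied to every frame, imaged as spectrograms.

    Returns exactly ``5 * len(frames)`` images tagged ``nongenerative_aug``;
    the originals are not included.
    """
    if not frames:
        raise ValueError("no frames to augment")
    cfg = cfg or AudioAugmentConfig()
    images: List[SpectrogramImage] = []
    for i, frame in enumerate(frames):
        for technique in TECHNIQUES:
            aug = augment_audio(frame, technique, cfg)
            images.append(frame_to_image(
                aug, spectro_cfg, origin="nongenerative_aug",
                frame_ref=f"{frame.subject_id}@{frame.start_index}#{technique}"))
    return images
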