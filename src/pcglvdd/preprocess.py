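"""Preprocessing: resampling to 1000 Hz, wavelet denoising, amplitude normalization.

Heart-sound energy lives in roughly 20-200 Hz, so recordings are decimated to
1000 Hz (comfortably above Nyquist for the band of interest) before wavelet
denoising and peak normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal

from .types import DegenerateSignalError, Recording

__all__ = ["DenoiseConfig", "resample", "denoise", "normalize", "preprocess"]

TARGET_RATE = 1000.0


@dataclass
class DenoiseConfig:
    """Wavelet-denoising parameters.

    Daubechies-6 with 5 decomposition levels and a level-dependent universal
    soft threshold is the default; each detail level is thresholded at
    ``sigma_j * sqrt(2 log n_j)`` with ``sigma_j`` estimated from that
    level's median absolute deviation.
    """

    wavelet_name: str = "db6"
    decomposition_levels: int = 5
    threshold_rule: str = "universal"  # or "sure"
    threshold_mode: str = "soft"  # or "hard"

    def __post_init__(self) -> None:
        if self.decomposition_levels < 1:
            raise ValueError("decomposition_levels must be >= 1")
        if self.threshold_rule not in ("universal", "sure"):
            raise ValueError("threshold_rule must be 'universal' or 'sure'")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")


def resample(rec: Recording, target_rate: float = TARGET_RATE, allow_upsample: bool = False) -> Recording:
    """Anti-aliased polyphase resampling to ``target_rate``.

    Raises ``ValueError`` when upsampling is requested but not allowed.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rec.sampling_rate and not allow_upsample:
        raise ValueError(
            f"refusing to upsample from {rec.sampling_rate} Hz to {target_rate} Hz")
    if target_rate == rec.sampling_rate:
        return rec.with_samples(rec.samples.copy())
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    expected = int(round(len(rec) * target_rate / rec.sampling_rate))
    if out.size > expected:
        out = out[:expected]
    elif out.size < expected:
        out = np.pad(out, (0, expected - out.size))
    return rec.with_samples(out, sampling_rate=target_rate)


def _sure_threshold(coeffs: np.ndarray, sigma: float) -> float:
    """Stein's unbiased risk estimate threshold for one detail level."""
    n = coeffs.size
    sq = np.sort((coeffs / sigma) ** 2)
    cum = np.cumsum(sq)
    risks = (n - 2 * np.arange(1, n + 1) + cum + (n - np.arange(1, n + 1)) * sq) / n
    return float(sigma * np.sqrt(sq[np.argmin(risks)]))


def denoise(rec: Recording, cfg: DenoiseConfig | None = None) -> Recording:
    """Wavelet shrinkage denoising; preserves length.

    The signal is decomposed with the configured wavelet, detail coefficients
    are shrunk (soft or hard) with a per-level threshold, and the signal is
    reconstructed. An all-zero input is returned unchanged.
    """
    cfg = cfg or DenoiseConfig()
    x = rec.samples
    if x.size <= 2**cfg.decomposition_levels:
        raise ValueError("signal too short for the requested decomposition depth")
    if not np.any(x):
        return rec.with_samples(x.copy())
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.decomposition_levels, mode="symmetric")
    # noise scale from the finest detail level (robust to in-band signal),
    # threshold per level through its coefficient count
    sigma = float(np.median(np.abs(coeffs[-1])) / 0.6745)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        if sigma == 0.0:
            out.append(detail)
            continue
        if cfg.threshold_rule == "universal":
            thr = sigma * np.sqrt(2.0 * np.log(detail.size))
        else:
            thr = _sure_threshold(detail, sigma)
        out.append(pywt.threshold(detail, thr, mode=cfg.threshold_mode))
    rebuilt = pywt.waverec(out, cfg.wavelet_name, mode="symmetric")
    return rec.with_samples(rebuilt[: x.size])


def normalize(rec: Recording) -> Recording:
    """Scale so the maximum absolute amplitude is exactly 1.

    S_norm[n] = S[n] / max_n |S[n]|. All-zero input raises
    :class:`DegenerateSignalError`.
    """
    peak = float(np.max(np.abs(rec.samples)))
    if peak == 0.0:
        raise DegenerateSignalError("cannot normalize an all-zero signal")
    return rec.with_samples(rec.samples / peak)


def preprocess(rec: Recording, target_rate: float = TARGET_RATE,
               cfg: DenoiseConfig | None = None) -> Recording:
    """resample -> denoise -> normalize, the standard preparation chain."""
    return normalize(denoise(resample(rec, target_rate), cfg))
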