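"""STFT log-spectrogram imaging of 1.6 s heart-sound frames.

The short-time Fourier transform S(t, f) of a frame s is computed with a
256-sample Hann window; the log-power matrix is min-max scaled to [0, 1]
and shaped into a 128x128 3-channel image, the input format of both the
classifier and the GAN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .types import Frame, SpectrogramImage

__all__ = ["SpectrogramConfig", "stft", "spectrogram_image", "frame_to_image", "save_png"]


@dataclass
class SpectrogramConfig:
    """Imaging parameters.

    With the defaults a 1600-sample frame yields 135 STFT columns of which
    the central 128 are kept; the one-sided spectrum has 129 bins and the
    Nyquist bin is dropped, giving a 128x128 image.
    """

    window_length: int = 256
    hop: int = 10
    fft_length: int = 256
    log_epsilon: float = 1e-10
    output_size: Tuple[int, int] = (128, 128)
    channel_mode: str = "replicate3"  # or "colormap"

    def __post_init__(self) -> None:
        if self.window_length != self.fft_length:
            raise ValueError("window_length must equal fft_length")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        h, w = self.output_size
        base = self.fft_length // 2
        if base % h or base % w:
            raise ValueError(f"output_size must divide the {base}-point base grid")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")
        if self.channel_mode not in ("replicate3", "colormap"):
            raise ValueError("channel_mode must be 'replicate3' or 'colormap'")

    def window(self) -> np.ndarray:
        # periodic Hann: integer-bin nulls, the standard analysis window
        n = np.arange(self.window_length)
        return 0.5 - 0.5 * np.cos(2 * np.pi * n / self.window_length)


def stft(samples: np.ndarray | Frame, cfg: Optional[SpectrogramConfig] = None) -> np.ndarray:
    """One-sided STFT matrix, shape (fft_length // 2 + 1, n_columns).

    Column t is the DFT of ``samples[t*hop : t*hop + L]`` multiplied by the
    Hann window; trailing samples that do not fill a window are dropped.
    """
    cfg = cfg or SpectrogramConfig()
    x = samples.samples if isinstance(samples, Frame) else np.asarray(samples, dtype=np.float64)
    L = cfg.window_length
    if x.ndim != 1 or x.size < L:
        raise ValueError(f"frame must be 1-D with at least {L} samples")
    n_cols = 1 + (x.size - L) // cfg.hop
    idx = np.arange(L)[None, :] + cfg.hop * np.arange(n_cols)[:, None]
    frames = x[idx] * cfg.window()[None, :]
    return np.fft.rfft(frames, n=cfg.fft_length, axis=1).T


def spectrogram_image(
    S: np.ndarray,
    cfg: Optional[SpectrogramConfig] = None,
    *,
    class_label: Optional[str] = None,
    subject_id: str = "",
    frame_ref: str = "",
    origin: str = "real",
) -> SpectrogramImage:
    """Log-power image from an STFT matrix.

    log(|S|^2 + eps) is min-max rescaled per image to [0, 1]; the frequency
    axis keeps bins 0..127 (Nyquist dropped), the time axis is center-cropped
    (or symmetrically edge-padded) to 128 columns. Row 0 is DC. A constant
    matrix maps to all zeros with a warning.
    """
    cfg = cfg or SpectrogramConfig()
    h, w = cfg.output_size
    base = cfg.fft_length // 2  # 128 frequency rows; Nyquist bin dropped
    logpow = np.log(np.abs(S) ** 2 + cfg.log_epsilon)

    logpow = logpow[:base, :]
    n_cols = logpow.shape[1]
    if n_cols >= base:
        off = (n_cols - base) // 2
        logpow = logpow[:, off:off + base]
    else:
        pad = base - n_cols
        logpow = np.pad(logpow, ((0, 0), (pad // 2, pad - pad // 2)), mode="edge")

    lo, hi = float(logpow.min()), float(logpow.max())
    if hi == lo:
        warnings.warn("constant spectrogram; emitting an all-zero image")
        scaled = np.zeros_like(logpow)
    else:
        scaled = (logpow - lo) / (hi - lo)

    if (h, w) != (base, base):
        # desk-scale sizes: average-pool the full-band grid so the whole
        # frequency range survives downsizing
        scaled = scaled.reshape(h, base // h, w, base // w).mean(axis=(1, 3))

    if cfg.channel_mode == "replicate3":
        pixels = np.repeat(scaled[:, :, None], 3, axis=2)
    else:
        # simple blue->red heat palette for visual inspection
        pixels = np.stack([scaled, 4 * scaled * (1 - scaled), 1 - scaled], axis=2)
    return SpectrogramImage(pixels.astype(np.float32), class_label=class_label,
                            subject_id=subject_id, frame_ref=frame_ref, origin=origin)


def frame_to_image(frame: Frame, cfg: Optional[SpectrogramConfig] = None,
                   origin: str = "real", frame_ref: str = "") -> SpectrogramImage:
    """Convenience: STFT + imaging with the frame's provenance attached."""
    S = stft(frame, cfg)
    return spectrogram_image(
        S, cfg,
        class_label=frame.class_label,
        subject_id=frame.subject_id,
        frame_ref=frame_ref or f"{frame.subject_id}@{frame.start_index}",
        origin=origin,
    )


def save_png(image: SpectrogramImage, path: str | Path) -> None:
    """Write an 8-bit PNG (frequency increasing downward flipped to upward)."""
    from PIL import Image

    arr = (np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr[::-1]).save(str(path))
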