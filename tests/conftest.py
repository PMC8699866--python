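"""Shared fixtures: small simulated recordings and separable synthetic image sets."""

from __future__ import annotations

import numpy as np
import pytest

from pcglvdd.synth import default_config, simulate_recording
from pcglvdd.types import SpectrogramImage


@pytest.fixture(scope="session")
def clean_recording():
    """10 s noise-free simulated PCG at 8 kHz (LVDD class)."""
    cfg = default_config("lvdd", duration=10.0, noise_snr=np.inf, seed=11)
    return simulate_recording(cfg, "clean_lvdd")


@pytest.fixture(scope="session")
def clean_cohort():
    """Six clean 30 s recordings, alternating classes, varied heart rates."""
    recs = []
    for i in range(6):
        label = "lvdd" if i % 2 else "control"
        cfg = default_config(label, duration=30.0, noise_snr=np.inf, seed=300 + i,
                             heart_rate_mean=58 + 4 * i)
        recs.append(simulate_recording(cfg, f"{label}_{i}"))
    return recs


def make_band_images(n_per_class: int, size: int = 32, seed: int = 0,
                     n_subjects: int = 8) -> list[SpectrogramImage]:
    """Two trivially separable classes: a bright horizontal band in the lower
    (lvdd) vs upper (control) half of the image, on a dim noise background."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_per_class):
        for label, row in (("lvdd", size // 5), ("control", size * 7 // 10)):
            px = 0.1 * rng.random((size, size, 3)).astype(np.float32)
            px[row:row + max(2, size // 6), :, :] += 0.8
            out.append(SpectrogramImage(np.clip(px, 0, 1), class_label=label,
                                        subject_id=f"{label[0]}{i % n_subjects}"))
    return out


@pytest.fixture
def band_images():
    return make_band_images
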