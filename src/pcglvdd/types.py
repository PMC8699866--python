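"""Core containers shared across the pipeline.

A recording flows through preprocessing and segmentation as a
:class:`Recording`; segmentation yields a per-sample :class:`StateSequence`
over the four cardiac states (S1, systole, S2, diastole); framing cuts 1.6 s
:class:`Frame` windows at detected S1 onsets; spectrogram imaging turns each
frame into a :class:`SpectrogramImage` consumed by augmentation and
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

#: Cyclic state order of the cardiac period.
STATES: Tuple[str, str, str, str] = ("S1", "systole", "S2", "diastole")
STATE_INDEX = {name: i for i, name in enumerate(STATES)}

#: Class labels. LVDD is the positive class throughout.
CLASSES: Tuple[str, str] = ("control", "lvdd")
CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}


class DegenerateSignalError(ValueError):
    """Raised when an operation receives an all-zero or otherwise unusable signal."""


@dataclass
class Recording:
    """Mono PCG amplitude series with provenance.

    Parameters
    ----------
    samples : 1-D float array
    sampling_rate : Hz
    subject_id : identifier used for subject-wise cross-validation
    class_label : ``"lvdd"`` or ``"control"`` (optional until labelled)
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.class_label is not None and self.class_label not in CLASS_INDEX:
            raise ValueError(f"unknown class label {self.class_label!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def with_samples(self, samples: np.ndarray, sampling_rate: Optional[float] = None) -> "Recording":
        return replace(
            self,
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
        )


@dataclass
class StateSequence:
    """Per-sample cardiac-state labels (integer codes into :data:`STATES`)."""

    labels: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")

    def __len__(self) -> int:
        return self.labels.size

    def runs(self) -> list[tuple[int, int, int]]:
        """Half-open ``(start, end, state)`` runs in order of appearance."""
        lab = self.labels
        if lab.size == 0:
            return []
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lab.size]))
        return [(int(s), int(e), int(lab[s])) for s, e in zip(starts, ends)]

    def onsets(self, state: str = "S1") -> np.ndarray:
        """Sample indices where runs of ``state`` begin."""
        code = STATE_INDEX[state]
        lab = self.labels
        is_state = lab == code
        begin = np.flatnonzero(is_state & ~np.concatenate(([False], is_state[:-1])))
        return begin

    def check_cyclic(self) -> None:
        """Assert the run sequence follows S1 -> systole -> S2 -> diastole cyclically."""
        runs = self.runs()
        for (_, _, a), (_, _, b) in zip(runs, runs[1:]):
            if b != (a + 1) % 4:
                raise ValueError(f"state order violated: {STATES[a]} -> {STATES[b]}")


@dataclass
class Frame:
    """Fixed-length analysis window starting at a detected S1 onset."""

    samples: np.ndarray
    start_index: int
    subject_id: str = ""
    class_label: Optional[str] = None
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SpectrogramImage:
    """128x128x3 (by default) image in [0, 1] with provenance.

    ``origin`` is one of ``"real"``, ``"nongenerative_aug"``, ``"gan_generated"``.
    """

    pixels: np.ndarray
    class_label: Optional[str] = None
    subject_id: str = ""
    frame_ref: str = ""
    origin: str = "real"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.origin not in ("real", "nongenerative_aug", "gan_generated"):
            raise ValueError(f"unknown origin {self.origin!r}")


def stack_pixels(images: Sequence[SpectrogramImage]) -> np.ndarray:
    """Stack image pixels into an (N, C, H, W) float32 batch."""
    return np.stack([img.pixels.transpose(2, 0, 1) for img in images]).astype(np.float32)


def labels_of(images: Sequence[SpectrogramImage]) -> np.ndarray:
    """Integer class labels of a set of images (control=0, lvdd=1)."""
    out = np.empty(len(images), dtype=np.int64)
    for i, img in enumerate(images):
        if img.class_label is None:
            raise ValueError("image without class label")
        out[i] = CLASS_INDEX[img.class_label]
    return out
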