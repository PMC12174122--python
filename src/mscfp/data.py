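"""In-memory containers for the THz imaging pipeline.

The acquisition analogue is a per-pixel picosecond waveform cube
(:class:`THzVolume`); its Fourier transform is a per-pixel magnitude
spectrum cube (:class:`SpectralVolume`); a single frequency bin of that
cube, taken across all pixels, is the 2-D image that feeds the classifier
(:class:`LabeledImageSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four mold degrees, ordered from sound grain to heaviest encapsulation.
MOLD_CLASSES = ("normal", "slight", "moderate", "serious")

TRAIN, TEST = "train", "test"


@dataclass
class THzVolume:
    """Time-domain cube [H, W, T] with a uniform picosecond time axis."""

    data: np.ndarray
    time_axis: np.ndarray  # ps, length T, uniform over [0, time_window)
    pixel_pitch: float = 0.1  # mm

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("THzVolume.data must be [H, W, T]")
        if len(self.time_axis) != self.data.shape[2]:
            raise ValueError("time axis length must match the T dimension")

    @property
    def time_window(self) -> float:
        """Scan window in ps (the axis is uniform over [0, window))."""
        t = self.time_axis
        return float(t[-1] + (t[1] - t[0]))

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SpectralVolume:
    """Frequency-domain magnitude cube [H, W, F] with a THz frequency axis."""

    data: np.ndarray
    freq_axis: np.ndarray  # THz, length F, uniform, freq_axis[0] >= 0

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("SpectralVolume.data must be [H, W, F]")
        if len(self.freq_axis) != self.data.shape[2]:
            raise ValueError("frequency axis length must match the F dimension")
        if self.freq_axis[0] < 0:
            raise ValueError("frequency axis must be non-negative")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabeledImageSet:
    """2-D grayscale images with 4-way mold labels and train/test tags."""

    images: list[np.ndarray]
    labels: np.ndarray                      # int class ids into MOLD_CLASSES
    split: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        if not self.split:
            self.split = [TRAIN] * len(self.images)
        if len(self.split) != len(self.images):
            raise ValueError("one split tag per image required")
        bad = set(self.labels) - set(range(len(MOLD_CLASSES)))
        if bad:
            raise ValueError(f"unknown class ids: {sorted(bad)}")

    def __len__(self):
        return len(self.images)

    def subset(self, tag: str) -> "LabeledImageSet":
        idx = [i for i, s in enumerate(self.split) if s == tag]
        return LabeledImageSet([self.images[i] for i in idx],
                               self.labels[idx], [tag] * len(idx))

    def as_array(self) -> np.ndarray:
        """Stack into [N, 1, H, W] for the network."""
        return np.stack(self.images)[:, None]
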