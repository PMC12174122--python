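"""THz preprocessing chain: FFT, frequency slicing, background removal, split.

A 180x180x9000-point time-domain cube becomes a 180x180x300 magnitude
spectrum cube (lowest 300 non-negative-frequency bins; bin spacing
1/90 ps ~ 11.1 GHz), from which the 0.3 THz slice is extracted, the kernel
foreground is isolated (Otsu threshold + largest connected component), and
the labelled images are split 9:1 per class into train and test sets.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.fft
from skimage.filters import threshold_otsu
from skimage.measure import label

from .data import TEST, TRAIN, LabeledImageSet, SpectralVolume, THzVolume

log = logging.getLogger(__name__)

DEFAULT_N_KEEP = 300
DEFAULT_SLICE_THZ = 0.3


def time_to_frequency(vol: THzVolume, n_keep: int = DEFAULT_N_KEEP) -> SpectralVolume:
    """Per-pixel DFT magnitude, truncated to the first ``n_keep`` bins.

    The frequency axis is ``k / time_window`` (THz when time is in ps),
    k = 0..n_keep-1, so the default 300 bins of a 90 ps scan span
    0 to ~3.32 THz.
    """
    h, w, t_len = vol.data.shape
    if n_keep > t_len // 2 + 1:
        raise ValueError(f"n_keep={n_keep} exceeds the {t_len // 2 + 1} "
                         "non-negative-frequency bins available")
    # row-chunked so a full 180x180x9000 cube never holds two copies of the
    # untruncated spectrum in memory; scipy.fft keeps float32 in single
    # precision (numpy.fft would promote to float64)
    spectrum = np.empty((h, w, n_keep), dtype=vol.data.dtype)
    chunk = max(1, int(2e7) // (w * t_len))
    for i in range(0, h, chunk):
        spectrum[i:i + chunk] = np.abs(
            scipy.fft.rfft(vol.data[i:i + chunk], axis=2)[:, :, :n_keep])
    freq_axis = np.arange(n_keep) / vol.time_window
    return SpectralVolume(data=spectrum, freq_axis=freq_axis)


def select_frequency_slice(sv: SpectralVolume, f: float = DEFAULT_SLICE_THZ
                           ) -> np.ndarray:
    """The [H, W] image at the bin nearest ``f`` (ties toward the lower bin)."""
    axis = sv.freq_axis
    if not (axis[0] <= f <= axis[-1]):
        raise ValueError(f"frequency {f} THz outside the axis range "
                         f"[{axis[0]:.4f}, {axis[-1]:.4f}]")
    k = int(np.argmin(np.abs(axis - f)))   # argmin keeps the first (lower) tie
    return sv.data[:, :, k]


def remove_background(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero everything but the kernel body.

    The mask is the largest connected component above Otsu's global
    threshold; a constant image yields an empty mask (with a warning).
    Returns ``(masked_image, mask)``.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(img) == 0:
        log.warning("constant image: background removal yields an empty mask")
        mask = np.zeros(img.shape, dtype=bool)
        return img * mask, mask
    thresh = threshold_otsu(img)
    above = img > thresh
    labels_img = label(above, connectivity=2)
    if labels_img.max() == 0:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        counts = np.bincount(labels_img.ravel())
        counts[0] = 0
        mask = labels_img == counts.argmax()
    return img * mask, mask


def split_dataset(image_set: LabeledImageSet, ratio: float = 0.9,
                  seed: int = 0) -> LabeledImageSet:
    """Stratified train/test split: round(ratio * n_class) train per class.

    Deterministic in ``seed``; returns a new set with split tags assigned
    (1200 balanced images at ratio 0.9 give 1080 train / 120 test).
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    labels = image_set.labels
    split = [None] * len(image_set)
    rng = np.random.default_rng(seed)
    for cid in np.unique(labels):
        idx = np.flatnonzero(labels == cid)
        if idx.size == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"class {cid} has no images")
        perm = rng.permutation(idx)
        n_train = int(np.floor(ratio * idx.size + 0.5))
        for i in perm[:n_train]:
            split[i] = TRAIN
        for i in perm[n_train:]:
            split[i] = TEST
    classes_present = set(labels)
    missing = set(range(4)) - classes_present
    if missing:
        raise ValueError(f"classes without images: {sorted(missing)}")
    return LabeledImageSet(images=list(image_set.images),
                           labels=labels.copy(), split=split)
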