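"""Synthetic THz volumes and slice images for the four wheat mold degrees.

No public moldy-wheat THz dataset exists, so this module generates data
with the same statistical structure the instrument produces: an elliptical
kernel on an empty background, a per-pixel single-cycle pulse whose
spectrum peaks near 0.3 THz and decays beyond 0.5 THz, and a mold-degree
effect modelled as progressive foreground attenuation (mold encapsulation
damps the reflected signal) plus increasing surface-texture roughness.

The generator is the package's study-condition definition, not a physics
simulation: Fresnel reflection, dispersion and mycotoxin chemistry are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import MOLD_CLASSES, LabeledImageSet, THzVolume

#: Pulse carrier in THz — the band where the measured spectra peak.
CARRIER_THZ = 0.3
#: Gaussian envelope width (ps) chosen so the spectral magnitude halves by
#: 0.6 THz: sigma_f = 0.3/sqrt(2 ln 2) THz, sigma_t = 1/(2 pi sigma_f).
PULSE_SIGMA_PS = 1.0 / (2.0 * np.pi * (CARRIER_THZ / np.sqrt(2.0 * np.log(2.0))))
#: Pulse arrival time (ps) inside the scan window.
PULSE_DELAY_PS = 10.0

#: Reflected-signal level per class: encapsulation lightens the kernel body,
#: so the level decreases strictly from normal to serious.
DEFAULT_FOREGROUND_LEVELS = {"normal": 0.90, "slight": 0.75,
                             "moderate": 0.60, "serious": 0.45}
#: Multiplicative surface-roughness amplitude, strictly increasing with mold.
DEFAULT_TEXTURE_SIGMAS = {"normal": 0.02, "slight": 0.06,
                          "moderate": 0.10, "serious": 0.15}


@dataclass
class GeneratorConfig:
    n_per_class: int = 300
    image_size: int = 180
    n_time: int = 9000
    time_window: float = 90.0          # ps
    class_params: dict = field(default_factory=dict)
    noise_sigma: float = 0.01
    seed: int = 0
    pixel_pitch: float = 0.1           # mm

    def __post_init__(self):
        if not self.class_params:
            self.class_params = {
                name: {"foreground_level": DEFAULT_FOREGROUND_LEVELS[name],
                       "texture_sigma": DEFAULT_TEXTURE_SIGMAS[name]}
                for name in MOLD_CLASSES
            }
        if tuple(self.class_params) != MOLD_CLASSES:
            raise ValueError(f"class_params must cover exactly {MOLD_CLASSES}")
        if self.n_per_class <= 0 or self.image_size <= 0 or self.n_time <= 0 \
                or self.time_window <= 0:
            raise ValueError("dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        fg = [self.class_params[c]["foreground_level"] for c in MOLD_CLASSES]
        tx = [self.class_params[c]["texture_sigma"] for c in MOLD_CLASSES]
        if not all(0 < v <= 1 for v in fg):
            raise ValueError("foreground_level must lie in (0, 1]")
        if any(b >= a for a, b in zip(fg, fg[1:])):
            raise ValueError("foreground_level must strictly decrease "
                             "normal -> serious")
        if any(v < 0 for v in tx):
            raise ValueError("texture_sigma must be >= 0")
        if any(b <= a for a, b in zip(tx, tx[1:])):
            raise ValueError("texture_sigma must strictly increase "
                             "normal -> serious")

    @classmethod
    def easy(cls, n_per_class: int = 60, image_size: int = 64, seed: int = 0,
             **kw) -> "GeneratorConfig":
        """Widely separated classes — the sanity floor for training tests."""
        params = {
            "normal": {"foreground_level": 0.95, "texture_sigma": 0.02},
            "slight": {"foreground_level": 0.70, "texture_sigma": 0.10},
            "moderate": {"foreground_level": 0.45, "texture_sigma": 0.25},
            "serious": {"foreground_level": 0.20, "texture_sigma": 0.45},
        }
        return cls(n_per_class=n_per_class, image_size=image_size, seed=seed,
                   class_params=params, **kw)


def _class_id(class_id) -> int:
    if isinstance(class_id, str):
        if class_id not in MOLD_CLASSES:
            raise ValueError(f"unknown class {class_id!r}; "
                             f"expected one of {MOLD_CLASSES}")
        return MOLD_CLASSES.index(class_id)
    cid = int(class_id)
    if not 0 <= cid < len(MOLD_CLASSES):
        raise ValueError(f"class id {cid} out of range")
    return cid


def _sample_rng(cfg: GeneratorConfig, cid: int, index: int) -> np.random.Generator:
    # Counter-style stream keyed on (seed, class, index): regenerating any
    # single sample is independent of generation order.
    return np.random.default_rng([cfg.seed, cid, index])


def sample_fields(cfg: GeneratorConfig, class_id, index: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free reflectance field and ground-truth kernel mask.

    Returns ``(amplitude, mask)``: the elliptical wheat-kernel foreground at
    the class's attenuation level, modulated by a smoothed multiplicative
    texture field, and the boolean ellipse mask itself (the oracle for
    background-removal tests).
    """
    cid = _class_id(class_id)
    if not 0 <= index < cfg.n_per_class:
        raise ValueError(f"index {index} out of range for n_per_class="
                         f"{cfg.n_per_class}")
    rng = _sample_rng(cfg, cid, index)
    n = cfg.image_size
    scale = n / 180.0
    jitter = 5.0 * scale
    cy = n / 2.0 + rng.uniform(-jitter, jitter)
    cx = n / 2.0 + rng.uniform(-jitter, jitter)
    a, b = 55.0 * scale, 35.0 * scale            # wheat-kernel aspect
    yy, xx = np.mgrid[0:n, 0:n]
    mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0

    p = cfg.class_params[MOLD_CLASSES[cid]]
    rough = rng.standard_normal((n, n))
    rough = gaussian_filter(rough, sigma=max(1.0, 3.0 * scale))
    sd = rough.std()
    if sd > 0:
        rough /= sd
    texture = np.clip(1.0 + p["texture_sigma"] * rough, 0.05, None)
    amplitude = np.where(mask, p["foreground_level"] * texture, 0.0)
    return amplitude, mask


def pulse_waveform(time_axis: np.ndarray) -> np.ndarray:
    """Unit-amplitude Gaussian-windowed cosine pulse on ``time_axis`` (ps)."""
    t = np.asarray(time_axis, dtype=np.float64) - PULSE_DELAY_PS
    return np.cos(2.0 * np.pi * CARRIER_THZ * t) * \
        np.exp(-t ** 2 / (2.0 * PULSE_SIGMA_PS ** 2))


def generate_volume(cfg: GeneratorConfig, class_id, index: int) -> THzVolume:
    """One synthetic time-domain cube [H, W, T] for a single kernel.

    Foreground pixels carry the amplitude-scaled pulse; background pixels
    are pure noise (zero when ``noise_sigma`` is 0). Deterministic in
    ``(seed, class_id, index)``.
    """
    cid = _class_id(class_id)
    amplitude, _ = sample_fields(cfg, cid, index)
    time_axis = np.arange(cfg.n_time) * (cfg.time_window / cfg.n_time)
    pulse = pulse_waveform(time_axis).astype(np.float32)
    data = amplitude.astype(np.float32)[:, :, None] * pulse[None, None, :]
    if cfg.noise_sigma > 0:
        noise_rng = np.random.default_rng([cfg.seed, cid, index, 1])
        data += noise_rng.normal(0.0, cfg.noise_sigma,
                                 size=data.shape).astype(np.float32)
    return THzVolume(data=data, time_axis=time_axis, pixel_pitch=cfg.pixel_pitch)


def generate_image_set(cfg: GeneratorConfig) -> LabeledImageSet:
    """All ``4 * n_per_class`` slice images, bypassing the volume path.

    Each image equals the sample's reflectance field plus background noise —
    the same foreground/texture statistics the volume path yields at the
    0.3 THz slice, up to the pulse's fixed spectral gain.
    """
    images, labels = [], []
    for cid in range(len(MOLD_CLASSES)):
        for index in range(cfg.n_per_class):
            amplitude, _ = sample_fields(cfg, cid, index)
            img = amplitude
            if cfg.noise_sigma > 0:
                noise_rng = np.random.default_rng([cfg.seed, cid, index, 2])
                img = img + noise_rng.normal(0.0, cfg.noise_sigma, amplitude.shape)
            images.append(img)
            labels.append(cid)
    return LabeledImageSet(images=images, labels=np.array(labels))
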