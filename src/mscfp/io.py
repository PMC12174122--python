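"""Disk formats: HDF5 volume containers, 16-bit PNG slices, CSV manifests.

Volumes are stored as one HDF5 dataset per sample with the time axis and
pixel pitch in a JSON sidecar; image sets are 16-bit grayscale PNGs plus a
``manifest.csv`` with fixed columns ``path,class,split``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .data import MOLD_CLASSES, LabeledImageSet, THzVolume

MANIFEST_COLUMNS = ["path", "class", "split"]


def save_volumes(path, volumes: list[THzVolume], names: list[str]):
    """Write volumes to one HDF5 file + JSON axis sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for name, vol in zip(names, volumes):
            fh.create_dataset(name, data=vol.data)
    sidecar = {
        "time_axis_ps": np.asarray(volumes[0].time_axis).tolist(),
        "pixel_pitch_mm": volumes[0].pixel_pitch,
        "datasets": list(names),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_volumes(path) -> list[THzVolume]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    time_axis = np.asarray(sidecar["time_axis_ps"])
    out = []
    with h5py.File(path, "r") as fh:
        for name in sidecar["datasets"]:
            out.append(THzVolume(data=fh[name][...], time_axis=time_axis,
                                 pixel_pitch=sidecar["pixel_pitch_mm"]))
    return out


def _to_uint16(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    span = hi - lo if hi > lo else 1.0
    return ((img - lo) / span * 65535.0).round().astype(np.uint16)


def save_image_set(out_dir, image_set: LabeledImageSet) -> Path:
    """PNG per image + manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, cid, split) in enumerate(zip(image_set.images,
                                              image_set.labels,
                                              image_set.split)):
        cls = MOLD_CLASSES[cid]
        rel = f"{cls}_{i:05d}.png"
        iio.imwrite(out_dir / rel, _to_uint16(img))
        rows.append({"path": rel, "class": cls, "split": split})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_image_set(manifest_path) -> LabeledImageSet:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    images, labels, split = [], [], []
    for _, row in df.iterrows():
        img = iio.imread(root / row["path"]).astype(np.float64) / 65535.0
        images.append(img)
        labels.append(MOLD_CLASSES.index(row["class"]))
        split.append(row["split"])
    return LabeledImageSet(images=images, labels=np.array(labels), split=split)
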