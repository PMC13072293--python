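"""Reading and writing the package's on-disk formats.

Images come in as JPEG or PNG and always go out as PNG (lossless, so the
artifact-suppression step is not undone by re-compression).  Binary masks
are single-channel PNGs with 0 = outside, 255 = inside.  Per-pixel float
maps (concentration, anomaly scores) are stored in HDF5; tabular pixel data
as CSV; configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image

from .frame import as_frame


def read_frame(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG image as an (H, W, 3) uint8 RGB frame."""
    with Image.open(path) as im:
        return as_frame(np.asarray(im.convert("RGB")))


def write_frame(path: str | Path, frame: np.ndarray) -> None:
    """Write a frame as PNG (the extension must be .png)."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError("processed output is written losslessly; use a .png path")
    Image.fromarray(as_frame(frame), mode="RGB").save(path, format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a boolean plane."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=bool)
    Image.fromarray((mask * np.uint8(255)), mode="L").save(Path(path), format="PNG")


def write_float_map(path: str | Path, name: str, data: np.ndarray, **attrs) -> None:
    """Store a per-pixel float plane (e.g. concentration map) in HDF5."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=np.asarray(data, dtype=np.float32))
        for k, v in attrs.items():
            ds.attrs[k] = v


def read_float_map(path: str | Path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return np.asarray(f[name])


def read_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def write_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)
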