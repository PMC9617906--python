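"""Serialisation helpers: kinetic constants (YAML/JSON), images (TIFF).

Concentration unit conventions follow the experimental figure captions —
ATP in uM, proteins in nM, lengths in um — and the observation-table column
names carry the units (atp_uM, motors_nM, prc1_nM, mt_length_um).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .inference import Priors
from .kinetics import KineticConstants

__all__ = ["save_constants", "load_constants", "load_priors",
           "read_image", "write_image", "read_stack"]


def save_constants(k: KineticConstants, path) -> None:
    path = Path(path)
    data = dataclasses.asdict(k)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def load_constants(path) -> KineticConstants:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return KineticConstants(**data)


def load_priors(path) -> Priors:
    data = yaml.safe_load(Path(path).read_text())
    return Priors(**{key: tuple(value) for key, value in data.items()})


def read_image(path) -> np.ndarray:
    """Single-page grayscale TIFF (8/16-bit or float) as a float array."""
    img = tifffile.imread(path)
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    return np.asarray(img, dtype=float)


def read_stack(path) -> np.ndarray:
    """Multi-page TIFF as a (frames, H, W) float array."""
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_image(path, image, as_uint16: bool = True) -> None:
    img = np.asarray(image)
    if as_uint16:
        lo, hi = float(img.min()), float(img.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        img = ((img - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, img)
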