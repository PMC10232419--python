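"""Image and config I/O: float/uint16 TIFF, read-only PNG, YAML/JSON configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["read_image", "write_float_tiff", "write_uint16_tiff", "load_config_file", "provenance"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D grayscale image (TIFF preferred; PNG accepted read-only)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        img = np.asarray(Image.open(path).convert("F"))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {img.shape}")
    return img


def write_float_tiff(path: str | Path, img: np.ndarray) -> None:
    """Lossless 32-bit float TIFF — the interchange format of the pipeline."""
    tifffile.imwrite(Path(path), np.asarray(img, dtype=np.float32))


def write_uint16_tiff(path: str | Path, img: np.ndarray) -> dict:
    """16-bit TIFF for viewers; returns the scale/offset of the mapping.

    The image is mapped affinely onto [0, 65535]; the returned dict records
    the transform so values can be recovered.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    out = np.round((img - lo) * scale).astype(np.uint16)
    tifffile.imwrite(Path(path), out)
    meta = {"offset": lo, "scale": scale}
    Path(path).with_suffix(".scale.json").write_text(json.dumps(meta))
    return meta


def load_config_file(path: str | Path) -> dict:
    """Load a flat YAML or JSON configuration file (dialect sniffed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    # YAML is a superset of JSON, so this covers both dialects
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def provenance(config: dict, seed: int | None) -> dict:
    """Machine-readable run record: config hash, seed, library versions."""
    import bsscatter

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {
            "bsscatter": bsscatter.__version__,
            "numpy": np.__version__,
        },
    }
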