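"""Image and table I/O.

Images are TIFF or PNG; intensities are passed through without
rescaling so ratios and thresholds operate on the recorded values.
Tables are CSV with a single leading comment line recording the seed
and a hash of the run configuration, so every output file identifies
the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "assemble_channels",
    "write_gradient_tiff",
    "write_rgb_image",
    "write_ground_truth",
    "read_ground_truth",
    "config_hash",
    "write_table",
    "read_table",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_SUPPORTED = _TIFF_SUFFIXES | {".png"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG image, preserving dtype and intensities.

    Multi-page grayscale TIFFs come back as (C, H, W); RGB images as
    (H, W, 3); single-channel images as (H, W).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _SUPPORTED:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    if suffix in _TIFF_SUFFIXES:
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def assemble_channels(signal_path: str | Path, nuclear_path: str | Path) -> np.ndarray:
    """Stack two single-channel images into a (2, H, W) signal+nuclear image."""
    signal = read_image(signal_path)
    nuclear = read_image(nuclear_path)
    if signal.ndim != 2 or nuclear.ndim != 2:
        raise ValueError("channel files must be single-channel 2-D images")
    if signal.shape != nuclear.shape:
        raise ValueError("signal and nuclear channels must have the same shape")
    return np.stack([signal, nuclear]).astype(np.float64)


def write_gradient_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a (2, H, W) image as a 2-page grayscale float32 TIFF."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a (2, H, W) two-channel image")
    tifffile.imwrite(Path(path), image.astype(np.float32))


def write_rgb_image(path: str | Path, image: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 image as PNG or TIFF."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def write_ground_truth(path: str | Path, record: dict) -> None:
    """Write a phantom's ground-truth sidecar as JSON."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config: dict | None) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a CSV with a single header-comment line (seed + config hash)."""
    path = Path(path)
    header = f"# embryoquant seed={seed} config_sha256={config_hash(config)}\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
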