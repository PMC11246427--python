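"""Raster I/O: multichannel TIFF and per-channel PNG round trips.

Intensities are never rescaled on read — 8/16-bit integers map to the same
real values in memory, so thresholds and correlation statistics are
independent of the file dialect.  Channel names and pixel size ride along in
the TIFF image description as JSON and survive a write/read round trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import FieldImage

__all__ = ["read_field_image", "write_field_image", "write_labels"]


def write_field_image(image: FieldImage, path: str | Path) -> None:
    """Write a FieldImage as a multichannel (C, H, W) TIFF with JSON metadata."""
    path = Path(path)
    stack = image.to_stack()
    desc = json.dumps(
        {"channels": image.channel_names, "px_size_um": image.px_size_um}
    )
    tifffile.imwrite(path, stack, description=desc, photometric="minisblack")


def read_field_image(
    path: str | Path | Mapping[str, str | Path],
    channel_names: list[str] | None = None,
    px_size_um: float | None = None,
) -> FieldImage:
    """Read a multichannel TIFF, or a mapping of channel name -> PNG/TIFF path.

    Channel names and pixel size come from embedded metadata when present;
    explicit arguments override (and are required when metadata is absent).
    A channel-count/name mismatch is an explicit error, never a silent
    truncation.
    """
    if isinstance(path, Mapping):
        channels: dict[str, np.ndarray] = {}
        for name, p in path.items():
            arr = np.asarray(iio.imread(Path(p)))
            if arr.ndim != 2:
                raise ValueError(f"channel file {p} is not single-channel (shape {arr.shape})")
            channels[name] = arr
        if px_size_um is None:
            raise ValueError("px_size_um is required when reading per-channel files")
        return FieldImage(channels, px_size_um)

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description or ""
        meta: dict = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"{path}: expected a (C, H, W) stack, got shape {stack.shape}")
        names = channel_names or meta.get("channels")
        if names is None:
            names = [f"ch{i}" for i in range(stack.shape[0])]
        if len(names) != stack.shape[0]:
            raise ValueError(
                f"{path}: {len(names)} channel names for {stack.shape[0]} planes"
            )
        px = px_size_um if px_size_um is not None else meta.get("px_size_um")
        if px is None:
            raise ValueError(f"{path}: no pixel size in metadata; pass px_size_um")
        return FieldImage.from_stack(stack, list(names), float(px), meta)
    raise ValueError(f"unknown image format: {path}")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a label raster as 16-bit TIFF (errors above 65535 labels)."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError(f"{labels.max()} labels exceed 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))
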