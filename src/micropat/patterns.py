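"""Binary ligand design patterns: generation, import, and pixel scrambling.

A micropatterned substrate presents a surface-tethered ligand (e.g. GFP) in a
user-defined binary geometry — square arrays, stripes, or arbitrary bitmaps —
onto which receiver cells are seeded.  The :class:`PatternMask` is the design
raster registered to the imaged field; it doubles as the reference for the
spatial-fidelity statistics and, pixel-scrambled, as their negative control.

Coordinate convention (package-wide): row-major, origin at the top-left,
0-based indices, pixel centres at integer coordinates. Rasterization rounds
micrometre dimensions to the nearest pixel; partial features truncated by the
field edge are kept, as they are on a stamped coverslip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PatternMask",
    "make_square_array",
    "make_rows",
    "load_pattern_bitmap",
    "save_pattern",
    "scramble_pattern",
]


@dataclass(frozen=True)
class PatternMask:
    """Binary design raster with physical pixel size.

    ``pixels`` holds 0/1 (uint8); ``px_size_um`` is µm per pixel.
    """

    pixels: np.ndarray
    px_size_um: float
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pattern must be a non-empty 2-D raster, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"pattern values must be 0/1, found {vals[:10]}")
        if self.px_size_um <= 0:
            raise ValueError(f"px_size_um must be positive, got {self.px_size_um}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) in micrometres."""
        nrow, ncol = self.pixels.shape
        return (ncol * self.px_size_um, nrow * self.px_size_um)

    @property
    def foreground_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())

    def to_dose(self, dose_ug_ml: float) -> np.ndarray:
        """Uniform ligand dose raster (µg/mL): ``mask * dose``.

        The ligand is assumed homogeneously transferred within the printed
        features, so the binary design scales directly to a dose map.
        """
        if dose_ug_ml < 0:
            raise ValueError("dose must be non-negative")
        return self.pixels.astype(np.float64) * float(dose_ug_ml)

    def complement(self) -> "PatternMask":
        return PatternMask(1 - self.pixels, self.px_size_um, f"~{self.name}")


def _field_shape_px(field_um: tuple[float, float], px_size_um: float) -> tuple[int, int]:
    width_um, height_um = field_um
    ncol = int(round(width_um / px_size_um))
    nrow = int(round(height_um / px_size_um))
    if nrow < 1 or ncol < 1:
        raise ValueError(f"field {field_um} µm smaller than one pixel at {px_size_um} µm/px")
    return nrow, ncol


def make_square_array(
    side_um: float,
    interspace_um: float,
    field_um: tuple[float, float],
    px_size_um: float,
    name: str | None = None,
) -> PatternMask:
    """Square array pattern: ``side_um`` squares tiled with ``interspace_um`` gaps.

    Tiling starts at the top-left corner of the field with period
    ``side + interspace``; squares truncated by the field edge are kept.
    """
    if side_um <= 0:
        raise ValueError(f"side_um must be positive, got {side_um}")
    if interspace_um < 0:
        raise ValueError(f"interspace_um must be non-negative, got {interspace_um}")
    if px_size_um <= 0:
        raise ValueError(f"px_size_um must be positive, got {px_size_um}")
    if side_um > max(field_um):
        raise ValueError(f"square side {side_um} µm exceeds field {field_um} µm")

    nrow, ncol = _field_shape_px(field_um, px_size_um)
    side_px = max(1, int(round(side_um / px_size_um)))
    period_px = max(side_px, int(round((side_um + interspace_um) / px_size_um)))
    rows = (np.arange(nrow) % period_px) < side_px
    cols = (np.arange(ncol) % period_px) < side_px
    pixels = np.outer(rows, cols).astype(np.uint8)
    if name is None:
        name = f"squares_{side_um:g}um_gap{interspace_um:g}um"
    return PatternMask(pixels, px_size_um, name)


def make_rows(
    width_um: float,
    interspace_um: float,
    field_um: tuple[float, float],
    px_size_um: float,
    orientation: str = "horizontal",
    name: str | None = None,
) -> PatternMask:
    """Stripe pattern of ``width_um`` rows separated by ``interspace_um``.

    ``orientation='horizontal'`` makes stripes running left–right (foreground
    varies along the row axis); ``'vertical'`` the transpose.
    """
    if width_um <= 0:
        raise ValueError(f"width_um must be positive, got {width_um}")
    if interspace_um < 0:
        raise ValueError(f"interspace_um must be non-negative, got {interspace_um}")
    if width_um > max(field_um):
        raise ValueError(f"stripe width {width_um} µm exceeds field {field_um} µm")
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"orientation must be horizontal|vertical, got {orientation!r}")

    nrow, ncol = _field_shape_px(field_um, px_size_um)
    width_px = max(1, int(round(width_um / px_size_um)))
    period_px = max(width_px, int(round((width_um + interspace_um) / px_size_um)))
    if orientation == "horizontal":
        stripe = (np.arange(nrow) % period_px) < width_px
        pixels = np.repeat(stripe[:, None], ncol, axis=1)
    else:
        stripe = (np.arange(ncol) % period_px) < width_px
        pixels = np.repeat(stripe[None, :], nrow, axis=0)
    if name is None:
        name = f"rows_{width_um:g}um_gap{interspace_um:g}um_{orientation}"
    return PatternMask(pixels.astype(np.uint8), px_size_um, name)


def load_pattern_bitmap(
    path: str | Path,
    px_size_um: float,
    threshold: float = 128,
    reduce: str | None = None,
) -> PatternMask:
    """Load an arbitrary design bitmap (PNG/TIFF) and binarize at ``threshold``.

    Pixels with value ``>= threshold`` become foreground. Multichannel images
    are rejected unless ``reduce`` names a reduction (``'mean'`` or ``'max'``)
    or all channels are identical.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - delegated to imageio
        raise ValueError(f"cannot read pattern bitmap {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if reduce == "mean":
            arr = arr.mean(axis=-1)
        elif reduce == "max":
            arr = arr.max(axis=-1)
        elif reduce is None and arr.shape[-1] <= 4 and np.all(arr[..., :1] == arr[..., : min(3, arr.shape[-1])]):
            arr = arr[..., 0]
        else:
            raise ValueError(
                f"{path} has {arr.shape[-1]} channels; pass reduce='mean'|'max'"
            )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel raster, got shape {arr.shape}")
    pixels = (arr.astype(np.float64) >= threshold).astype(np.uint8)
    return PatternMask(pixels, px_size_um, path.stem)


def save_pattern(mask: PatternMask, path: str | Path) -> None:
    """Write a pattern as an 8-bit single-channel image (foreground = 255)."""
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def scramble_pattern(
    mask: PatternMask, seed: int | np.random.Generator | np.random.SeedSequence
) -> PatternMask:
    """Uniformly random permutation of all pixels of the design raster.

    This is the negative control for the spatial-fidelity score: the scramble
    conserves the exact foreground pixel count while destroying all spatial
    structure. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    flat = mask.pixels.ravel()
    scrambled = rng.permutation(flat).reshape(mask.shape)
    return PatternMask(scrambled, mask.px_size_um, f"scrambled({mask.name})")
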