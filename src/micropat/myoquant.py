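"""Myotube detection, myogenic index, and orientation-order statistics.

Orientation is estimated per pixel with the smoothed structure tensor
``J = G_sigma * (grad I grad I^T)``: the local orientation is the eigenvector
of the smaller eigenvalue (along the stripes), mapped to [-90, 90) degrees
measured counter-clockwise from the +x (column) axis with y pointing up;
coherency is the tensor anisotropy ``(l1 - l2) / (l1 + l2)`` in [0, 1], and
energy the tensor trace.  Orientations are summarized in a 360-bin histogram
at 0.5-degree increments, from which the orientation order parameter (OOP)
is the magnitude of the doubled-angle resultant,

    OOP = | sum_i w_i exp(2 i theta_i) | / sum_i w_i ,

the largest eigenvalue of the mean 2-D orientational order tensor
``<2 n n^T - I>``: 0 for an isotropic field, 1 for perfect alignment.

The myogenic index is the number of nuclei colocalized with the
alpha-actinin-positive (myotube) mask divided by the total nuclei count,
optionally restricted to the on- or off-pattern region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import structure_tensor
from skimage.filters import threshold_otsu

from .cellquant import drop_small_components

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "MyoResult",
    "myotube_mask",
    "myogenic_index",
    "local_orientation",
    "orientation_histogram",
    "orientation_order_parameter",
    "straighten_along_polyline",
    "coherency_score",
    "HIST_BIN_EDGES",
]

HIST_BIN_EDGES = np.arange(-90.0, 90.0 + 0.5, 0.5)  # 360 bins of 0.5 degrees


# ---------------------------------------------------------------------------
# myotubes

def myotube_mask(
    channel: np.ndarray,
    threshold: str | float = "otsu",
    min_size_px: int = 200,
) -> tuple[np.ndarray, int]:
    """Size-and-intensity thresholding of the alpha-actinin signal.

    Binarize at ``threshold`` (Otsu by default), drop connected components
    smaller than ``min_size_px``, and return the mask plus the number of
    surviving components (the myotube count).
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D channel, got shape {img.shape}")
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return np.zeros_like(img, dtype=bool), 0
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    binary = img > thr
    if min_size_px > 0:
        binary = drop_small_components(binary, min_size_px)
    _, count = ndi.label(binary)
    return binary, int(count)


@dataclass(frozen=True)
class MyoResult:
    """Myogenic-index result for one region."""

    myotube_mask: np.ndarray
    myotube_count: int
    nuclei_total: int
    nuclei_in_myotubes: int
    myogenic_index: float
    region: str = "all"

    @property
    def undefined(self) -> bool:
        return self.nuclei_total == 0


def _nuclei_centroids_px(nuclei: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(nuclei, pd.DataFrame):
        rows = nuclei["row_px"].to_numpy(dtype=float).round().astype(int)
        cols = nuclei["col_px"].to_numpy(dtype=float).round().astype(int)
        return rows, cols
    labels = np.asarray(nuclei)
    idx = np.unique(labels)
    idx = idx[idx > 0]
    if len(idx) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    cents = ndi.center_of_mass(labels > 0, labels, idx)
    cents = np.asarray(cents)
    return cents[:, 0].round().astype(int), cents[:, 1].round().astype(int)


def myogenic_index(
    nuclei: pd.DataFrame | np.ndarray,
    myotube_mask_arr: np.ndarray,
    region_mask: np.ndarray | None = None,
    myotube_count: int | None = None,
    region: str = "all",
) -> MyoResult:
    """Fraction of nuclei whose centroid falls within the myotube mask.

    ``nuclei`` is either a cell table with ``row_px/col_px`` columns or a
    label raster.  When ``region_mask`` is given, nuclei outside the region
    are excluded before the ratio is taken (the on/off-pattern restriction).
    Zero nuclei after restriction yields a NaN index flagged ``undefined``.
    """
    mask = np.asarray(myotube_mask_arr).astype(bool)
    rows, cols = _nuclei_centroids_px(nuclei)
    rows = np.clip(rows, 0, mask.shape[0] - 1)
    cols = np.clip(cols, 0, mask.shape[1] - 1)
    if region_mask is not None:
        region_mask = np.asarray(region_mask).astype(bool)
        if region_mask.shape != mask.shape:
            raise ValueError(
                f"region mask shape {region_mask.shape} != myotube mask {mask.shape}"
            )
        keep = region_mask[rows, cols]
        rows, cols = rows[keep], cols[keep]
    n_total = len(rows)
    n_in = int(mask[rows, cols].sum()) if n_total else 0
    index = n_in / n_total if n_total else float("nan")
    if myotube_count is None:
        _, myotube_count = ndi.label(mask)
    return MyoResult(mask, int(myotube_count), n_total, n_in, index, region)


# ---------------------------------------------------------------------------
# orientation

@dataclass
class OrientationField:
    """Per-pixel structure-tensor orientation (deg in [-90, 90)), coherency, energy.

    ``valid`` masks out pixels with (numerically) zero gradient energy, where
    orientation is undefined.
    """

    orientation_deg: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray
    valid: np.ndarray
    tensor_sigma: float

    @property
    def mean_coherency(self) -> float:
        """Energy-weighted mean coherency over valid pixels (NaN if no energy)."""
        w = self.energy[self.valid]
        if w.sum() == 0:
            return float("nan")
        return float((self.coherency[self.valid] * w).sum() / w.sum())


def local_orientation(channel: np.ndarray, tensor_sigma: float = 2.0) -> OrientationField:
    """Smoothed structure-tensor orientation estimate.

    ``tensor_sigma`` (px) sets the Gaussian neighbourhood over which the
    gradient outer products are averaged — the scale of the structures whose
    orientation is being measured.  A constant image has zero energy
    everywhere and an all-False ``valid`` mask.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D channel, got shape {img.shape}")
    if tensor_sigma <= 0:
        raise ValueError(f"tensor_sigma must be positive, got {tensor_sigma}")
    if np.ptp(img) == 0:
        zero = np.zeros_like(img)
        return OrientationField(zero, zero.copy(), zero.copy(),
                                np.zeros(img.shape, bool), tensor_sigma)
    # reflect-pad so that image borders do not fabricate gradients
    Arr, Arc, Acc = structure_tensor(img, sigma=tensor_sigma, mode="reflect", order="rc")
    energy = Arr + Acc
    # orientation of the structure (minor eigenvector), y-up convention:
    # theta = 1/2 atan2(2*Jrc, Jrr - Jcc)
    theta = 0.5 * np.arctan2(2.0 * Arc, Arr - Acc)
    orientation = np.degrees(theta)
    orientation = (orientation + 90.0) % 180.0 - 90.0
    with np.errstate(divide="ignore", invalid="ignore"):
        coherency = np.where(
            energy > 0, np.sqrt((Acc - Arr) ** 2 + 4.0 * Arc**2) / energy, 0.0
        )
    valid = energy > energy.max() * 1e-12 if energy.max() > 0 else np.zeros_like(energy, bool)
    return OrientationField(orientation, np.clip(coherency, 0.0, 1.0), energy, valid, tensor_sigma)


@dataclass
class OrientationHistogram:
    """360-bin, 0.5-degree orientation histogram over [-90, 90)."""

    counts: np.ndarray
    weight: str = "none"
    empty: bool = False

    @property
    def bin_edges(self) -> np.ndarray:
        return HIST_BIN_EDGES

    @property
    def bin_centers(self) -> np.ndarray:
        return (HIST_BIN_EDGES[:-1] + HIST_BIN_EDGES[1:]) / 2.0

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start_deg": HIST_BIN_EDGES[:-1], "count": self.counts}
        )


def orientation_histogram(
    orientation: OrientationField | np.ndarray,
    weight: str = "none",
    mask: np.ndarray | None = None,
) -> OrientationHistogram:
    """Histogram of local orientations at 0.5-degree increments.

    ``weight='none'`` counts pixels (the number of pixels locally oriented
    along every angle); ``'energy'`` and ``'coherency'`` weight each pixel by
    the corresponding structure-tensor quantity (requires an
    :class:`OrientationField` input).  ``mask`` restricts to a pixel subset;
    invalid (zero-energy) pixels are always excluded.
    """
    if isinstance(orientation, OrientationField):
        angles = orientation.orientation_deg
        keep = orientation.valid.copy()
        if weight == "none":
            w = None
        elif weight == "energy":
            w = orientation.energy
        elif weight == "coherency":
            w = orientation.coherency
        else:
            raise ValueError(f"unknown weight {weight!r}")
    else:
        angles = np.asarray(orientation, dtype=np.float64)
        keep = np.ones(angles.shape, dtype=bool)
        if weight != "none":
            raise ValueError("weighted histograms need an OrientationField input")
        w = None
    if np.any((angles < -90.0) | (angles >= 90.0)):
        raise ValueError("orientation values must lie in [-90, 90)")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != angles.shape:
            raise ValueError(f"mask shape {mask.shape} != raster {angles.shape}")
        keep &= mask
    vals = angles[keep]
    weights = w[keep] if w is not None else None
    empty = vals.size == 0
    if empty:
        warnings.warn("orientation histogram over an empty pixel set")
    counts, _ = np.histogram(vals, bins=HIST_BIN_EDGES, weights=weights)
    return OrientationHistogram(counts.astype(np.float64), weight, empty)


def orientation_order_parameter(
    histogram: OrientationHistogram | np.ndarray,
) -> float:
    """Orientation order parameter from a 0.5-degree orientation histogram.

    With bin-centre angles ``theta_i`` and weights ``w_i``::

        C = sum w_i cos(2 theta_i) / sum w_i
        S = sum w_i sin(2 theta_i) / sum w_i
        OOP = sqrt(C**2 + S**2)

    This is the largest eigenvalue of the mean orientational order tensor
    ``<2 n n^T - I>`` and equals ``2 <cos^2(theta - theta_bar)> - 1`` about
    the director: 0 for a completely randomized field (exactly, by symmetry
    of the 360 equal bins), 1 for perfect alignment.
    """
    if isinstance(histogram, OrientationHistogram):
        counts = histogram.counts
    else:
        counts = np.asarray(histogram, dtype=np.float64)
    if counts.shape != (360,):
        raise ValueError(f"expected 360-bin histogram, got shape {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("orientation histogram has zero total weight")
    centers = np.radians((HIST_BIN_EDGES[:-1] + HIST_BIN_EDGES[1:]) / 2.0)
    C = float((counts * np.cos(2.0 * centers)).sum() / total)
    S = float((counts * np.sin(2.0 * centers)).sum() / total)
    return float(np.hypot(C, S))


# ---------------------------------------------------------------------------
# curve straightening and coherency

def straighten_along_polyline(
    image: np.ndarray,
    vertices_um: np.ndarray,
    band_width_um: float,
    px_size_um: float,
) -> np.ndarray:
    """Resample a band of the image along a polyline into a straight raster.

    The polyline (``(x_um, y_um)`` vertices) is resampled at one-pixel arc
    steps; at each sample, pixels are bilinearly interpolated along the local
    normal over a band of ``band_width_um``.  The output has height = band
    width in px and length = polyline arc length in px, so a curved stripe
    becomes a straight one — the pre-processing step for fair coherency
    scoring of curved patterns.  Warns if the band self-intersects (band
    half-width exceeding the local radius of curvature).
    """
    img = np.asarray(image, dtype=np.float64)
    verts = np.asarray(vertices_um, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 2:
        raise ValueError("polyline needs >= 2 (x_um, y_um) vertices")
    if band_width_um <= 0:
        raise ValueError("band_width_um must be positive")

    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("polyline has zero-length segments")
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    n_samples = max(2, int(round(total / px_size_um)))
    s = np.arange(n_samples) * px_size_um  # exact one-pixel arc steps
    x = np.interp(s, arc, verts[:, 0])
    y = np.interp(s, arc, verts[:, 1])

    tx = np.gradient(x, s)
    ty = np.gradient(y, s)
    norm = np.hypot(tx, ty)
    tx, ty = tx / norm, ty / norm
    # curvature from the turning rate of the tangent
    dtheta = np.gradient(np.unwrap(np.arctan2(ty, tx)), s)
    if np.nanmax(np.abs(dtheta)) * band_width_um / 2.0 > 1.0:
        warnings.warn(
            "band half-width exceeds the local radius of curvature; "
            "the straightened band self-intersects"
        )
    nx, ny = -ty, tx  # unit normal

    band_px = max(1, int(round(band_width_um / px_size_um)))
    offsets = (np.arange(band_px) - (band_px - 1) / 2.0) * px_size_um
    xs = x[None, :] + offsets[:, None] * nx[None, :]
    ys = y[None, :] + offsets[:, None] * ny[None, :]
    coords = np.stack([ys / px_size_um, xs / px_size_um])
    return ndi.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)


def coherency_score(raster: np.ndarray, tensor_sigma: float = 2.0) -> float:
    """Energy-weighted mean structure-tensor coherency of an image.

    Near 1 for parallel stripes, near 0 for isotropic texture; NaN for a
    zero-gradient (constant) image where coherency is undefined.
    """
    field = local_orientation(raster, tensor_sigma)
    return field.mean_coherency
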