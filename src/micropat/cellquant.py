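"""Nuclear segmentation, per-cell intensity measurement, and activation calls.

Implements the ImageJ-style quantification chain used for percent-activation
readouts: Gaussian blur -> threshold -> optional watershed split -> particle
(area) filter, then per-cell mean channel intensities, a positive/negative
call against an intensity threshold, and a four-state dual-reporter
classification by pattern region.

Percent activation is the number of reporter-positive cells divided by the
total number of segmented nuclei; the activated intensity is the mean
reporter intensity over cells above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import relabel_sequential, watershed

from .image import FieldImage

__all__ = [
    "drop_small_components",
    "ActivationSummary",
    "segment_nuclei",
    "measure_cells",
    "activation_summary",
    "classify_dual_states",
    "STATE_COLUMNS",
]


def drop_small_components(binary: np.ndarray, min_area_px: int) -> np.ndarray:
    """Remove connected components with strictly fewer than ``min_area_px`` pixels."""
    labels, n = ndi.label(binary)
    if n == 0:
        return binary
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def segment_nuclei(
    channel: np.ndarray,
    blur_sigma: float = 2.0,
    threshold_method: str | float = "otsu",
    min_area_px: int = 20,
    use_watershed: bool = True,
    watershed_min_distance_px: int | None = None,
) -> np.ndarray:
    """Label nuclei (or constitutive-marker cell bodies) in one channel.

    Blur with ``blur_sigma``, binarize (Otsu by default, or a fixed raw-unit
    threshold), optionally split touching objects with a distance-transform
    watershed seeded at local maxima, and drop regions below ``min_area_px``.
    Labels are contiguous from 1. An image that thresholds to empty yields
    zero labels, not an error.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected single-channel 2-D raster, got shape {img.shape}")
    if blur_sigma < 0:
        raise ValueError(f"blur_sigma must be non-negative, got {blur_sigma}")
    blurred = gaussian(img, sigma=blur_sigma, preserve_range=True) if blur_sigma > 0 else img

    if threshold_method == "otsu":
        if np.ptp(blurred) == 0:
            return np.zeros_like(img, dtype=np.int32)
        thr = threshold_otsu(blurred)
    elif isinstance(threshold_method, (int, float)):
        thr = float(threshold_method)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = blurred > thr
    if min_area_px > 0:
        binary = drop_small_components(binary, min_area_px)
    if not binary.any():
        return np.zeros_like(img, dtype=np.int32)

    if use_watershed:
        dist = ndi.distance_transform_edt(binary)
        if watershed_min_distance_px is None:
            # default separation: the median object's equivalent radius
            lab0, n0 = ndi.label(binary)
            areas = np.bincount(lab0.ravel())[1:]
            r_eq = np.sqrt(np.median(areas) / np.pi) if len(areas) else 3.0
            watershed_min_distance_px = max(2, int(round(r_eq)))
        peaks = peak_local_max(
            dist, min_distance=watershed_min_distance_px, labels=binary, exclude_border=False
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.max() == 0:
            labels, _ = ndi.label(binary)
        else:
            labels = watershed(-dist, markers, mask=binary)
    else:
        labels, _ = ndi.label(binary)

    if min_area_px > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area_px)
        labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def measure_cells(labels: np.ndarray, image: FieldImage) -> pd.DataFrame:
    """One record per labelled cell with centroid, area, and per-channel means.

    Columns: ``cell_id, row_px, col_px, x_um, y_um, area_px`` and one
    ``mean_<channel>`` per channel of ``image``.
    """
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ValueError(f"labels shape {labels.shape} != image shape {image.shape}")
    if labels.max() == 0:
        cols = ["cell_id", "row_px", "col_px", "x_um", "y_um", "area_px"] + [
            f"mean_{c}" for c in image.channel_names
        ]
        return pd.DataFrame({c: [] for c in cols})

    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    df = pd.DataFrame(
        {
            "cell_id": props["label"],
            "row_px": props["centroid-0"],
            "col_px": props["centroid-1"],
            "area_px": props["area"].astype(int),
        }
    )
    df["x_um"] = df["col_px"] * image.px_size_um
    df["y_um"] = df["row_px"] * image.px_size_um
    index = df["cell_id"].to_numpy()
    for name in image.channel_names:
        df[f"mean_{name}"] = ndi.mean(image[name], labels=labels, index=index)
    return df[
        ["cell_id", "row_px", "col_px", "x_um", "y_um", "area_px"]
        + [f"mean_{c}" for c in image.channel_names]
    ]


@dataclass(frozen=True)
class ActivationSummary:
    """Percent-positive summary for one reporter channel.

    ``percent_activation`` is ``n_positive / n_total`` in [0, 1];
    ``mean_activated_intensity`` averages the reporter over positive cells.
    Both are NaN (with ``undefined=True``) when their denominator is zero —
    an empty field is flagged, never silently reported as 0% activation.
    """

    n_total: int
    n_positive: int
    percent_activation: float
    mean_activated_intensity: float
    channel: str
    threshold: float

    @property
    def undefined(self) -> bool:
        return self.n_total == 0


def activation_summary(
    cells: pd.DataFrame, channel: str, positive_threshold: float
) -> ActivationSummary:
    """Call cells positive when their mean ``channel`` intensity exceeds the threshold."""
    col = f"mean_{channel}" if f"mean_{channel}" in cells.columns else channel
    if col not in cells.columns:
        raise KeyError(f"channel column {col!r} not in cell table ({list(cells.columns)})")
    vals = cells[col].to_numpy(dtype=float)
    n_total = len(vals)
    pos = vals > positive_threshold
    n_pos = int(pos.sum())
    pct = n_pos / n_total if n_total else float("nan")
    mai = float(vals[pos].mean()) if n_pos else float("nan")
    return ActivationSummary(n_total, n_pos, pct, mai, channel, positive_threshold)


STATE_COLUMNS = ("neg_neg", "neg_pos", "pos_neg", "pos_pos")


def classify_dual_states(
    cells: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    thr_a: float,
    thr_b: float,
    region_masks: Mapping[str, np.ndarray] | None = None,
    px_size_um: float | None = None,
) -> pd.DataFrame:
    """Four-state dual-reporter classification, per pattern region.

    Each cell is called +/- on reporters A and B against the two thresholds,
    giving states A-B-, A-B+, A+B-, A+B+ (columns ``neg_neg, neg_pos,
    pos_neg, pos_pos``; the first letter is channel A).  Cells are assigned
    to a region by centroid membership, with precedence following the
    iteration order of ``region_masks``; a centroid in no region falls in
    ``'unpatterned'``. Counts per region always sum to the region cell total.
    """
    if thr_a < 0 or thr_b < 0:
        raise ValueError("thresholds must be non-negative")
    ca = f"mean_{channel_a}" if f"mean_{channel_a}" in cells.columns else channel_a
    cb = f"mean_{channel_b}" if f"mean_{channel_b}" in cells.columns else channel_b
    for c in (ca, cb):
        if c not in cells.columns:
            raise KeyError(f"channel column {c!r} not in cell table")
    a_pos = cells[ca].to_numpy(dtype=float) > thr_a
    b_pos = cells[cb].to_numpy(dtype=float) > thr_b

    n = len(cells)
    region = np.full(n, "unpatterned", dtype=object)
    if region_masks:
        rows = cells["row_px"].to_numpy(dtype=float).round().astype(int)
        colv = cells["col_px"].to_numpy(dtype=float).round().astype(int)
        assigned = np.zeros(n, dtype=bool)
        for name, mask in region_masks.items():
            mask = np.asarray(mask).astype(bool)
            rr = np.clip(rows, 0, mask.shape[0] - 1)
            cc = np.clip(colv, 0, mask.shape[1] - 1)
            hit = mask[rr, cc] & ~assigned
            region[hit] = name
            assigned |= hit

    state = np.where(a_pos, "pos", "neg").astype(object)
    state = np.char.add(np.char.add(state.astype(str), "_"), np.where(b_pos, "pos", "neg"))

    region_order = list(region_masks) + ["unpatterned"] if region_masks else ["unpatterned"]
    records = []
    for name in region_order:
        sel = region == name
        n_region = int(sel.sum())
        rec = {"region": name, "n_total": n_region}
        for st in STATE_COLUMNS:
            cnt = int((state[sel] == st).sum())
            rec[f"n_{st}"] = cnt
            rec[f"pct_{st}"] = cnt / n_region if n_region else float("nan")
        records.append(rec)
    return pd.DataFrame(records)
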