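"""Spatial-fidelity scoring, scramble null, intensity profiles, dose fits.

The fidelity of a patterned activation experiment is scored as the Pearson
product-moment correlation between the binary design raster (treated as
{0,1} reals) and the reporter-intensity image, computed over all pixels.
Its negative control is the scrambled-pattern null: the correlation of the
same image against uniformly pixel-permuted copies of the design, which
conserve the foreground count but carry no spatial structure.  Under
permutation the null correlation has mean 0 and standard deviation close to
1/sqrt(N-1) for N pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .patterns import PatternMask, scramble_pattern

__all__ = [
    "ZeroVarianceError",
    "FidelityResult",
    "IntensityProfile",
    "DoseResponseFit",
    "pearson_fidelity",
    "scramble_null_test",
    "intensity_profile",
    "onoff_region_masks",
    "hill",
    "fit_dose_response",
]


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one input has zero variance."""


def _as_pixels(x: PatternMask | np.ndarray) -> np.ndarray:
    if isinstance(x, PatternMask):
        return x.pixels.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


def pearson_fidelity(mask: PatternMask | np.ndarray, image: np.ndarray) -> float:
    """Pearson correlation between a design raster and an intensity image.

    Computed over the full field (the colocalization-plugin default). Raises
    :class:`ZeroVarianceError` for a constant image or an all-ones/all-zeros
    mask rather than silently returning 0.
    """
    a = _as_pixels(mask).ravel()
    b = _as_pixels(image).ravel()
    if a.size != b.size:
        raise ValueError(f"geometry mismatch: {a.size} vs {b.size} pixels")
    if np.ptp(a) == 0:
        raise ZeroVarianceError("design mask has zero variance (all fore- or background)")
    if np.ptp(b) == 0:
        raise ZeroVarianceError("image has zero variance; correlation undefined")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@dataclass
class FidelityResult:
    """Observed fidelity with its scrambled-pattern null distribution.

    ``empirical_p`` uses the add-one rule ``(1 + #{null >= observed}) /
    (n_scrambles + 1)`` — conservative on ties and never exactly zero.
    """

    r_observed: float
    null_r: np.ndarray
    z_score: float
    empirical_p: float
    n_scrambles: int
    seed: int | None

    @property
    def null_mean(self) -> float:
        return float(self.null_r.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_r.std(ddof=1))

    def null_quantile(self, q: float) -> float:
        return float(np.quantile(self.null_r, q))

    def summary(self) -> dict:
        return {
            "r_observed": self.r_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_q95": self.null_quantile(0.95),
            "z_score": self.z_score,
            "empirical_p": self.empirical_p,
            "n_scrambles": self.n_scrambles,
            "seed": self.seed,
        }


def scramble_null_test(
    mask: PatternMask,
    image: np.ndarray,
    n_scrambles: int = 100,
    seed: int | None = 0,
) -> FidelityResult:
    """Observed fidelity against ``n_scrambles`` pixel-scrambled patterns.

    Each scramble uses an independent child seed derived from ``seed``, so
    the whole null distribution is reproducible from one integer.
    """
    if n_scrambles < 1:
        raise ValueError(f"n_scrambles must be >= 1, got {n_scrambles}")
    r_obs = pearson_fidelity(mask, image)
    children = np.random.SeedSequence(seed).spawn(n_scrambles)
    null = np.empty(n_scrambles, dtype=np.float64)
    for i, child in enumerate(children):
        null[i] = pearson_fidelity(scramble_pattern(mask, child), image)
    p = (1 + int((null >= r_obs).sum())) / (n_scrambles + 1)
    sd = null.std(ddof=1)
    z = (r_obs - null.mean()) / sd if sd > 0 else float("inf")
    return FidelityResult(r_obs, null, float(z), float(p), n_scrambles, seed)


@dataclass
class IntensityProfile:
    """1-D trace of mean intensity along an image axis.

    ``positions_um`` are pixel-centre positions along the chosen axis;
    ``values`` are the mean over the perpendicular axis, normalized according
    to ``normalization``. ``flat`` flags a zero-range image under min-max
    normalization (values forced to 0 instead of dividing by zero).
    """

    positions_um: np.ndarray
    values: np.ndarray
    normalization: str
    axis: str
    flat: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_um": self.positions_um, "intensity": self.values}
        )


def intensity_profile(
    channel: np.ndarray,
    px_size_um: float,
    axis: str = "x",
    roi: tuple[int, int, int, int] | None = None,
    normalization: str = "per_image",
    global_range: tuple[float, float] | None = None,
) -> IntensityProfile:
    """Profile plot: mean intensity against position along ``axis``.

    ``axis='x'`` averages each column over rows (profile runs left–right);
    ``axis='y'`` the converse.  ``roi`` restricts to a ``(r0, c0, r1, c1)``
    rectangle (half-open).  Normalization: ``'per_image'`` min-max scales the
    profile to [0, 1]; ``'global_minmax'`` scales by a caller-supplied range
    (for traces normalized jointly across a time course); ``'none'`` leaves
    raw units.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D channel, got shape {img.shape}")
    if roi is not None:
        r0, c0, r1, c1 = roi
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ValueError(f"ROI {roi} outside image {img.shape}")
        img = img[r0:r1, c0:c1]
    if axis == "x":
        vals = img.mean(axis=0)
    elif axis == "y":
        vals = img.mean(axis=1)
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    pos = np.arange(vals.size) * px_size_um

    flat = False
    if normalization == "per_image":
        rng_ = np.ptp(vals)
        if rng_ == 0:
            flat = True
            warnings.warn("flat profile under min-max normalization; returning zeros")
            vals = np.zeros_like(vals)
        else:
            vals = (vals - vals.min()) / rng_
    elif normalization == "global_minmax":
        if global_range is None:
            raise ValueError("global_minmax normalization requires global_range=(lo, hi)")
        lo, hi = global_range
        if hi <= lo:
            raise ValueError(f"invalid global range {global_range}")
        vals = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return IntensityProfile(pos, vals, normalization, axis, flat)


def onoff_region_masks(pattern: PatternMask) -> tuple[np.ndarray, np.ndarray]:
    """(on, off) boolean masks partitioning the field by the design pattern."""
    on = pattern.pixels.astype(bool)
    return on, ~on


# ---------------------------------------------------------------------------
# dose-response

def hill(c: np.ndarray, p_basal: float, p_max: float, K: float, h: float) -> np.ndarray:
    """Hill dose–response with basal leak (same form as the generator model)."""
    c = np.asarray(c, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, c**h / (K**h + c**h), 0.0)
    return p_basal + (p_max - p_basal) * frac


@dataclass
class DoseResponseFit:
    """Least-squares Hill fit of percent activation against ligand dose."""

    p_basal: float
    p_max: float
    K: float
    h: float
    rss: float
    converged: bool
    message: str = ""
    dose: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    response: np.ndarray = dc_field(default_factory=lambda: np.array([]))

    def predict(self, c: np.ndarray) -> np.ndarray:
        return hill(c, self.p_basal, self.p_max, self.K, self.h)

    def summary(self) -> str:
        lines = [
            "Hill dose-response fit",
            "----------------------",
            f"p_basal   {self.p_basal:10.4f}",
            f"p_max     {self.p_max:10.4f}",
            f"K (ug/mL) {self.K:10.3f}",
            f"h         {self.h:10.3f}",
            f"RSS       {self.rss:10.3e}",
            f"converged {self.converged}",
        ]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


def fit_dose_response(
    dose: np.ndarray, percent_activation: np.ndarray
) -> DoseResponseFit:
    """Fit ``p(c) = p_basal + (p_max - p_basal) c^h / (K^h + c^h)``.

    Requires at least four distinct doses including 0.  Multistart
    initialization over a grid of (K, h) guards against the flat local optima
    typical of saturating curves; the start with lowest residual sum of
    squares wins.  Degenerate (constant) responses are flagged non-converged
    with ``p_max`` set to the mean response.
    """
    c = np.asarray(dose, dtype=np.float64)
    y = np.asarray(percent_activation, dtype=np.float64)
    if c.shape != y.shape:
        raise ValueError("dose and response must have the same length")
    distinct = np.unique(c)
    if len(distinct) < 4:
        raise ValueError(f"need >= 4 distinct doses, got {len(distinct)}")
    if 0.0 not in distinct:
        raise ValueError("dose ladder must include 0")
    if np.any(c < 0):
        raise ValueError("doses must be non-negative")

    if np.ptp(y) == 0:
        m = float(y.mean())
        return DoseResponseFit(
            m, m, float(np.median(distinct[distinct > 0]) or 1.0), 1.0,
            0.0, False, "constant response; fit degenerate", c, y,
        )

    cmax = float(c.max())
    pos = distinct[distinct > 0]
    k_starts = np.unique(np.concatenate([pos, [np.sqrt(pos[0] * pos[-1])]]))
    h_starts = (0.5, 1.0, 2.0, 4.0)
    lo = [0.0, 0.0, 1e-6, 0.05]
    hi = [1.0, 1.0, 10.0 * cmax, 10.0]
    y0 = float(np.clip(y[c == 0].mean(), 0, 1))
    ymax = float(np.clip(y.max(), 0, 1))

    best = None
    for K0 in k_starts:
        for h0 in h_starts:
            p0 = [y0, ymax, float(np.clip(K0, lo[2], hi[2])), h0]
            try:
                popt, _ = curve_fit(
                    hill, c, y, p0=p0, bounds=(lo, hi), maxfev=5000
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((hill(c, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return DoseResponseFit(
            y0, ymax, cmax / 2, 1.0, float("inf"), False, "all starts failed", c, y
        )
    (p_basal, p_max, K, h), rss = best
    return DoseResponseFit(
        float(p_basal), float(p_max), float(K), float(h), rss, True, "", c, y
    )
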