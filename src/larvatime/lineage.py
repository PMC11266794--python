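"""Division-density estimation from a cell-lineage diagram image.

The post-embryonic lineage of *C. elegans* is conventionally drawn as a tree
in which the vertical axis is developmental time: thin vertical lines trace
cells, wider horizontal bars mark division events, and small 'X' markers mark
programmed cell deaths.  Because every horizontal bar is a division, the
number of bars per pixel row of the diagram is a raw record of division
timing.  This module turns such a diagram into a calibrated division-density
curve:

1. ``binarize`` — grayscale diagram to an ink mask;
2. ``strip_narrow_elements`` — delete everything of width <= 2 px (vertical
   cell lines and death markers), keeping only the division bars;
3. ``count_bars_per_row`` — count maximal horizontal ink runs per row;
4. ``calibrate_time`` — map pixel rows to developmental hours through two
   anchor events of known timing (the seam-cell division bursts at the L2
   and L3 onsets);
5. ``smooth_density`` — spread each row count over neighbouring rows with an
   inverse-distance kernel, conserving total event mass.

``lineage_density_pipeline`` composes the five steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "TimeCalibration",
    "DivisionDensitySeries",
    "binarize",
    "strip_narrow_elements",
    "count_bars_per_row",
    "calibrate_time",
    "inverse_kernel",
    "smooth_density",
    "lineage_density_pipeline",
]


@dataclass(frozen=True)
class TimeCalibration:
    """Linear pixel-row -> developmental-hour map through two anchors.

    Rows are 0-based.  Anchor rows given as the midpoint of a two-row peak
    (e.g. 448.5 for a peak spanning rows 448-449) keep the map unbiased.
    """

    anchors: tuple[tuple[float, float], tuple[float, float]]
    slope: float  # h per px
    intercept: float  # h at row 0

    def hours(self, rows):
        """Map row coordinates (scalar or array) to hours."""
        return self.intercept + self.slope * np.asarray(rows, dtype=float)


@dataclass
class DivisionDensitySeries:
    """Per-row division counts and smoothed density on a calibrated hour axis."""

    counts: np.ndarray
    density: np.ndarray
    time_h: np.ndarray
    kernel_weights: np.ndarray = field(repr=False)
    calibration: TimeCalibration | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": np.arange(len(self.counts)),
                "time_h": self.time_h,
                "count": self.counts,
                "density": self.density,
            }
        )


def binarize(image, threshold: float | None = None) -> np.ndarray:
    """Binarize a grayscale diagram: ink (dark) -> 1, background (light) -> 0.

    Parameters
    ----------
    image : 2-D array of intensities, higher = lighter.
    threshold : intensity cutoff; a pixel is ink iff intensity <= threshold.
        ``None`` selects the threshold automatically (Otsu).
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if threshold is None:
        lo, hi = arr.min(), arr.max()
        if lo == hi:
            # Uniform image: all ink if dark-ish, else all background.
            threshold = lo if lo <= (np.iinfo(arr.dtype).max // 2 if arr.dtype.kind in "ui" else 0.5) else lo - 1
        else:
            threshold = filters.threshold_otsu(arr)
    return (arr <= threshold).astype(np.uint8)


def strip_narrow_elements(
    image: np.ndarray, max_width_px: int = 2, method: str = "component"
) -> np.ndarray:
    """Erase narrow diagram elements, keeping only the division bars.

    method="component": delete every 8-connected ink component whose
    bounding-box width is <= ``max_width_px`` (vertical lines, death-marker
    dots).  method="row_runs": delete, independently in each row, every
    horizontal ink run of length <= ``max_width_px``; this variant also
    handles diagrams in which vertical lines touch the bars, since a
    vertical line still crosses each row as a narrow run.
    """
    if max_width_px < 1:
        raise ValueError("max_width_px must be >= 1")
    img = np.ascontiguousarray(np.asarray(image, dtype=np.uint8))
    if method == "component":
        labels, n = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return img.copy()
        out = img.copy()
        for prop in measure.regionprops(labels):
            r0, c0, r1, c1 = prop.bbox
            if c1 - c0 <= max_width_px:
                out[labels == prop.label] = 0
        return out
    if method == "row_runs":
        out = img.copy()
        for row in out:
            # run-length encode each row
            padded = np.diff(np.concatenate(([0], row, [0])))
            starts = np.flatnonzero(padded == 1)
            ends = np.flatnonzero(padded == -1)
            for s, e in zip(starts, ends):
                if e - s <= max_width_px:
                    row[s:e] = 0
        return out
    raise ValueError(f"unknown method {method!r}")


def count_bars_per_row(image: np.ndarray) -> np.ndarray:
    """Count maximal horizontal ink runs in each row (within-row connectivity).

    On a stripped diagram each run is one division bar; a 2 px-tall bar
    contributes to both of its rows, which is what yields the paired peak
    rows at the seam-cell division bursts.
    """
    img = np.asarray(image, dtype=np.uint8)
    if img.ndim != 2:
        raise ValueError("expected a 2-D binary image")
    rises = (img[:, 1:] > img[:, :-1]).sum(axis=1)
    return (rises + img[:, 0]).astype(np.int64)


def calibrate_time(
    anchor1: tuple[float, float], anchor2: tuple[float, float]
) -> TimeCalibration:
    """Fit the linear row->hour map through two (row, hour) anchors."""
    (r1, h1), (r2, h2) = anchor1, anchor2
    if r1 == r2:
        raise ValueError("anchor rows must be distinct")
    if h1 == h2:
        raise ValueError("anchor hours must be distinct")
    slope = (h2 - h1) / (r2 - r1)
    intercept = h1 - slope * r1
    return TimeCalibration(anchors=(tuple(anchor1), tuple(anchor2)), slope=slope, intercept=intercept)


def inverse_kernel(half_width: int, exponent: float = 1.0) -> np.ndarray:
    """Inverse-distance weights k_j for offsets j in [-w, w].

    k_0 = 1 and k_j = 1/|j|**exponent otherwise (unnormalized).
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    j = np.arange(-half_width, half_width + 1)
    k = np.ones(j.shape, dtype=float)
    nz = j != 0
    k[nz] = 1.0 / np.abs(j[nz]).astype(float) ** exponent
    return k


def smooth_density(
    counts, half_width: int = 10, exponent: float = 1.0
) -> np.ndarray:
    """Smooth per-row counts into a density with the inverse kernel.

    Each count V_i is spread over rows i-w..i+w with weights k_j normalized
    over the offsets that fall inside the series, so total event mass is
    conserved exactly: sum(density) == sum(counts).  ``half_width == 0``
    returns the counts unchanged.
    """
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("counts must be 1-D")
    if half_width == 0:
        return v.copy()
    k = inverse_kernel(half_width, exponent)
    # per-source normalizer: sum of weights landing inside the series
    norm = ndimage.correlate1d(np.ones_like(v), k, mode="constant", cval=0.0)
    return ndimage.correlate1d(v / norm, k, mode="constant", cval=0.0)


def lineage_density_pipeline(
    image,
    anchors: tuple[tuple[float, float], tuple[float, float]],
    threshold: float | None = None,
    half_width: int = 10,
    exponent: float = 1.0,
    max_width_px: int = 2,
    strip_method: str = "component",
) -> DivisionDensitySeries:
    """Full diagram-to-density pipeline.

    binarize -> strip narrow elements -> count bars per row -> calibrate the
    hour axis through the two anchors -> smooth with the inverse kernel.
    """
    binary = binarize(image, threshold=threshold)
    stripped = strip_narrow_elements(binary, max_width_px=max_width_px, method=strip_method)
    counts = count_bars_per_row(stripped)
    cal = calibrate_time(*anchors)
    density = smooth_density(counts, half_width=half_width, exponent=exponent)
    return DivisionDensitySeries(
        counts=counts,
        density=density,
        time_h=cal.hours(np.arange(len(counts))),
        kernel_weights=inverse_kernel(half_width, exponent),
        calibration=cal,
    )
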