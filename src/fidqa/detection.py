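"""Marker segmentation and centre-of-mass extraction.

Implements the detection half of the confirmation workflow: mask a
rectangular ROI around the marker cluster, binarise (fixed threshold for the
DRR where the burned-in markers are the brightest objects; normalise +
invert + Otsu for the CkV where the gold markers are the darkest), label
8-connected components, discard components whose pixel area falls outside
the expected marker-size bounds, and return the unweighted binary centroid
of each surviving blob.

Otsu's threshold is computed in-package because the pipeline contract pins
its details (histogram-exact on integer samples, ties broken toward the
lowest threshold) and the test-suite checks it against an exhaustive
between-class-variance search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import (
    DegenerateHistogramError,
    DetectionCountError,
    InvalidParameterError,
)
from .image import ProjectionImage
from .registration import PointCloud2D

__all__ = [
    "RoiMask",
    "MarkerBlob",
    "otsu_threshold",
    "label_and_filter_components",
    "component_com",
    "detect_markers_drr",
    "detect_markers_ckv",
    "default_size_bounds",
]


@dataclass(frozen=True)
class RoiMask:
    """Rectangular region of interest, ``(x0, y0, width, height)`` in pixels."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError("ROI width and height must be positive")

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > cols or self.y0 + self.height > rows:
            raise InvalidParameterError(
                f"ROI {self} does not lie within raster of shape {shape}"
            )

    def crop(self, raster: np.ndarray) -> np.ndarray:
        self.validate_within(raster.shape)
        return raster[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]

    def shifted(self, dx: int, dy: int) -> "RoiMask":
        return RoiMask(self.x0 + dx, self.y0 + dy, self.width, self.height)


@dataclass
class MarkerBlob:
    """One 8-connected candidate-marker component."""

    rows: np.ndarray
    cols: np.ndarray
    area: int
    bounding_box: tuple[int, int, int, int]  # (x0, y0, w, h)
    com_px: tuple[float, float]  # (x, y), sub-pixel

    def com_mm(self, spacing: float) -> tuple[float, float]:
        return (self.com_px[0] * spacing, self.com_px[1] * spacing)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximising the between-class variance.

    Foreground is ``value > threshold``. For integer-valued samples every
    intensity level is a candidate cut, which makes the result identical to
    an exhaustive search over all cut points; float samples are binned into
    ``nbins`` equal-width bins. Ties are broken toward the lowest threshold.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or np.min(vals) == np.max(vals):
        raise DegenerateHistogramError(
            "threshold undefined: sample needs >= 2 distinct finite values"
        )
    vmin, vmax = float(np.min(vals)), float(np.max(vals))
    integral = bool(np.all(vals == np.round(vals))) and (vmax - vmin) < 65536
    if integral:
        levels = np.arange(vmin, vmax + 1.0)
        counts, _ = np.histogram(vals, bins=np.concatenate([levels - 0.5, [vmax + 0.5]]))
    else:
        counts, edges = np.histogram(vals, bins=nbins, range=(vmin, vmax))
        levels = 0.5 * (edges[:-1] + edges[1:])

    counts = counts.astype(np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1] / total  # background weight for cut after level i
    mu_cum = np.cumsum(counts * levels)
    mu_t = mu_cum[-1] / total
    mu0 = mu_cum[:-1] / np.maximum(np.cumsum(counts)[:-1], 1e-300)
    w1 = 1.0 - w0
    mu1 = (mu_t - w0 * mu0) / np.maximum(w1, 1e-300)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    # argmax returns the first maximum -> lowest threshold on ties
    return float(levels[int(np.argmax(sigma_b))])


def label_and_filter_components(
    binary: np.ndarray, min_area: int, max_area: int
) -> list[MarkerBlob]:
    """Label 8-connected components and keep those with area in bounds.

    Blobs are returned sorted by centre of mass (row, then column) so marker
    labels are reproducible across runs.
    """
    if not (0 < min_area <= max_area):
        raise InvalidParameterError("require 0 < min_area <= max_area")
    labels = measure.label(np.asarray(binary, dtype=bool), connectivity=2)
    blobs: list[MarkerBlob] = []
    for region in measure.regionprops(labels):
        if not (min_area <= region.area <= max_area):
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        r0, c0, r1, c1 = region.bbox
        com_row, com_col = region.centroid
        blobs.append(
            MarkerBlob(
                rows=rr,
                cols=cc,
                area=int(region.area),
                bounding_box=(int(c0), int(r0), int(c1 - c0), int(r1 - r0)),
                com_px=(float(com_col), float(com_row)),
            )
        )
    blobs.sort(key=lambda b: (b.com_px[1], b.com_px[0]))
    return blobs


def component_com(blob: MarkerBlob, spacing: float) -> tuple[float, float]:
    """Unweighted centroid of a blob's pixel set, in mm ``(x, y)``."""
    if blob.area == 0 or len(blob.rows) == 0:
        raise InvalidParameterError("empty blob has no centre of mass")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    return (float(np.mean(blob.cols)) * spacing, float(np.mean(blob.rows)) * spacing)


def default_size_bounds(
    spacing: float,
    marker_length_mm: float = 5.0,
    marker_diameter_mm: float = 1.0,
    burned_in_diameter_mm: float = 4.0,
    margin: float = 3.0,
) -> tuple[int, int]:
    """Pixel-area bounds derived from the physical marker sizes.

    The lower bound is the projected area of the cylindrical marker
    (length x diameter rectangle) divided by ``margin``; the upper bound is
    the area of the round burned-in synthetic marker times ``margin``.
    """
    rect_px = marker_length_mm * marker_diameter_mm / spacing**2
    disc_px = np.pi * (burned_in_diameter_mm / 2.0) ** 2 / spacing**2
    lo = max(1, int(np.floor(rect_px / margin)))
    hi = int(np.ceil(disc_px * margin))
    return lo, hi


def _blobs_to_cloud(
    blobs: list[MarkerBlob],
    roi: RoiMask,
    spacing: float,
    expected_n: int,
    frame: str,
) -> PointCloud2D:
    if len(blobs) != expected_n:
        raise DetectionCountError(len(blobs), expected_n, [b.area for b in blobs])
    pts = np.array(
        [[(b.com_px[0] + roi.x0) * spacing, (b.com_px[1] + roi.y0) * spacing] for b in blobs]
    )
    return PointCloud2D(points=pts, labels=[f"M{i + 1}" for i in range(len(blobs))], frame=frame)


def detect_markers_drr(
    drr: ProjectionImage,
    roi: RoiMask,
    threshold: float | None = None,
    size_bounds: tuple[int, int] | None = None,
    expected_n: int = 3,
) -> PointCloud2D:
    """Detect the bright burned-in markers in the DRR inside ``roi``.

    A fixed intensity threshold retains the bright objects; by default it is
    set halfway between the ROI minimum and maximum, which isolates the
    markers because they are the brightest structures by construction.
    """
    sub = roi.crop(drr.raster).astype(np.float64)
    if threshold is None:
        threshold = float(sub.min() + 0.5 * (sub.max() - sub.min()))
    if size_bounds is None:
        if drr.pixel_spacing is None:
            raise InvalidParameterError("size_bounds required when pixel spacing unknown")
        size_bounds = default_size_bounds(drr.pixel_spacing)
    blobs = label_and_filter_components(sub > threshold, *size_bounds)
    if drr.pixel_spacing is None:
        raise InvalidParameterError("DRR pixel spacing required to report mm coordinates")
    return _blobs_to_cloud(blobs, roi, drr.pixel_spacing, expected_n, frame="DRR")


def detect_markers_ckv(
    ckv_rescaled: ProjectionImage,
    roi: RoiMask,
    size_bounds: tuple[int, int] | None = None,
    expected_n: int = 3,
) -> PointCloud2D:
    """Detect the dark gold markers in the rescaled CkV image inside ``roi``.

    The ROI sample is normalised to [0, 1], inverted so the markers become
    the bright class, binarised with Otsu's threshold, then labelled and
    filtered exactly like the DRR path. Expects the image already resampled
    onto the DRR geometry (same pixel spacing).
    """
    sub = roi.crop(ckv_rescaled.raster).astype(np.float64)
    lo, hi = float(sub.min()), float(sub.max())
    if hi <= lo:
        raise DegenerateHistogramError("ROI is constant; cannot normalise")
    inverted = 1.0 - (sub - lo) / (hi - lo)
    thr = otsu_threshold(inverted)
    if size_bounds is None:
        if ckv_rescaled.pixel_spacing is None:
            raise InvalidParameterError("size_bounds required when pixel spacing unknown")
        size_bounds = default_size_bounds(ckv_rescaled.pixel_spacing)
    blobs = label_and_filter_components(inverted > thr, *size_bounds)
    if ckv_rescaled.pixel_spacing is None:
        raise InvalidParameterError("rescaled CkV needs the reference pixel spacing")
    return _blobs_to_cloud(blobs, roi, ckv_rescaled.pixel_spacing, expected_n, frame="CkV")
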