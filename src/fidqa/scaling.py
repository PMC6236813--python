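"""Anatomic image-scale estimation and bicubic resampling.

The C-arm capture carries no pixel spacing, so the common geometry between
it and the DRR is established anatomically: the same horizontal distance
over the pubic symphysis (left-right interface between the obturator
foramen and the body of the pubic bone) is measured in both images and
their ratio defines the scale factor.

Convention (fixed here, since either direction could be argued): the C-arm
magnifies the anatomy relative to the DRR grid, so

    factor = d_ckv_px / d_drr_px    (> 1 in practice, ~3.5-4.4)

and :func:`rescale_to_reference` *divides* CkV pixel coordinates by the
factor, shrinking the CkV raster onto the DRR geometry. Resampling is
bicubic (cubic spline) with a Gaussian anti-alias prefilter when
downscaling, anchored at pixel (0, 0) so a feature at pixel ``p`` lands
exactly at ``p / factor``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidMeasurementError, InvalidParameterError, RasterSizeError
from .image import ProjectionImage

__all__ = [
    "ScaleEstimate",
    "compute_scale_factor",
    "scale_factor_cv",
    "rescale_to_reference",
    "measure_landmark_separation",
]


@dataclass
class ScaleEstimate:
    """CkV -> DRR scale factor with the raw measurements that produced it."""

    factor: float
    d_ckv_px: float
    d_drr_px: float
    repeats: list[float] | None = None
    cv: float | None = None


def compute_scale_factor(d_ckv_px: float, d_drr_px: float) -> ScaleEstimate:
    """Scale factor from one landmark distance measured in both images.

    Both distances are in each image's own pixels; sub-pixel values are
    welcome (manual picks are made at finer-than-pixel resolution).
    """
    if not (d_ckv_px > 0 and d_drr_px > 0):
        raise InvalidMeasurementError(
            f"landmark distances must be positive, got ckv={d_ckv_px}, drr={d_drr_px}"
        )
    return ScaleEstimate(factor=d_ckv_px / d_drr_px, d_ckv_px=d_ckv_px, d_drr_px=d_drr_px)


def scale_factor_cv(repeats: list[float]) -> float:
    """Coefficient of variation (sample SD / mean, n-1 denominator) of repeats."""
    r = np.asarray(repeats, dtype=np.float64)
    if r.size < 2:
        raise InvalidMeasurementError("CV needs at least 2 repeated measurements")
    mean = float(np.mean(r))
    if mean == 0:
        raise InvalidMeasurementError("CV undefined for zero-mean repeats")
    return float(np.std(r, ddof=1) / mean)


def rescale_to_reference(
    ckv: ProjectionImage,
    estimate: ScaleEstimate,
    reference_spacing: float,
    max_raster_px: int = 8192,
) -> ProjectionImage:
    """Resample the CkV raster onto the DRR pixel grid.

    Any landmark pair ``d`` px apart in the input ends up ``d / factor`` px
    apart in the output, matching the DRR; the output pixel spacing is the
    reference (DRR) spacing. Bicubic interpolation; Gaussian anti-alias
    prefilter with sigma ``(factor - 1) / 2`` when factor > 1 (the standard
    anti-aliasing width for a downscale), nothing when enlarging.
    """
    f = estimate.factor
    if not f > 0:
        raise InvalidParameterError(f"scale factor must be > 0, got {f}")
    if reference_spacing <= 0:
        raise InvalidParameterError("reference_spacing must be > 0")
    raster = np.asarray(ckv.raster, dtype=np.float64)
    out_shape = tuple(int(np.ceil(s / f)) for s in raster.shape)
    if max(out_shape) > max_raster_px:
        raise RasterSizeError(
            f"rescaled raster {out_shape} exceeds maximum {max_raster_px} px"
        )
    if f > 1.0:
        sigma = (f - 1.0) / 2.0
        raster = ndi.gaussian_filter(raster, sigma=sigma, mode="nearest")
    if f == 1.0 and out_shape == raster.shape:
        resampled = raster
    else:
        # output(o) = input(f * o): pure scaling about the pixel-(0,0) origin
        resampled = ndi.affine_transform(
            raster,
            matrix=np.diag([f, f]),
            output_shape=out_shape,
            order=3,
            mode="nearest",
        )
    return replace(
        ckv,
        raster=resampled,
        pixel_spacing=float(reference_spacing),
    )


def measure_landmark_separation(
    raster: np.ndarray,
    approx_points: np.ndarray,
    window_halfwidth_px: int = 12,
    strip_halfheight_px: int = 6,
) -> tuple[float, np.ndarray]:
    """Refine two dark vertical landmark features and return their separation.

    For each approximate point, intensities are averaged over a horizontal
    strip of ``2 * strip_halfheight_px + 1`` rows, and the feature centre is
    the darkness-weighted centroid of the column profile within
    ``+/- window_halfwidth_px`` columns -- a sub-pixel estimate, standing in
    for the manual finer-than-pixel picks made on clinical images.

    Returns ``(horizontal separation in px, refined (2, 2) points)``.
    """
    raster = np.asarray(raster, dtype=np.float64)
    pts = np.asarray(approx_points, dtype=np.float64)
    if pts.shape != (2, 2):
        raise InvalidMeasurementError("approx_points must be two (x, y) pixel points")
    refined = []
    for x, y in pts:
        r0 = max(0, int(round(y)) - strip_halfheight_px)
        r1 = min(raster.shape[0], int(round(y)) + strip_halfheight_px + 1)
        c0 = max(0, int(round(x)) - window_halfwidth_px)
        c1 = min(raster.shape[1], int(round(x)) + window_halfwidth_px + 1)
        if r1 <= r0 or c1 <= c0:
            raise InvalidMeasurementError(f"landmark window around ({x}, {y}) is empty")
        profile = raster[r0:r1, c0:c1].mean(axis=0)
        darkness = profile.max() - profile
        total = darkness.sum()
        if total <= 0:
            raise InvalidMeasurementError(
                f"no dark feature found in landmark window around ({x}, {y})"
            )
        xc = c0 + float(np.sum(np.arange(c1 - c0) * darkness) / total)
        refined.append((xc, y))
    refined_arr = np.asarray(refined)
    return float(abs(refined_arr[1, 0] - refined_arr[0, 0])), refined_arr
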