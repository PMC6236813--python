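"""End-to-end confirmation run and cohort-level migration assessment.

``confirm_pair`` executes the full in-memory workflow on two projection
images: present the C-arm capture as AP, estimate the anatomic scale factor
from the landmark picks, resample the CkV onto the DRR grid, pre-align by
the landmark midpoints, detect the markers in both images, couple the point
clouds, fit the rigid transform, and report per-marker displacements plus
the QA decision. ``run_confirmation`` is the file-based wrapper that also
writes the CSV/JSON report and a log of every parameter and intermediate.

Stage failures abort fail-fast wrapped in :class:`~fidqa.errors.StageError`
with the stage name and a machine-readable code -- a QA tool must not
silently degrade into a partial report.
"""

from __future__ import annotations

import dataclasses
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import detection, qa, registration, scaling
from .detection import RoiMask
from .errors import FidqaError, InvalidParameterError, StageError
from .image import (
    ProjectionImage,
    read_ckv_dicom,
    read_drr_image,
    write_displacement_report,
)
from .phantom import PhantomGroundTruth
from .qa import CohortComparison, QADecision
from .registration import DisplacementReport, PointCloud2D, RigidTransform2D

__all__ = [
    "RunConfig",
    "ConfirmationResult",
    "confirm_pair",
    "run_confirmation",
    "run_cohort_comparison",
    "roi_around_markers",
    "config_from_phantom",
]


@dataclass
class RunConfig:
    """Inputs and parameters of one file-based confirmation run."""

    drr_path: str
    ckv_path: str
    landmarks_drr: np.ndarray  # (2, 2) sub-pixel (x, y) picks on the DRR
    landmarks_ckv: np.ndarray  # (2, 2) picks on the AP-presented CkV
    roi: RoiMask  # DRR pixel coordinates
    out_dir: str | None = None
    drr_spacing: float | None = None  # mm/pixel override
    drr_threshold: float | None = None
    size_bounds: tuple[int, int] | None = None
    expected_n: int = 3
    qa_threshold_mm: float = 5.0
    angle_tag: str = "PositionerPrimaryAngle"
    angle_tolerance_deg: float = 2.0
    init_translation_mm: tuple[float, float] | None = None
    cohort_label: str = ""
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["landmarks_drr"] = np.asarray(d["landmarks_drr"], dtype=float)
        d["landmarks_ckv"] = np.asarray(d["landmarks_ckv"], dtype=float)
        d["roi"] = RoiMask(*d["roi"])
        if d.get("size_bounds") is not None:
            d["size_bounds"] = tuple(d["size_bounds"])
        if d.get("init_translation_mm") is not None:
            d["init_translation_mm"] = tuple(d["init_translation_mm"])
        return cls(**d)


@dataclass
class ConfirmationResult:
    report: DisplacementReport
    decision: QADecision
    scale: scaling.ScaleEstimate
    transform: RigidTransform2D
    correspondences: list[tuple[int, int]]
    drr_cloud: PointCloud2D
    ckv_cloud: PointCloud2D
    log: dict = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def _horizontal_distance(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if pts.shape != (2, 2):
        raise InvalidParameterError("landmarks must be two (x, y) points")
    return float(abs(pts[1, 0] - pts[0, 0]))


def confirm_pair(
    drr: ProjectionImage,
    ckv: ProjectionImage,
    landmarks_drr: np.ndarray,
    landmarks_ckv: np.ndarray,
    roi: RoiMask,
    drr_threshold: float | None = None,
    size_bounds: tuple[int, int] | None = None,
    expected_n: int = 3,
    qa_threshold_mm: float = 5.0,
    init_translation_mm: tuple[float, float] | None = None,
    cohort_label: str = "",
) -> ConfirmationResult:
    """Run the confirmation workflow on in-memory projection images.

    ``landmarks_ckv`` are pixel picks on the AP-presented CkV at its native
    resolution. The rigid transform is fitted mapping the CkV marker cloud
    onto the DRR cloud and applied to the CkV coordinates; displacements are
    therefore expressed in the DRR frame in mm.
    """
    log: dict = {}
    with _stage("present_ap"):
        ckv_ap = ckv.presented_ap()
        log["ckv_mirrored_to_ap"] = ckv_ap.mirrored_to_ap
        log["ckv_angle_deg"] = ckv_ap.acquisition_angle_deg
        log["ckv_angle_warning"] = ckv_ap.angle_warning
        if drr.pixel_spacing is None:
            raise InvalidParameterError("DRR pixel spacing is required")
        spacing = drr.pixel_spacing

    with _stage("scale"):
        d_drr = _horizontal_distance(landmarks_drr)
        d_ckv = _horizontal_distance(landmarks_ckv)
        estimate = scaling.compute_scale_factor(d_ckv_px=d_ckv, d_drr_px=d_drr)
        log["scale_factor"] = estimate.factor
        log["d_drr_px"] = d_drr
        log["d_ckv_px"] = d_ckv

    with _stage("rescale"):
        ckv_rescaled = scaling.rescale_to_reference(ckv_ap, estimate, spacing)

    with _stage("pre_align"):
        mid_drr_mm = np.mean(np.asarray(landmarks_drr, dtype=float), axis=0) * spacing
        mid_ckv_mm = (
            np.mean(np.asarray(landmarks_ckv, dtype=float), axis=0) / estimate.factor * spacing
        )
        shift_mm = mid_drr_mm - mid_ckv_mm
        log["landmark_shift_mm"] = shift_mm.tolist()
        shift_px = np.round(shift_mm / spacing).astype(int)

    with _stage("detect_drr"):
        drr_cloud = detection.detect_markers_drr(
            drr, roi, threshold=drr_threshold, size_bounds=size_bounds, expected_n=expected_n
        )
        log["drr_points_mm"] = drr_cloud.points.tolist()

    with _stage("detect_ckv"):
        roi_ckv = roi.shifted(-int(shift_px[0]), -int(shift_px[1]))
        ckv_cloud = detection.detect_markers_ckv(
            ckv_rescaled, roi_ckv, size_bounds=size_bounds, expected_n=expected_n
        )
        log["ckv_points_mm"] = ckv_cloud.points.tolist()

    with _stage("couple"):
        init = None if init_translation_mm is None else np.asarray(init_translation_mm)
        correspondences = registration.couple_points(ckv_cloud, drr_cloud, init)
        log["correspondences"] = correspondences

    with _stage("register"):
        icp = registration.icp_register(
            ckv_cloud, drr_cloud, correspondences=correspondences
        )
        transform = icp.transform
        registered = PointCloud2D(
            points=transform.apply(ckv_cloud.points),
            labels=ckv_cloud.labels,
            frame="DRR",
        )
        log["transform"] = transform.to_dict()

    with _stage("displacements"):
        report = registration.compute_displacements(
            drr_cloud, registered, correspondences, cohort_label=cohort_label
        )

    with _stage("qa"):
        decision = qa.qa_decide(report, threshold=qa_threshold_mm)
        log["decision"] = decision.to_dict()

    return ConfirmationResult(
        report=report,
        decision=decision,
        scale=estimate,
        transform=transform,
        correspondences=correspondences,
        drr_cloud=drr_cloud,
        ckv_cloud=ckv_cloud,
        log=log,
    )


def run_confirmation(config: RunConfig) -> ConfirmationResult:
    """File-based confirmation: read, run, and (optionally) write outputs."""
    with _stage("read_drr"):
        drr = read_drr_image(config.drr_path, pixel_spacing_override=config.drr_spacing)
    with _stage("read_ckv"):
        ckv = read_ckv_dicom(
            config.ckv_path,
            angle_tag=config.angle_tag,
            angle_tolerance_deg=config.angle_tolerance_deg,
        )
    result = confirm_pair(
        drr,
        ckv,
        landmarks_drr=config.landmarks_drr,
        landmarks_ckv=config.landmarks_ckv,
        roi=config.roi,
        drr_threshold=config.drr_threshold,
        size_bounds=config.size_bounds,
        expected_n=config.expected_n,
        qa_threshold_mm=config.qa_threshold_mm,
        init_translation_mm=config.init_translation_mm,
        cohort_label=config.cohort_label,
    )
    result.log["config"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else dataclasses.astuple(v) if isinstance(v, RoiMask) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    if config.out_dir is not None:
        with _stage("write"):
            out = Path(config.out_dir)
            payload = write_displacement_report(result.report, out)
            payload["decision"] = result.decision.to_dict()
            payload["scale_factor"] = result.scale.factor
            payload["transform"] = result.transform.to_dict()
            with open(out / "report.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            with open(out / "log.json", "w") as fh:
                json.dump(result.log, fh, indent=2, default=str)
    return result


def run_cohort_comparison(
    reports_a: list[DisplacementReport],
    reports_b: list[DisplacementReport],
    pooling: str = "markers",
    alpha: float = 0.05,
    method: str = "auto",
) -> CohortComparison:
    """Compare the total displacements of two cohorts (Mann-Whitney U).

    ``pooling="markers"`` pools every per-marker total displacement;
    ``pooling="patients"`` reduces each report to its mean first (the
    per-patient values are independent, which the pooled per-marker values
    within one patient are not -- they share a single rigid fit).
    """
    if not reports_a or not reports_b:
        raise InvalidParameterError("both cohorts must be nonempty")
    if pooling not in ("markers", "patients"):
        raise InvalidParameterError("pooling must be 'markers' or 'patients'")

    def pool(reports: list[DisplacementReport]) -> np.ndarray:
        if pooling == "markers":
            return np.concatenate([r.dtotal for r in reports])
        return np.array([float(np.mean(r.dtotal)) for r in reports])

    return qa.mann_whitney_u(pool(reports_a), pool(reports_b), alpha=alpha, method=method)


def roi_around_markers(
    points_mm: np.ndarray,
    spacing: float,
    raster_shape: tuple[int, int],
    margin_mm: float = 15.0,
) -> RoiMask:
    """Rectangular ROI (DRR pixels) enclosing marker positions plus a margin."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) / spacing
    margin = margin_mm / spacing
    x0 = max(0, int(np.floor(pts[:, 0].min() - margin)))
    y0 = max(0, int(np.floor(pts[:, 1].min() - margin)))
    x1 = min(raster_shape[1], int(np.ceil(pts[:, 0].max() + margin)))
    y1 = min(raster_shape[0], int(np.ceil(pts[:, 1].max() + margin)))
    return RoiMask(x0, y0, x1 - x0, y1 - y0)


def config_from_phantom(
    truth: PhantomGroundTruth,
    drr_path: str | Path,
    ckv_path: str | Path,
    raster_shape: tuple[int, int],
    out_dir: str | None = None,
    margin_mm: float = 15.0,
    **overrides,
) -> RunConfig:
    """Build a RunConfig from phantom ground truth (landmarks, ROI, spacing)."""
    roi = roi_around_markers(
        truth.drr_marker_com, truth.pixel_spacing_drr, raster_shape, margin_mm=margin_mm
    )
    return RunConfig(
        drr_path=str(drr_path),
        ckv_path=str(ckv_path),
        landmarks_drr=np.asarray(truth.landmark_points_drr, dtype=float),
        landmarks_ckv=np.asarray(truth.landmark_points_ckv, dtype=float),
        roi=roi,
        out_dir=out_dir,
        drr_spacing=truth.pixel_spacing_drr,
        seed=truth.seed,
        **overrides,
    )
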