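"""Projection-image container and file I/O.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` = column (patient right -> left once the image is AP-presented),
``y`` = row (superior -> inferior). Physical distances are millimetres.

The C-arm acquires posterior-anterior (PA) projections that the X-ray system
presents as anterior-posterior (AP) images by left-right mirroring; the CkV
reader reproduces that convention so every downstream module sees AP rasters.
The CkV DICOM typically carries no pixel-spacing information, so the reader
never requires it -- scaling is anatomic (see :mod:`fidqa.scaling`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import FidqaError, InvalidParameterError, MissingSpacingError, UnsupportedFormatError

__all__ = [
    "ProjectionImage",
    "mirror_lr",
    "read_ckv_dicom",
    "read_drr_image",
    "write_ckv_dicom",
    "write_drr_png",
    "write_displacement_report",
    "read_displacement_report",
]

#: default DICOM element holding the recorded C-arm angle; the vendor element
#: is not standardised, so readers accept any keyword.
DEFAULT_ANGLE_TAG = "PositionerPrimaryAngle"


@dataclass
class ProjectionImage:
    """A single-channel 2-D projection raster plus acquisition metadata.

    Parameters
    ----------
    raster
        2-D intensity array. Intensity ordering is never silently rescaled:
        bright stays bright, dark stays dark.
    pixel_spacing
        Isotropic spacing in mm/pixel, or ``None`` when unknown (the usual
        case for C-arm captures).
    view
        ``"AP"`` or ``"PA"`` -- the acquisition direction.
    mirrored_to_ap
        True once a PA acquisition has been left-right mirrored so that it
        presents as an AP image.
    acquisition_angle_deg
        Recorded C-arm angle, or ``None`` when the header lacked it.
    source
        One of ``{"DRR", "CkV", "phantom"}``.
    angle_warning
        Set when ``|acquisition_angle_deg|`` exceeded the reader's tolerance.
    """

    raster: np.ndarray
    pixel_spacing: float | None = None
    view: str = "AP"
    mirrored_to_ap: bool = False
    acquisition_angle_deg: float | None = None
    source: str = "phantom"
    angle_warning: bool = False

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise UnsupportedFormatError(
                f"raster must be single-channel 2-D, got shape {self.raster.shape}"
            )
        if self.pixel_spacing is not None and not self.pixel_spacing > 0:
            raise InvalidParameterError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.view not in ("AP", "PA"):
            raise InvalidParameterError(f"view must be 'AP' or 'PA', got {self.view!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape  # type: ignore[return-value]

    def presented_ap(self) -> "ProjectionImage":
        """Return this image presented as AP (mirroring a raw PA raster)."""
        if self.view == "PA" and not self.mirrored_to_ap:
            return replace(self, raster=mirror_lr(self.raster), mirrored_to_ap=True)
        return self


def mirror_lr(raster: np.ndarray) -> np.ndarray:
    """Left-right mirror (column reversal); an involution."""
    return np.ascontiguousarray(np.asarray(raster)[:, ::-1])


def _check_single_frame_grayscale(ds: Dataset, path: Path) -> None:
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: colour DICOM not supported")


def read_ckv_dicom(
    path: str | Path,
    angle_tag: str = DEFAULT_ANGLE_TAG,
    angle_tolerance_deg: float = 2.0,
) -> ProjectionImage:
    """Read a C-arm kV capture and present it as an AP image.

    If the stored view is PA (``ViewPosition``) and the raster has not already
    been mirrored, columns are flipped so the returned image is AP-presented
    and ``mirrored_to_ap`` is set. The recorded C-arm angle is read from
    ``angle_tag`` when present; when its magnitude exceeds
    ``angle_tolerance_deg`` the ``angle_warning`` flag is set (a non-zero
    angle breaks the pure-PA projection assumption) and a ``UserWarning`` is
    emitted. Pixel spacing is read if present but never required.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise OSError(f"unreadable DICOM file {path}: {exc}") from exc
    _check_single_frame_grayscale(ds, path)

    raster = ds.pixel_array.astype(np.float64)
    view = str(getattr(ds, "ViewPosition", "") or "AP").upper()
    view = view if view in ("AP", "PA") else "AP"

    angle: float | None = None
    raw_angle = getattr(ds, angle_tag, None)
    if raw_angle is not None and str(raw_angle) != "":
        angle = float(raw_angle)

    spacing = None
    sp = getattr(ds, "ImagerPixelSpacing", None) or getattr(ds, "PixelSpacing", None)
    if sp is not None:
        spacing = float(sp[0])

    img = ProjectionImage(
        raster=raster,
        pixel_spacing=spacing,
        view=view,
        mirrored_to_ap=False,
        acquisition_angle_deg=angle,
        source="CkV",
    ).presented_ap()

    if angle is not None and abs(angle) > angle_tolerance_deg:
        img.angle_warning = True
        warnings.warn(
            f"recorded C-arm angle {angle:g} deg exceeds tolerance "
            f"{angle_tolerance_deg:g} deg; projection is not purely PA",
            UserWarning,
            stacklevel=2,
        )
    return img


def read_drr_image(
    path: str | Path, pixel_spacing_override: float | None = None
) -> ProjectionImage:
    """Read a DRR-like reference image (DICOM or grayscale PNG/TIFF).

    The DRR defines the common geometry, so its pixel spacing is mandatory:
    it comes from the DICOM header or from ``pixel_spacing_override`` (which
    also takes precedence over a header value).
    """
    path = Path(path)
    spacing = pixel_spacing_override
    if path.suffix.lower() in (".dcm", ".dicom", ".ima"):
        ds = pydicom.dcmread(path)
        _check_single_frame_grayscale(ds, path)
        raster = ds.pixel_array.astype(np.float64)
        if spacing is None:
            sp = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
            if sp is not None:
                spacing = float(sp[0])
    else:
        raster = np.asarray(iio.imread(path))
        if raster.ndim != 2:
            raise UnsupportedFormatError(
                f"{path}: expected single-channel grayscale, got shape {raster.shape}"
            )
        raster = raster.astype(np.float64)
    if spacing is None:
        raise MissingSpacingError(
            f"{path}: no pixel spacing in file; pass pixel_spacing_override (mm/pixel)"
        )
    return ProjectionImage(
        raster=raster,
        pixel_spacing=float(spacing),
        view="AP",
        source="DRR",
    )


def _to_uint16(raster: np.ndarray) -> np.ndarray:
    """Map a float raster in [0, 1] (or any range) onto uint16, order-preserving."""
    r = np.asarray(raster, dtype=np.float64)
    lo, hi = float(r.min()), float(r.max())
    if hi <= lo:
        return np.zeros(r.shape, dtype=np.uint16)
    return np.round((r - lo) / (hi - lo) * 65535.0).astype(np.uint16)


def write_ckv_dicom(path: str | Path, image: ProjectionImage) -> None:
    """Write a CkV-like image as a single-frame secondary-capture DICOM.

    A PA image that has *not* been mirrored is stored raw with
    ``ViewPosition = PA`` so the round trip through :func:`read_ckv_dicom`
    reproduces the system's mirror-on-read behaviour. No pixel spacing is
    written (the clinical captures carry none). Intensities are quantised to
    uint16 preserving their ordering.
    """
    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "XA"
    ds.ViewPosition = image.view
    if image.acquisition_angle_deg is not None:
        ds.PositionerPrimaryAngle = f"{image.acquisition_angle_deg:g}"
    pixels = _to_uint16(image.raster)
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_drr_png(path: str | Path, image: ProjectionImage) -> None:
    """Write a DRR-like image as a 16-bit grayscale PNG (spacing travels separately)."""
    iio.imwrite(Path(path), _to_uint16(image.raster))


def write_displacement_report(report, directory: str | Path, stem: str = "report") -> dict:
    """Write a displacement report as ``<stem>.csv`` + ``<stem>.json``.

    The CSV holds one row per marker (label, dX, dY, dTotal in mm) at full
    float precision; the JSON holds per-marker values, column summaries and,
    when attached, the QA decision. Returns the JSON payload.
    """
    from .registration import DisplacementReport  # local import avoids cycle at doc build

    if not isinstance(report, DisplacementReport):
        raise InvalidParameterError("report must be a DisplacementReport")
    if report.n_markers == 0:
        raise InvalidParameterError("refusing to write an empty displacement report")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(directory / f"{stem}.csv", index=False)
    payload = report.to_dict()
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def read_displacement_report(directory: str | Path, stem: str = "report"):
    """Read back a report written by :func:`write_displacement_report`."""
    from .registration import DisplacementReport

    with open(Path(directory) / f"{stem}.json") as fh:
        payload = json.load(fh)
    return DisplacementReport.from_dict(payload)
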