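"""Synthetic phantom: paired DRR-like and C-arm-like projections with truth.

The generator emulates the study conditions of the clinical confirmation
workflow: three ~5 x 1 mm gold cylinders implanted 2-3 cm apart in the
prostate, imaged twice --

* a 512 x 512 anterior-posterior DRR at known isotropic spacing, where the
  markers appear as *bright* burned-in round objects (4 mm discs, the way a
  planning system renders identified marker positions into a synthetic CT),
  over a smooth mid-intensity pelvis backdrop with two dark vertical bar
  features standing in for the pubic-bone / obturator-foramen interfaces
  used for anatomic scaling;
* a C-arm kV capture of the same scene, magnified by ``scale_factor``
  relative to the DRR grid (the C-arm detector samples the anatomy much
  more finely), with the markers as *dark* 5 x 1 mm vertical rectangles,
  optionally displaced by per-marker migration, laterally shifted by a
  depth-dependent C-arm angle error, degraded by additive Gaussian noise,
  and stored posterior-anterior (left-right mirrored), spacing unknown.

Everything rendered is recorded in a ground-truth object so the whole
pipeline can be validated without clinical data. All coordinates in the
truth record are AP-presented; x = left-right (columns), y =
inferior-superior (rows); physical units mm.

Migration model
---------------
The per-marker migration vector is drawn i.i.d. isotropic Gaussian per
component with SD ``migration_sigma``; magnitudes are then Rayleigh with
mean ``sigma * sqrt(pi/2)``. Because the downstream rigid registration
absorbs 3 of the 2n degrees of freedom of the perturbation, the *measured*
post-registration displacement is smaller than the true migration by the
factor ``sqrt((2n - 3) / (2n))`` (RMS sense; 1/sqrt(2) for n = 3).
:func:`sigma_for_measured_mean` inverts that relation so a cohort can be
calibrated against a reported post-registration mean.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError, InvalidParameterError
from .image import ProjectionImage, mirror_lr, write_ckv_dicom, write_drr_png
from .registration import RigidTransform2D

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "sample_migration",
    "sigma_for_true_mean",
    "sigma_for_measured_mean",
    "generate_phantom_pair",
    "sample_patient_config",
    "write_phantom",
]


@dataclass
class PhantomConfig:
    """All knobs of the paired-projection phantom. Distances in mm."""

    image_shape_drr: tuple[int, int] = (512, 512)
    #: isotropic DRR spacing; matches the in-plane sampling of the synthetic-CT
    #: images the clinical DRRs are generated from
    pixel_spacing_drr: float = 0.4
    image_shape_ckv: tuple[int, int] = (1280, 1280)
    #: CkV anatomy magnification relative to the DRR grid (d_ckv_px / d_drr_px)
    scale_factor: float = 4.0
    n_markers: int = 3
    marker_length: float = 5.0
    marker_diameter: float = 1.0
    #: target inter-marker distance used by the default layout
    marker_spacing: float = 25.0
    #: explicit (n, 2) marker positions in scene mm; None -> regular polygon
    marker_positions_mm: np.ndarray | None = None
    #: diameter of the round burned-in marker rendering in the DRR
    drr_marker_diameter: float = 4.0
    migration_sigma: float = 0.0
    #: explicit (n, 2) migration vectors override sampling when given
    migration_vectors_mm: np.ndarray | None = None
    carm_angle_deg: float = 0.0
    #: simulated marker depths (out-of-plane, mm); None -> sampled U(-spread, spread)
    marker_depths_mm: np.ndarray | None = None
    depth_spread_mm: float = 10.0
    noise_sd: float = 0.02
    distractors: int = 0
    distractor_diameter_mm: float = 10.0
    #: render one DRR marker displaced radially (a calcification mistaken for
    #: the marker during identification); the CkV keeps the true position
    confusable: bool = False
    confusable_offset_mm: float = 10.0
    landmark_separation_mm: float = 60.0
    landmark_offset_y_mm: float = 45.0
    landmark_width_mm: float = 2.0
    landmark_height_mm: float = 10.0
    #: translation of the CkV frame relative to the scene centre; None -> U(-5, 5)
    frame_offset_mm: tuple[float, float] | None = None
    frame_rotation_deg: float = 0.0
    store_pa: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.scale_factor <= 0:
            raise InvalidParameterError("scale_factor must be > 0")
        if not (self.marker_length > self.marker_diameter > 0):
            raise InvalidParameterError("require marker_length > marker_diameter > 0")
        if self.n_markers < 1:
            raise InvalidParameterError("n_markers must be >= 1")
        if self.migration_sigma < 0:
            raise InvalidParameterError("migration_sigma must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.pixel_spacing_drr <= 0:
            raise InvalidParameterError("pixel_spacing_drr must be > 0")


@dataclass
class PhantomGroundTruth:
    """Everything the generator rendered, for validating the pipeline."""

    drr_marker_com: np.ndarray  # (n, 2) mm, DRR frame (as rendered/identified)
    ckv_marker_com: np.ndarray  # (n, 2) mm, CkV frame (post-migration)
    ckv_marker_com_premigration: np.ndarray  # (n, 2) mm, CkV frame
    migration_vectors: np.ndarray  # (n, 2) mm, scene frame
    angle_offsets_mm: np.ndarray  # (n, 2) mm lateral shift from C-arm angle
    landmark_points_drr: np.ndarray  # (2, 2) px
    landmark_points_ckv: np.ndarray  # (2, 2) px, AP presentation
    true_transform: RigidTransform2D  # CkV-frame mm -> DRR-frame mm (ignoring migration)
    scale_factor: float
    pixel_spacing_drr: float
    seed: int
    misidentified_marker: int | None = None

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "true_transform"
        }
        out = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
        out["true_transform"] = self.true_transform.to_dict()
        out["units"] = "mm unless stated; landmark points in pixels; x=left-right, y=inferior-superior"
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomGroundTruth":
        return cls(
            drr_marker_com=np.asarray(d["drr_marker_com"]),
            ckv_marker_com=np.asarray(d["ckv_marker_com"]),
            ckv_marker_com_premigration=np.asarray(d["ckv_marker_com_premigration"]),
            migration_vectors=np.asarray(d["migration_vectors"]),
            angle_offsets_mm=np.asarray(d["angle_offsets_mm"]),
            landmark_points_drr=np.asarray(d["landmark_points_drr"]),
            landmark_points_ckv=np.asarray(d["landmark_points_ckv"]),
            true_transform=RigidTransform2D.from_dict(d["true_transform"]),
            scale_factor=float(d["scale_factor"]),
            pixel_spacing_drr=float(d["pixel_spacing_drr"]),
            seed=int(d["seed"]),
            misidentified_marker=d.get("misidentified_marker"),
        )


def sample_migration(
    n_markers: int, sigma: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw per-marker migration vectors, i.i.d. N(0, sigma^2) per component.

    Displacement magnitudes are then Rayleigh-distributed with mean
    ``sigma * sqrt(pi / 2)``.
    """
    if sigma < 0:
        raise InvalidParameterError(f"migration sigma must be >= 0, got {sigma}")
    if n_markers < 0:
        raise InvalidParameterError("n_markers must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma == 0:
        rng.normal(size=(n_markers, 2))  # keep the stream position deterministic
        return np.zeros((n_markers, 2))
    return rng.normal(0.0, sigma, size=(n_markers, 2))


def sigma_for_true_mean(mean_mm: float) -> float:
    """Per-component SD whose Rayleigh magnitude mean equals ``mean_mm``."""
    return mean_mm / math.sqrt(math.pi / 2.0)


def sigma_for_measured_mean(mean_mm: float, n_markers: int = 3) -> float:
    """Per-component SD whose *post-registration* mean displacement is ``mean_mm``.

    The rigid least-squares registration of ``n`` corresponded points
    removes 3 of the ``2n`` perturbation degrees of freedom, shrinking the
    residuals by ``sqrt((2n - 3) / (2n))`` in the RMS sense, so the target
    observable is inflated by the inverse factor before the Rayleigh-mean
    inversion.
    """
    if n_markers < 2:
        raise InvalidParameterError("registration shrinkage defined for n_markers >= 2")
    shrink = math.sqrt((2 * n_markers - 3) / (2 * n_markers))
    return sigma_for_true_mean(mean_mm / shrink)


# ---------------------------------------------------------------------------
# rendering primitives (sub-pixel coverage, blended into the backdrop)

def _blend(raster: np.ndarray, rows: slice, cols: slice, cov: np.ndarray, value: float) -> None:
    raster[rows, cols] = raster[rows, cols] * (1.0 - cov) + value * cov


def _rect_coverage(shape, center, half_w, half_h):
    """Exact pixel coverage of an axis-aligned rectangle; centers in px."""
    x, y = center
    c0 = max(0, int(np.floor(x - half_w - 0.5)))
    c1 = min(shape[1], int(np.ceil(x + half_w + 0.5)) + 1)
    r0 = max(0, int(np.floor(y - half_h - 0.5)))
    r1 = min(shape[0], int(np.ceil(y + half_h + 0.5)) + 1)
    cc = np.arange(c0, c1)
    rr = np.arange(r0, r1)
    cov_x = np.clip(np.minimum(cc + 0.5, x + half_w) - np.maximum(cc - 0.5, x - half_w), 0, 1)
    cov_y = np.clip(np.minimum(rr + 0.5, y + half_h) - np.maximum(rr - 0.5, y - half_h), 0, 1)
    return slice(r0, r1), slice(c0, c1), np.outer(cov_y, cov_x)


def _disc_coverage(shape, center, radius, supersample: int = 5):
    """Pixel coverage of a disc by regular sub-pixel sampling."""
    x, y = center
    c0 = max(0, int(np.floor(x - radius - 1)))
    c1 = min(shape[1], int(np.ceil(x + radius + 1)) + 1)
    r0 = max(0, int(np.floor(y - radius - 1)))
    r1 = min(shape[0], int(np.ceil(y + radius + 1)) + 1)
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    cc = np.arange(c0, c1)[:, None] + off[None, :]  # (w, s)
    rr = np.arange(r0, r1)[:, None] + off[None, :]
    dx2 = (cc - x) ** 2  # (w, s)
    dy2 = (rr - y) ** 2  # (h, s)
    inside = (dy2[:, None, :, None] + dx2[None, :, None, :]) <= radius**2
    cov = inside.mean(axis=(2, 3))
    return slice(r0, r1), slice(c0, c1), cov


def _check_inside(shape, center, half_w, half_h, what: str) -> None:
    x, y = center
    if (
        x - half_w < 1 or y - half_h < 1
        or x + half_w > shape[1] - 2 or y + half_h > shape[0] - 2
    ):
        raise GenerationError(
            f"{what} at pixel ({x:.1f}, {y:.1f}) would fall outside raster {shape}"
        )


def _backdrop(shape, center_px, spacing, base, amplitude, radius_mm=150.0):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    r2 = ((cc - center_px[0]) ** 2 + (rr - center_px[1]) ** 2) * spacing**2
    return base + amplitude * np.exp(-r2 / (2.0 * radius_mm**2))


def _default_positions(n: int, center: np.ndarray, spacing: float) -> np.ndarray:
    """Markers on a regular polygon with side length ``spacing`` (n=1: centre)."""
    if n == 1:
        return center[None, :].copy()
    radius = spacing / (2.0 * math.sin(math.pi / n))
    ang = np.pi / 2.0 + 2.0 * np.pi * np.arange(n) / n
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def generate_phantom_pair(
    config: PhantomConfig,
) -> tuple[ProjectionImage, ProjectionImage, PhantomGroundTruth]:
    """Render one DRR/CkV pair plus ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.pixel_spacing_drr
    s_ckv = s / config.scale_factor  # mm of anatomy per CkV pixel
    shape_d = tuple(config.image_shape_drr)
    shape_c = tuple(config.image_shape_ckv)
    center = np.array([shape_d[1] / 2.0 * s, shape_d[0] / 2.0 * s])  # scene centre, mm
    ckv_center_px = np.array([shape_c[1] / 2.0, shape_c[0] / 2.0])

    # --- scene geometry -----------------------------------------------------
    if config.marker_positions_mm is not None:
        positions = np.asarray(config.marker_positions_mm, dtype=np.float64)
        if positions.shape != (config.n_markers, 2):
            raise InvalidParameterError("marker_positions_mm must be (n_markers, 2)")
    else:
        positions = _default_positions(config.n_markers, center, config.marker_spacing)

    if config.marker_depths_mm is not None:
        depths = np.asarray(config.marker_depths_mm, dtype=np.float64)
    elif config.carm_angle_deg != 0.0:
        depths = rng.uniform(-config.depth_spread_mm, config.depth_spread_mm, config.n_markers)
    else:
        depths = np.zeros(config.n_markers)
    angle_offsets = np.column_stack(
        [depths * math.tan(math.radians(config.carm_angle_deg)), np.zeros(config.n_markers)]
    )

    if config.migration_vectors_mm is not None:
        migration = np.asarray(config.migration_vectors_mm, dtype=np.float64)
        if migration.shape != (config.n_markers, 2):
            raise InvalidParameterError("migration_vectors_mm must be (n_markers, 2)")
    else:
        migration = sample_migration(config.n_markers, config.migration_sigma, rng)

    if config.frame_offset_mm is not None:
        offset = np.asarray(config.frame_offset_mm, dtype=np.float64)
    else:
        offset = rng.uniform(-5.0, 5.0, 2)
    rot = math.radians(config.frame_rotation_deg)
    rmat = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])

    half_sep = config.landmark_separation_mm / 2.0
    landmarks = np.array(
        [
            center + [-half_sep, config.landmark_offset_y_mm],
            center + [half_sep, config.landmark_offset_y_mm],
        ]
    )

    # distractor positions (anatomy frame): near the cluster, clear of markers
    distractor_pos = []
    cluster_centroid = positions.mean(axis=0)
    for _ in range(config.distractors):
        for _attempt in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(10.0, 14.0)
            cand = cluster_centroid + rad * np.array([math.cos(ang), math.sin(ang)])
            if np.min(np.linalg.norm(positions - cand, axis=1)) < 7.0:
                continue
            if np.min(np.linalg.norm(landmarks - cand, axis=1)) < 12.0:
                continue
            distractor_pos.append(cand)
            break
        else:  # pragma: no cover
            raise GenerationError("could not place a distractor clear of the markers")

    # DRR marker rendering positions: misidentification mode shifts one
    drr_positions = positions.copy()
    misidentified = None
    if config.confusable:
        misidentified = 0
        direction = positions[0] - cluster_centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([0.0, 1.0])
        drr_positions[0] = positions[0] + config.confusable_offset_mm * direction

    # --- DRR raster ---------------------------------------------------------
    drr = _backdrop(shape_d, center / s, s, base=0.45, amplitude=0.10)
    for lm in landmarks:
        sl_r, sl_c, cov = _rect_coverage(
            shape_d, lm / s, config.landmark_width_mm / 2 / s, config.landmark_height_mm / 2 / s
        )
        _check_inside(shape_d, lm / s, config.landmark_width_mm / 2 / s,
                      config.landmark_height_mm / 2 / s, "landmark")
        _blend(drr, sl_r, sl_c, cov, 0.10)
    for dpos in distractor_pos:
        radius = config.distractor_diameter_mm / 2.0 / s
        _check_inside(shape_d, dpos / s, radius, radius, "distractor")
        sl_r, sl_c, cov = _disc_coverage(shape_d, dpos / s, radius)
        _blend(drr, sl_r, sl_c, cov, 0.90)
    for i, p in enumerate(drr_positions):
        radius = config.drr_marker_diameter / 2.0 / s
        _check_inside(shape_d, p / s, radius, radius, f"marker {i + 1} (DRR)")
        sl_r, sl_c, cov = _disc_coverage(shape_d, p / s, radius)
        _blend(drr, sl_r, sl_c, cov, 1.00)

    # --- CkV raster (AP presentation first) ---------------------------------
    def to_ckv_px(pt_mm: np.ndarray) -> np.ndarray:
        return ckv_center_px + (rmat @ (pt_mm - center) + offset) / s_ckv

    ckv = _backdrop(shape_c, ckv_center_px, s_ckv, base=0.55, amplitude=0.08)
    lm_ckv_px = np.array([to_ckv_px(lm) for lm in landmarks])
    for i, lm_px in enumerate(lm_ckv_px):
        hw = config.landmark_width_mm / 2 / s_ckv
        hh = config.landmark_height_mm / 2 / s_ckv
        _check_inside(shape_c, lm_px, hw, hh, f"landmark {i + 1} (CkV)")
        sl_r, sl_c, cov = _rect_coverage(shape_c, lm_px, hw, hh)
        _blend(ckv, sl_r, sl_c, cov, 0.20)
    for dpos in distractor_pos:
        dpx = to_ckv_px(dpos)
        radius = config.distractor_diameter_mm / 2.0 / s_ckv
        _check_inside(shape_c, dpx, radius, radius, "distractor (CkV)")
        sl_r, sl_c, cov = _disc_coverage(shape_c, dpx, radius)
        _blend(ckv, sl_r, sl_c, cov, 0.10)

    ckv_marker_mm_pre = np.zeros_like(positions)
    ckv_marker_mm = np.zeros_like(positions)
    hw = config.marker_diameter / 2.0 / s_ckv
    hh = config.marker_length / 2.0 / s_ckv
    for i, p in enumerate(positions):
        pre_px = to_ckv_px(p + angle_offsets[i])
        final_px = to_ckv_px(p + migration[i] + angle_offsets[i])
        ckv_marker_mm_pre[i] = pre_px * s_ckv
        ckv_marker_mm[i] = final_px * s_ckv
        _check_inside(shape_c, final_px, hw, hh, f"marker {i + 1} (CkV)")
        sl_r, sl_c, cov = _rect_coverage(shape_c, final_px, hw, hh)
        _blend(ckv, sl_r, sl_c, cov, 0.00)

    if config.noise_sd > 0:
        ckv = np.clip(ckv + rng.normal(0.0, config.noise_sd, shape_c), 0.0, 1.0)

    # CkV-frame mm -> DRR-frame mm (pure frame transform; migration excluded)
    k = ckv_center_px * s_ckv + offset
    r_inv = rmat.T
    true_transform = RigidTransform2D(theta=-rot, t=center - r_inv @ k)

    stored = mirror_lr(ckv) if config.store_pa else ckv
    drr_img = ProjectionImage(
        raster=drr, pixel_spacing=s, view="AP", source="DRR",
    )
    ckv_img = ProjectionImage(
        raster=stored,
        pixel_spacing=None,
        view="PA" if config.store_pa else "AP",
        mirrored_to_ap=False,
        acquisition_angle_deg=config.carm_angle_deg,
        source="CkV",
    )
    truth = PhantomGroundTruth(
        drr_marker_com=drr_positions,
        ckv_marker_com=ckv_marker_mm,
        ckv_marker_com_premigration=ckv_marker_mm_pre,
        migration_vectors=migration,
        angle_offsets_mm=angle_offsets,
        landmark_points_drr=landmarks / s,
        landmark_points_ckv=lm_ckv_px,
        true_transform=true_transform,
        scale_factor=config.scale_factor,
        pixel_spacing_drr=s,
        seed=config.seed,
        misidentified_marker=misidentified,
    )
    return drr_img, ckv_img, truth


def sample_patient_config(
    rng: np.random.Generator, **overrides
) -> PhantomConfig:
    """One random patient: jittered marker triangle, realistic magnification.

    Markers are re-sampled until every pairwise distance lies in 18-32 mm
    (the 2-3 cm implant spacing); the CkV magnification is drawn from the
    3.5-4.4 range observed across patients; a minority of patients get a
    1-degree C-arm set-up deviation. Remaining fields can be overridden.
    """
    base = PhantomConfig(**{k: v for k, v in overrides.items() if k != "seed"})
    s = base.pixel_spacing_drr
    center = np.array(
        [base.image_shape_drr[1] / 2.0 * s, base.image_shape_drr[0] / 2.0 * s]
    )
    for _ in range(500):
        pts = center + rng.uniform(-18.0, 18.0, size=(base.n_markers, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        off_diag = d[~np.eye(base.n_markers, dtype=bool)]
        if off_diag.size == 0 or (np.all(off_diag >= 18.0) and np.all(off_diag <= 32.0)):
            break
    else:  # pragma: no cover
        raise GenerationError("failed to sample a valid marker layout")
    angle = float(rng.choice([0.0, 1.0], p=[0.87, 0.13]) * rng.choice([-1.0, 1.0]))
    cfg = dataclasses.replace(
        base,
        marker_positions_mm=pts,
        scale_factor=float(rng.uniform(3.5, 4.4)),
        frame_offset_mm=tuple(rng.uniform(-5.0, 5.0, 2)),
        carm_angle_deg=angle,
        seed=int(overrides.get("seed", rng.integers(0, 2**31 - 1))),
    )
    return cfg


def write_phantom(
    directory: str | Path,
    drr: ProjectionImage,
    ckv: ProjectionImage,
    truth: PhantomGroundTruth,
) -> dict[str, Path]:
    """Write ``drr.png`` (16-bit), ``ckv.dcm`` and ``truth.json`` into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "drr": directory / "drr.png",
        "ckv": directory / "ckv.dcm",
        "truth": directory / "truth.json",
    }
    write_drr_png(paths["drr"], drr)
    write_ckv_dicom(paths["ckv"], ckv)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return paths
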