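"""Rigid 2-D point-set registration of marker centres of mass.

The DRR and CkV marker centroids form two small labelled point clouds
(typically three points each). The pipeline couples them, fits a proper
rigid transform (rotation + translation, det = +1, no scale or reflection)
by closed-form least squares, and reports per-marker displacements.

A full iterative-closest-point loop is provided for unlabelled clouds, but
with three coupled points ICP converges to the closed-form Procrustes
solution in a single iteration, so the closed form is the default path.

Physical blind spots of the rigid model (inherited by any implementation):
a displacement common to all markers is indistinguishable from organ motion
and registered away, and a single migrating marker has its displacement
underestimated because the least-squares fit spreads it over the cloud.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, UnderdeterminedError

__all__ = [
    "PointCloud2D",
    "RigidTransform2D",
    "DisplacementReport",
    "ICPResult",
    "couple_points",
    "fit_rigid_2d",
    "icp_register",
    "compute_displacements",
]

#: exhaustive coupling is O(n!); the workflow never has more than a handful
#: of fiducials per image.
MAX_COUPLE_POINTS = 6


@dataclass
class PointCloud2D:
    """Ordered set of marker centre-of-mass coordinates in mm, one frame."""

    points: np.ndarray
    labels: list[str] | None = None
    frame: str = "DRR"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] < 1:
            raise InvalidParameterError(f"points must be (n, 2), got {self.points.shape}")
        n = len(self.points)
        if n > 1:
            d = np.linalg.norm(self.points[:, None] - self.points[None, :], axis=-1)
            if np.min(d[~np.eye(n, dtype=bool)]) == 0.0:
                raise InvalidParameterError("point cloud contains coincident points")
        if self.labels is None:
            self.labels = [str(i) for i in range(n)]
        elif len(self.labels) != n:
            raise InvalidParameterError("labels length must match point count")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class RigidTransform2D:
    """Proper rotation by ``theta`` (radians, CCW) followed by translation ``t`` (mm)."""

    theta: float = 0.0
    t: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64).reshape(2)

    @property
    def rotation(self) -> np.ndarray:
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.rotation.T + self.t

    def inverse(self) -> "RigidTransform2D":
        r_inv = self.rotation.T
        return RigidTransform2D(theta=-self.theta, t=-(r_inv @ self.t))

    def to_dict(self) -> dict:
        return {"theta_deg": math.degrees(self.theta), "t_mm": self.t.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(theta=math.radians(d["theta_deg"]), t=np.asarray(d["t_mm"]))


def couple_points(
    moving: PointCloud2D,
    fixed: PointCloud2D,
    init_translation: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Find the marker correspondence between two equally sized clouds.

    After shifting the moving cloud by ``init_translation`` (default: the
    centroid difference, the automated stand-in for the manual
    translation-only overlay performed on the images), the permutation
    minimising the sum of squared pair distances is found by exhaustive
    search over all ``n!`` pairings. Returns ``(moving_index, fixed_index)``
    pairs ordered by fixed index.
    """
    if len(moving) != len(fixed):
        raise InvalidParameterError(
            f"point counts differ: moving {len(moving)} vs fixed {len(fixed)}"
        )
    n = len(fixed)
    if n > MAX_COUPLE_POINTS:
        raise InvalidParameterError(f"exhaustive coupling limited to n <= {MAX_COUPLE_POINTS}")
    if init_translation is None:
        init_translation = fixed.centroid - moving.centroid
    shifted = moving.points + np.asarray(init_translation, dtype=np.float64)

    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(n)):
        cost = float(np.sum((shifted[list(perm)] - fixed.points) ** 2))
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    assert best_perm is not None
    return [(best_perm[j], j) for j in range(n)]


def fit_rigid_2d(
    moving: PointCloud2D,
    fixed: PointCloud2D,
    correspondences: list[tuple[int, int]] | None = None,
) -> RigidTransform2D:
    """Least-squares proper rigid transform (Kabsch/Procrustes, det = +1).

    Minimises ``sum ||R m_i + t - f_i||^2`` over rotations with determinant
    +1 and translations; reflections are refused by construction, so a
    mirror-image cloud yields a genuine-rotation fit with non-zero residual.
    """
    if correspondences is None:
        if len(moving) != len(fixed):
            raise InvalidParameterError("equal point counts required without correspondences")
        correspondences = [(i, i) for i in range(len(fixed))]
    mi = [c[0] for c in correspondences]
    fi = [c[1] for c in correspondences]
    m = moving.points[mi]
    f = fixed.points[fi]
    if len(m) < 2:
        raise UnderdeterminedError("at least 2 corresponded pairs required")
    m_bar, f_bar = m.mean(axis=0), f.mean(axis=0)
    mc, fc = m - m_bar, f - f_bar
    if np.allclose(mc, 0.0) or np.allclose(fc, 0.0):
        raise UnderdeterminedError("all corresponded points coincident; rotation undefined")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    theta = math.atan2(r[1, 0], r[0, 0])
    t = f_bar - r @ m_bar
    return RigidTransform2D(theta=theta, t=t)


@dataclass
class ICPResult:
    transform: RigidTransform2D
    correspondences: list[tuple[int, int]]
    residuals_mm: np.ndarray
    objective_history: list[float]

    @property
    def rms_mm(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_mm**2)))


def icp_register(
    moving: PointCloud2D,
    fixed: PointCloud2D,
    max_iter: int = 50,
    tol: float = 1e-9,
    correspondences: list[tuple[int, int]] | None = None,
) -> ICPResult:
    """Iterative closest point: alternate nearest-neighbour coupling and rigid fits.

    The mean-squared nearest-distance objective is non-increasing across
    iterations; iteration stops when its improvement drops below ``tol``
    (mm^2) or after ``max_iter`` rounds. With externally fixed
    ``correspondences`` this reduces to a single closed-form fit.
    """
    if correspondences is not None:
        transform = fit_rigid_2d(moving, fixed, correspondences)
        reg = transform.apply(moving.points)
        res = np.linalg.norm(
            reg[[c[0] for c in correspondences]] - fixed.points[[c[1] for c in correspondences]],
            axis=1,
        )
        return ICPResult(transform, list(correspondences), res, [float(np.mean(res**2))])

    tree = cKDTree(fixed.points)
    transform = RigidTransform2D()
    history: list[float] = []
    corr: list[tuple[int, int]] = [(i, i) for i in range(len(moving))]
    for _ in range(max_iter):
        reg = transform.apply(moving.points)
        dists, nn = tree.query(reg)
        corr = [(i, int(nn[i])) for i in range(len(moving))]
        objective = float(np.mean(dists**2))
        if history and history[-1] - objective < tol:
            history.append(objective)
            break
        history.append(objective)
        transform = fit_rigid_2d(moving, fixed, corr)
    reg = transform.apply(moving.points)
    res = np.linalg.norm(reg - fixed.points[[c[1] for c in corr]], axis=1)
    return ICPResult(transform, corr, res, history)


@dataclass
class DisplacementReport:
    """Per-marker |dX|, |dY| and Euclidean dTotal (mm) plus column summaries.

    dX is the left-right component, dY inferior-superior, dTotal the
    Euclidean distance; all are absolute values.
    """

    marker_labels: list[str]
    dx: np.ndarray
    dy: np.ndarray
    dtotal: np.ndarray
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.dx = np.abs(np.asarray(self.dx, dtype=np.float64))
        self.dy = np.abs(np.asarray(self.dy, dtype=np.float64))
        self.dtotal = np.asarray(self.dtotal, dtype=np.float64)
        if not (len(self.marker_labels) == len(self.dx) == len(self.dy) == len(self.dtotal)):
            raise InvalidParameterError("report columns must have equal length")
        if not np.allclose(self.dtotal, np.hypot(self.dx, self.dy), atol=1e-9):
            raise InvalidParameterError("dtotal must equal hypot(dx, dy) per marker")

    @property
    def n_markers(self) -> int:
        return len(self.dtotal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_labels,
                "dx_mm": self.dx,
                "dy_mm": self.dy,
                "dtotal_mm": self.dtotal,
            }
        )

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, col in (("dx_mm", self.dx), ("dy_mm", self.dy), ("dtotal_mm", self.dtotal)):
            out[name] = {
                "mean": float(np.mean(col)),
                "sd": float(np.std(col, ddof=1)) if len(col) > 1 else float("nan"),
                "median": float(np.median(col)),
                "min": float(np.min(col)),
                "max": float(np.max(col)),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "per_marker": self.to_frame().to_dict(orient="records"),
            "summary": self.summary(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplacementReport":
        rows = d["per_marker"]
        return cls(
            marker_labels=[str(r["marker"]) for r in rows],
            dx=[r["dx_mm"] for r in rows],
            dy=[r["dy_mm"] for r in rows],
            dtotal=[r["dtotal_mm"] for r in rows],
            cohort_label=d.get("cohort_label", ""),
        )


def compute_displacements(
    fixed: PointCloud2D,
    registered_moving: PointCloud2D,
    correspondences: list[tuple[int, int]],
    cohort_label: str = "",
) -> DisplacementReport:
    """Per-marker displacement between corresponded clouds in one frame (mm)."""
    if len(correspondences) == 0:
        raise InvalidParameterError("empty correspondence list")
    mi = [c[0] for c in correspondences]
    fi = [c[1] for c in correspondences]
    if max(mi) >= len(registered_moving) or max(fi) >= len(fixed):
        raise InvalidParameterError("correspondence indices exceed cloud sizes")
    delta = fixed.points[fi] - registered_moving.points[mi]
    labels = [fixed.labels[j] for j in fi]
    return DisplacementReport(
        marker_labels=labels,
        dx=np.abs(delta[:, 0]),
        dy=np.abs(delta[:, 1]),
        dtotal=np.linalg.norm(delta, axis=1),
        cohort_label=cohort_label,
    )
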