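"""Per-tree local ground fitting.

Rather than building a plot-wide terrain model, the pipeline fits a small
ground plane under each detected tree: extract a cylinder of points around
the trunk, keep the lowest ~10 cm slab (ground returns plus some trunk
bottom), fit a plane robustly with RANSAC, and project the trunk-circle
centre vertically onto that plane to define the tree's local zero-height
point ``p_zero``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NoGroundError
from .geometry import PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "PlaneModel",
    "CylinderNeighborhood",
    "extract_cylinder",
    "extract_ground_slab",
    "fit_plane_ransac",
    "project_zero_point",
]

#: inclination (degrees) above which a fitted plane is rejected as non-ground
MAX_GROUND_INCLINATION = 45.0
#: inclination above which breast height would need tilt correction; the
#: tree is processed but flagged
STEEP_GROUND_FLAG_DEG = 10.0


@dataclass
class PlaneModel:
    """Plane ``n . p = offset`` with unit upward normal.

    ``inclination_deg = arccos(n_z)`` is the tilt from horizontal.
    """

    normal: np.ndarray
    offset: float
    inlier_idx: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if nrm == 0:
            raise ValueError("zero normal")
        self.normal = self.normal / nrm
        if self.normal[2] < 0:
            self.normal = -self.normal
            self.offset = -self.offset

    @property
    def inclination_deg(self) -> float:
        return float(np.rad2deg(np.arccos(np.clip(self.normal[2], -1.0, 1.0))))

    def z_at(self, x: float, y: float) -> float:
        """Height of the plane at plan position (x, y)."""
        nx, ny, nz = self.normal
        if nz == 0:
            raise ValueError("vertical plane has no height function")
        return (self.offset - nx * x - ny * y) / nz

    def distances(self, points: np.ndarray) -> np.ndarray:
        return np.abs(points @ self.normal - self.offset)


@dataclass
class CylinderNeighborhood:
    """Points within a vertical cylinder around a plan-view centre."""

    center_xy: tuple[float, float]
    diameter: float
    points: PointCloud

    def __len__(self) -> int:
        return len(self.points)


def extract_cylinder(
    cloud: PointCloud, center_xy, diameter: float = 0.8
) -> CylinderNeighborhood:
    """Points with planar distance to ``center_xy`` at most ``diameter/2``.

    Defaults: 0.8 m for the per-tree cylinder; the ground extraction
    re-runs with 0.6 m.  An empty neighborhood is returned, not raised.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cx, cy = center_xy
    d = np.hypot(cloud.x - cx, cloud.y - cy)
    return CylinderNeighborhood(
        center_xy=(float(cx), float(cy)),
        diameter=diameter,
        points=cloud.select(d <= diameter / 2.0),
    )


def extract_ground_slab(
    neighborhood: CylinderNeighborhood, thickness: float = 0.10
) -> PointCloud:
    """Lowest slab of the neighborhood: ``z <= z_min + thickness``.

    The slab holds the ground returns plus some points at the bottom of
    the trunk; RANSAC treats the latter as outliers.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    pts = neighborhood.points
    if len(pts) == 0:
        raise ValueError("empty neighborhood has no ground slab")
    z0 = float(pts.z.min())
    return pts.select(pts.z <= z0 + thickness)


def fit_plane_ransac(
    points,
    inlier_tol: float = 0.02,
    max_iters: int = 200,
    min_inlier_frac: float = 0.5,
    seed: int = 0,
) -> PlaneModel:
    """RANSAC plane fit: random 3-point hypotheses, least-squares refinement.

    The best-consensus hypothesis is refined by an SVD plane fit on its
    inliers and the inlier set recomputed once.  Deterministic for a fixed
    seed.  Raises :class:`~stemscan.errors.NoGroundError` when the final
    consensus is below ``min_inlier_frac`` or the plane is steeper than
    45 degrees.
    """
    pts = np.asarray(points.xyz if isinstance(points, PointCloud) else points, dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise NoGroundError(f"need >= 3 points for a plane, got {n}")
    rng = np.random.default_rng(seed)
    best_count = -1
    best = None
    for _ in range(max_iters):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        nrm = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nrm)
        if norm < 1e-12:
            continue
        nrm = nrm / norm
        off = nrm @ p0
        count = int(np.count_nonzero(np.abs(pts @ nrm - off) <= inlier_tol))
        if count > best_count:
            best_count = count
            best = (nrm, off)
    if best is None:
        raise NoGroundError("all hypotheses degenerate")

    def refine(nrm, off):
        inl = np.abs(pts @ nrm - off) <= inlier_tol
        sub = pts[inl]
        centroid = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
        nrm2 = vt[-1]
        return nrm2, float(nrm2 @ centroid), np.nonzero(inl)[0]

    nrm, off, _ = refine(*best)
    nrm, off, inlier_idx = refine(nrm, off)
    frac = len(inlier_idx) / n
    if frac < min_inlier_frac:
        raise NoGroundError(
            f"consensus {frac:.2f} below minimum {min_inlier_frac:.2f}"
        )
    plane = PlaneModel(normal=nrm, offset=off, inlier_idx=inlier_idx, n_points=n)
    if plane.inclination_deg > MAX_GROUND_INCLINATION:
        raise NoGroundError(
            f"fitted plane inclined {plane.inclination_deg:.1f} deg: not ground"
        )
    logger.info(
        "fit_plane_ransac: %d/%d inliers, inclination %.2f deg",
        len(inlier_idx),
        n,
        plane.inclination_deg,
    )
    return plane


def project_zero_point(plane: PlaneModel, center_xy) -> np.ndarray:
    """Vertical projection of the circle centre onto the ground plane.

    The returned ``p_zero = (x, y, z_plane(x, y))`` defines the tree's
    local zero height and its position.  (Projection is along z rather
    than along the plane normal; at the few-degree inclinations of real
    ground the difference is well below measurement noise.)
    """
    if plane.inclination_deg > MAX_GROUND_INCLINATION:
        raise NoGroundError("plane too steep to be ground")
    x, y = center_xy
    return np.array([x, y, plane.z_at(x, y)])
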