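"""Per-tree estimates: DBH, total height, and position.

Given a detected trunk and its local ground plane, the pipeline

1. re-slices the cloud at ``z(p_zero) + 1.3 m`` inside the tree's cylinder
   and fits a circle: the diameter is the DBH and the centre the refined
   tree position;
2. projects the refined centre onto the ground plane: ``p_zero``;
3. takes the points within 0.5 m of the cylinder's highest point, removes
   sparse outliers with a k-nearest-neighbour mean-distance filter, and
   calls the highest surviving point ``p_top``;
4. reports ``height = z(p_top) - z(p_zero)``.

The KNN top filter: for each of the ``M`` candidate top points compute the
mean distance ``md_i`` to its 10 nearest neighbours; points with ``md_i``
at or below the grand mean ``md`` are tree points, the rest are outliers or
low-confidence returns (isolated twig hits, noise).  Since the minimum of
the ``md_i`` cannot exceed their mean, the tree-point set is never empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .circlefit import CircleModel, fit_gauss_newton, fit_pratt, fit_taubin
from .detect import ClusterParams, TrunkCandidate, detect_trunks
from .errors import DegenerateFitError, NoGroundError
from .geometry import PointCloud, ScannerConfig, ScanRecords, build_cloud
from .ground import (
    STEEP_GROUND_FLAG_DEG,
    extract_cylinder,
    extract_ground_slab,
    fit_plane_ransac,
    project_zero_point,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TopFilterState",
    "TreeRecord",
    "estimate_dbh",
    "extract_top",
    "knn_mean_distances",
    "filter_top",
    "estimate_height",
    "process_plot",
    "tree_records_to_dataframe",
]

_FITTERS = {"pratt": fit_pratt, "taubin": fit_taubin, "gauss-newton": fit_gauss_newton}

#: breast height above the local zero point, metres
BREAST_HEIGHT = 1.3
#: vertical window below the highest point that defines the top set, metres
TOP_WINDOW = 0.5


@dataclass
class TopFilterState:
    """State of the KNN top filter over the candidate top set ``V_top``."""

    points: np.ndarray                    # (M, 3)
    z_max: float
    window: float = TOP_WINDOW
    mean_dists: np.ndarray | None = None  # md_i, (M,)
    grand_mean: float | None = None       # md
    tree_mask: np.ndarray | None = None   # True where tree point

    @property
    def m(self) -> int:
        return self.points.shape[0]


def extract_top(points, window: float = TOP_WINDOW) -> TopFilterState:
    """Candidate top set: points with ``|z_max - z| < window``."""
    xyz = np.atleast_2d(np.asarray(
        points.xyz if isinstance(points, PointCloud) else points, dtype=float
    ))
    if xyz.shape[0] == 0:
        raise ValueError("empty point set has no top")
    z_max = float(xyz[:, 2].max())
    keep = (z_max - xyz[:, 2]) < window
    return TopFilterState(points=xyz[keep], z_max=z_max, window=window)


def knn_mean_distances(state: TopFilterState, k_neighbors: int = 10) -> TopFilterState:
    """Per-point mean distance to the k nearest neighbours, and its mean.

    With fewer than ``k_neighbors + 1`` points every other point is a
    neighbour (k falls back to M - 1).  A single-point set passes through
    untouched; it is its own top.
    """
    m = state.m
    if m == 1:
        state.mean_dists = np.zeros(1)
        state.grand_mean = 0.0
        return state
    k = min(k_neighbors, m - 1)
    tree = cKDTree(state.points)
    dists, _ = tree.query(state.points, k=k + 1)  # first neighbour is self
    state.mean_dists = dists[:, 1:].mean(axis=1)
    state.grand_mean = float(state.mean_dists.mean())
    return state


def filter_top(state: TopFilterState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition the top set and pick the highest tree point.

    Returns ``(tree_points, outliers, p_top)``.  A point is a tree point
    when ``md_i <= md``; z-ties at the top break by first occurrence in
    input order.
    """
    if state.mean_dists is None or state.grand_mean is None:
        raise ValueError("call knn_mean_distances first")
    mask = state.mean_dists <= state.grand_mean
    assert mask.any(), "min(md_i) <= mean(md_i): tree set cannot be empty"
    tree_pts = state.points[mask]
    outliers = state.points[~mask]
    p_top = tree_pts[int(np.argmax(tree_pts[:, 2]))]
    state.tree_mask = mask
    return tree_pts, outliers, p_top


def estimate_dbh(
    cloud: PointCloud,
    p_zero,
    half_thickness: float = 0.05,
    fit_method: str = "pratt",
    cylinder_diameter: float = 0.8,
    min_points: int = 10,
) -> tuple[float, CircleModel]:
    """DBH from the breast-height re-slice around ``p_zero``.

    Slice ``z(p_zero) + 1.3 +/- half_thickness`` restricted to the tree's
    cylinder, fit a circle, and report the diameter in cm.  The circle
    centre is the refined tree position.  Raises
    :class:`~stemscan.errors.DegenerateFitError` when fewer than
    ``min_points`` remain or the fit degenerates.
    """
    p_zero = np.asarray(p_zero, dtype=float)
    neigh = extract_cylinder(cloud, p_zero[:2], diameter=cylinder_diameter)
    z_bh = p_zero[2] + BREAST_HEIGHT
    pts = neigh.points
    mask = np.abs(pts.z - z_bh) <= half_thickness
    sub = pts.xyz[mask][:, :2]
    if sub.shape[0] < min_points:
        raise DegenerateFitError(
            f"only {sub.shape[0]} points in breast-height re-slice"
        )
    circle = _FITTERS[fit_method](sub)
    return circle.diameter * 100.0, circle


def estimate_height(p_top, p_zero) -> tuple[float, list[str]]:
    """Vertical distance from ``p_top`` down to ``p_zero``.

    Negative values (possible when the top filter ends below the fitted
    ground) are clamped to zero and flagged.
    """
    dz = float(np.asarray(p_top, float)[2] - np.asarray(p_zero, float)[2])
    if dz < 0:
        return 0.0, ["negative_height_clamped"]
    return dz, []


@dataclass
class TreeRecord:
    """Final per-tree estimate with full provenance."""

    tree_id: int
    x: float
    y: float
    dbh_cm: float | None
    height_m: float | None
    p_zero: np.ndarray | None
    p_top: np.ndarray | None
    ground_inclination_deg: float | None
    fit_rms_m: float | None
    n_fit_points: int
    cluster_id: int
    flags: list[str] = field(default_factory=list)


def _dedup_candidates(accepted: list[TrunkCandidate], min_sep: float) -> list[TrunkCandidate]:
    """Merge accepted candidates whose centres nearly coincide.

    A trunk occasionally splits into two clusters (e.g. a noise gap); the
    larger cluster wins.  ``min_sep`` well below the planting spacing keeps
    distinct trees apart.
    """
    kept: list[TrunkCandidate] = []
    for cand in sorted(accepted, key=lambda c: -c.n_points):
        if all(
            np.hypot(cand.circle.xc - k.circle.xc, cand.circle.yc - k.circle.yc) > min_sep
            for k in kept
        ):
            kept.append(cand)
    return kept


def process_plot(
    data: ScanRecords | PointCloud,
    scanner_config: ScannerConfig | None = None,
    cluster_params: ClusterParams | None = None,
    scanner_height: float | None = None,
    fit_method: str = "pratt",
    half_thickness: float = 0.05,
    tree_cylinder_diameter: float = 0.8,
    ground_cylinder_diameter: float = 0.6,
    slab_thickness: float = 0.10,
    ransac_tol: float = 0.02,
    ransac_iters: int = 200,
    min_dbh_points: int = 10,
    dedup_distance: float = 0.3,
    seed: int = 0,
) -> list[TreeRecord]:
    """Run the full single-scan pipeline and emit one record per tree.

    Records or a cloud go through: cloud building, breast-height transect
    detection, per-tree ground fitting, DBH re-slice, KNN top filter and
    height estimation.  The detection slice is centred 1.3 m above the
    plot's lowest returns (1st percentile of z, or ``-scanner_height`` if
    given); each tree's final breast height uses its own fitted ground.
    Per-tree failures set flags, they never abort the plot.
    """
    scanner_config = scanner_config or ScannerConfig()
    cluster_params = cluster_params or ClusterParams.from_scanner(scanner_config)
    cloud = data if isinstance(data, PointCloud) else build_cloud(data, scanner_config)

    if scanner_height is not None:
        z_ground = -scanner_height
    else:
        z_ground = float(np.percentile(cloud.z, 1.0))
    slice_center = z_ground + BREAST_HEIGHT
    candidates = detect_trunks(
        cloud,
        cluster_params,
        scanner_config,
        slice_center_z=slice_center,
        half_thickness=half_thickness,
        fit_method=fit_method,
    )
    accepted = _dedup_candidates(
        [c for c in candidates if c.status == "accepted"], dedup_distance
    )
    logger.info(
        "process_plot: %d points, %d candidates, %d accepted trunks",
        len(cloud),
        len(candidates),
        len(accepted),
    )

    records: list[TreeRecord] = []
    for tid, cand in enumerate(accepted):
        flags: list[str] = []
        cx, cy = cand.circle.xc, cand.circle.yc
        dbh_cm = None
        height = None
        p_zero = None
        p_top = None
        incl = None
        rms = None
        n_fit = cand.n_points

        # --- local ground plane
        plane = None
        try:
            gneigh = extract_cylinder(cloud, (cx, cy), diameter=ground_cylinder_diameter)
            if len(gneigh) < 3:
                raise NoGroundError("too few points near the trunk base")
            slab = extract_ground_slab(gneigh, thickness=slab_thickness)
            plane = fit_plane_ransac(
                slab,
                inlier_tol=ransac_tol,
                max_iters=ransac_iters,
                seed=seed + tid,
            )
            incl = plane.inclination_deg
            if incl > STEEP_GROUND_FLAG_DEG:
                flags.append("steep_ground")
            p_zero = project_zero_point(plane, (cx, cy))
        except NoGroundError as exc:
            flags.append("no_ground")
            logger.warning("tree %d: %s", tid, exc)

        # --- DBH re-slice at the confirmed breast height
        if p_zero is not None:
            try:
                dbh_cm, circle = estimate_dbh(
                    cloud,
                    p_zero,
                    half_thickness=half_thickness,
                    fit_method=fit_method,
                    cylinder_diameter=tree_cylinder_diameter,
                    min_points=min_dbh_points,
                )
                # the plausibility gate applies to the re-slice fit too: an
                # occluded arc can fit an absurd diameter
                if (
                    cluster_params.dbh_min * 100.0
                    <= dbh_cm
                    <= cluster_params.dbh_max * 100.0
                ):
                    cx, cy = circle.xc, circle.yc
                    rms = circle.rms_residual
                    n_fit = circle.n_points
                    p_zero = project_zero_point(plane, (cx, cy))
                else:
                    flags.append("reslice_out_of_range")
                    dbh_cm = cand.circle.diameter * 100.0
                    rms = cand.circle.rms_residual
            except DegenerateFitError as exc:
                flags.append("no_dbh")
                dbh_cm = cand.circle.diameter * 100.0  # fall back to detection fit
                rms = cand.circle.rms_residual
                logger.warning("tree %d: %s", tid, exc)

        # --- top filter and height
        if p_zero is not None:
            tneigh = extract_cylinder(cloud, (cx, cy), diameter=tree_cylinder_diameter)
            above = tneigh.points.select(tneigh.points.z > p_zero[2] + BREAST_HEIGHT)
            if len(above) == 0:
                flags.append("no_height")
            else:
                state = extract_top(above)
                knn_mean_distances(state)
                _, _, p_top = filter_top(state)
                height, hflags = estimate_height(p_top, p_zero)
                flags.extend(hflags)

        records.append(
            TreeRecord(
                tree_id=tid,
                x=float(cx),
                y=float(cy),
                dbh_cm=None if dbh_cm is None else float(dbh_cm),
                height_m=height,
                p_zero=p_zero,
                p_top=p_top,
                ground_inclination_deg=incl,
                fit_rms_m=rms,
                n_fit_points=n_fit,
                cluster_id=cand.cluster_id,
                flags=flags,
            )
        )
    return records


def tree_records_to_dataframe(records: list[TreeRecord]) -> pd.DataFrame:
    """Principal output table (positions to cm, DBH to 0.01 cm)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.tree_id,
                "x_m": round(r.x, 2),
                "y_m": round(r.y, 2),
                "dbh_cm": np.nan if r.dbh_cm is None else round(r.dbh_cm, 2),
                "height_m": np.nan if r.height_m is None else round(r.height_m, 2),
                "ground_inclination_deg": (
                    np.nan
                    if r.ground_inclination_deg is None
                    else round(r.ground_inclination_deg, 2)
                ),
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "x_m", "y_m", "dbh_cm", "height_m", "ground_inclination_deg", "flags"],
    )
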