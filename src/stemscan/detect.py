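"""Trunk detection in a single-scan cloud.

The detector slices a thin horizontal transect at breast height, clusters
it with an adaptive threshold derived from the scanner's angular steps, and
validates each cluster by fitting a circle and gating on the fitted
diameter.

The clustering rule follows the instrument geometry: two returns that are
angularly adjacent on the lattice sit about ``d = sqrt(Ra^2 + Rb^2 -
2 Ra Rb cos(step))`` apart, so two transect points are linked when their
planar distance is below ``k * max(d_horizontal, d_vertical)`` evaluated at
their mean range (``k = 1.5``).  Connected components of that relation are
the candidate trunks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .circlefit import CircleModel, fit_gauss_newton, fit_pratt, fit_taubin
from .errors import DegenerateFitError
from .geometry import PointCloud, ScannerConfig, adjacent_distance

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "TransectSlice",
    "TrunkCandidate",
    "slice_transect",
    "cluster_threshold",
    "cluster_transect",
    "detect_trunks",
]

_FITTERS = {"pratt": fit_pratt, "taubin": fit_taubin, "gauss-newton": fit_gauss_newton}


@dataclass
class ClusterParams:
    """Clustering and validation parameters for trunk detection.

    ``k`` scales the expected adjacent-point spacing into the linking
    threshold (1.5 works well in practice).  ``dbh_min``/``dbh_max`` are the
    plot's rough visual limits on stem diameter; fits outside them are
    rejected as outlier-driven.  An optional RMS-residual gate (off by
    default) additionally rejects fits whose residual exceeds
    ``max_rms_residual``.
    """

    k: float = 1.5
    delta_theta: float = 0.1667
    delta_phi: float = 0.1
    min_cluster_size: int = 10
    dbh_min: float = 0.05
    dbh_max: float = 0.30
    max_rms_residual: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not self.dbh_min < self.dbh_max:
            raise ValueError("need dbh_min < dbh_max")

    @classmethod
    def from_scanner(cls, config: ScannerConfig, **kw) -> "ClusterParams":
        return cls(delta_theta=config.delta_theta, delta_phi=config.delta_phi, **kw)


@dataclass
class TransectSlice:
    """Points of the cloud within ``|z - center| <= half_thickness``."""

    cloud: PointCloud
    slice_center_z: float
    half_thickness: float

    def __len__(self) -> int:
        return len(self.cloud)


@dataclass
class TrunkCandidate:
    """One clustered candidate with its fit and audit status."""

    cluster_id: int
    indices: np.ndarray
    circle: CircleModel | None
    status: str  # accepted | rejected_diameter | rejected_size | rejected_degenerate

    @property
    def n_points(self) -> int:
        return len(self.indices)


def slice_transect(
    cloud: PointCloud, center_z: float = 1.3, half_thickness: float = 0.05
) -> TransectSlice:
    """Cut the horizontal transect ``|z - center_z| <= half_thickness``.

    An empty result is a valid (empty) slice: downstream then reports zero
    trees rather than failing.
    """
    if half_thickness <= 0:
        raise ValueError("half_thickness must be positive")
    mask = np.abs(cloud.z - center_z) <= half_thickness
    return TransectSlice(
        cloud=cloud.select(mask),
        slice_center_z=center_z,
        half_thickness=half_thickness,
    )


def cluster_threshold(d_ab: float, d_ac: float, k: float = 1.5):
    """Adaptive linking threshold: ``k * max(d_ab, d_ac)``."""
    d_ab = np.asarray(d_ab, float)
    d_ac = np.asarray(d_ac, float)
    if np.any(d_ab < 0) or np.any(d_ac < 0):
        raise ValueError("distances must be non-negative")
    return k * np.maximum(d_ab, d_ac)


def cluster_transect(slc: TransectSlice, params: ClusterParams) -> list[np.ndarray]:
    """Single-linkage clustering under the adaptive angular threshold.

    For a candidate pair the expected adjacent spacings are evaluated at the
    mean of the two ranges, giving a per-pair threshold; linked pairs form a
    graph whose connected components are the clusters.  Components smaller
    than ``min_cluster_size`` are discarded.  Returns index arrays into the
    slice, sorted by size (largest first).
    """
    cloud = slc.cloud
    n = len(cloud)
    if n == 0:
        return []
    if cloud.range_r is None:
        raise ValueError("clustering needs (R, theta, phi) back-references")
    xy = cloud.xyz[:, :2]
    r = cloud.range_r
    # search radius: threshold at the largest range present in the slice
    r_max = float(r.max())
    d_h = adjacent_distance(r_max, r_max, params.delta_phi)
    d_v = adjacent_distance(r_max, r_max, params.delta_theta)
    search = float(cluster_threshold(d_h, d_v, params.k))
    tree = cKDTree(xy)
    pairs = tree.query_pairs(search, output_type="ndarray")
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        rm = 0.5 * (r[i] + r[j])
        thr = cluster_threshold(
            adjacent_distance(rm, rm, params.delta_phi),
            adjacent_distance(rm, rm, params.delta_theta),
            params.k,
        )
        dist = np.linalg.norm(xy[i] - xy[j], axis=1)
        keep = dist < thr
        i, j = i[keep], j[keep]
    else:
        i = j = np.zeros(0, dtype=int)
    graph = scipy.sparse.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    clusters = [np.nonzero(comp == c)[0] for c in range(n_comp)]
    clusters = [c for c in clusters if len(c) >= params.min_cluster_size]
    clusters.sort(key=len, reverse=True)
    logger.info(
        "cluster_transect: %d slice points -> %d clusters (>= %d points)",
        n,
        len(clusters),
        params.min_cluster_size,
    )
    return clusters


def detect_trunks(
    cloud: PointCloud,
    params: ClusterParams,
    scanner_config: ScannerConfig | None = None,
    slice_center_z: float = 1.3,
    half_thickness: float = 0.05,
    fit_method: str = "pratt",
) -> list[TrunkCandidate]:
    """Detect candidate trunks: slice, cluster, fit, gate on diameter.

    Every cluster is returned with an audit status; only ``accepted``
    candidates carry a diameter inside ``[dbh_min, dbh_max]``.  A fit on a
    short arc typically yields an implausibly large diameter and is
    rejected rather than reported.
    """
    if scanner_config is not None:
        params = ClusterParams(
            k=params.k,
            delta_theta=scanner_config.delta_theta,
            delta_phi=scanner_config.delta_phi,
            min_cluster_size=params.min_cluster_size,
            dbh_min=params.dbh_min,
            dbh_max=params.dbh_max,
            max_rms_residual=params.max_rms_residual,
        )
    fitter = _FITTERS[fit_method]
    slc = slice_transect(cloud, center_z=slice_center_z, half_thickness=half_thickness)
    clusters = cluster_transect(slc, params)
    candidates: list[TrunkCandidate] = []
    for cid, idx in enumerate(clusters):
        pts = slc.cloud.xyz[idx][:, :2]
        try:
            circle = fitter(pts)
        except DegenerateFitError:
            candidates.append(TrunkCandidate(cid, idx, None, "rejected_degenerate"))
            continue
        if not params.dbh_min <= circle.diameter <= params.dbh_max:
            status = "rejected_diameter"
        elif (
            params.max_rms_residual is not None
            and circle.rms_residual > params.max_rms_residual
        ):
            status = "rejected_residual"
        else:
            status = "accepted"
        candidates.append(TrunkCandidate(cid, idx, circle, status))
    n_acc = sum(1 for c in candidates if c.status == "accepted")
    logger.info("detect_trunks: %d candidates, %d accepted", len(candidates), n_acc)
    return candidates


def candidates_to_dataframe(candidates: list[TrunkCandidate]) -> pd.DataFrame:
    """Audit report: one row per candidate cluster."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "n_points": c.n_points,
                "center_x": np.nan if c.circle is None else c.circle.xc,
                "center_y": np.nan if c.circle is None else c.circle.yc,
                "diameter_m": np.nan if c.circle is None else c.circle.diameter,
                "status": c.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_points", "center_x", "center_y", "diameter_m", "status"],
    )
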