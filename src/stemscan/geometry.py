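"""Scan geometry: polar returns, Cartesian clouds, cylindrical maps.

A rotating 2-D laser profiler records, for every emitted pulse that returns,
a slant range ``R`` (m), an intensity ``I``, a vertical angle ``theta`` and a
horizontal angle ``phi`` (degrees).  This module converts such records into
3-D point clouds with the scanner at the origin, projects them onto the
scanner's angular lattice as range/intensity maps, and provides the
small geometric utilities (expected spacing between angularly adjacent
returns, beam footprint, vertical point spacing) that the trunk detector and
the documentation of instrument resolution rely on.

Conventions
-----------
* Right-handed axes, ``z`` up, ``x`` toward ``phi = 0``.
* ``theta`` is the signed elevation above the horizontal plane; the default
  instrument lattice spans (-90, 90) degrees, which together with the full
  360-degree rotation covers the sphere (the physical sensor sweeps a 190
  degree fan mounted symmetric about the horizon).
* Degrees at every API boundary, radians internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCloudError

logger = logging.getLogger(__name__)

__all__ = [
    "ScannerConfig",
    "ScanRecords",
    "PointCloud",
    "CylindricalMap",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "build_cloud",
    "build_map",
    "adjacent_distance",
    "resolution_metrics",
]

#: Angular step widths (degrees) the emulated sensor can be preset to.
SUPPORTED_STEP_WIDTHS = (0.1667, 0.167, 0.25, 0.333, 0.5, 0.667, 1.0)


@dataclass(frozen=True)
class ScannerConfig:
    """Instrument description used by the converter, mapper and simulator.

    Defaults emulate a low-cost 2-D profiler (0.7-80 m range, +/-12 mm range
    accuracy, 4.7 mrad beam divergence in high-resolution mode) rotated by a
    stepper motor at one degree per second.

    Parameters
    ----------
    delta_theta, delta_phi
        Vertical / horizontal angular step widths in degrees.
    fov_theta
        Elevation interval covered by the vertical fan, degrees.
    rotation_speed
        Horizontal rotation speed, degrees per second (documentation only;
        the horizontal step is exposed directly as ``delta_phi``).
    range_accuracy_sigma
        1-sigma Gaussian range noise in metres.
    range_min, range_max
        Valid measurement distance window in metres.
    beam_divergence_mrad
        Full beam divergence in milliradians.
    """

    delta_theta: float = 0.1667
    delta_phi: float = 0.1
    fov_theta: tuple[float, float] = (-90.0, 90.0)
    rotation_speed: float = 1.0
    range_accuracy_sigma: float = 0.012
    range_min: float = 0.7
    range_max: float = 80.0
    beam_divergence_mrad: float = 4.7

    def __post_init__(self) -> None:
        if self.delta_theta <= 0 or self.delta_phi <= 0:
            raise ValueError("angular step widths must be positive")
        if not (self.fov_theta[0] < self.fov_theta[1]):
            raise ValueError("fov_theta must be an increasing interval")
        if not (0 < self.range_min < self.range_max):
            raise ValueError("need 0 < range_min < range_max")

    @property
    def n_theta(self) -> int:
        span = self.fov_theta[1] - self.fov_theta[0]
        return int(round(span / self.delta_theta))

    @property
    def n_phi(self) -> int:
        return int(round(360.0 / self.delta_phi))

    def theta_centers(self) -> np.ndarray:
        """Lattice elevations: ``fov[0] + (i + 1/2) * delta_theta``."""
        i = np.arange(self.n_theta)
        return self.fov_theta[0] + (i + 0.5) * self.delta_theta

    def phi_centers(self) -> np.ndarray:
        return np.arange(self.n_phi) * self.delta_phi


@dataclass
class ScanRecords:
    """Column-oriented container of raw polar returns.

    One entry per laser return: ``(range_r, intensity, theta, phi)``.
    ``label`` is an optional per-return provenance code attached by the
    simulator (ground / stem index / crown); field data carries none.
    """

    range_r: np.ndarray
    intensity: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.range_r = np.asarray(self.range_r, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.range_r)
        for name in ("intensity", "theta", "phi"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if self.label is not None and len(self.label) != n:
            raise ValueError("label length mismatch")

    def __len__(self) -> int:
        return len(self.range_r)

    def valid_mask(self, config: ScannerConfig) -> np.ndarray:
        """Returns that are finite, inside the range window and the FOV.

        Out-of-window records are dropped (not clamped) downstream.
        """
        finite = (
            np.isfinite(self.range_r)
            & np.isfinite(self.theta)
            & np.isfinite(self.phi)
        )
        in_range = (self.range_r >= config.range_min) & (
            self.range_r <= config.range_max
        )
        lo, hi = config.fov_theta
        in_fov = (self.theta >= lo) & (self.theta <= hi)
        return finite & in_range & in_fov

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phi_deg": self.phi,
                "theta_deg": self.theta,
                "range_m": self.range_r,
                "intensity": self.intensity,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ScanRecords":
        return cls(
            range_r=df["range_m"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            theta=df["theta_deg"].to_numpy(float),
            phi=df["phi_deg"].to_numpy(float),
        )


@dataclass
class PointCloud:
    """Cartesian points with the scanner at the origin.

    ``theta``, ``phi``, ``range_r`` are per-point back-references to the
    polar record each point came from; the trunk-detection clustering rule
    needs them.
    """

    xyz: np.ndarray
    intensity: np.ndarray | None = None
    theta: np.ndarray | None = None
    phi: np.ndarray | None = None
    range_r: np.ndarray | None = None
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def select(self, idx) -> "PointCloud":
        """Subset cloud by a boolean mask or index array, keeping back-refs."""

        def take(a):
            return None if a is None else a[idx]

        return PointCloud(
            xyz=self.xyz[idx],
            intensity=take(self.intensity),
            theta=take(self.theta),
            phi=take(self.phi),
            range_r=take(self.range_r),
            label=take(self.label),
        )


@dataclass
class CylindricalMap:
    """Range or intensity values on the (theta, phi) lattice.

    ``values[i, j]`` holds the value of the return at lattice direction
    ``(theta_centers[i], phi_centers[j])``; cells with no return hold NaN.
    """

    values: np.ndarray
    theta_centers: np.ndarray
    phi_centers: np.ndarray
    kind: str = "range"
    fill: float = field(default=float("nan"))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def filled_cells(self) -> int:
        return int(np.count_nonzero(np.isfinite(self.values)))


def polar_to_cartesian(range_r, theta_deg, phi_deg) -> np.ndarray:
    """Convert slant range and angles to Cartesian coordinates.

    ``x = R cos(theta) cos(phi)``, ``y = R cos(theta) sin(phi)``,
    ``z = R sin(theta)`` -- the signed-trigonometric form, valid in every
    quadrant and for overhead elevations.  Scalars in, shape-(3,) out;
    arrays broadcast to ``(..., 3)``.
    """
    r = np.asarray(range_r, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    ph = np.deg2rad(np.asarray(phi_deg, dtype=float))
    x = r * np.cos(th) * np.cos(ph)
    y = r * np.cos(th) * np.sin(ph)
    z = r * np.sin(th)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)

def cartesian_to_polar(xyz) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`polar_to_cartesian`.

    Returns ``(range, theta_deg, phi_deg)`` with theta in [-90, 90] and phi
    in [0, 360).
    """
    p = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(p, axis=-1)
    with np.errstate(invalid="ignore"):
        theta = np.rad2deg(np.arcsin(np.clip(p[..., 2] / np.where(r == 0, 1, r), -1, 1)))
    phi = np.rad2deg(np.arctan2(p[..., 1], p[..., 0])) % 360.0
    return r, theta, phi


def build_cloud(records: ScanRecords, config: ScannerConfig) -> PointCloud:
    """Convert validated records into a point cloud (scanner at origin).

    Invalid returns (non-finite, outside the range window or the FOV) are
    dropped; one point per surviving record.  Raises
    :class:`~stemscan.errors.EmptyCloudError` when nothing survives.
    """
    if len(records) == 0:
        raise EmptyCloudError("no records supplied")
    mask = records.valid_mask(config)
    n_valid = int(mask.sum())
    logger.info("build_cloud: %d records, %d valid", len(records), n_valid)
    if n_valid == 0:
        raise EmptyCloudError("all records invalid or out of range")
    r = records.range_r[mask]
    th = records.theta[mask]
    ph = records.phi[mask]
    xyz = polar_to_cartesian(r, th, ph)
    return PointCloud(
        xyz=xyz,
        intensity=records.intensity[mask],
        theta=th,
        phi=ph,
        range_r=r,
        label=None if records.label is None else records.label[mask],
    )


def build_map(
    records: ScanRecords, config: ScannerConfig, value_kind: str = "range"
) -> CylindricalMap:
    """Project records onto the angular lattice as a range or intensity map.

    Each valid record fills the cell of its ``(theta, phi)`` direction.  When
    two records land in one cell the nearer return wins (a warning is
    logged); cells with no return hold NaN.
    """
    if value_kind not in ("range", "intensity"):
        raise ValueError("value_kind must be 'range' or 'intensity'")
    nt, nph = config.n_theta, config.n_phi
    grid = np.full((nt, nph), np.nan)
    best_range = np.full((nt, nph), np.inf)
    if len(records):
        mask = records.valid_mask(config)
        th = records.theta[mask]
        ph = records.phi[mask]
        rr = records.range_r[mask]
        vals = rr if value_kind == "range" else records.intensity[mask]
        i = np.clip(
            np.round((th - config.fov_theta[0]) / config.delta_theta - 0.5).astype(int),
            0,
            nt - 1,
        )
        j = np.round(ph / config.delta_phi).astype(int) % nph
        # nearest-range conflict resolution: process in decreasing range so
        # the nearest return is written last
        order = np.argsort(-rr)
        i, j, rr, vals = i[order], j[order], rr[order], vals[order]
        flat = i * nph + j
        n_dup = len(flat) - len(np.unique(flat))
        if n_dup:
            logger.warning("build_map: %d duplicate-cell records, keeping nearest", n_dup)
        grid.ravel()[flat] = vals
        best_range.ravel()[flat] = rr
    return CylindricalMap(
        values=grid,
        theta_centers=config.theta_centers(),
        phi_centers=config.phi_centers(),
        kind=value_kind,
    )


def adjacent_distance(r_a, r_b, delta_angle_deg):
    """Euclidean distance between two returns one angular step apart.

    Law of cosines on the triangle (scanner, A, B):
    ``sqrt(Ra^2 + Rb^2 - 2 Ra Rb cos(delta))``.  Symmetric in the two
    ranges and never below ``|Ra - Rb|``.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if np.any(r_a <= 0) or np.any(r_b <= 0):
        raise ValueError("ranges must be positive")
    d = np.deg2rad(delta_angle_deg)
    sq = r_a**2 + r_b**2 - 2.0 * r_a * r_b * np.cos(d)
    return np.sqrt(np.maximum(sq, 0.0))


def resolution_metrics(config: ScannerConfig, distance: float) -> dict:
    """Beam footprint and vertical point spacing at a given distance.

    ``footprint = divergence(rad) * distance`` (e.g. 4.7 mrad -> 4.7 cm at
    10 m); ``vertical_spacing = distance * tan(delta_theta)`` (about 3 cm at
    10 m for a 0.1667-degree step).
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return {
        "footprint": config.beam_divergence_mrad * 1e-3 * distance,
        "vertical_spacing": distance * np.tan(np.deg2rad(config.delta_theta)),
    }
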