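"""Synthetic single-scan plantation plots with known ground truth.

The simulator emulates a tripod-mounted rotating profiler scanning a small
plantation plot: stems on a rectangular planting grid (with vacancies where
trees died and were removed), stem diameters and heights drawn from the
plantation's distributions, a flat / tilted / undulating ground surface, and
sparse branch elements near each tree top.  For every direction on the
instrument's angular lattice a ray is cast from the scanner and the nearest
scene intersection is recorded (first-return, so occlusion/shadowing arises
by construction), Gaussian range noise is added, and returns outside the
instrument's measurement window are dropped.

Every intersection is an exact geometric solution (quadratics for stem
frustums and branch spheres, closed form for planes), so the simulator
doubles as an analytic oracle for the reconstruction pipeline.

Scene frame: ground nominally at z = 0, scanner at ``scanner_pos`` (default
1.5 m above ground).  Emitted records are polar coordinates *relative to
the scanner*, and the ground-truth table is expressed in the scanner-centred
frame so estimates and truth compare directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScannerConfig, ScanRecords

__all__ = [
    "StemModel",
    "GroundModel",
    "SyntheticPlot",
    "generate_plot",
    "simulate_scan",
    "reference_table",
    "plantation_campaign",
]

# per-return provenance codes
LABEL_GROUND = 0
LABEL_STEM = 1
LABEL_CROWN = 2

#: breast height above local ground (m) at which reference DBH is defined
BREAST_HEIGHT = 1.3


@dataclass
class StemModel:
    """One tree: a vertical, linearly tapered frustum plus a sparse crown.

    ``dbh`` is the diameter at breast height (1.3 m above the local
    ground); the frustum radius decays linearly from the base so that the
    radius at breast height matches ``dbh / 2`` and the radius at the tip is
    ``(1 - taper)`` times the base radius.  ``lean`` is reserved; only
    vertical stems (lean = 0) are simulated.
    """

    x: float
    y: float
    dbh: float
    height: float
    taper: float = 0.7
    lean: float = 0.0

    def __post_init__(self) -> None:
        if self.dbh <= 0 or self.height <= 0:
            raise ValueError("dbh and height must be positive")
        if not (0 <= self.taper < 1):
            raise ValueError("taper must be in [0, 1)")
        if self.lean != 0.0:
            raise NotImplementedError("only vertical stems (lean = 0) are simulated")

    @property
    def base_radius(self) -> float:
        # r(h) = r0 * (1 - taper * h / height); solve r(1.3) = dbh/2
        shrink = 1.0 - self.taper * min(BREAST_HEIGHT, self.height) / self.height
        return 0.5 * self.dbh / shrink

    def radius_at(self, h: float) -> float:
        """Stem radius at height ``h`` above its base."""
        return self.base_radius * (1.0 - self.taper * h / self.height)


@dataclass
class GroundModel:
    """Ground surface: flat, tilted plane, or sinusoidal undulation.

    ``z(x, y) = z0 + slope_x * x + slope_y * y`` for kind ``"tilted"``;
    ``"undulating"`` adds ``amplitude * sin(2 pi x / wavelength)``.
    """

    kind: str = "flat"
    z0: float = 0.0
    slope_x: float = 0.0
    slope_y: float = 0.0
    amplitude: float = 0.0
    wavelength: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "tilted", "undulating"):
            raise ValueError(f"unknown ground kind {self.kind!r}")
        if self.kind == "undulating" and self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @classmethod
    def tilted(cls, inclination_deg: float, azimuth_deg: float = 0.0, z0: float = 0.0):
        """Plane tilted by ``inclination_deg`` with its upslope direction at
        ``azimuth_deg``."""
        s = np.tan(np.deg2rad(inclination_deg))
        a = np.deg2rad(azimuth_deg)
        return cls(kind="tilted", z0=z0, slope_x=s * np.cos(a), slope_y=s * np.sin(a))

    def height(self, x, y):
        z = self.z0 + self.slope_x * np.asarray(x, float) + self.slope_y * np.asarray(y, float)
        if self.kind == "undulating":
            z = z + self.amplitude * np.sin(2.0 * np.pi * np.asarray(x, float) / self.wavelength)
        return z

    @property
    def inclination_deg(self) -> float:
        """Inclination of the planar part, degrees from horizontal."""
        return float(np.rad2deg(np.arctan(np.hypot(self.slope_x, self.slope_y))))


@dataclass
class SyntheticPlot:
    """A generated plot: stems, ground, crown parameters and its seed."""

    extent: float
    stems: list[StemModel]
    ground: GroundModel
    crown_elements_per_tree: int = 60
    crown_fraction: float = 0.15
    crown_radius_range: tuple[float, float] = (0.02, 0.04)
    crown_spread_sd: float = 0.3
    seed: int = 0
    # private: crown spheres, built lazily per scan seed is NOT desired --
    # crowns belong to the scene, so they are drawn at generation time
    crown_spheres: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    crown_tree_index: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


def generate_plot(
    extent: float = 10.0,
    spacing_ns: float = 1.6,
    spacing_we: float = 2.8,
    vacancy_prob: float = 0.05,
    dbh_mean: float = 0.1211,
    dbh_sd: float = 0.0237,
    height_mean: float = 8.43,
    height_sd: float = 0.78,
    position_jitter_sd: float = 0.15,
    taper: float = 0.7,
    ground: GroundModel | None = None,
    crown_elements_per_tree: int = 60,
    seed: int = 0,
) -> SyntheticPlot:
    """Generate a plantation plot on a rectangular planting grid.

    Stems sit at the nodes of a centred grid with north-south spacing
    ``spacing_ns`` (rows along y) and west-east spacing ``spacing_we``
    (columns along x): ``floor(extent / spacing)`` nodes per direction.
    Each node is vacant with probability ``vacancy_prob`` (dead trees were
    removed from the plantation); per-node attribute draws are made for
    every node regardless of vacancy, so the same seed yields nested stem
    sets as the vacancy probability grows.  DBH and height are drawn from
    the plantation's normal distributions truncated at zero; plan positions
    get Gaussian jitter matching the scatter of surveyed stem maps.
    """
    if spacing_ns <= 0 or spacing_we <= 0:
        raise ValueError("spacings must be positive")
    if not 0 <= vacancy_prob <= 1:
        raise ValueError("vacancy_prob must be a probability")
    n_ns = int(extent // spacing_ns)
    n_we = int(extent // spacing_we)
    if n_ns < 1 or n_we < 1:
        raise ValueError("extent smaller than one grid cell")
    ground = ground or GroundModel()
    rng = np.random.default_rng(seed)
    ys = (np.arange(n_ns) - (n_ns - 1) / 2.0) * spacing_ns
    xs = (np.arange(n_we) - (n_we - 1) / 2.0) * spacing_we
    stems: list[StemModel] = []
    half = extent / 2.0
    for gx in xs:
        for gy in ys:
            # one fixed-length draw block per node -> vacancy-monotone seeds
            u = rng.uniform()
            jx, jy = rng.normal(0.0, position_jitter_sd, size=2)
            dbh = rng.normal(dbh_mean, dbh_sd)
            h = rng.normal(height_mean, height_sd)
            while dbh <= 0.01:
                dbh = rng.normal(dbh_mean, dbh_sd)
            while h <= 0.5:
                h = rng.normal(height_mean, height_sd)
            if u < vacancy_prob:
                continue
            x = float(np.clip(gx + jx, -half, half))
            y = float(np.clip(gy + jy, -half, half))
            stems.append(StemModel(x=x, y=y, dbh=float(dbh), height=float(h), taper=taper))
    plot = SyntheticPlot(
        extent=extent,
        stems=stems,
        ground=ground,
        crown_elements_per_tree=crown_elements_per_tree,
        seed=seed,
    )
    _grow_crowns(plot, rng)
    return plot


def _grow_crowns(plot: SyntheticPlot, rng: np.random.Generator) -> None:
    """Scatter branch spheres in the top fraction of each stem.

    Centres stay at or below the stem tip so the crown never raises the
    true tree top.
    """
    spheres = []
    tree_idx = []
    lo_r, hi_r = plot.crown_radius_range
    for k, s in enumerate(plot.stems):
        zg = float(plot.ground.height(s.x, s.y))
        n = plot.crown_elements_per_tree
        if n == 0:
            continue
        h = rng.uniform((1.0 - plot.crown_fraction) * s.height, s.height, size=n)
        az = rng.uniform(0, 2 * np.pi, size=n)
        rad = np.abs(rng.normal(0.0, plot.crown_spread_sd, size=n))
        # branches thin toward the very top
        rad *= 1.0 - 0.7 * (h - (1 - plot.crown_fraction) * s.height) / (
            plot.crown_fraction * s.height
        )
        r_el = rng.uniform(lo_r, hi_r, size=n)
        cx = s.x + rad * np.cos(az)
        cy = s.y + rad * np.sin(az)
        cz = np.minimum(zg + h, zg + s.height - r_el)
        spheres.append(np.column_stack([cx, cy, cz, r_el]))
        tree_idx.extend([k] * n)
    if spheres:
        plot.crown_spheres = np.vstack(spheres)
        plot.crown_tree_index = np.asarray(tree_idx, int)


def reference_table(plot: SyntheticPlot, scanner_pos=(0.0, 0.0, 1.5)) -> pd.DataFrame:
    """Ground-truth table, the synthetic stand-in for tape measurements.

    Columns: ``tree_id, x_m, y_m, dbh_cm, height_m`` with plan positions in
    the scanner-centred frame (scanner plan position subtracted).
    """
    sx, sy = scanner_pos[0], scanner_pos[1]
    rows = [
        {
            "tree_id": i,
            "x_m": s.x - sx,
            "y_m": s.y - sy,
            "dbh_cm": s.dbh * 100.0,
            "height_m": s.height,
        }
        for i, s in enumerate(plot.stems)
    ]
    return pd.DataFrame(rows, columns=["tree_id", "x_m", "y_m", "dbh_cm", "height_m"])


# ---------------------------------------------------------------------------
# ray casting


def _ray_plane(origin, dirs, ground: GroundModel):
    """Smallest positive t with origin + t*dirs on the (planar) ground."""
    denom = dirs[:, 2] - ground.slope_x * dirs[:, 0] - ground.slope_y * dirs[:, 1]
    numer = ground.z0 + ground.slope_x * origin[0] + ground.slope_y * origin[1] - origin[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numer / denom
    t[~np.isfinite(t) | (t <= 0)] = np.inf
    return t


def _ray_undulating(origin, dirs, ground: GroundModel, t_max: float = 90.0):
    """Ray-marching intersection with an undulating surface.

    Coarse forward march (step = wavelength / 24) to bracket the first
    sign change of ``z_ray - z_ground``, then bisection refinement.  Used
    only for ``kind == "undulating"``; planar grounds use the closed form.
    """
    step = ground.wavelength / 24.0
    n_steps = int(t_max / step)
    t_hit = np.full(dirs.shape[0], np.inf)
    active = np.arange(dirs.shape[0])
    prev_t = np.full(dirs.shape[0], 1e-6)
    p = origin[None, :] + prev_t[:, None] * dirs
    prev_f = p[:, 2] - ground.height(p[:, 0], p[:, 1])
    for i in range(1, n_steps + 1):
        if active.size == 0:
            break
        t = np.full(active.size, i * step)
        p = origin[None, :] + t[:, None] * dirs[active]
        f = p[:, 2] - ground.height(p[:, 0], p[:, 1])
        crossed = (prev_f[active] > 0) & (f <= 0)
        if crossed.any():
            idx = active[crossed]
            lo = prev_t[idx].copy()
            hi = t[crossed].copy()
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                pm = origin[None, :] + mid[:, None] * dirs[idx]
                fm = pm[:, 2] - ground.height(pm[:, 0], pm[:, 1])
                hi = np.where(fm <= 0, mid, hi)
                lo = np.where(fm > 0, mid, lo)
            t_hit[idx] = 0.5 * (lo + hi)
        prev_t[active] = t[0] if np.isscalar(t) else t
        prev_f[active] = f
        active = active[~crossed]
    return t_hit


def _ray_frustum(origin, dirs, stem: StemModel, zg: float):
    """Smallest positive t hitting the tapered stem between base and tip.

    The frustum satisfies ``(x-cx)^2 + (y-cy)^2 = r(z)^2`` with ``r`` linear
    in z, giving a quadratic in t.  Roots whose hit height falls outside
    ``[0, height]`` are discarded (end caps are not modelled; top-disk hits
    are a measure-zero grazing case at plantation geometry).
    """
    ox = origin[0] - stem.x
    oy = origin[1] - stem.y
    dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    s = stem.base_radius * stem.taper / stem.height  # dr/dh, >= 0
    u = stem.base_radius - s * (origin[2] - zg)  # r at the ray origin height
    a = dx * dx + dy * dy - s * s * dz * dz
    b = 2.0 * (ox * dx + oy * dy) + 2.0 * u * s * dz
    c = ox * ox + oy * oy - u * u
    disc = b * b - 4.0 * a * c
    t_best = np.full(dirs.shape[0], np.inf)
    ok = (disc >= 0) & (np.abs(a) > 1e-300)
    if not ok.any():
        return t_best
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sign in (-1.0, 1.0):
        t = np.where(ok, (-b + sign * sq) / (2.0 * a), np.inf)
        h = origin[2] + t * dz - zg
        good = ok & (t > 1e-9) & (h >= 0.0) & (h <= stem.height) & (t < t_best)
        t_best = np.where(good, t, t_best)
    return t_best


def _ray_sphere(origin, dirs, center, radius):
    oc = origin - center
    b = 2.0 * dirs @ oc
    c = oc @ oc - radius * radius
    disc = b * b - 4.0 * c
    t = np.full(dirs.shape[0], np.inf)
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-b - sq) / 2.0
    t2 = (-b + sq) / 2.0
    cand = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, np.inf))
    t[ok] = cand[ok]
    return t


def _phi_window(phi_centers_rad, az, half_width):
    """Lattice azimuth indices within +/- half_width of az (wrapping)."""
    d = np.abs((phi_centers_rad - az + np.pi) % (2 * np.pi) - np.pi)
    return np.nonzero(d <= half_width)[0]


def simulate_scan(
    plot: SyntheticPlot,
    scanner_pos=(0.0, 0.0, 1.5),
    config: ScannerConfig | None = None,
    seed: int = 0,
    clip_margin: float = 1.0,
) -> tuple[ScanRecords, pd.DataFrame]:
    """Cast one ray per lattice direction and record first returns.

    Returns ``(records, truth)`` where ``records`` carries polar returns
    relative to ``scanner_pos`` (with per-return provenance labels) and
    ``truth`` is :func:`reference_table` in the scanner frame.  Gaussian
    range noise of ``config.range_accuracy_sigma`` is added and returns
    outside ``[range_min, range_max]`` are dropped.  Ground hits outside the
    plot square (grown by ``clip_margin``) are discarded, emulating the
    plot extraction applied to field scans.
    """
    config = config or ScannerConfig()
    origin = np.asarray(scanner_pos, dtype=float)
    zg_scanner = float(plot.ground.height(origin[0], origin[1]))
    if origin[2] <= zg_scanner:
        raise ValueError("scanner must sit above the local ground")

    theta = np.deg2rad(config.theta_centers())
    phi = np.deg2rad(config.phi_centers())
    nt, nph = theta.size, phi.size
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    t_min = np.full(nt * nph, np.inf)
    label = np.full(nt * nph, -1, dtype=np.int16)
    tree_of = np.full(nt * nph, -1, dtype=np.int32)
    cos_inc = np.zeros(nt * nph)

    def dirs_for(rows, cols):
        """Unit directions for the lattice submatrix rows x cols, flattened."""
        ct = cos_t[rows][:, None]
        st = sin_t[rows][:, None]
        return np.stack(
            [
                (ct * cos_p[cols][None, :]).ravel(),
                (ct * sin_p[cols][None, :]).ravel(),
                np.broadcast_to(st, (rows.size, cols.size)).ravel(),
            ],
            axis=1,
        )

    def update(flat_idx, t_new, lab, tree, cos_i):
        better = t_new < t_min[flat_idx]
        idx = flat_idx[better]
        t_min[idx] = t_new[better]
        label[idx] = lab
        tree_of[idx] = tree if np.isscalar(tree) else tree[better]
        cos_inc[idx] = cos_i[better]

    all_rows = np.arange(nt)
    all_cols = np.arange(nph)

    # --- ground: all downward-capable rays in one vectorized pass
    dirs = dirs_for(all_rows, all_cols)
    if plot.ground.kind == "undulating":
        down = dirs[:, 2] < 0.3  # undulation can rise above the horizon
        t_g = np.full(dirs.shape[0], np.inf)
        t_g[down] = _ray_undulating(origin, dirs[down], plot.ground)
    else:
        t_g = _ray_plane(origin, dirs, plot.ground)
    finite = np.isfinite(t_g)
    half = plot.extent / 2.0 + clip_margin
    if finite.any():
        hit = origin[None, :] + t_g[finite, None] * dirs[finite]
        inside = (np.abs(hit[:, 0]) <= half) & (np.abs(hit[:, 1]) <= half)
        idx = np.nonzero(finite)[0][inside]
        hit = hit[inside]
        if plot.ground.kind == "undulating":
            # normal from the surface gradient at the hit point
            gx = plot.ground.slope_x + plot.ground.amplitude * (
                2 * np.pi / plot.ground.wavelength
            ) * np.cos(2 * np.pi * hit[:, 0] / plot.ground.wavelength)
            gy = np.full(gx.shape, plot.ground.slope_y)
        else:
            gx = np.full(idx.size, plot.ground.slope_x)
            gy = np.full(idx.size, plot.ground.slope_y)
        nrm = np.column_stack([-gx, -gy, np.ones_like(gx)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        ci = np.abs(np.sum(dirs[finite][inside] * nrm, axis=1))
        update(idx, t_g[finite][inside], LABEL_GROUND, -1, ci)
    del dirs

    phi_c = phi  # lattice azimuths in radians

    # --- stems: per-stem azimuth/elevation windows keep this cheap
    for k, s in enumerate(plot.stems):
        rel = np.array([s.x - origin[0], s.y - origin[1]])
        d0 = float(np.hypot(*rel))
        zg = float(plot.ground.height(s.x, s.y))
        r_eff = s.base_radius + 0.02
        if d0 <= r_eff:
            cols = all_cols
            rows = all_rows
        else:
            az = float(np.arctan2(rel[1], rel[0]))
            halfw = float(np.arcsin(min(1.0, r_eff / d0))) + 2 * np.deg2rad(config.delta_phi)
            cols = _phi_window(phi_c, az, halfw)
            d_near = max(d0 - r_eff, 0.05)
            el_lo = np.arctan2(zg - origin[2], d0 + r_eff) - 2 * np.deg2rad(config.delta_theta)
            el_hi = np.arctan2(zg + s.height - origin[2], d_near) + 2 * np.deg2rad(
                config.delta_theta
            )
            rows = np.nonzero((theta >= el_lo) & (theta <= el_hi))[0]
        if rows.size == 0 or cols.size == 0:
            continue
        dirs = dirs_for(rows, cols)
        t = _ray_frustum(origin, dirs, s, zg)
        ok = np.isfinite(t)
        if not ok.any():
            continue
        flat = (rows[:, None] * nph + cols[None, :]).ravel()
        hitp = origin[None, :] + t[ok, None] * dirs[ok]
        radial = hitp[:, :2] - np.array([s.x, s.y])[None, :]
        nr = np.linalg.norm(radial, axis=1)
        nr[nr == 0] = 1.0
        # frustum normal ~ radial for small taper; adequate for intensity
        ci = np.zeros(dirs.shape[0])
        ci[ok] = np.abs(
            np.sum(dirs[ok, :2] * (radial / nr[:, None]), axis=1)
        )
        update(flat[ok], t[ok], LABEL_STEM, k, ci[ok])

    # --- crown spheres
    for sph, k in zip(plot.crown_spheres, plot.crown_tree_index):
        center = sph[:3]
        radius = sph[3]
        rel = center - origin
        d0 = float(np.linalg.norm(rel))
        if d0 <= radius:
            continue
        az = float(np.arctan2(rel[1], rel[0]))
        ang = float(np.arcsin(min(1.0, radius / d0)))
        halfw = ang + 2 * np.deg2rad(config.delta_phi)
        cols = _phi_window(phi_c, az, halfw)
        el = float(np.arcsin(rel[2] / d0))
        el_pad = ang + 2 * np.deg2rad(config.delta_theta)
        rows = np.nonzero((theta >= el - el_pad) & (theta <= el + el_pad))[0]
        if rows.size == 0 or cols.size == 0:
            continue
        dirs = dirs_for(rows, cols)
        t = _ray_sphere(origin, dirs, center, radius)
        ok = np.isfinite(t)
        if not ok.any():
            continue
        flat = (rows[:, None] * nph + cols[None, :]).ravel()
        hitp = origin[None, :] + t[ok, None] * dirs[ok]
        nrm = hitp - center[None, :]
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        ci = np.zeros(dirs.shape[0])
        ci[ok] = np.abs(np.sum(dirs[ok] * nrm, axis=1))
        update(flat[ok], t[ok], LABEL_CROWN, int(k), ci[ok])

    # --- assemble returns
    got = np.isfinite(t_min)
    flat = np.nonzero(got)[0]
    rows, cols = np.divmod(flat, nph)
    ranges = t_min[flat]
    rng = np.random.default_rng(seed)
    if config.range_accuracy_sigma > 0:
        ranges = ranges + rng.normal(0.0, config.range_accuracy_sigma, size=ranges.size)
    keep = (ranges >= config.range_min) & (ranges <= config.range_max)
    records = ScanRecords(
        range_r=ranges[keep],
        intensity=100.0 * cos_inc[flat][keep],
        theta=config.theta_centers()[rows[keep]],
        phi=config.phi_centers()[cols[keep]],
        label=label[flat][keep].astype(int),
    )
    truth = reference_table(plot, scanner_pos=tuple(origin))
    return records, truth


def plantation_campaign(
    n_plots: int = 4,
    seed: int = 0,
    config: ScannerConfig | None = None,
    extent: float = 10.0,
    ground_inclination_deg: float = 3.0,
    vacancy_prob: float = 0.05,
    scanner_height: float = 1.5,
):
    """Simulate a multi-plot single-scan campaign over a plantation.

    One 10 m x 10 m plot per scan, planting grid 1.6 m (N-S) x 2.8 m (W-E),
    DBH ~ N(12.11, 2.37^2) cm, height ~ N(8.43, 0.78^2) m, local ground
    tilted by about 3 degrees (the inclination the ground-fitting stage
    reports on such terrain) with a different aspect per plot.  The scanner
    stands near the plot centre, halfway between planting lines -- field
    practice places it for a good field of view, off the planting lines --
    at ``scanner_height`` above local ground.

    Yields ``(records, truth)`` pairs; all randomness derives from ``seed``.
    """
    config = config or ScannerConfig()
    master = np.random.default_rng(seed)
    out = []
    for p in range(n_plots):
        plot_seed = int(master.integers(0, 2**31 - 1))
        scan_seed = int(master.integers(0, 2**31 - 1))
        ground = GroundModel.tilted(
            ground_inclination_deg, azimuth_deg=p * 90.0 + 30.0
        )
        plot = generate_plot(
            extent=extent,
            vacancy_prob=vacancy_prob,
            ground=ground,
            seed=plot_seed,
        )
        # mid-cell nearest the plot centre: halfway between planting lines
        # in each direction (a centred grid with an odd node count has a
        # line through the centre; an even count already has a cell there)
        sx = 1.4 if int(extent // 2.8) % 2 == 1 else 0.0
        sy = 0.8 if int(extent // 1.6) % 2 == 1 else 0.0
        sz = float(ground.height(sx, sy)) + scanner_height
        records, truth = simulate_scan(
            plot, scanner_pos=(sx, sy, sz), config=config, seed=scan_seed
        )
        out.append((records, truth))
    return out
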