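"""Circle fitting for stem cross-sections.

A circle is written algebraically as ``A(x^2 + y^2) + Bx + Cy + D = 0``.
With the normalization ``B^2 + C^2 - 4AD = 1`` the center is
``(-B/2A, -C/2A)`` and the radius ``1/(2|A|)``.  Writing ``z_i = x_i^2 +
y_i^2``, both algebraic fitters minimize the same quadratic form
``sum_i (A z_i + B x_i + C y_i + D)^2`` and differ only in the constraint:

* Pratt:   ``B^2 + C^2 - 4AD = 1``
* Taubin:  ``4 A^2 zbar + 4AB xbar + 4AC ybar + B^2 + C^2 = 1``

Both reduce to a 4x4 generalized eigenproblem and are exact on noiseless
circular data.  The Gauss-Newton fitter minimizes the geometric objective
``sum_i (dist(p_i, center) - r)^2`` iteratively, with step halving to keep
the objective non-increasing; it is the reference the faster algebraic
fits are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegenerateFitError

__all__ = [
    "CircleModel",
    "fit_pratt",
    "fit_taubin",
    "fit_gauss_newton",
    "circle_params",
]

# relative singular-value threshold below which planar points are treated
# as collinear
_COLLINEAR_TOL = 1e-12


@dataclass
class CircleModel:
    """Fitted circle in both algebraic and geometric form.

    ``(A, B, C, D)`` obey the Pratt normalization ``B^2+C^2-4AD = 1``
    (to rounding), so ``r = 1/(2|A|)`` and ``center = (-B/2A, -C/2A)``.
    ``rms_residual`` is the RMS orthogonal distance of the points to the
    circle; ``converged`` is False only for an iterative fit stopped at
    ``max_iter``.
    """

    xc: float
    yc: float
    r: float
    A: float
    B: float
    C: float
    D: float
    rms_residual: float
    n_points: int
    method: str
    converged: bool = True

    @property
    def center(self) -> tuple[float, float]:
        return (self.xc, self.yc)

    @property
    def diameter(self) -> float:
        return 2.0 * self.r


def circle_params(A: float, B: float, C: float, D: float) -> tuple[tuple[float, float], float]:
    """Center and radius of the algebraic circle ``A(x²+y²)+Bx+Cy+D=0``.

    Raises :class:`~stemscan.errors.DegenerateFitError` for ``A = 0`` (a
    line, not a circle) or a negative discriminant (no real circle).
    """
    if A == 0:
        raise DegenerateFitError("A = 0 describes a line, not a circle")
    disc = B * B + C * C - 4.0 * A * D
    if disc <= 0:
        raise DegenerateFitError("negative discriminant: no real circle")
    center = (-B / (2.0 * A), -C / (2.0 * A))
    radius = float(np.sqrt(disc) / (2.0 * abs(A)))
    return center, radius


def _canonical_abcd(xc: float, yc: float, r: float) -> tuple[float, float, float, float]:
    """Pratt-normalized coefficients of the circle (center, r)."""
    A = 1.0 / (2.0 * r)
    return A, -2.0 * A * xc, -2.0 * A * yc, A * (xc * xc + yc * yc - r * r)


def _check_points(points) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 3:
        raise DegenerateFitError(f"need >= 3 points, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < _COLLINEAR_TOL:
        raise DegenerateFitError("points are collinear (or coincident)")
    return pts, centered


def _rms_residual(pts: np.ndarray, xc: float, yc: float, r: float) -> float:
    d = np.hypot(pts[:, 0] - xc, pts[:, 1] - yc) - r
    return float(np.sqrt(np.mean(d * d)))


def _algebraic_fit(points, constraint: str) -> CircleModel:
    """Shared eigen-solver for the Pratt and Taubin constraints.

    Work in centroid-centered coordinates for conditioning, form
    ``M = Z^T Z`` with rows ``(z_i, x_i, y_i, 1)``, and solve
    ``M a = eta * N a`` where ``N`` is the constraint matrix.  Among real
    eigenpairs normalizable to ``a^T N a = 1`` the one with the smallest
    non-negative objective ``a^T M a`` is the fit.
    """
    pts, c = _check_points(points)
    x, y = c[:, 0], c[:, 1]
    z = x * x + y * y
    Z = np.column_stack([z, x, y, np.ones_like(x)])
    M = Z.T @ Z
    if constraint == "pratt":
        N = np.array(
            [
                [0.0, 0.0, 0.0, -2.0],
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
                [-2.0, 0.0, 0.0, 0.0],
            ]
        )
    else:  # taubin
        zbar, xbar, ybar = z.mean(), x.mean(), y.mean()
        N = np.array(
            [
                [4.0 * zbar, 2.0 * xbar, 2.0 * ybar, 0.0],
                [2.0 * xbar, 1.0, 0.0, 0.0],
                [2.0 * ybar, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
    vals, vecs = scipy.linalg.eig(M, N)
    best = None
    for k in range(len(vals)):
        if not np.isfinite(vals[k]):
            continue
        if abs(vals[k].imag) > 1e-8 * (1.0 + abs(vals[k].real)):
            continue
        a = np.real(vecs[:, k])
        norm = a @ N @ a
        if norm <= 0:
            continue
        a = a / np.sqrt(norm)
        obj = float(a @ M @ a)
        if obj < -1e-9:
            continue
        if best is None or obj < best[0]:
            best = (max(obj, 0.0), a)
    if best is None:
        raise DegenerateFitError(f"{constraint} eigenproblem yielded no valid circle")
    a = best[1]
    try:
        (xc0, yc0), r = circle_params(*a)
    except DegenerateFitError as exc:  # e.g. best solution is a line
        raise DegenerateFitError(f"{constraint} fit degenerate: {exc}") from exc
    mean = pts.mean(axis=0)
    xc, yc = xc0 + mean[0], yc0 + mean[1]
    A, B, C, D = _canonical_abcd(xc, yc, r)
    return CircleModel(
        xc=float(xc),
        yc=float(yc),
        r=float(r),
        A=A,
        B=B,
        C=C,
        D=D,
        rms_residual=_rms_residual(pts, xc, yc, r),
        n_points=pts.shape[0],
        method=constraint,
    )


def fit_pratt(points) -> CircleModel:
    """Pratt algebraic circle fit (constraint ``B²+C²-4AD = 1``)."""
    return _algebraic_fit(points, "pratt")


def fit_taubin(points) -> CircleModel:
    """Taubin algebraic circle fit, renormalized to the Pratt convention."""
    return _algebraic_fit(points, "taubin")


def fit_gauss_newton(
    points,
    init: CircleModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> CircleModel:
    """Geometric circle fit by damped Gauss-Newton iteration.

    Minimizes the sum of squared orthogonal distances starting from ``init``
    (default: the Pratt fit).  Steps are halved until the objective does not
    increase, so the objective is monotonically non-increasing.  If the
    parameter change has not dropped below ``tol`` after ``max_iter``
    iterations the last iterate is returned with ``converged = False``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pts, _ = _check_points(points)
    if init is None:
        init = fit_pratt(points)
    xc, yc, r = init.xc, init.yc, init.r

    def objective(xc, yc, r):
        d = np.hypot(pts[:, 0] - xc, pts[:, 1] - yc) - r
        return float(d @ d)

    obj = objective(xc, yc, r)
    converged = False
    for _ in range(max_iter):
        dx = pts[:, 0] - xc
        dy = pts[:, 1] - yc
        d = np.hypot(dx, dy)
        d_safe = np.where(d == 0, 1.0, d)
        f = d - r
        J = np.column_stack([-dx / d_safe, -dy / d_safe, -np.ones_like(d)])
        step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        scale = 1.0
        for _halve in range(30):
            cand = (xc + scale * step[0], yc + scale * step[1], r + scale * step[2])
            if cand[2] > 0 and objective(*cand) <= obj + 1e-15:
                break
            scale *= 0.5
        else:
            converged = True  # no productive step remains: at a minimum
            break
        xc, yc, r = cand
        obj = objective(xc, yc, r)
        if float(np.max(np.abs(scale * step))) < tol:
            converged = True
            break
    A, B, C, D = _canonical_abcd(xc, yc, r)
    return CircleModel(
        xc=float(xc),
        yc=float(yc),
        r=float(r),
        A=A,
        B=B,
        C=C,
        D=D,
        rms_residual=_rms_residual(pts, xc, yc, r),
        n_points=pts.shape[0],
        method="gauss-newton",
        converged=converged,
    )
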