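"""Ellipse geometry primitives.

Coordinate convention: ``x`` is the column index and ``y`` the row index,
both 0-based. ``theta`` is the orientation of the major axis in radians,
counter-clockwise in the mathematical (y-up) sense, normalized to ``[0, pi)``
and stored against image coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import special

__all__ = [
    "Point2D",
    "Ellipse",
    "ConicCoefficients",
    "EllipseFitError",
    "fit_ellipse_lsq",
    "conic_to_geometric",
    "geometric_to_conic",
    "ellipse_perimeter",
    "ellipse_arc_length",
    "point_ellipse_distance",
    "points_ellipse_distance",
    "ellipse_area",
    "long_axis",
    "ellipse_point",
    "ellipse_bbox",
    "rasterize_ellipse_arc",
]

_THETA_EPS = 1e-12


class Point2D(NamedTuple):
    """A 2-D pixel coordinate (x = column, y = row, 0-based)."""

    x: float
    y: float


class EllipseFitError(ValueError):
    """Raised when input points do not determine a valid ellipse."""


@dataclass(frozen=True)
class Ellipse:
    """Geometric ellipse.

    Parameters
    ----------
    cx, cy : float
        Center in pixel coordinates.
    a, b : float
        Semi-major and semi-minor axis lengths, ``a >= b > 0``.
    theta : float
        Orientation of the major axis, radians, normalized to ``[0, pi)``.
        For circles (``a == b``) the orientation is fixed to 0.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.cx, self.cy, self.a, self.b, self.theta))):
            raise ValueError("ellipse parameters must be finite")
        a, b, theta = self.a, self.b, self.theta
        if b <= 0 or a <= 0:
            raise ValueError(f"semi-axes must be positive, got a={a}, b={b}")
        if a < b:
            a, b = b, a
            theta = theta + math.pi / 2.0
        theta = theta % math.pi
        if abs(a - b) <= _THETA_EPS * max(a, b):
            theta = 0.0
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "theta", theta)

    @property
    def center(self) -> Point2D:
        return Point2D(self.cx, self.cy)


@dataclass(frozen=True)
class ConicCoefficients:
    """Coefficients of ``A x^2 + B xy + C y^2 + D x + E y + F = 0``.

    Defined up to a nonzero scalar multiple; the locus is an ellipse iff
    ``B^2 - 4AC < 0``.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def is_ellipse(self) -> bool:
        return self.B * self.B - 4.0 * self.A * self.C < 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D, self.E, self.F], dtype=float)


def _as_points_array(points: Iterable) -> np.ndarray:
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (x, y) pairs")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def geometric_to_conic(e: Ellipse) -> ConicCoefficients:
    """Convert a geometric ellipse to conic coefficients (F-normalized)."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    a2, b2 = e.a * e.a, e.b * e.b
    A = ct * ct / a2 + st * st / b2
    B = 2.0 * ct * st * (1.0 / a2 - 1.0 / b2)
    C = st * st / a2 + ct * ct / b2
    D = -2.0 * A * e.cx - B * e.cy
    E = -B * e.cx - 2.0 * C * e.cy
    F = A * e.cx * e.cx + B * e.cx * e.cy + C * e.cy * e.cy - 1.0
    return ConicCoefficients(A, B, C, D, E, F)


def conic_to_geometric(conic: ConicCoefficients) -> Ellipse:
    """Convert conic coefficients to geometric ellipse form.

    Raises
    ------
    EllipseFitError
        If the conic is not a (real, non-degenerate) ellipse.
    """
    A, B, C, D, E, F = conic.as_array()
    disc = B * B - 4.0 * A * C
    if not disc < 0.0:
        raise EllipseFitError(f"conic is not an ellipse (B^2-4AC = {disc:g} >= 0)")
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    bvec = np.array([D, E])
    center = np.linalg.solve(2.0 * M, -bvec)
    k = float(center @ M @ center + bvec @ center + F)
    evals, evecs = np.linalg.eigh(M)
    axes2 = -k / evals
    if not np.all(axes2 > 0.0):
        raise EllipseFitError("conic has no real ellipse locus")
    semi = np.sqrt(axes2)
    # eigh sorts eigenvalues ascending, so semi[0] is the major axis.
    major_vec = evecs[:, 0]
    theta = math.atan2(major_vec[1], major_vec[0])
    return Ellipse(float(center[0]), float(center[1]), float(semi[0]), float(semi[1]), theta)


def fit_ellipse_lsq(points: Sequence | np.ndarray) -> Ellipse:
    """Direct least-squares ellipse fit (ellipse-specific constraint).

    Uses the numerically stable partitioned eigensystem formulation of the
    direct fit with constraint ``4AC - B^2 = 1``, which guarantees the
    returned conic is an ellipse. With exactly five points in general
    position the fit interpolates them.

    Parameters
    ----------
    points : (N, 2) array-like
        At least 5 distinct ``(x, y)`` points.

    Raises
    ------
    EllipseFitError
        Fewer than 5 distinct points, collinear/degenerate input, or no
        valid ellipse solution.
    """
    pts = _as_points_array(points)
    if len(np.unique(pts, axis=0)) < 5:
        raise EllipseFitError("need at least 5 distinct points")
    # Condition by centering and isotropic scaling.
    mean = pts.mean(axis=0)
    centered = pts - mean
    scale = float(np.sqrt((centered ** 2).sum(axis=1).mean()))
    if scale <= 0:
        raise EllipseFitError("degenerate (coincident) points")
    u = centered / scale
    x, y = u[:, 0], u[:, 1]

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # Premultiply by C1^{-1} for constraint 4AC - B^2 = 1.
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    try:
        evals, evecs = np.linalg.eig(M)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("eigen decomposition failed") from exc
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    valid = np.isreal(evals) & np.isfinite(evals.real) & (cond.real > 0)
    if not np.any(valid):
        raise EllipseFitError("no ellipse solution (degenerate or non-elliptical data)")
    a1 = np.real(evecs[:, np.argmax(valid)])
    coeffs = np.concatenate([a1, T @ a1])
    A, B, C, D, E, F = coeffs
    ell = conic_to_geometric(ConicCoefficients(A, B, C, D, E, F))
    # Undo the conditioning transform.
    return Ellipse(
        ell.cx * scale + mean[0],
        ell.cy * scale + mean[1],
        ell.a * scale,
        ell.b * scale,
        ell.theta,
    )


def ellipse_perimeter(e: Ellipse) -> float:
    """Perimeter via the complete elliptic integral of the second kind.

    Exact (to machine precision) evaluation ``4 a E(m)`` with eccentricity
    parameter ``m = 1 - (b/a)^2``; reduces to ``2 pi r`` for circles.
    """
    m = 1.0 - (e.b / e.a) ** 2
    return float(4.0 * e.a * special.ellipe(m))


def ellipse_arc_length(e: Ellipse, t0: float, t1: float, n: int = 2048) -> float:
    """Arc length between parametric angles ``t0 <= t1`` (composite quadrature)."""
    if t1 < t0:
        raise ValueError("require t0 <= t1")
    t = np.linspace(t0, t1, n)
    speed = np.hypot(e.a * np.sin(t), e.b * np.cos(t))
    return float(np.trapezoid(speed, t))


def ellipse_point(e: Ellipse, t: float | np.ndarray) -> np.ndarray:
    """Point(s) on the ellipse at parametric angle(s) ``t``; shape (..., 2)."""
    t = np.asarray(t, dtype=float)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    px = e.a * np.cos(t)
    py = e.b * np.sin(t)
    return np.stack([e.cx + ct * px - st * py, e.cy + st * px + ct * py], axis=-1)


def points_ellipse_distance(points: Sequence | np.ndarray, e: Ellipse) -> np.ndarray:
    """Orthogonal (foot-point) distance from each point to the ellipse boundary.

    Vectorized robust solver: the problem is reduced to the first quadrant in
    the ellipse frame and the foot-point parameter is bracketed and bisected,
    which converges unconditionally.
    """
    pts = np.atleast_2d(_as_points_array(points))
    ct, st = math.cos(e.theta), math.sin(e.theta)
    dx = pts[:, 0] - e.cx
    dy = pts[:, 1] - e.cy
    u = np.abs(ct * dx + st * dy)
    v = np.abs(-st * dx + ct * dy)
    a, b = e.a, e.b

    if (a - b) <= 1e-14 * a:  # circle
        return np.abs(np.hypot(u, v) - a)

    dist = np.empty(len(pts), dtype=float)
    c2 = a * a - b * b

    at_center = (u == 0.0) & (v == 0.0)
    # Points near the major axis inside the evolute cusp: the foot point is
    # off-axis and the stationary equation degenerates; closed form instead.
    on_axis = (v == 0.0) & (u * a <= c2) & ~at_center
    general = ~(at_center | on_axis)

    dist[at_center] = b
    if np.any(on_axis):
        ux = u[on_axis]
        fx = a * a * ux / c2
        fy = b * np.sqrt(np.clip(1.0 - (fx / a) ** 2, 0.0, None))
        dist[on_axis] = np.hypot(ux - fx, fy)

    if np.any(general):
        ug, vg = u[general], v[general]
        au, bv = a * ug, b * vg
        lo = -b * b + bv
        hi = -b * b + np.hypot(au, bv)
        for _ in range(90):
            mid = 0.5 * (lo + hi)
            t1 = np.where(au > 0, au / (mid + a * a), 0.0)
            t2 = np.where(bv > 0, bv / (mid + b * b), 0.0)
            f = t1 * t1 + t2 * t2 - 1.0
            take_hi = f > 0
            lo = np.where(take_hi, mid, lo)
            hi = np.where(take_hi, hi, mid)
        t = 0.5 * (lo + hi)
        fx = a * a * ug / (t + a * a)
        fy = b * b * vg / (t + b * b)
        dist[general] = np.hypot(ug - fx, vg - fy)
    return dist


def point_ellipse_distance(p: Point2D | Sequence[float], e: Ellipse) -> float:
    """Scalar foot-point distance from ``p`` to the ellipse boundary."""
    return float(points_ellipse_distance(np.asarray(p, dtype=float)[None, :], e)[0])


def ellipse_area(e: Ellipse) -> float:
    """Projected area ``pi * a * b`` in square pixels."""
    return math.pi * e.a * e.b


def long_axis(e: Ellipse) -> float:
    """Long-axis length ``2 a`` in pixels."""
    return 2.0 * e.a


def ellipse_bbox(e: Ellipse) -> tuple[float, float, float, float]:
    """Tight axis-aligned bounds ``(x_min, y_min, x_max, y_max)``."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    ex = math.hypot(e.a * ct, e.b * st)
    ey = math.hypot(e.a * st, e.b * ct)
    return (e.cx - ex, e.cy - ey, e.cx + ex, e.cy + ey)


def rasterize_ellipse_arc(
    e: Ellipse,
    angle_range: tuple[float, float] = (0.0, 2.0 * math.pi),
    image_shape: tuple[int, int] | None = None,
    step: float = 0.3,
) -> np.ndarray:
    """Rasterize an elliptical arc to a 1-px-wide, 8-connected pixel chain.

    Parameters
    ----------
    e : Ellipse
    angle_range : (t0, t1)
        Parametric angle interval, ``t0 <= t1``; the full range
        ``[0, 2 pi)`` yields a closed contour.
    image_shape : (H, W), optional
        If given, pixels outside the image are dropped.
    step : float
        Maximum arc-length advance per parameter sample, in pixels. Must be
        < 1 to guarantee 8-connectivity of the rounded chain.

    Returns
    -------
    (N, 2) int ndarray of unique (x, y) pixels ordered along the arc.
    """
    t0, t1 = angle_range
    if t1 < t0:
        raise ValueError("require t0 <= t1")
    if t1 == t0:
        pts = ellipse_point(e, t0)[None, :]
    else:
        arclen = ellipse_arc_length(e, t0, t1, n=256)
        n = max(int(math.ceil(arclen / step)) + 1, 2)
        pts = ellipse_point(e, np.linspace(t0, t1, n))
    pix = np.round(pts).astype(int)
    # Ordered de-duplication.
    seen = dict.fromkeys(map(tuple, pix))
    pix = np.array(list(seen), dtype=int).reshape(-1, 2)
    if len(pix) > 1 and np.all(pix[0] == pix[-1]):
        pix = pix[:-1]
    if image_shape is not None:
        h, w = image_shape
        keep = (pix[:, 0] >= 0) & (pix[:, 0] < w) & (pix[:, 1] >= 0) & (pix[:, 1] < h)
        pix = pix[keep]
    return pix
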