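"""Iterative least-squares ellipse fitting with random sample consensus.

The loop draws minimal 5-pixel samples from a contour, fits a direct
least-squares ellipse to each draw, scores it by the fraction of contour
pixels lying within a distance threshold of the fitted boundary relative to
the fitted perimeter, and keeps the best-scoring model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Ellipse,
    EllipseFitError,
    ellipse_bbox,
    ellipse_perimeter,
    fit_ellipse_lsq,
    points_ellipse_distance,
)

__all__ = ["RansacConfig", "FitResult", "compute_iteration_count", "fitness", "ransac_fit_ellipse"]


@dataclass(frozen=True)
class RansacConfig:
    """Configuration of the consensus loop.

    Parameters
    ----------
    p : float
        Desired probability that at least one draw is all-inlier, in (0, 1).
    err : float
        Assumed outlier fraction among contour pixels, in [0, 1).
    s : int
        Minimal sample size per draw (>= 5 points determine a conic).
    d : float
        Inlier distance threshold in pixels (> 0). The default of 1.0 px
        (~1.6x the rasterization error of a 1-px contour) keeps models
        that merge arcs of adjacent contours from out-scoring the target.
    seed : int or None
        Seed for the loop's private random generator.
    min_fitness : float
        Acceptance floor applied by callers when deciding whether a fit
        is good enough to report.
    max_iterations : int
        Hard cap on the iteration count; the theoretical count diverges
        as ``err`` approaches 1.
    refit : bool
        After the consensus loop, iteratively least-squares refit the best
        model on its inlier set until convergence. Minimal 5-point models
        locate the contour but extrapolate poorly; the consensus-set refit
        removes that bias while staying a plain (non-robust) least squares.
    refit_iterations : int
        Cap on refit passes.
    """

    p: float = 0.99
    err: float = 0.5
    s: int = 5
    d: float = 1.0
    seed: int | None = None
    min_fitness: float = 0.5
    max_iterations: int = 2000
    refit: bool = True
    refit_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not 0.0 <= self.err < 1.0:
            raise ValueError(f"err must be in [0, 1), got {self.err}")
        if self.s < 5:
            raise ValueError(f"s must be >= 5, got {self.s}")
        if self.d <= 0.0:
            raise ValueError(f"d must be positive, got {self.d}")
        if not 0.0 <= self.min_fitness:
            raise ValueError("min_fitness must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Best model found by the consensus loop."""

    ellipse: Ellipse
    fitness: float
    inliers: np.ndarray = field(repr=False)
    iterations: int = 0


def compute_iteration_count(p: float, err: float, s: int) -> int:
    """Number of draws needed for an all-inlier sample with probability ``p``.

    ``K = ceil( log(1 - p) / log(1 - (1 - err)^s) )`` with a floor of 1.

    Raises
    ------
    ValueError
        If ``p`` or ``err`` make the formula undefined (``p >= 1`` or
        ``err >= 1``) or are otherwise out of range.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not 0.0 <= err < 1.0:
        raise ValueError(f"err must be in [0, 1), got {err}")
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    w = (1.0 - err) ** s  # probability a single draw is all-inlier
    if w >= 1.0:
        return 1
    return max(1, int(math.ceil(math.log(1.0 - p) / math.log(1.0 - w))))


def fitness(e: Ellipse, contour: np.ndarray, d: float) -> float:
    """Model fitness: inliers within distance ``d`` per unit fitted perimeter.

    The numerator counts contour pixels whose orthogonal distance to the
    ellipse boundary is at most ``d``; the denominator is the exact ellipse
    perimeter. An empty contour scores 0.
    """
    if d <= 0.0:
        raise ValueError("d must be positive")
    contour = np.asarray(contour, dtype=float)
    if contour.size == 0:
        return 0.0
    n_in = int(np.count_nonzero(points_ellipse_distance(contour, e) <= d))
    return n_in / ellipse_perimeter(e)


def _within_bounds(e: Ellipse, bounds: tuple[float, float, float, float]) -> bool:
    x0, y0, x1, y1 = ellipse_bbox(e)
    bx0, by0, bx1, by1 = bounds
    return x0 >= bx0 and y0 >= by0 and x1 <= bx1 and y1 <= by1


def ransac_fit_ellipse(
    contour: np.ndarray,
    cfg: RansacConfig | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> FitResult:
    """Fit an ellipse to noisy contour pixels by random sample consensus.

    Runs exactly ``K`` draws (``K`` from :func:`compute_iteration_count`,
    capped at ``cfg.max_iterations``). Each draw samples ``cfg.s`` distinct
    pixels without replacement, fits a direct least-squares ellipse and
    scores it; draws whose fit degenerates consume an iteration with score
    0. Ties keep the earlier draw, so results are deterministic given the
    seed.

    Parameters
    ----------
    contour : (N, 2) array of (x, y) pixels, ``N >= cfg.s``.
    cfg : RansacConfig, optional
    bounds : (x_min, y_min, x_max, y_max), optional
        If given, candidate ellipses whose tight bounding box extends
        outside these bounds are rejected (scored 0). Candidate regions
        are expected to bound the target contour, so this suppresses
        models that merge arcs of neighboring objects.

    Returns
    -------
    FitResult
        Best ellipse, its fitness, its inlier pixels and the number of
        iterations actually run.

    Raises
    ------
    ValueError
        If the contour has fewer than ``cfg.s`` pixels.
    EllipseFitError
        If no draw produced a valid ellipse.
    """
    if cfg is None:
        cfg = RansacConfig()
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array")
    n = len(contour)
    if n < cfg.s:
        raise ValueError(f"contour has {n} pixels, need at least s={cfg.s}")

    k = min(compute_iteration_count(cfg.p, cfg.err, cfg.s), cfg.max_iterations)
    rng = np.random.default_rng(cfg.seed)

    best_f = -1.0
    best_ellipse: Ellipse | None = None
    for _ in range(k):
        idx = rng.choice(n, size=cfg.s, replace=False)
        try:
            candidate = fit_ellipse_lsq(contour[idx])
        except EllipseFitError:
            continue
        if bounds is not None and not _within_bounds(candidate, bounds):
            continue
        f = fitness(candidate, contour, cfg.d)
        if f > best_f:
            best_f = f
            best_ellipse = candidate

    if best_ellipse is None:
        raise EllipseFitError("no RANSAC draw produced a valid ellipse")
    if cfg.refit:
        best_ellipse, best_f = _refit_on_inliers(best_ellipse, best_f, contour, cfg, bounds)
    dists = points_ellipse_distance(contour, best_ellipse)
    inliers = contour[dists <= cfg.d]
    return FitResult(ellipse=best_ellipse, fitness=best_f, inliers=inliers, iterations=k)


def _refit_on_inliers(
    model: Ellipse,
    f: float,
    contour: np.ndarray,
    cfg: RansacConfig,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[Ellipse, float]:
    """Iterate (inlier selection, least-squares fit) to convergence."""
    current, current_f = model, f
    for _ in range(cfg.refit_iterations):
        inl = contour[points_ellipse_distance(contour, current) <= cfg.d]
        if len(inl) < cfg.s:
            break
        try:
            cand = fit_ellipse_lsq(inl)
        except EllipseFitError:
            break
        if bounds is not None and not _within_bounds(cand, bounds):
            break
        cand_f = fitness(cand, contour, cfg.d)
        converged = (
            abs(cand.cx - current.cx) < 1e-9
            and abs(cand.cy - current.cy) < 1e-9
            and abs(cand.a - current.a) < 1e-9
            and abs(cand.b - current.b) < 1e-9
        )
        current, current_f = cand, cand_f
        if converged:
            break
    return current, current_f
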