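"""Synthetic grape-cluster scenes with full ground truth.

Clusters of overlapping ellipses are rendered as 1-px contours; arcs hidden
by nearer grapes are removed, then contour dropout and spurious edge noise
are applied. Every stage of the measurement pipeline can therefore be tested
without any external imagery. Also provides the flip/rotate/scale
augmentation pipeline and a sinusoid-plus-trend area time-series generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import rescale, rotate

from .geometry import (
    Ellipse,
    ellipse_area,
    ellipse_arc_length,
    ellipse_bbox,
    ellipse_perimeter,
    ellipse_point,
    rasterize_ellipse_arc,
)
from .pipeline import CandidateBox

__all__ = [
    "SceneSpec",
    "SceneGroundTruth",
    "AugmentedImage",
    "generate_cluster_scene",
    "occlude_contours",
    "add_noise",
    "augment_images",
    "generate_area_series",
    "render_scene_image",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic cluster scene.

    ``overlap_factor`` sets the spacing of neighboring grape centers as a
    fraction of the sum of their mean radii (< 1 forces overlap);
    ``dropout_rate`` deletes visible contour pixels i.i.d.;
    ``spurious_rate`` adds random noise pixels in proportion to the visible
    contour pixel count. Scenes are resampled until every grape keeps at
    least ``min_visible_fraction`` of its contour visible.
    """

    n_grapes: int = 5
    axis_range: tuple[float, float] = (28.0, 45.0)
    aspect_max: float = 1.4
    image_size: tuple[int, int] = (384, 544)
    overlap_factor: float = 0.85
    dropout_rate: float = 0.0
    spurious_rate: float = 0.0
    min_visible_fraction: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_grapes < 1:
            raise ValueError("n_grapes must be >= 1")
        lo, hi = self.axis_range
        if not 0 < lo <= hi:
            raise ValueError("axis_range must be positive and ordered")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.spurious_rate < 0.0:
            raise ValueError("spurious_rate must be >= 0")
        if self.aspect_max < 1.0:
            raise ValueError("aspect_max must be >= 1")
        if not 0.0 <= self.min_visible_fraction <= 1.0:
            raise ValueError("min_visible_fraction must be in [0, 1]")
        h, w = self.image_size
        if 2 * hi >= min(h, w):
            raise ValueError("axis_range too large for image_size")


@dataclass(frozen=True)
class SceneGroundTruth:
    """True scene description; list order is z-order (later = nearer)."""

    ellipses: list[Ellipse]
    visible_arcs: list[list[tuple[float, float]]]
    boxes: list[CandidateBox]
    areas: list[float] = field(default_factory=list)
    visible_fraction: list[float] = field(default_factory=list)


def occlude_contours(
    ellipses: Sequence[Ellipse], n_samples: int = 2048
) -> tuple[list[list[tuple[float, float]]], list[float]]:
    """Visible angular intervals of each contour under z-order occlusion.

    A contour point of grape ``g`` is hidden iff it lies strictly inside a
    grape with higher z (a later list position). Returns the per-ellipse
    visible intervals in parameter angle and the visible fraction of each
    perimeter (arc-length weighted).
    """
    arcs: list[list[tuple[float, float]]] = []
    fractions: list[float] = []
    t = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    for i, e in enumerate(ellipses):
        pts = ellipse_point(e, t)
        hidden = np.zeros(n_samples, dtype=bool)
        for j in range(i + 1, len(ellipses)):
            o = ellipses[j]
            ct, st = math.cos(o.theta), math.sin(o.theta)
            dx = pts[:, 0] - o.cx
            dy = pts[:, 1] - o.cy
            u = (ct * dx + st * dy) / o.a
            v = (-st * dx + ct * dy) / o.b
            hidden |= u * u + v * v < 1.0 - 1e-12
        visible = ~hidden
        speed = np.hypot(e.a * np.sin(t), e.b * np.cos(t))
        total = float(speed.sum())
        fractions.append(float(speed[visible].sum()) / total if total else 0.0)
        arcs.append(_mask_to_intervals(visible, t))
    return arcs, fractions


def _mask_to_intervals(visible: np.ndarray, t: np.ndarray) -> list[tuple[float, float]]:
    """Runs of True in a circular boolean mask, as (t_start, t_end) pairs."""
    n = len(visible)
    if visible.all():
        return [(0.0, 2.0 * math.pi)]
    if not visible.any():
        return []
    step = 2.0 * math.pi / n
    # Rotate so the mask starts on a hidden sample, then scan runs linearly.
    start = int(np.argmin(visible))
    rolled = np.roll(visible, -start)
    intervals = []
    in_run = False
    run_start = 0
    for k in range(n + 1):
        val = rolled[k % n] if k < n else False
        if val and not in_run:
            in_run, run_start = True, k
        elif not val and in_run:
            in_run = False
            t0 = (start + run_start) * step
            t1 = (start + k) * step
            intervals.append((t0, t1))
    return intervals


def add_noise(
    edge_map: np.ndarray,
    dropout_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Delete contour pixels i.i.d. and sprinkle spurious edge pixels.

    ``spurious_rate`` is relative to the current contour pixel count; rates
    of 0 return the input unchanged. Deterministic given the seed.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must be in [0, 1]")
    if spurious_rate < 0.0:
        raise ValueError("spurious_rate must be >= 0")
    edge_map = np.asarray(edge_map)
    if dropout_rate == 0.0 and spurious_rate == 0.0:
        return edge_map.copy()
    rng = np.random.default_rng(seed)
    out = edge_map.copy()
    ys, xs = np.nonzero(out)
    n = len(xs)
    if dropout_rate > 0.0 and n:
        drop = rng.random(n) < dropout_rate
        out[ys[drop], xs[drop]] = 0
    if spurious_rate > 0.0 and n:
        n_spur = int(round(spurious_rate * n))
        h, w = out.shape
        sy = rng.integers(0, h, size=n_spur)
        sx = rng.integers(0, w, size=n_spur)
        out[sy, sx] = 1
    return out


def _box_for(e: Ellipse, image_shape: tuple[int, int]) -> CandidateBox:
    x0, y0, x1, y1 = ellipse_bbox(e)
    h, w = image_shape
    return CandidateBox(
        max(0, int(math.floor(x0)) - 1),
        max(0, int(math.floor(y0)) - 1),
        min(w, int(math.ceil(x1)) + 2),
        min(h, int(math.ceil(y1)) + 2),
    )


def _sample_cluster(spec: SceneSpec, rng: np.random.Generator) -> list[Ellipse]:
    """Place grapes one by one, retrying placements that over-occlude.

    A new grape is always fully visible (it has the highest z so far), so
    each placement only needs to keep the *earlier* grapes above the
    visibility floor; this makes incremental rejection cheap and reliable.
    """
    h, w = spec.image_size
    lo, hi = spec.axis_range
    ellipses: list[Ellipse] = []
    margin = hi + 2.0
    for i in range(spec.n_grapes):
        a = rng.uniform(lo, hi)
        b = a / rng.uniform(1.0, spec.aspect_max)
        theta = rng.uniform(0.0, math.pi)
        r_new = 0.5 * (a + b)
        placed = False
        for _ in range(80):
            if not ellipses:
                cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
                cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
            else:
                anchor = ellipses[rng.integers(0, len(ellipses))]
                r_anchor = 0.5 * (anchor.a + anchor.b)
                dist = spec.overlap_factor * (r_anchor + r_new)
                ang = rng.uniform(0.0, 2.0 * math.pi)
                cx = anchor.cx + dist * math.cos(ang)
                cy = anchor.cy + dist * math.sin(ang)
            cx = float(np.clip(cx, margin, w - margin))
            cy = float(np.clip(cy, margin, h - margin))
            candidate = ellipses + [Ellipse(cx, cy, a, b, theta)]
            _, fractions = occlude_contours(candidate, n_samples=512)
            if all(f >= spec.min_visible_fraction for f in fractions):
                ellipses = candidate
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place a cluster meeting min_visible_fraction; relax the spec"
            )
    return ellipses


def generate_cluster_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Generate a binary edge map of an overlapping-grape cluster plus truth.

    Ellipse parameters are drawn from the spec ranges and placed around a
    cluster anchor; nearer grapes occlude farther ones. Visible arcs are
    rasterized at 1 px, then dropout and spurious noise are applied. The
    whole construction is deterministic given ``spec.seed``; placements are
    resampled (bounded retries) until every grape keeps at least
    ``min_visible_fraction`` of its contour.
    """
    rng = np.random.default_rng(spec.seed)
    ellipses = _sample_cluster(spec, rng)
    arcs, fractions = occlude_contours(ellipses)
    h, w = spec.image_size
    edge_map = np.zeros((h, w), dtype=np.uint8)
    # Rasterize full contours and mask occluded pixels, so visible pixels
    # are an exact subset of the full rasterized contours.
    for i, e in enumerate(ellipses):
        pix = rasterize_ellipse_arc(e, (0.0, 2.0 * math.pi), image_shape=(h, w))
        if not len(pix):
            continue
        hidden = np.zeros(len(pix), dtype=bool)
        for j in range(i + 1, len(ellipses)):
            o = ellipses[j]
            ct, st = math.cos(o.theta), math.sin(o.theta)
            dx = pix[:, 0] - o.cx
            dy = pix[:, 1] - o.cy
            u = (ct * dx + st * dy) / o.a
            v = (-st * dx + ct * dy) / o.b
            hidden |= u * u + v * v < 1.0 - 1e-12
        keep = pix[~hidden]
        edge_map[keep[:, 1], keep[:, 0]] = 1
    noise_seed = None if spec.seed is None else spec.seed + 1
    edge_map = add_noise(edge_map, spec.dropout_rate, spec.spurious_rate, seed=noise_seed)
    gt = SceneGroundTruth(
        ellipses=list(ellipses),
        visible_arcs=arcs,
        boxes=[_box_for(e, (h, w)) for e in ellipses],
        areas=[ellipse_area(e) for e in ellipses],
        visible_fraction=fractions,
    )
    return edge_map, gt


def render_scene_image(
    gt: SceneGroundTruth,
    image_size: tuple[int, int],
    background: float = 0.15,
    blur_sigma: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Grayscale rendering: filled ellipses at distinct gray levels + blur.

    Farther grapes are painted first so nearer ones cover them, matching the
    occlusion model of the edge maps. Used to exercise image-domain edge
    detectors on scenes with known contours.
    """
    h, w = image_size
    rng = np.random.default_rng(seed)
    img = np.full((h, w), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    levels = np.linspace(0.45, 0.9, max(len(gt.ellipses), 2))
    rng.shuffle(levels)
    for e, level in zip(gt.ellipses, levels):
        ct, st = math.cos(e.theta), math.sin(e.theta)
        dx = xx - e.cx
        dy = yy - e.cy
        u = (ct * dx + st * dy) / e.a
        v = (-st * dx + ct * dy) / e.b
        img[u * u + v * v <= 1.0] = level
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma, mode="nearest")
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class AugmentedImage:
    """One augmented output and the transform that produced it."""

    image: np.ndarray
    flipped: bool
    rotation_deg: float
    scale: float


def augment_images(
    images: Sequence[np.ndarray],
    include_flip: bool = True,
    rotation_step_deg: float = 22.5,
    scales: Sequence[float] = (0.5, 1.0, 1.5),
) -> list[AugmentedImage]:
    """Combinatorial flip x rotation x scale augmentation.

    With the defaults each source image yields ``2 * 16 * 3 = 96`` outputs
    (identity member included); the identity transform reproduces the source
    array exactly.
    """
    if rotation_step_deg <= 0 or 360.0 % rotation_step_deg != 0.0:
        raise ValueError("rotation_step_deg must evenly divide 360")
    rotations = np.arange(0.0, 360.0, rotation_step_deg)
    flips = (False, True) if include_flip else (False,)
    out: list[AugmentedImage] = []
    for img in images:
        img = np.asarray(img, dtype=float)
        for flip in flips:
            base = np.fliplr(img) if flip else img
            for ang in rotations:
                rotated = base if ang == 0.0 else rotate(base, ang, resize=False, mode="edge")
                for s in scales:
                    scaled = (
                        rotated
                        if s == 1.0
                        else rescale(rotated, s, channel_axis=-1 if img.ndim == 3 else None)
                    )
                    out.append(
                        AugmentedImage(image=scaled, flipped=flip, rotation_deg=float(ang), scale=float(s))
                    )
    return out


def generate_area_series(
    base_area: float,
    daily_amplitude: float,
    trend_per_day: float,
    days: float,
    samples_per_day: int = 24,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoid-plus-trend projected-area series with Gaussian noise.

    ``area(t) = base * (1 + trend * t) + amplitude * sin(2 pi t) + noise``
    with ``t`` in days; mimics the daily shrink/expand cycle superimposed on
    growth. Returns ``(t_days, areas)``.
    """
    if base_area <= 0:
        raise ValueError("base_area must be positive")
    if samples_per_day < 1:
        raise ValueError("samples_per_day must be >= 1")
    n = int(round(days * samples_per_day))
    t = np.arange(n) / samples_per_day
    rng = np.random.default_rng(seed)
    areas = (
        base_area * (1.0 + trend_per_day * t)
        + daily_amplitude * np.sin(2.0 * math.pi * t)
        + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    )
    return t, areas
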