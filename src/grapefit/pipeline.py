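"""Second-step orchestration: edge map + candidate boxes -> per-grape phenotypes.

For each candidate box the binary edge map is segmented into 8-connected
contour segments, the segment pixels are pooled and passed to the consensus
ellipse fitter, and a phenotype record (long axis, projected area) is emitted
when the fit clears the acceptance floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage import measure

from .geometry import Ellipse, EllipseFitError, ellipse_area, long_axis
from .ransac import FitResult, RansacConfig, ransac_fit_ellipse

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateBox",
    "ContourSegment",
    "PhenotypeRecord",
    "binarize_edge_map",
    "region_grow_contours",
    "fit_grapes_in_boxes",
    "aggregate_time_series",
]


@dataclass(frozen=True)
class CandidateBox:
    """Axis-aligned candidate region, 0-based half-open ``[min, max)``."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError(f"degenerate box: {self}")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    def clipped(self, image_shape: tuple[int, int]) -> "CandidateBox":
        h, w = image_shape
        return CandidateBox(
            max(0, self.x_min),
            max(0, self.y_min),
            min(w, self.x_max),
            min(h, self.y_max),
            self.score,
        )

    def expanded(self, fraction: float) -> "CandidateBox":
        """Box grown by ``fraction`` of its width/height on each side."""
        dx = (self.x_max - self.x_min) * fraction
        dy = (self.y_max - self.y_min) * fraction
        return CandidateBox(
            int(math.floor(self.x_min - dx)),
            int(math.floor(self.y_min - dy)),
            int(math.ceil(self.x_max + dx)),
            int(math.ceil(self.y_max + dy)),
            self.score,
        )

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class ContourSegment:
    """Ordered, 8-connected chain of edge pixels inside one box."""

    pixels: np.ndarray  # (N, 2) int, (x, y)

    def __post_init__(self) -> None:
        if len(self.pixels) == 0:
            raise ValueError("segment must be non-empty")

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-grape measurement: fitted ellipse and derived phenotypes."""

    grape_id: int
    box: CandidateBox
    ellipse: Ellipse
    long_axis_px: float
    area_px2: float
    fitness: float


def binarize_edge_map(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary map with 1 wherever the probability is >= ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError("edge map must be 2-D")
    return (p >= threshold).astype(np.uint8)


def _order_chain(pixels: np.ndarray) -> np.ndarray:
    """Order component pixels into a chain by greedy 8-neighbor walking."""
    pts = {tuple(p) for p in pixels}
    neigh = {}
    for x, y in pts:
        neigh[(x, y)] = [
            (x + dx, y + dy)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx or dy) and (x + dx, y + dy) in pts
        ]
    start = min(pts, key=lambda p: (len(neigh[p]), p))
    order = [start]
    visited = {start}
    current = start
    while True:
        nxt = [p for p in neigh[current] if p not in visited]
        if not nxt:
            remaining = pts - visited
            if not remaining:
                break
            # Branch point or gap inside the component: jump to the nearest
            # unvisited pixel and continue the walk.
            current = min(
                remaining, key=lambda p: (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
            )
        else:
            current = min(nxt, key=lambda p: abs(p[0] - current[0]) + abs(p[1] - current[1]))
        order.append(current)
        visited.add(current)
    return np.array(order, dtype=int)


def region_grow_contours(
    binary_map: np.ndarray,
    box: CandidateBox,
    min_segment_len: int = 10,
) -> list[ContourSegment]:
    """Grow maximal 8-connected contour segments inside a candidate box.

    Every edge pixel inside the box belongs to exactly one segment; segments
    shorter than ``min_segment_len`` pixels are discarded.
    """
    binary_map = np.asarray(binary_map)
    box = box.clipped(binary_map.shape)
    crop = binary_map[box.y_min : box.y_max, box.x_min : box.x_max]
    if crop.size == 0 or not crop.any():
        return []
    labels = measure.label(crop > 0, connectivity=2)
    segments = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(xs) < min_segment_len:
            continue
        pix = np.column_stack([xs + box.x_min, ys + box.y_min])
        segments.append(ContourSegment(pixels=_order_chain(pix)))
    return segments


def fit_grapes_in_boxes(
    edge_map: np.ndarray,
    boxes: Sequence[CandidateBox],
    cfg: RansacConfig | None = None,
    threshold: float = 0.5,
    min_segment_len: int = 10,
    box_expand: float = 0.05,
    segment_mode: str = "pool",
) -> list[PhenotypeRecord]:
    """Fit one ellipse per candidate box and emit accepted phenotype records.

    Parameters
    ----------
    edge_map : 2-D array
        Probability or binary edge map; binarized at ``threshold`` first.
    boxes : sequence of CandidateBox
    cfg : RansacConfig
        Consensus-fit configuration; per-box loops get decorrelated seeds
        derived from ``cfg.seed`` so the run is reproducible end to end.
    segment_mode : {'pool', 'longest'}
        Fit all segment pixels of the box jointly, or only the longest
        segment.

    A record is emitted only when the best fitness reaches
    ``cfg.min_fitness`` and the fitted center lies inside the box expanded
    by ``box_expand`` on each side. Boxes with too few contour pixels are
    skipped with a warning.
    """
    if cfg is None:
        cfg = RansacConfig()
    if segment_mode not in ("pool", "longest"):
        raise ValueError("segment_mode must be 'pool' or 'longest'")
    binary = binarize_edge_map(edge_map, threshold)
    records: list[PhenotypeRecord] = []
    for i, box in enumerate(boxes):
        box = box.clipped(binary.shape)
        segments = region_grow_contours(binary, box, min_segment_len)
        if not segments:
            logger.warning("box %d: no contour segments, skipped", i)
            continue
        if segment_mode == "longest":
            pixels = max(segments, key=len).pixels
        else:
            pixels = np.concatenate([s.pixels for s in segments])
        if len(pixels) < cfg.s:
            logger.warning("box %d: only %d contour pixels (< s=%d), skipped", i, len(pixels), cfg.s)
            continue
        box_cfg = replace(cfg, seed=(cfg.seed or 0) + 7919 * (i + 1))
        fit_bounds = box.expanded(box_expand)
        try:
            result: FitResult = ransac_fit_ellipse(
                pixels.astype(float),
                box_cfg,
                bounds=(fit_bounds.x_min, fit_bounds.y_min, fit_bounds.x_max, fit_bounds.y_max),
            )
        except EllipseFitError:
            logger.warning("box %d: no valid ellipse found", i)
            continue
        e = result.ellipse
        if result.fitness < cfg.min_fitness:
            logger.info("box %d: fitness %.3f below floor %.3f", i, result.fitness, cfg.min_fitness)
            continue
        if not box.expanded(box_expand).contains(e.cx, e.cy):
            logger.info("box %d: fitted center outside expanded box", i)
            continue
        records.append(
            PhenotypeRecord(
                grape_id=i,
                box=box,
                ellipse=e,
                long_axis_px=long_axis(e),
                area_px2=ellipse_area(e),
                fitness=result.fitness,
            )
        )
    return records


def aggregate_time_series(
    records_by_timestamp: Mapping[object, Iterable[PhenotypeRecord | float]],
) -> dict:
    """Instance-wise mean projected area per timestamp.

    Accepts either phenotype records or raw area values; timestamps with no
    instances are omitted from the output. Keys are returned sorted.
    """
    out = {}
    for ts in sorted(records_by_timestamp):
        areas = [
            r.area_px2 if isinstance(r, PhenotypeRecord) else float(r)
            for r in records_by_timestamp[ts]
        ]
        if areas:
            out[ts] = float(np.mean(areas))
    return out
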