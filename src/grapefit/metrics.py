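"""Evaluation statistics for edge maps and phenotype measurements.

Edge-map agreement is computed from a tolerance-based one-to-one pixel
matching; derived scores are the Dice coefficient, pixel recall, the contour
redundancy rate, and threshold-sweep ODS/OIS F-measures. Phenotype accuracy
is summarized by the average absolute relative deviation (AARD) and the
fitting recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .edges import validate_binary_map, validate_probability_map

__all__ = [
    "EdgeMatchResult",
    "PhenotypePair",
    "match_edge_pixels",
    "dice_coefficient",
    "pixel_recall",
    "redundancy_rate",
    "fitting_recall",
    "aard",
    "nms_thin",
    "ods_ois",
]


@dataclass(frozen=True)
class EdgeMatchResult:
    """One-to-one correspondence counts between predicted and true edges."""

    TP: int
    count_X: int
    count_Y: int

    def __post_init__(self) -> None:
        if self.TP > self.count_X or self.TP > self.count_Y or self.TP < 0:
            raise ValueError("inconsistent match counts")

    @property
    def FN(self) -> int:
        return self.count_Y - self.TP


@dataclass(frozen=True)
class PhenotypePair:
    """A measured phenotype value and its ground truth (same units)."""

    measured: float
    truth: float

    def __post_init__(self) -> None:
        if not self.truth > 0:
            raise ValueError(f"truth must be positive, got {self.truth}")


def match_edge_pixels(x: np.ndarray, y: np.ndarray, tol: float = 2.0) -> EdgeMatchResult:
    """Greedy nearest-neighbor one-to-one matching of edge pixels.

    Candidate pairs are predicted/true pixels within Euclidean distance
    ``tol``; pairs are consumed in order of increasing distance, each pixel
    matched at most once. ``tol = 0`` degenerates to exact overlap.

    Parameters
    ----------
    x, y : binary 2-D arrays of equal shape
        Predicted and ground-truth edge maps.
    tol : float >= 0
    """
    x = validate_binary_map(x)
    y = validate_binary_map(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    px = np.argwhere(x > 0)
    py = np.argwhere(y > 0)
    if len(px) == 0 or len(py) == 0:
        return EdgeMatchResult(TP=0, count_X=len(px), count_Y=len(py))
    pairs = cKDTree(px).sparse_distance_matrix(cKDTree(py), max_distance=tol, output_type="coo_matrix")
    order = np.argsort(pairs.data, kind="stable")
    used_x = np.zeros(len(px), dtype=bool)
    used_y = np.zeros(len(py), dtype=bool)
    tp = 0
    for i, j in zip(pairs.row[order], pairs.col[order]):
        if not used_x[i] and not used_y[j]:
            used_x[i] = True
            used_y[j] = True
            tp += 1
    return EdgeMatchResult(TP=tp, count_X=len(px), count_Y=len(py))


def dice_coefficient(match: EdgeMatchResult) -> float:
    """Similarity ``2 |X ∩ Y| / (|X| + |Y|)`` under the tolerance matching."""
    total = match.count_X + match.count_Y
    if total == 0:
        return 1.0
    return 2.0 * match.TP / total


def pixel_recall(match: EdgeMatchResult) -> float:
    """Fraction of true edge pixels recovered, ``TP / (TP + FN)``."""
    if match.count_Y == 0:
        return 1.0 if match.count_X == 0 else 0.0
    return match.TP / (match.TP + match.FN)


def redundancy_rate(match: EdgeMatchResult) -> float:
    """Contour redundancy ``(1 - TP / Count(X)) * 100`` in percent."""
    if match.count_X == 0:
        return 0.0
    return (1.0 - match.TP / match.count_X) * 100.0


def fitting_recall(n_fitted: int, n_actual: int) -> float:
    """Percentage of actual contours successfully fitted."""
    if n_actual <= 0:
        raise ValueError("n_actual must be positive")
    if n_fitted < 0:
        raise ValueError("n_fitted must be >= 0")
    return n_fitted / n_actual * 100.0


def aard(pairs: Iterable[PhenotypePair | tuple[float, float]]) -> float:
    """Average absolute relative deviation in percent.

    ``mean_i |measured_i - truth_i| / truth_i * 100`` over the given
    (measured, truth) pairs.
    """
    vals = []
    for pr in pairs:
        if not isinstance(pr, PhenotypePair):
            pr = PhenotypePair(*pr)
        vals.append(abs(pr.measured - pr.truth) / pr.truth)
    if not vals:
        raise ValueError("aard requires at least one pair")
    return float(np.mean(vals)) * 100.0


# ---------------------------------------------------------------------------
# non-maximum suppression


_DIR_OFFSETS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}  # (dy, dx) per bin


def _suppress_once(p: np.ndarray, sigma: float) -> np.ndarray:
    """One suppression pass: zero pixels not maximal across the local edge."""
    sm = gaussian_filter(p, sigma, mode="nearest")
    gy, gx = np.gradient(sm)
    # Structure tensor gives a robust across-edge orientation even on the
    # crest of a thin line, where the raw gradient vanishes.
    j11 = gaussian_filter(gx * gx, sigma, mode="nearest")
    j12 = gaussian_filter(gx * gy, sigma, mode="nearest")
    j22 = gaussian_filter(gy * gy, sigma, mode="nearest")
    angle = 0.5 * np.arctan2(2.0 * j12, j11 - j22)  # dominant variation direction
    bins = np.round(angle / (np.pi / 4.0)).astype(int) % 4

    padded = np.pad(p, 1, mode="constant")
    keep = np.zeros_like(p, dtype=bool)
    for b, (dy, dx) in _DIR_OFFSETS.items():
        n1 = padded[1 + dy : 1 + dy + p.shape[0], 1 + dx : 1 + dx + p.shape[1]]
        n2 = padded[1 - dy : 1 - dy + p.shape[0], 1 - dx : 1 - dx + p.shape[1]]
        keep |= (bins == b) & (p >= n1) & (p >= n2)
    return np.where(keep, p, 0.0)


def nms_thin(p: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Thin an edge-probability map by non-maximum suppression.

    Pixels that are not maximal along the across-edge direction (estimated
    from the structure tensor of the smoothed map) are suppressed. The pass
    is repeated until a fixed point is reached, which makes the operation
    idempotent by construction; in practice one or two passes suffice.
    """
    p = validate_probability_map(p)
    out = p
    for _ in range(max(1, p.size)):
        nxt = _suppress_once(out, sigma)
        if np.array_equal(nxt, out):
            break
        out = nxt
    return out


# ---------------------------------------------------------------------------
# threshold-sweep scores


def _f_measure(match: EdgeMatchResult) -> float:
    if match.count_X == 0 and match.count_Y == 0:
        return 1.0
    if match.TP == 0:
        return 0.0
    prec = match.TP / match.count_X
    rec = match.TP / match.count_Y
    return 2.0 * prec * rec / (prec + rec)


def ods_ois(
    predictions: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    thresholds: Sequence[float] | None = None,
    tol: float = 2.0,
) -> tuple[float, float]:
    """Best-threshold F-measures over a dataset of edge predictions.

    For each threshold the prediction is binarized and matched to the truth
    within ``tol`` pixels; the per-image F-measure is ``2PR/(P+R)``. The
    dataset score at a threshold is the mean over images of the per-image F
    (this aggregation makes ``OIS >= ODS`` hold unconditionally).

    Returns
    -------
    (ODS, OIS) : float pair
        ODS is the best single-threshold dataset score; OIS averages each
        image's own best-threshold score.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    if len(predictions) == 0:
        raise ValueError("need at least one image")
    if thresholds is None:
        thresholds = np.arange(1, 34) / 34.0  # 33 evenly spaced in (0, 1)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")

    f_table = np.zeros((len(predictions), len(thresholds)))
    for i, (pred, truth) in enumerate(zip(predictions, truths)):
        pred = validate_probability_map(pred)
        truth = validate_binary_map(truth)
        for j, t in enumerate(thresholds):
            match = match_edge_pixels((pred >= t).astype(float), truth, tol=tol)
            f_table[i, j] = _f_measure(match)
    ods = float(f_table.mean(axis=0).max())
    ois = float(f_table.max(axis=1).mean())
    return ods, ois
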