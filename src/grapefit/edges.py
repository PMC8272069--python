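"""Edge detection: class-imbalance-aware losses, a dense-side-output edge
network, multi-scale pyramid inference, and a classical fallback detector.

Probability maps are plain ``H x W`` float arrays with values in ``[0, 1]``;
ground-truth maps are binary ``{0, 1}`` arrays of the same shape. Losses are
implemented in the plain numeric layer so they are unit-testable without any
deep-learning framework; the network itself is a deterministic, seeded,
forward-only implementation with the same I/O contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import color, filters
from skimage.transform import resize

EPSILON = 1e-7

__all__ = [
    "EPSILON",
    "LossConfig",
    "NetworkSpec",
    "ImprovedHED",
    "validate_probability_map",
    "validate_binary_map",
    "weighted_cross_entropy",
    "dice_loss",
    "combined_loss",
    "combined_loss_grad",
    "build_improved_hed",
    "pyramid_predict",
    "fallback_edge_detector",
]


# ---------------------------------------------------------------------------
# map validation


def validate_probability_map(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError(f"probability map must be 2-D, got shape {p.shape}")
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    return p


def validate_binary_map(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    if g.ndim != 2:
        raise ValueError(f"ground-truth map must be 2-D, got shape {g.shape}")
    g = g.astype(float)
    if g.size and not np.all((g == 0.0) | (g == 1.0)):
        raise ValueError("ground-truth map must be binary")
    return g


def _check_same_shape(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")


# ---------------------------------------------------------------------------
# losses


@dataclass(frozen=True)
class LossConfig:
    """Mixing weight ``alpha`` for the combined loss and the numeric floor."""

    alpha: float = 0.6
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")


def weighted_cross_entropy(p: np.ndarray, g: np.ndarray, epsilon: float = EPSILON) -> float:
    """Class-balanced cross-entropy summed over pixels.

    ``L = -beta * sum_{edge} log p  -  (1 - beta) * sum_{non-edge} log(1 - p)``
    where ``beta`` is the per-image non-edge pixel fraction. Probabilities are
    clamped to ``[epsilon, 1 - epsilon]`` before taking logs. Note the
    degenerate all-background case (``beta = 1``) yields 0 by construction.
    """
    p = validate_probability_map(p)
    g = validate_binary_map(g)
    _check_same_shape(p, g)
    n = g.size
    if n == 0:
        return 0.0
    n_pos = float(g.sum())
    beta = (n - n_pos) / n
    pc = np.clip(p, epsilon, 1.0 - epsilon)
    pos_term = np.sum(np.log(pc)[g == 1.0])
    neg_term = np.sum(np.log1p(-pc)[g == 0.0])
    return float(-beta * pos_term - (1.0 - beta) * neg_term)


def dice_loss(p: np.ndarray, g: np.ndarray, epsilon: float = EPSILON) -> float:
    """Reciprocal soft-Dice loss ``(sum p^2 + sum g^2) / (2 sum p g)``.

    Stabilized by ``epsilon`` in numerator and denominator so the value is
    always finite and ``>= 1``, with equality iff ``p == g`` elementwise.
    """
    p = validate_probability_map(p)
    g = validate_binary_map(g)
    _check_same_shape(p, g)
    num = float(np.sum(p * p) + np.sum(g * g)) + epsilon
    den = 2.0 * float(np.sum(p * g)) + epsilon
    return num / den


def combined_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Convex combination ``alpha * dice + (1 - alpha) * weighted-CE``."""
    if cfg is None:
        cfg = LossConfig()
    return cfg.alpha * dice_loss(p, g, cfg.epsilon) + (1.0 - cfg.alpha) * weighted_cross_entropy(
        p, g, cfg.epsilon
    )


def combined_loss_grad(p: np.ndarray, g: np.ndarray, cfg: LossConfig | None = None) -> np.ndarray:
    """Analytic gradient of :func:`combined_loss` with respect to ``p``.

    Used by the training smoke path (gradient descent directly on the
    predicted map); pixels clamped by ``epsilon`` get zero cross-entropy
    gradient, matching the clamped forward value.
    """
    if cfg is None:
        cfg = LossConfig()
    p = validate_probability_map(p)
    g = validate_binary_map(g)
    _check_same_shape(p, g)
    eps = cfg.epsilon
    n = g.size
    n_pos = float(g.sum())
    beta = (n - n_pos) / n

    pc = np.clip(p, eps, 1.0 - eps)
    inside = (p > eps) & (p < 1.0 - eps)
    grad_ce = np.where(g == 1.0, -beta / pc, (1.0 - beta) / (1.0 - pc))
    grad_ce = np.where(inside, grad_ce, 0.0)

    num = float(np.sum(p * p) + np.sum(g * g)) + eps
    den = 2.0 * float(np.sum(p * g)) + eps
    grad_dice = (2.0 * p * den - 2.0 * g * num) / (den * den)

    return cfg.alpha * grad_dice + (1.0 - cfg.alpha) * grad_ce


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True)
class NetworkSpec:
    """Layout of the dense-side-output edge network.

    The backbone is a 13-conv-layer, five-stage VGG16-style stack. Stages in
    ``dense_side_stages`` route *every* conv layer of the stage through a
    1x1 side conv of depth ``side_channels``; the per-layer side maps are
    superimposed (channel concatenation by default, elementwise sum when
    ``merge='sum'``) and reduced by a 1x1 -> 1 conv. Remaining stages keep a
    single side output from their last conv layer. All stage maps are
    restored to input size by bilinear upsampling and fused by arithmetic
    mean in inference-only mode.
    """

    stage_convs: tuple[int, ...] = (2, 2, 3, 3, 3)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    dense_side_stages: frozenset[int] = frozenset({3, 4, 5})
    side_channels: int = 25
    merge: str = "concat"
    pyramid_scales: tuple[float, ...] = (0.5, 1.0, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_convs) != len(self.stage_channels):
            raise ValueError("stage_convs and stage_channels must have equal length")
        stages = set(range(1, len(self.stage_convs) + 1))
        if not set(self.dense_side_stages) <= stages:
            raise ValueError(f"dense_side_stages must be a subset of {sorted(stages)}")
        if self.side_channels < 1:
            raise ValueError("side_channels must be >= 1")
        if self.merge not in ("concat", "sum"):
            raise ValueError("merge must be 'concat' or 'sum'")


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 2-D convolution, x: (H, W, Cin), w: (kh, kw, Cin, Cout)."""
    kh, kw, cin, cout = w.shape
    if kh == 1 and kw == 1:
        return x @ w.reshape(cin, cout) + b
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((ph, ph), (pw, pw), (0, 0)), mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(0, 1))
    # win: (H, W, Cin, kh, kw) -> (H, W, kh*kw*Cin)
    h, wd = x.shape[:2]
    patches = win.transpose(0, 1, 3, 4, 2).reshape(h, wd, kh * kw * cin)
    return patches @ w.reshape(kh * kw * cin, cout) + b


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _bilinear(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == tuple(shape):
        return img
    return resize(img, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


class ImprovedHED:
    """Forward-only dense-side-output edge network with seeded weights.

    Calling the instance on an ``H x W x 3`` image returns the fused map;
    :meth:`predict` additionally returns the five per-stage maps. Inputs
    whose sides are not multiples of 32 are reflect-padded internally and
    the outputs cropped back.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self._weights: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        cin = 3
        for si, (n_convs, cout) in enumerate(zip(spec.stage_convs, spec.stage_channels), start=1):
            for li in range(n_convs):
                self._add_conv(rng, f"s{si}c{li}", 3, cin, cout)
                cin = cout
            if si in spec.dense_side_stages:
                for li in range(n_convs):
                    self._add_conv(rng, f"s{si}side{li}", 1, cout, spec.side_channels)
                fuse_in = (
                    spec.side_channels * n_convs if spec.merge == "concat" else spec.side_channels
                )
                self._add_conv(rng, f"s{si}fuse", 1, fuse_in, 1)
            else:
                self._add_conv(rng, f"s{si}fuse", 1, cout, 1)

    def _add_conv(self, rng: np.random.Generator, name: str, k: int, cin: int, cout: int) -> None:
        fan_in = k * k * cin
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(k, k, cin, cout))
        self._weights[name] = (w, np.zeros(cout))

    def predict(self, image: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return ``(side_maps, fused)``: five stage maps plus their mean."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
        h0, w0 = image.shape[:2]
        ph = (-h0) % 32
        pw = (-w0) % 32
        if ph or pw:
            image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")

        spec = self.spec
        x = image
        side_maps: list[np.ndarray] = []
        for si, n_convs in enumerate(spec.stage_convs, start=1):
            layer_outputs = []
            for li in range(n_convs):
                w, b = self._weights[f"s{si}c{li}"]
                x = np.maximum(_conv2d(x, w, b), 0.0)
                layer_outputs.append(x)
            if si in spec.dense_side_stages:
                sides = []
                for li, feat in enumerate(layer_outputs):
                    w, b = self._weights[f"s{si}side{li}"]
                    sides.append(_conv2d(feat, w, b))
                merged = np.concatenate(sides, axis=2) if spec.merge == "concat" else sum(sides)
                w, b = self._weights[f"s{si}fuse"]
                logit = _conv2d(merged, w, b)[..., 0]
            else:
                w, b = self._weights[f"s{si}fuse"]
                logit = _conv2d(layer_outputs[-1], w, b)[..., 0]
            side = _bilinear(_sigmoid(logit), image.shape[:2])
            side_maps.append(np.clip(side, 0.0, 1.0))
            if si < len(spec.stage_convs):  # 2x2 max pool between stages
                hh = x.shape[0] - x.shape[0] % 2
                ww = x.shape[1] - x.shape[1] % 2
                x = x[:hh, :ww].reshape(hh // 2, 2, ww // 2, 2, -1).max(axis=(1, 3))

        fused = np.mean(side_maps, axis=0)
        side_maps = [m[:h0, :w0] for m in side_maps]
        return side_maps, np.clip(fused[:h0, :w0], 0.0, 1.0)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.predict(image)[1]


def build_improved_hed(spec: NetworkSpec | None = None) -> ImprovedHED:
    """Construct the deterministic forward predictor for ``spec``."""
    return ImprovedHED(spec or NetworkSpec())


def pyramid_predict(image: np.ndarray, scales, predictor) -> np.ndarray:
    """Multi-scale prediction: resize, predict per scale, fuse by mean.

    ``predictor`` is any callable mapping an image to an ``H x W`` map in
    ``[0, 1]``; per-scale maps are bilinearly resized back to the input size
    before the pixelwise arithmetic mean.
    """
    scales = list(scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    maps = []
    for s in scales:
        hs, ws = max(1, round(h * s)), max(1, round(w * s))
        scaled = _bilinear(image, (hs, ws)) if (hs, ws) != (h, w) else image
        pred = np.asarray(predictor(scaled), dtype=float)
        maps.append(_bilinear(pred, (h, w)))
    fused = np.mean(maps, axis=0)
    return np.clip(fused, 0.0, 1.0)


def fallback_edge_detector(
    image: np.ndarray,
    sigma: float = 1.2,
    low: float = 0.08,
    high: float = 0.20,
) -> np.ndarray:
    """Classical gradient-magnitude edge detector with hysteresis gating.

    Lets the full two-step pipeline run when no trained network weights are
    available. The Gaussian-smoothed Sobel magnitude is normalized to
    ``[0, 1]`` and masked by hysteresis thresholding, so weak responses
    connected to strong ones survive while isolated noise is suppressed.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        if image.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count: {image.shape[2]}")
        gray = color.rgb2gray(image[..., :3])
    elif image.ndim == 2:
        gray = image
    else:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {image.shape}")
    smoothed = filters.gaussian(gray, sigma=sigma, preserve_range=True)
    mag = filters.sobel(smoothed)
    peak = mag.max()
    if peak <= 0.0:
        return np.zeros_like(mag)
    mag = mag / peak
    mask = filters.apply_hysteresis_threshold(mag, low, high)
    return np.clip(mag * mask, 0.0, 1.0)
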