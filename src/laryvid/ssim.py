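"""Structural Similarity Index (SSIM) between video frames.

SSIM compares two images through local luminance, contrast and structure
statistics rather than raw pixel differences, following the standard
formulation of Wang et al.:

    SSIM(x, y) = [(2 mu_x mu_y + C1)(2 sigma_xy + C2)]
                 / [(mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)]

evaluated per local window and mean-pooled. C1 = (K1 L)^2 and C2 = (K2 L)^2
stabilize near-zero denominators, with L the dynamic range (255 for 8-bit).
A score of 1 means the images are pixel-identical; the formula can in
principle be negative (down to -1) for anti-correlated structure, so no
clamping is applied.

This is the frame-similarity measure driving keyframe extraction: for an
endoscopic video, consecutive frames are usually near-identical (SSIM close
to 1) and a drop below a threshold marks a content change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageFrame",
    "SSIMParams",
    "SSIMResult",
    "as_frame",
    "to_grayscale",
    "ssim",
    "consecutive_ssim_trace",
]

#: BT.601 luma weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum spatial extent an ImageFrame must have on each axis.
MIN_FRAME_SIDE = 8


@dataclass(frozen=True)
class ImageFrame:
    """A single video frame.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB intensity grid with values
        in ``[0, dynamic_range]``.
    dynamic_range
        Maximum representable intensity ``L`` (255 for 8-bit material).
    frame_index
        Position of the frame in its source video (0-based).
    """

    pixels: np.ndarray
    dynamic_range: float = 255.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim not in (2, 3):
            raise ValueError(f"frame must be 2-D or 3-D, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise ValueError(f"frame must have 1 or 3 channels, got {px.shape[2]}")
        h, w = px.shape[:2]
        if h < MIN_FRAME_SIDE or w < MIN_FRAME_SIDE:
            raise ValueError(
                f"frame too small ({h}x{w}); each side must be >= {MIN_FRAME_SIDE}"
            )
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")
        lo, hi = float(px.min()), float(px.max())
        if lo < 0 or hi > self.dynamic_range:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.dynamic_range}]"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


def as_frame(x, dynamic_range: float = 255.0, frame_index: int = 0) -> ImageFrame:
    """Coerce an array (or ImageFrame) into an :class:`ImageFrame`."""
    if isinstance(x, ImageFrame):
        return x
    return ImageFrame(np.asarray(x), dynamic_range=dynamic_range, frame_index=frame_index)


@dataclass(frozen=True)
class SSIMParams:
    """Windowing and stabilization constants for the SSIM computation.

    Defaults follow the de facto reference configuration: 11x11 Gaussian
    window with sigma 1.5, K1 = 0.01, K2 = 0.03, L = 255.

    ``mode="windowed"`` computes the local SSIM map over all valid windows
    (no padding; the map is smaller than the image by ``window_size - 1``
    per axis) and mean-pools it. ``mode="global"`` treats the whole image as
    a single uniform window, which is convenient for very small test images.
    """

    window_size: int = 11
    window_kind: str = "gaussian"  # "uniform" | "gaussian"
    gaussian_sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    dynamic_range: float = 255.0
    mode: str = "windowed"  # "windowed" | "global"

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.window_kind not in ("uniform", "gaussian"):
            raise ValueError(f"unknown window_kind {self.window_kind!r}")
        if self.window_kind == "gaussian" and self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1 and K2 must be positive")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        if self.mode not in ("windowed", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def C1(self) -> float:
        return (self.K1 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.dynamic_range) ** 2

    def window_weights_1d(self) -> np.ndarray:
        """Normalized 1-D window weights (the 2-D window is separable)."""
        if self.window_kind == "uniform":
            w = np.ones(self.window_size)
        else:
            r = self.window_size // 2
            i = np.arange(-r, r + 1, dtype=float)
            w = np.exp(-(i**2) / (2.0 * self.gaussian_sigma**2))
        return w / w.sum()


@dataclass(frozen=True)
class SSIMResult:
    """Mean SSIM score plus the per-window SSIM map it was pooled from."""

    score: float
    map: np.ndarray | None = None


def to_grayscale(frame: ImageFrame) -> ImageFrame:
    """Convert a frame to single-channel grayscale via BT.601 luma weights.

    Single-channel input is returned unchanged (a trailing singleton channel
    axis is squeezed). The dynamic range and frame index are preserved.
    """
    frame = as_frame(frame)
    px = frame.pixels
    if px.ndim == 2:
        return frame
    if px.shape[2] == 1:
        return replace(frame, pixels=px[:, :, 0])
    if px.shape[2] != 3:
        raise ValueError(f"cannot convert {px.shape[2]}-channel frame to grayscale")
    gray = np.asarray(px, dtype=float) @ LUMA_WEIGHTS
    # Weighted sum of in-range values stays in range up to rounding noise.
    gray = np.clip(gray, 0.0, frame.dynamic_range)
    return replace(frame, pixels=gray)


def _weighted_local_means(img: np.ndarray, params: SSIMParams) -> np.ndarray:
    """Window-weighted local mean of ``img``, cropped to valid windows only."""
    w1 = params.window_weights_1d()
    out = ndimage.correlate1d(img, w1, axis=0, mode="constant")
    out = ndimage.correlate1d(out, w1, axis=1, mode="constant")
    r = params.window_size // 2
    return out[r:-r or None, r:-r or None]


def ssim(a, b, params: SSIMParams | None = None) -> SSIMResult:
    """Mean SSIM between two grayscale frames of identical shape.

    Local weighted moments are computed with a separable correlation and the
    SSIM formula is evaluated per valid window (variances are the weighted
    population moments, no Bessel correction, matching the reference
    formulation). The score is the arithmetic mean of the map.
    """
    if params is None:
        params = SSIMParams()
    fa, fb = as_frame(a), as_frame(b)
    if fa.pixels.ndim != 2 or fb.pixels.ndim != 2:
        raise ValueError("ssim expects grayscale frames; convert with to_grayscale")
    if fa.pixels.shape != fb.pixels.shape:
        raise ValueError(
            f"shape mismatch: {fa.pixels.shape} vs {fb.pixels.shape}"
        )
    x = np.asarray(fa.pixels, dtype=np.float64)
    y = np.asarray(fb.pixels, dtype=np.float64)
    C1, C2 = params.C1, params.C2

    if params.mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        s = ((2 * mx * my + C1) * (2 * cxy + C2)) / (
            (mx**2 + my**2 + C1) * (vx + vy + C2)
        )
        return SSIMResult(score=float(s), map=np.array([[s]]))

    if min(x.shape) < params.window_size:
        raise ValueError(
            f"image {x.shape} smaller than window ({params.window_size})"
        )
    mx = _weighted_local_means(x, params)
    my = _weighted_local_means(y, params)
    mxx = _weighted_local_means(x * x, params)
    myy = _weighted_local_means(y * y, params)
    mxy = _weighted_local_means(x * y, params)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    ssim_map = ((2 * mx * my + C1) * (2 * cxy + C2)) / (
        (mx * mx + my * my + C1) * (vx + vy + C2)
    )
    return SSIMResult(score=float(ssim_map.mean()), map=ssim_map)


def consecutive_ssim_trace(
    frames: Sequence, params: SSIMParams | None = None
) -> list[tuple[int, float]]:
    """SSIM between every pair of consecutive frames.

    Returns ``N - 1`` entries ``(i, score)`` where ``score`` compares frame
    ``i - 1`` with frame ``i``. Color frames are converted to grayscale
    first. This trace is what the keyframe threshold is applied to.
    """
    if params is None:
        params = SSIMParams()
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for a consecutive SSIM trace")
    grays = [to_grayscale(as_frame(f)) for f in frames]
    shapes = {g.pixels.shape for g in grays}
    if len(shapes) > 1:
        raise ValueError(f"frames have inconsistent shapes: {sorted(shapes)}")
    return [
        (i, ssim(grays[i - 1], grays[i], params).score)
        for i in range(1, len(grays))
    ]
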