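"""Synthetic laryngoscopy-like videos and labeled frame sets with ground truth.

Real endoscopic recordings are private, so the pipeline is exercised on
generated material engineered to reproduce the statistics the method
consumes rather than the anatomy: long runs of slowly drifting,
highly self-similar frames (consecutive SSIM near 1) punctuated by abrupt
scene changes (consecutive SSIM well below the working thresholds), and
three lesion classes whose morphology follows the clinical picture —
healthy cords carry no lesion, nodules appear as two small symmetric
blobs, and a polyp as a single larger unilateral mass.

Each frame is a smooth scene (radial illumination gradient plus a
band-limited texture field) with the class lesion added, advanced in time
by sub-pixel translation jitter, slight brightness flicker and per-frame
sensor noise. At each *event* index the scene content is rebuilt (fresh
texture, displaced illumination center, repositioned lesion), which stands
in for camera jumps and new clinical content. Default magnitudes were
fixed once by calibration so that, at defaults, non-event transitions
score SSIM > 0.98 and event transitions score SSIM < 0.90; the test suite
re-asserts this property rather than trusting the constants.

Everything is deterministic given the spec seed (bit-identical replays).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd
from scipy import ndimage

from .ssim import ImageFrame
from .video_io import MANIFEST_COLUMNS, DatasetManifest

__all__ = [
    "VideoSpec",
    "ClassSignature",
    "generate_video",
    "generate_classification_dataset",
    "write_synthetic_video",
    "CLASS_ORDER",
]

#: Canonical class order (label -> integer code).
CLASS_ORDER = ("healthy", "nodule", "polyp")

#: Multiplicative brightness-flicker std, as a fraction of drift_amplitude.
FLICKER_RATIO = 0.02

#: Std (gray levels) of the band-limited background texture field.
TEXTURE_STD = 10.0


@dataclass(frozen=True)
class VideoSpec:
    """Recipe for one synthetic video.

    ``drift_amplitude`` is the per-frame standard deviation (pixels) of the
    sub-pixel translation random walk; ``noise_sigma`` the per-frame
    additive Gaussian noise (gray levels on a 0–255 scale);
    ``event_magnitude`` the displacement (pixels) of the illumination
    center when the scene is rebuilt at an event. The 25 fps default
    matches the recording rate of the endoscopic material being emulated.
    """

    n_frames: int = 50
    fps: int = 25
    frame_size: tuple[int, int] = (64, 64)
    drift_amplitude: float = 0.05
    noise_sigma: float = 0.5
    event_indices: tuple[int, ...] = ()
    event_magnitude: float = 16.0
    class_label: str = "healthy"
    contrast: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.fps < 1:
            raise ValueError("fps must be positive")
        if min(self.frame_size) < 16:
            raise ValueError("frame_size sides must be >= 16")
        if self.drift_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("drift_amplitude and noise_sigma must be >= 0")
        if self.event_magnitude <= 0:
            raise ValueError("event_magnitude must be > 0")
        ev = tuple(int(i) for i in self.event_indices)
        object.__setattr__(self, "event_indices", ev)
        if any(i < 1 for i in ev):
            raise ValueError("event indices must be >= 1 (frame 0 opens the video)")
        if any(i >= self.n_frames for i in ev):
            raise ValueError("event index beyond the last frame")
        if list(ev) != sorted(set(ev)):
            raise ValueError("event_indices must be strictly increasing")
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class_label {self.class_label!r}")


@dataclass(frozen=True)
class ClassSignature:
    """Lesion descriptor for one class: blob centers, radii and amplitude.

    healthy carries no blobs; nodule two small blobs mirrored about the
    vertical midline at mid height; polyp one larger blob on a randomly
    chosen side. Centers are drawn within margins that keep every lesion
    pixel inside the frame.
    """

    class_label: str
    centers: tuple[tuple[float, float], ...]
    sigmas: tuple[float, ...]
    amplitude: float


def _draw_signature(
    label: str, rng: np.random.Generator, shape: tuple[int, int], contrast: float
) -> ClassSignature:
    h, w = shape
    if label == "healthy" or contrast == 0.0:
        return ClassSignature(label, (), (), 0.0)
    if label == "nodule":
        sig = 0.05 * min(h, w) + rng.uniform(0, 0.01 * min(h, w))
        row = h * rng.uniform(0.45, 0.55)
        off = w * rng.uniform(0.14, 0.20)
        centers = ((row, w / 2 - off), (row, w / 2 + off))
        return ClassSignature(label, centers, (sig, sig), contrast)
    if label == "polyp":
        sig = 0.11 * min(h, w) + rng.uniform(0, 0.02 * min(h, w))
        side = rng.choice([-1.0, 1.0])
        row = h * rng.uniform(0.45, 0.55)
        col = w / 2 + side * w * rng.uniform(0.15, 0.22)
        return ClassSignature(label, ((row, col),), (sig,), contrast)
    raise ValueError(f"unknown class_label {label!r}")


def _render_lesion(sig: ClassSignature, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    out = np.zeros((h, w))
    rr, cc = np.mgrid[0:h, 0:w]
    for (cy, cx), s in zip(sig.centers, sig.sigmas):
        out += sig.amplitude * np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * s**2)
        )
    return out


def _make_scene(
    rng: np.random.Generator,
    shape: tuple[int, int],
    class_label: str,
    contrast: float,
    center_shift: float = 0.0,
) -> np.ndarray:
    """Fresh scene content: illumination gradient + texture + class lesion."""
    h, w = shape
    # Event displacement keeps a minimum radius so every rebuilt scene is
    # guaranteed to differ structurally, not just in texture.
    angle = rng.uniform(0, 2 * np.pi)
    radius_px = center_shift * rng.uniform(0.6, 1.0)
    cy = h / 2 + radius_px * np.sin(angle)
    cx = w / 2 + radius_px * np.cos(angle)
    rr, cc = np.mgrid[0:h, 0:w]
    radius = np.hypot(rr - cy, cc - cx) / (0.75 * max(h, w))
    # Illumination level and falloff vary per scene, emulating exposure and
    # distance changes across camera jumps.
    level = rng.uniform(165.0, 215.0)
    falloff = rng.uniform(90.0, 130.0)
    gradient = level - falloff * np.clip(radius, 0, 1.2)
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), min(h, w) / 14)
    tstd = texture.std()
    if tstd > 0:
        texture *= TEXTURE_STD / tstd
    lesion = _render_lesion(
        _draw_signature(class_label, rng, (h, w), contrast), (h, w)
    )
    return np.clip(gradient + texture + lesion, 0.0, 255.0)


def generate_video(spec: VideoSpec) -> tuple[list[ImageFrame], tuple[int, ...]]:
    """Generate one synthetic video and its ground-truth event indices.

    With ``drift_amplitude = noise_sigma = 0`` and no events, every frame is
    identical. Otherwise, consecutive frames differ by the random-walk
    jitter, flicker and noise; at each event index the scene is rebuilt so
    the transition falls below the keyframe thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    scene = _make_scene(rng, (h, w), spec.class_label, spec.contrast)
    drift = np.zeros(2)
    flicker_sigma = FLICKER_RATIO * spec.drift_amplitude
    events = set(spec.event_indices)

    frames: list[ImageFrame] = []
    for t in range(spec.n_frames):
        if t in events:
            scene = _make_scene(
                rng, (h, w), spec.class_label, spec.contrast,
                center_shift=spec.event_magnitude,
            )
            drift = np.zeros(2)
        elif t > 0 and spec.drift_amplitude > 0:
            drift = drift + rng.normal(0, spec.drift_amplitude, 2)

        img = scene
        if np.any(drift != 0):
            img = ndimage.shift(scene, drift, order=1, mode="nearest")
        if flicker_sigma > 0:
            img = img * (1.0 + rng.normal(0, flicker_sigma))
        if spec.noise_sigma > 0:
            img = img + rng.normal(0, spec.noise_sigma, (h, w))
        frames.append(
            ImageFrame(np.clip(img, 0.0, 255.0), dynamic_range=255.0, frame_index=t)
        )
    return frames, spec.event_indices


def generate_classification_dataset(
    n_per_class: int,
    frame_size: tuple[int, int] = (32, 32),
    contrast: float = 80.0,
    seed: int = 0,
) -> tuple[list[ImageFrame], np.ndarray, DatasetManifest]:
    """Balanced three-class labeled image set with known class signatures.

    Lesion positions, sides and sizes are randomized per image within the
    class constraints; ``contrast = 0`` removes the lesions entirely so the
    classes become statistically indistinguishable (a chance-level
    control). Labels follow :data:`CLASS_ORDER` (healthy=0, nodule=1,
    polyp=2). The returned manifest uses virtual file paths (nothing is
    written to disk); each image is its own "patient".
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    rng = np.random.default_rng(seed)
    frames: list[ImageFrame] = []
    labels: list[int] = []
    rows = []
    for code, label in enumerate(CLASS_ORDER):
        for j in range(n_per_class):
            img = _make_scene(rng, frame_size, label, contrast)
            img = img + rng.normal(0, 1.0, frame_size)
            idx = len(frames)
            frames.append(
                ImageFrame(np.clip(img, 0, 255), dynamic_range=255.0, frame_index=idx)
            )
            labels.append(code)
            rows.append(
                dict(
                    file_path=f"synthetic://{label}/{j:06d}.png",
                    video_id=f"{label}_{j:04d}",
                    patient_id=f"{label}_{j:04d}",
                    class_label=label,
                    frame_index=idx,
                    split="none",
                )
            )
    manifest = DatasetManifest(
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS),
        dict(n_per_class=n_per_class, contrast=contrast, seed=seed),
    )
    return frames, np.asarray(labels), manifest


def write_synthetic_video(spec: VideoSpec, out_dir, video_id: str) -> Path:
    """Render a video to a PNG frame directory plus a ground-truth JSON.

    Frames are written as ``f<index, zero-padded to 6>.png`` so directory
    readers recover temporal order; the JSON records the event indices,
    class label and seed.
    """
    import imageio.v3 as iio

    out = Path(out_dir) / video_id
    out.mkdir(parents=True, exist_ok=True)
    frames, events = generate_video(spec)
    for fr in frames:
        px = np.clip(np.rint(fr.pixels), 0, 255).astype(np.uint8)
        iio.imwrite(out / f"f{fr.frame_index:06d}.png", px)
    gt = dict(
        video_id=video_id,
        event_indices=list(events),
        class_label=spec.class_label,
        seed=spec.seed,
        n_frames=spec.n_frames,
        fps=spec.fps,
    )
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    return out
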