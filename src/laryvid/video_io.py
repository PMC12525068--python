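"""Frame I/O, keyframe export, resizing and train/validation splitting.

Keyframe datasets are exported as lossless PNG files accompanied by a CSV
manifest mapping each file to its source video, patient, class label, frame
index and split assignment. The default split mirrors the study protocol:
a frame-level split stratified by class (80/20 by default). Because a
frame-level split can place frames of the same patient in both subsets, a
grouped mode that keeps each patient's frames together is provided as a
leakage-safe alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .keyframes import KeyframeSelection
from .ssim import ImageFrame, as_frame

__all__ = [
    "DatasetManifest",
    "read_frames",
    "export_keyframes",
    "resize_frame",
    "split_dataset",
]

MANIFEST_COLUMNS = [
    "file_path",
    "video_id",
    "patient_id",
    "class_label",
    "frame_index",
    "split",
]

CLASS_LABELS = ("healthy", "nodule", "polyp")
IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")
VIDEO_EXTENSIONS = (".mp4", ".avi", ".mov", ".mkv")


@dataclass(frozen=True)
class DatasetManifest:
    """Records mapping exported keyframe files to their provenance.

    ``records`` has the columns file_path, video_id, patient_id,
    class_label, frame_index, split (one of train/val/none). ``metadata``
    carries run provenance (threshold, SSIM parameters, seed).
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rec = self.records
        missing = [c for c in MANIFEST_COLUMNS if c not in rec.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if rec["file_path"].duplicated().any():
            dup = rec.loc[rec["file_path"].duplicated(), "file_path"].iloc[0]
            raise ValueError(f"duplicate file path in manifest: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def concat(self, other: "DatasetManifest") -> "DatasetManifest":
        rec = pd.concat([self.records, other.records], ignore_index=True)
        return DatasetManifest(rec, {**self.metadata, **other.metadata})

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)
        meta_path = Path(path).with_suffix(".meta.json")
        meta_path.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        records = pd.read_csv(path)
        meta_path = Path(path).with_suffix(".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(records, metadata)


def _read_image(path: Path, frame_index: int) -> ImageFrame:
    px = np.asarray(iio.imread(path))
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    return ImageFrame(px, dynamic_range=255.0, frame_index=frame_index)


def read_frames(source) -> list[ImageFrame]:
    """Read a video file or a directory of image frames.

    Directories are read in strict lexicographic order of their PNG/JPEG
    file names (the exporter zero-pads indices so this is temporal order).
    Video files are decoded through imageio when a codec-capable plugin is
    installed; otherwise an I/O error explains what is missing.
    """
    src = Path(source)
    if not src.exists():
        raise IOError(f"source does not exist: {src}")
    if src.is_dir():
        paths = sorted(
            p for p in src.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not paths:
            raise ValueError(f"directory contains no image frames: {src}")
        return [_read_image(p, i) for i, p in enumerate(paths)]
    if src.suffix.lower() in VIDEO_EXTENSIONS:
        try:
            frames = [
                ImageFrame(np.asarray(fr)[..., :3] if np.asarray(fr).ndim == 3 else np.asarray(fr),
                           dynamic_range=255.0, frame_index=i)
                for i, fr in enumerate(iio.imiter(src))
            ]
        except Exception as exc:  # pragma: no cover - depends on codec plugins
            raise IOError(
                f"could not decode video {src}: {exc}. Decoding {src.suffix} "
                "requires an imageio codec plugin (e.g. imageio-ffmpeg or "
                "pyav); alternatively supply a directory of PNG/JPEG frames."
            ) from exc
        if not frames:
            raise ValueError(f"video contains no frames: {src}")
        return frames
    return [_read_image(src, 0)]


def export_keyframes(
    frames: Sequence,
    selection: KeyframeSelection,
    out_dir,
    class_label: str,
    video_id: str,
    patient_id: str | None = None,
    *,
    image_format: str = "png",
    metadata: dict | None = None,
) -> DatasetManifest:
    """Write one image file per selected keyframe and return the manifest.

    File names are ``<video_id>_f<frame_index, zero-padded to 6>.png`` so a
    lexicographic listing preserves temporal order and video identity. PNG
    is the default because it is lossless (round trips are pixel-exact);
    JPEG is available via ``image_format="jpg"``.
    """
    frames = list(frames)
    if selection.n_total != len(frames):
        raise ValueError(
            f"selection covers {selection.n_total} frames but got {len(frames)}"
        )
    if image_format not in ("png", "jpg", "jpeg"):
        raise ValueError(f"unsupported image format {image_format!r}")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    rows = []
    for idx in selection.keyframe_indices:
        frame = as_frame(frames[idx], frame_index=idx)
        path = out / f"{video_id}_f{idx:06d}.{image_format}"
        px = np.asarray(frame.pixels)
        if not np.issubdtype(px.dtype, np.integer):
            px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
        else:
            px = px.astype(np.uint8)
        iio.imwrite(path, px)
        rows.append(
            dict(
                file_path=str(path),
                video_id=video_id,
                patient_id=patient_id if patient_id is not None else video_id,
                class_label=class_label,
                frame_index=idx,
                split="none",
            )
        )
    meta = dict(
        threshold=selection.threshold,
        n_total=selection.n_total,
        **(metadata or {}),
    )
    return DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), meta)


def resize_frame(frame, target: tuple[int, int]) -> ImageFrame:
    """Bilinear resize of a frame to ``target = (height, width)``.

    Output pixel centers are mapped linearly onto input pixel centers
    (coordinates clamped at the edges), and each output value is the
    bilinear interpolation of its four input neighbours, so a constant
    image stays constant and a same-size resize is the identity.
    """
    h, w = int(target[0]), int(target[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    frame = as_frame(frame)
    px = np.asarray(frame.pixels, dtype=float)
    if px.shape[:2] == (h, w):
        return replace(frame, pixels=frame.pixels)

    in_h, in_w = px.shape[:2]
    rows = (np.arange(h) + 0.5) * in_h / h - 0.5
    cols = (np.arange(w) + 0.5) * in_w / w - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr, cc])

    def _interp(channel: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(channel, coords, order=1, mode="nearest")

    if px.ndim == 2:
        out = _interp(px)
    else:
        out = np.stack([_interp(px[:, :, c]) for c in range(px.shape[2])], axis=2)
    out = np.clip(out, 0.0, frame.dynamic_range)
    return replace(frame, pixels=out)


def split_dataset(
    manifest: DatasetManifest,
    val_fraction: float = 0.2,
    seed: int = 0,
    group_by_patient: bool = False,
) -> DatasetManifest:
    """Assign each manifest record to the train or validation split.

    Default mode is a frame-level split stratified by class: within each
    class, ``round(n * val_fraction)`` frames are drawn at random for
    validation (so per-stratum counts are within one record of the
    requested ratio). Grouped mode instead assigns whole patients, so no
    patient's frames ever straddle the split. Both are deterministic given
    the seed.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    rng = np.random.default_rng(seed)
    records = manifest.records.copy()
    records["split"] = "train"

    for label, grp in records.groupby("class_label", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            continue
        if group_by_patient:
            patients = np.sort(grp["patient_id"].unique())
            n_val = int(round(len(patients) * val_fraction))
            chosen = rng.permutation(patients)[:n_val]
            mask = grp["patient_id"].isin(chosen)
            records.loc[grp.index[mask], "split"] = "val"
        else:
            n_val = int(round(len(grp) * val_fraction))
            chosen = rng.permutation(grp.index.to_numpy())[:n_val]
            records.loc[chosen, "split"] = "val"

    present = set(records["class_label"].unique())
    for label in CLASS_LABELS:
        if label not in present:
            warnings.warn(f"class {label!r} has no records; stratum skipped")

    meta = dict(
        manifest.metadata,
        val_fraction=val_fraction,
        split_seed=seed,
        group_by_patient=group_by_patient,
    )
    return DatasetManifest(records, meta)
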