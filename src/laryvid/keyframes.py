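"""Keyframe selection by thresholding consecutive-frame SSIM.

A laryngoscopy video at 25 fps is dominated by near-duplicate frames; the
summarization step keeps only frames that differ structurally from their
predecessor. Frame ``i`` (``i >= 1``) is a keyframe iff the SSIM between
frames ``i-1`` and ``i`` is strictly below the threshold; frame 0 always
seeds the selection so every summary is non-empty. Raising the threshold
keeps more frames: selections are nested across thresholds, which is the
qualitative pattern expected of the per-threshold count table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ssim import SSIMParams, consecutive_ssim_trace

__all__ = [
    "KeyframeSelection",
    "SummaryReport",
    "select_from_trace",
    "extract_keyframes",
    "threshold_sweep",
    "DEFAULT_THRESHOLDS",
]

#: Default summarization thresholds (fractions; "90%" maps to 0.90).
DEFAULT_THRESHOLDS = (0.90, 0.95, 0.98)


@dataclass(frozen=True)
class KeyframeSelection:
    """Result of thresholding one video's consecutive-SSIM trace.

    ``keyframe_indices`` is strictly increasing, always contains 0, and for
    ``i >= 1`` contains ``i`` exactly when ``ssim_trace[i-1] < threshold``
    (strict: a score exactly equal to the threshold is *not* a keyframe).
    """

    threshold: float
    keyframe_indices: tuple[int, ...]
    n_total: int
    ssim_trace: tuple[float, ...]

    @property
    def n_keyframes(self) -> int:
        return len(self.keyframe_indices)

    @property
    def eliminated_indices(self) -> tuple[int, ...]:
        kept = set(self.keyframe_indices)
        return tuple(i for i in range(self.n_total) if i not in kept)

    @property
    def reduction_fraction(self) -> float:
        """Fraction of frames eliminated: ``1 - kept / total``."""
        return 1.0 - self.n_keyframes / self.n_total


def _check_threshold(threshold: float) -> None:
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")


def select_from_trace(
    trace: Sequence[float], n_total: int, threshold: float
) -> KeyframeSelection:
    """Apply the keyframe rule to an already-computed SSIM trace."""
    _check_threshold(threshold)
    scores = [float(s) for s in trace]
    if len(scores) != n_total - 1:
        raise ValueError(
            f"trace length {len(scores)} inconsistent with {n_total} frames"
        )
    indices = [0] + [i for i in range(1, n_total) if scores[i - 1] < threshold]
    return KeyframeSelection(
        threshold=float(threshold),
        keyframe_indices=tuple(indices),
        n_total=n_total,
        ssim_trace=tuple(scores),
    )


def extract_keyframes(
    frames: Sequence,
    threshold: float,
    params: SSIMParams | None = None,
    *,
    compare_to_last_keyframe: bool = False,
) -> KeyframeSelection:
    """Select keyframes from a frame sequence at one SSIM threshold.

    Each frame is compared to the immediately preceding *raw* frame. The
    optional ``compare_to_last_keyframe`` mode compares against the most
    recently selected keyframe instead; it accumulates drift differently
    and is provided as an alternative semantics, not the default.

    A single-frame input yields the selection ``[0]``.
    """
    _check_threshold(threshold)
    frames = list(frames)
    if not frames:
        raise ValueError("cannot extract keyframes from an empty frame sequence")
    if params is None:
        params = SSIMParams()
    if len(frames) == 1:
        return KeyframeSelection(float(threshold), (0,), 1, ())

    if not compare_to_last_keyframe:
        trace = [s for _, s in consecutive_ssim_trace(frames, params)]
        return select_from_trace(trace, len(frames), threshold)

    from .ssim import as_frame, ssim, to_grayscale

    grays = [to_grayscale(as_frame(f)) for f in frames]
    indices = [0]
    scores: list[float] = []
    anchor = grays[0]
    for i in range(1, len(grays)):
        s = ssim(anchor, grays[i], params).score
        scores.append(s)
        if s < threshold:
            indices.append(i)
            anchor = grays[i]
    return KeyframeSelection(
        float(threshold), tuple(indices), len(frames), tuple(scores)
    )


@dataclass(frozen=True)
class SummaryReport:
    """Per-threshold, per-class keyframe counts and reduction fractions.

    One row per (threshold, class) plus a ``total`` row per threshold, with
    columns: threshold, class, n_videos, n_frames_total, n_keyframes,
    reduction_fraction.
    """

    table: pd.DataFrame

    def to_csv(self, path_or_buf=None) -> str | None:
        return self.table.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "SummaryReport":
        return cls(pd.read_csv(path_or_buf))

    def totals(self) -> pd.DataFrame:
        """The per-threshold ``total`` rows, sorted by threshold."""
        t = self.table[self.table["class"] == "total"]
        return t.sort_values("threshold").reset_index(drop=True)


def threshold_sweep(
    frames_by_class: Mapping[str, Sequence[Sequence]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    params: SSIMParams | None = None,
) -> SummaryReport:
    """Summarize a labeled video cohort at several SSIM thresholds.

    Each video's consecutive-SSIM trace is computed once and reused across
    all thresholds. Returns per-class and total keyframe counts per
    threshold; counts are monotone non-decreasing in the threshold because
    selections are nested.
    """
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("thresholds list must be non-empty")
    for t in thresholds:
        _check_threshold(t)
    if params is None:
        params = SSIMParams()

    traces: dict[str, list[tuple[list[float], int]]] = {}
    for label, videos in frames_by_class.items():
        traces[label] = []
        for video in videos:
            video = list(video)
            if not video:
                raise ValueError(f"class {label!r} contains an empty video")
            if len(video) == 1:
                traces[label].append(([], 1))
            else:
                tr = [s for _, s in consecutive_ssim_trace(video, params)]
                traces[label].append((tr, len(video)))

    rows = []
    for t in sorted(thresholds):
        total_frames = total_keep = total_videos = 0
        for label, video_traces in traces.items():
            n_frames = n_keep = 0
            for tr, n in video_traces:
                sel = select_from_trace(tr, n, t)
                n_frames += n
                n_keep += sel.n_keyframes
            rows.append(
                dict(
                    threshold=t,
                    **{"class": label},
                    n_videos=len(video_traces),
                    n_frames_total=n_frames,
                    n_keyframes=n_keep,
                    reduction_fraction=1.0 - n_keep / n_frames,
                )
            )
            total_frames += n_frames
            total_keep += n_keep
            total_videos += len(video_traces)
        rows.append(
            dict(
                threshold=t,
                **{"class": "total"},
                n_videos=total_videos,
                n_frames_total=total_frames,
                n_keyframes=total_keep,
                reduction_fraction=1.0 - total_keep / total_frames,
            )
        )
    return SummaryReport(pd.DataFrame(rows))
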