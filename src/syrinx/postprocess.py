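"""Convert per-time-bin network scores into clean annotations.

The pipeline is: argmax over classes per time bin; recovery of
background-delimited runs of syllable labels; removal of runs shorter
than a minimum duration (their bins become background); then a majority
vote that assigns each surviving run the single most frequent
non-background label, overriding any others.  The vote never moves
segment boundaries, and the duration filter never creates segments.

Also provides the per-bin likelihood normalization used to inspect model
outputs: subtract each time bin's minimum score and normalize the column
to sum to one (argmax-preserving).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import Annotation, Segment
from .dataset import BACKGROUND, frame_labels_to_segments

__all__ = [
    "PostprocessConfig",
    "argmax_labels",
    "postprocess",
    "segments_raw",
    "frame_likelihoods",
    "default_min_segment_dur",
]


def default_min_segment_dur(annotations) -> float:
    """Default minimum segment duration: half the 10th percentile of the
    corpus's syllable durations — ties the user knob to measurable data."""
    durations = [d for ann in annotations for d in ann.durations_s]
    if not durations:
        raise ValueError("no segments to estimate a minimum duration from")
    return float(np.percentile(durations, 10.0) / 2.0)


@dataclass(frozen=True)
class PostprocessConfig:
    """min_segment_dur_s: segments shorter than this are discarded;
    majority_vote: assign each segment its modal non-background label."""

    min_segment_dur_s: float = 0.0
    majority_vote: bool = True

    def __post_init__(self) -> None:
        if self.min_segment_dur_s < 0:
            raise ValueError("min_segment_dur_s must be >= 0")


def argmax_labels(scores: np.ndarray) -> np.ndarray:
    """Class with the highest score per time bin; (C, T) -> (T,).

    Ties break toward the lowest class index (the background class when it
    is involved)."""
    scores = np.asarray(scores)
    return scores.argmax(axis=0)


def _majority_label(bin_labels: np.ndarray) -> int:
    """Modal non-background label; ties go to the earliest-occurring label
    in the segment."""
    non_bg = bin_labels[bin_labels != BACKGROUND]
    if len(non_bg) == 0:
        return BACKGROUND
    values, counts = np.unique(non_bg, return_counts=True)
    best = counts.max()
    winners = set(values[counts == best].tolist())
    for lab in non_bg:
        if int(lab) in winners:
            return int(lab)
    raise AssertionError("unreachable")


def postprocess(
    y: np.ndarray,
    t: np.ndarray,
    bin_dur_s: float,
    labelmap,
    cfg: PostprocessConfig = PostprocessConfig(),
) -> Annotation:
    """Frame labels -> cleaned Annotation (single pass, in this order:
    run recovery, minimum-duration discard, majority vote)."""
    runs = frame_labels_to_segments(y, t, bin_dur_s)
    segments = []
    for run in runs:
        if run.offset_s - run.onset_s < cfg.min_segment_dur_s - 1e-12:
            continue
        if cfg.majority_vote:
            cls = _majority_label(run.bin_labels)
        else:
            cls = int(run.bin_labels[0])
        if cls == BACKGROUND:
            continue
        segments.append(
            Segment(run.onset_s, run.offset_s, labelmap.to_label(cls))
        )
    return Annotation(segments)


def segments_raw(
    y: np.ndarray, t: np.ndarray, bin_dur_s: float
) -> list[tuple[float, float, int]]:
    """Segments implied by the frame labels *without* post-processing:
    each maximal run of one constant non-background label is a segment.

    This is the sequence the raw (un-post-processed) syllable error rate
    is computed on: a label flip inside a syllable splits it into several
    segments here, whereas the majority vote in :func:`postprocess` would
    repair it."""
    y = np.asarray(y)
    out: list[tuple[float, float, int]] = []
    start = None
    for i in range(len(y)):
        if start is not None and (y[i] != y[start]):
            if y[start] != BACKGROUND:
                out.append((float(t[start]), float(t[i - 1] + bin_dur_s), int(y[start])))
            start = None
        if start is None and y[i] != BACKGROUND:
            start = i
    if start is not None:
        out.append((float(t[start]), float(t[len(y) - 1] + bin_dur_s), int(y[start])))
    return out


def frame_likelihoods(scores: np.ndarray) -> np.ndarray:
    """Normalize raw class scores to per-bin likelihoods.

    Per time bin: subtract the column minimum and divide by the sum, so
    columns are nonnegative and sum to one while preserving the argmax.
    An all-equal column (no information) maps to the uniform distribution.
    """
    a = np.asarray(scores, dtype=float)
    shifted = a - a.min(axis=0, keepdims=True)
    sums = shifted.sum(axis=0, keepdims=True)
    c = a.shape[0]
    uniform = np.full_like(a, 1.0 / c)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = shifted / sums
    return np.where(sums > 0, normalized, uniform)
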