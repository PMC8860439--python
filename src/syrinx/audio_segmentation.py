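"""Classic amplitude-threshold segmentation of song and its parameter estimation.

The widely used segmentation algorithm finds all periods where a smoothed
amplitude envelope stays above a threshold, removes inter-segment silent
intervals shorter than a minimum (merging their neighbors), and finally
discards segments shorter than a minimum syllable duration — in that order.

The amplitude computation itself is a lab-convention "dialect knob": here
the envelope is the rectified signal smoothed with a moving average
(default 2 ms window); both the window and the rectification are
configurable via :func:`compute_envelope`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import Annotation

__all__ = [
    "SegParams",
    "Envelope",
    "compute_envelope",
    "segment_audio",
    "estimate_seg_params",
]


@dataclass(frozen=True)
class SegParams:
    """Parameters of the threshold segmentation algorithm.

    threshold
        amplitude threshold, in envelope units.
    min_silent_interval_s
        silent intervals shorter than this are removed, merging neighbors.
    min_syllable_dur_s
        remaining segments shorter than this are discarded.
    """

    threshold: float
    min_silent_interval_s: float
    min_syllable_dur_s: float

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.min_silent_interval_s <= 0 or self.min_syllable_dur_s <= 0:
            raise ValueError("all segmentation parameters must be positive")


@dataclass
class Envelope:
    """Nonnegative amplitude series sampled at ``fs_env`` Hz."""

    values: np.ndarray
    fs_env: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("envelope must be non-empty")
        if (self.values < 0).any():
            raise ValueError("envelope values must be nonnegative")


def compute_envelope(
    waveform: np.ndarray, fs: float, smooth_win_s: float = 0.002
) -> Envelope:
    """Rectify-and-smooth amplitude envelope, same length as the waveform.

    The absolute value of the signal is smoothed with a centered moving
    average of ``smooth_win_s`` seconds.  Homogeneous of degree 1: scaling
    the waveform scales the envelope by the same factor.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("waveform must be non-empty")
    rect = np.abs(waveform)
    win = max(1, round(smooth_win_s * fs))
    kernel = np.ones(win) / win
    smoothed = np.convolve(rect, kernel, mode="same")
    return Envelope(values=smoothed, fs_env=fs)


def _above_threshold_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts.tolist(), stops.tolist()))


def segment_audio(env: Envelope, p: SegParams) -> list[tuple[float, float]]:
    """Segment an envelope into (onset_s, offset_s) intervals.

    Boundary convention: onset is the time of the first sample above
    threshold; offset is the time of the last sample above threshold plus
    one sample period (half-open in samples, reported in seconds).
    """
    runs = _above_threshold_runs(env.values > p.threshold)
    # 1) merge across silent intervals shorter than the minimum
    min_gap = p.min_silent_interval_s * env.fs_env
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) < min_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    # 2) then discard segments shorter than the minimum duration
    min_dur = p.min_syllable_dur_s * env.fs_env
    kept = [(a, b) for a, b in merged if (b - a) >= min_dur]
    return [(a / env.fs_env, b / env.fs_env) for a, b in kept]


def estimate_seg_params(
    corpus: list[tuple[Envelope, Annotation]],
) -> tuple[SegParams, dict[str, np.ndarray]]:
    """Estimate segmentation parameters from annotated song.

    Following the standard recipe: the threshold is the median envelope
    value at all ground-truth syllable onsets and offsets; the minimum
    syllable duration is the 10th percentile of syllable durations; the
    minimum silent interval is the 0.1th percentile of inter-syllable gaps.
    Percentiles use linear interpolation between order statistics
    (:func:`numpy.percentile` default) — relevant because the 0.1th
    percentile is extreme-tail sensitive.

    Returns the parameters and the three underlying empirical distributions
    (``boundary_amplitudes``, ``durations_s``, ``gaps_s``) for visual
    validation.
    """
    boundary_amps: list[float] = []
    durations: list[float] = []
    gaps: list[float] = []
    for env, ann in corpus:
        n = len(env.values)
        for seg in ann:
            onset_i = min(n - 1, round(seg.onset_s * env.fs_env))
            offset_i = min(n - 1, round(seg.offset_s * env.fs_env))
            boundary_amps.append(env.values[onset_i])
            boundary_amps.append(env.values[offset_i])
        durations.extend(ann.durations_s)
        gaps.extend(ann.gaps_s)
    if not durations:
        raise ValueError("corpus contains no annotated segments")
    if not gaps:
        raise ValueError(
            "corpus contains no silent intervals between segments; "
            "cannot take a percentile of gaps"
        )
    params = SegParams(
        threshold=float(np.median(boundary_amps)),
        min_silent_interval_s=float(np.percentile(gaps, 0.1)),
        min_syllable_dur_s=float(np.percentile(durations, 10.0)),
    )
    dists = {
        "boundary_amplitudes": np.asarray(boundary_amps),
        "durations_s": np.asarray(durations),
        "gaps_s": np.asarray(gaps),
    }
    return params, dists
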