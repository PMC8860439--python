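"""Spectrograms, normalization, frame labels, and the training window sampler.

Conventions used throughout the package:

* A spectrogram time bin ``i`` covers the half-open interval
  ``[t[i], t[i] + bin_dur_s)``; ``t[i] = i * step / fs`` marks the bin
  start.  Bin membership of an annotated segment is decided by the bin
  *center*, so onset and offset rounding are treated symmetrically.
* The background class (silent gaps, noises, non-song calls) always has
  integer index 0; syllable classes are 1..C-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .annotation import Annotation

__all__ = [
    "Spectrogram",
    "LabelMap",
    "Normalizer",
    "FrameSegment",
    "compute_spectrogram",
    "fit_normalizer",
    "apply_normalizer",
    "annotation_to_frame_labels",
    "frame_labels_to_segments",
    "WindowSampler",
]

#: time bins per window shown to the network, per species mode
DEFAULT_WINDOW_BINS = {"finch": 176, "canary": 370}

#: STFT parameters per species mode (number of FFT samples, hop in samples)
DEFAULT_STFT = {"finch": (512, 64), "canary": (1024, 119)}

BACKGROUND = 0


@dataclass
class Spectrogram:
    """Power spectrogram: ``s`` is (F frequency bins x T time bins)."""

    s: np.ndarray
    f: np.ndarray
    t: np.ndarray
    bin_dur_s: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.s.shape != (len(self.f), len(self.t)):
            raise ValueError(
                f"spectrogram shape {self.s.shape} does not match axes "
                f"({len(self.f)} frequencies, {len(self.t)} times)"
            )

    @property
    def n_freq(self) -> int:
        return self.s.shape[0]

    @property
    def n_time(self) -> int:
        return self.s.shape[1]

    def save(self, path) -> None:
        """Array archive with keys ``s``, ``f``, ``t`` (+ ``bin_dur_s``)."""
        np.savez(path, s=self.s, f=self.f, t=self.t, bin_dur_s=self.bin_dur_s)

    @classmethod
    def load(cls, path) -> "Spectrogram":
        with np.load(path) as z:
            return cls(s=z["s"], f=z["f"], t=z["t"], bin_dur_s=float(z["bin_dur_s"]))


def compute_spectrogram(
    waveform: np.ndarray,
    fs: float,
    nfft: int = 512,
    step: int = 64,
    threshold: float | None = None,
) -> Spectrogram:
    """STFT power spectrogram with Hann window.

    Produces ``T = floor((len - nfft) / step) + 1`` time bins of duration
    ``step / fs`` seconds and ``F = nfft // 2 + 1`` frequency bins.

    ``threshold``: optional floor applied to the power matrix (values below
    it set to 0).  Off by default — thresholding spectrograms slightly
    increases error rates and destabilizes training.
    """
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) < nfft:
        raise ValueError(
            f"waveform has {len(waveform)} samples, shorter than nfft={nfft}"
        )
    f, _, s = sps.spectrogram(
        waveform,
        fs=fs,
        window="hann",
        nperseg=nfft,
        noverlap=nfft - step,
        detrend=False,
        mode="psd",
    )
    T = (len(waveform) - nfft) // step + 1
    assert s.shape == (nfft // 2 + 1, T)
    bin_dur = step / fs
    t = np.arange(T) * bin_dur
    if threshold is not None:
        s = np.where(s < threshold, 0.0, s)
    return Spectrogram(s=s, f=f, t=t, bin_dur_s=bin_dur)


@dataclass
class LabelMap:
    """Bijection between syllable label strings and integer classes.

    Index 0 is reserved for the background class; syllable labels get
    1..C-1 in the given order.
    """

    labels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def background_class(self) -> int:
        return BACKGROUND

    @property
    def n_classes(self) -> int:
        """Syllable classes plus the background class."""
        return len(self.labels) + 1

    def to_index(self, label: str) -> int:
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"label {label!r} not in label map {self.labels}") from None

    def to_label(self, index: int) -> str:
        if index == BACKGROUND:
            raise ValueError("background class has no syllable label")
        return self.labels[index - 1]

    def to_json(self) -> str:
        return json.dumps({"labels": self.labels, "background_class": BACKGROUND})

    @classmethod
    def from_json(cls, text: str) -> "LabelMap":
        obj = json.loads(text)
        if obj.get("background_class", BACKGROUND) != BACKGROUND:
            raise ValueError("background class index must be 0")
        return cls(labels=list(obj["labels"]))


@dataclass
class Normalizer:
    """Per-frequency-bin standardization fitted on a training set."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive (flooring happens at fit time)")


SIGMA_FLOOR = 1e-6


def fit_normalizer(spectrograms: list[Spectrogram]) -> Normalizer:
    """Mean and s.d. of every frequency bin across all training spectrograms.

    Standard deviations below ``SIGMA_FLOOR`` (silent frequency bins) are
    floored so that applying the normalizer never divides by zero.
    """
    if not spectrograms:
        raise ValueError("need at least one training spectrogram")
    stacked = np.concatenate([sp.s for sp in spectrograms], axis=1)
    mu = stacked.mean(axis=1)
    sigma = stacked.std(axis=1)
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return Normalizer(mu=mu, sigma=sigma)


def apply_normalizer(norm: Normalizer, spect: Spectrogram) -> Spectrogram:
    s = (spect.s - norm.mu[:, None]) / norm.sigma[:, None]
    return Spectrogram(s=s, f=spect.f, t=spect.t, bin_dur_s=spect.bin_dur_s)


def annotation_to_frame_labels(
    annotation: Annotation, t: np.ndarray, bin_dur_s: float, labelmap: LabelMap
) -> np.ndarray:
    """Integer class per time bin; bins outside any segment are background.

    A bin belongs to a segment when its center ``t + bin_dur/2`` falls in
    ``[onset, offset)``.
    """
    t = np.asarray(t, dtype=float)
    y = np.full(len(t), BACKGROUND, dtype=np.int64)
    centers = t + bin_dur_s / 2.0
    for seg in annotation:
        cls = labelmap.to_index(seg.label)
        y[(centers >= seg.onset_s) & (centers < seg.offset_s)] = cls
    return y


@dataclass
class FrameSegment:
    """A maximal run of non-background bins, carrying its per-bin labels.

    Collapsing the per-bin labels to a single class (majority vote) is the
    post-processing stage's job, not the run recovery's.
    """

    onset_s: float
    offset_s: float
    bin_labels: np.ndarray
    start_bin: int
    stop_bin: int  # exclusive


def frame_labels_to_segments(
    y: np.ndarray, t: np.ndarray, bin_dur_s: float
) -> list[FrameSegment]:
    """Maximal runs of non-background bins, background-delimited.

    Onset is the start bin's time; offset is the end bin's time plus one
    bin duration.
    """
    y = np.asarray(y)
    t = np.asarray(t, dtype=float)
    if len(y) != len(t):
        raise ValueError(f"labels ({len(y)}) and time axis ({len(t)}) differ in length")
    mask = y != BACKGROUND
    segments: list[FrameSegment] = []
    if not mask.any():
        return segments
    diff = np.diff(mask.astype(np.int8))
    starts = (np.flatnonzero(diff == 1) + 1).tolist()
    stops = (np.flatnonzero(diff == -1) + 1).tolist()
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [len(y)]
    for a, b in zip(starts, stops):
        segments.append(
            FrameSegment(
                onset_s=float(t[a]),
                offset_s=float(t[b - 1] + bin_dur_s),
                bin_labels=y[a:b].copy(),
                start_bin=a,
                stop_bin=b,
            )
        )
    return segments


class WindowSampler:
    """Random non-repeating (window, frame-label) batch sampler.

    Enumerates every possible start bin of every spectrogram; within one
    epoch no (spectrogram, start-bin) pair repeats, and the order is a
    deterministic function of ``(seed, epoch)``: two samplers built with
    the same seed yield the same windows in the same order.
    """

    def __init__(
        self,
        data: list[tuple[Spectrogram, np.ndarray]],
        window_size_bins: int,
        batch_size: int,
        seed: int,
        names: list[str] | None = None,
    ) -> None:
        if names is None:
            names = [f"spectrogram[{i}]" for i in range(len(data))]
        too_short = [
            name
            for name, (sp, _) in zip(names, data)
            if sp.n_time < window_size_bins
        ]
        if too_short:
            raise ValueError(
                f"spectrograms shorter than window ({window_size_bins} bins): "
                f"{too_short}"
            )
        for sp, y in data:
            if len(y) != sp.n_time:
                raise ValueError("frame labels do not match spectrogram time axis")
        self.data = data
        self.window = window_size_bins
        self.batch_size = batch_size
        self.seed = seed
        self.index = [
            (i, start)
            for i, (sp, _) in enumerate(data)
            for start in range(sp.n_time - window_size_bins + 1)
        ]

    @property
    def windows_per_epoch(self) -> int:
        return len(self.index)

    def epoch_order(self, epoch: int) -> list[tuple[int, int]]:
        rng = np.random.default_rng([self.seed, epoch])
        perm = rng.permutation(len(self.index))
        return [self.index[j] for j in perm]

    def batches(self, epoch: int = 0):
        """Yield (x, y) batches: x is (B, 1, F, W), y is (B, W)."""
        order = self.epoch_order(epoch)
        for i in range(0, len(order), self.batch_size):
            chunk = order[i: i + self.batch_size]
            xs, ys = [], []
            for spec_i, start in chunk:
                sp, y = self.data[spec_i]
                xs.append(sp.s[None, :, start: start + self.window])
                ys.append(y[start: start + self.window])
            yield np.stack(xs), np.stack(ys)

    def infinite_batches(self):
        """Batches across epochs, reshuffling each epoch, never repeating
        a window within an epoch."""
        epoch = 0
        while True:
            yield from self.batches(epoch)
            epoch += 1
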