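"""Seeded generator of songbird-like audio corpora with exact ground truth.

Synthesizes song bouts as sequences of harmonic-stack syllables separated by
short silent gaps, following a (variable-order) Markov syntax over syllable
labels.  The generator emulates the statistical structure that makes
automated annotation hard in real recordings:

* class-specific spectro-temporal templates (fundamental, harmonics,
  amplitude envelope),
* wide within-bout amplitude variation across classes, so that no single
  amplitude threshold segments every syllable,
* short silent gaps between syllables,
* non-song noise events (broadband clicks) in the silent intervals,
* first-order branch points and canary-like phrase structure (trilled
  repeats, higher-order phrase-transition dependencies).

All randomness flows through explicitly passed :class:`numpy.random.Generator`
instances; identical seeds give byte-identical corpora.  Ground-truth times
are quantized to whole milliseconds so that annotations survive the
millisecond-precision CSV dialect exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .annotation import Annotation, Segment, read_annotation, write_annotation

__all__ = [
    "END",
    "SyllableTemplate",
    "SyntaxModel",
    "CorpusSpec",
    "generate_song",
    "generate_corpus",
    "read_corpus",
    "make_branchpoint_syntax",
    "make_canary_syntax",
    "make_linear_syntax",
    "default_templates",
    "sample_sequences",
]

#: reserved end-of-song symbol in next-symbol distributions
END = "<END>"

_ENVELOPE_SHAPES = ("flat", "ramp", "bell")

#: ground-truth time quantum (s); keeps annotations exact in ms-precision CSV
_QUANTUM_S = 1e-3


@dataclass(frozen=True)
class SyllableTemplate:
    """Acoustic template for one syllable class.

    The rendered syllable is a stack of ``n_harmonics`` harmonics of
    ``f0_hz`` with 1/k amplitude roll-off, shaped by one of three amplitude
    envelopes and scaled by ``rel_amplitude`` (linear gain; spanning these
    across classes reproduces the wide amplitude variation of real song).
    """

    label: str
    duration_mean_s: float
    duration_sd_s: float
    f0_hz: float
    n_harmonics: int = 3
    am_envelope: str = "flat"
    rel_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_mean_s <= 0:
            raise ValueError("duration_mean_s must be positive")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.am_envelope not in _ENVELOPE_SHAPES:
            raise ValueError(
                f"am_envelope must be one of {_ENVELOPE_SHAPES}, got {self.am_envelope!r}"
            )
        if self.rel_amplitude <= 0:
            raise ValueError("rel_amplitude must be positive")

    def validate_against_fs(self, fs: float) -> None:
        if self.f0_hz * self.n_harmonics >= fs / 2:
            raise ValueError(
                f"template {self.label!r}: highest harmonic "
                f"{self.f0_hz * self.n_harmonics} Hz exceeds Nyquist ({fs / 2} Hz)"
            )


@dataclass
class SyntaxModel:
    """Variable-order Markov model over single-character syllable labels.

    ``contexts`` maps a history suffix (most recent symbol last, ``""`` for
    the unconditional distribution) to a next-symbol distribution over
    ``labels`` and :data:`END`.  Sequences implicitly start with
    ``start_symbol``; when emitting, the longest context matching the
    current history is used.
    """

    labels: list[str]
    contexts: dict[str, dict[str, float]]
    start_symbol: str = "S"

    def __post_init__(self) -> None:
        if any(len(lab) != 1 for lab in self.labels):
            raise ValueError("syntax labels must be single characters")
        if self.start_symbol in self.labels:
            raise ValueError("start_symbol must not be a syllable label")
        symbols = set(self.labels) | {END}
        end_reachable = False
        for ctx, dist in self.contexts.items():
            unknown = set(dist) - symbols
            if unknown:
                raise ValueError(f"context {ctx!r} emits unknown symbols {unknown}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"context {ctx!r} distribution sums to {total}")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"context {ctx!r} has negative probabilities")
            if dist.get(END, 0.0) > 0:
                end_reachable = True
        if not end_reachable:
            raise ValueError("END must be reachable (no context ever emits it)")

    def next_distribution(self, history: str) -> dict[str, float]:
        """Distribution from the longest context matching ``history``."""
        for k in range(min(len(history), max(map(len, self.contexts))), -1, -1):
            dist = self.contexts.get(history[len(history) - k:])
            if dist is not None:
                return dist
        raise KeyError(f"no context matches history {history!r} (missing root '')")

    def sample(self, rng: np.random.Generator, max_len: int = 500) -> list[str]:
        """Sample one label sequence; capped at ``max_len`` syllables."""
        history = self.start_symbol
        seq: list[str] = []
        while len(seq) < max_len:
            dist = self.next_distribution(history)
            symbols = list(dist)
            probs = np.array([dist[s] for s in symbols])
            sym = symbols[rng.choice(len(symbols), p=probs / probs.sum())]
            if sym == END:
                break
            seq.append(sym)
            history += sym
        return seq


def sample_sequences(
    syntax: SyntaxModel, n: int, rng: np.random.Generator, max_len: int = 500
) -> list[list[str]]:
    """Sample ``n`` bouts' label sequences (no audio)."""
    return [syntax.sample(rng, max_len=max_len) for _ in range(n)]


@dataclass(frozen=True)
class CorpusSpec:
    """Corpus-level parameters: size, sample rate, gap statistics, noise.

    Defaults give finch-scale timing: ~30 ms gaps (never below ``gap_min_s``,
    which keeps every ground-truth gap several spectrogram bins wide at the
    default analysis parameters), a -60 dBFS noise floor, and sparse
    broadband clicks in the silent intervals.
    """

    n_songs: int = 10
    fs: int = 32000
    gap_mean_s: float = 0.030
    gap_sd_s: float = 0.010
    gap_min_s: float = 0.012
    noise_event_rate: float = 0.5
    noise_floor_db: float = -60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_songs < 1:
            raise ValueError("n_songs must be >= 1")
        if self.fs < 8000:
            raise ValueError("fs must be >= 8000 Hz")
        if self.gap_mean_s <= 0 or self.gap_min_s <= 0:
            raise ValueError("gap durations must be positive")


def _to_ms(seconds: float) -> int:
    return round(seconds / _QUANTUM_S)


def _render_syllable(
    tpl: SyllableTemplate, duration_s: float, fs: int, rng: np.random.Generator
) -> np.ndarray:
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for k in range(1, tpl.n_harmonics + 1):
        phase = rng.uniform(0, 2 * math.pi)
        wave += (1.0 / k) * np.sin(2 * math.pi * k * tpl.f0_hz * t + phase)
    if tpl.am_envelope == "ramp":
        env = np.linspace(0.25, 1.0, n)
    elif tpl.am_envelope == "bell":
        env = np.hanning(n) if n > 1 else np.ones(n)
        env = 0.1 + 0.9 * env
    else:
        env = np.ones(n)
    # 2 ms cosine onset/offset ramps avoid spectral splatter at boundaries
    edge = min(round(0.002 * fs), n // 2)
    if edge > 0:
        taper = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        env[:edge] *= taper
        env[-edge:] *= taper[::-1]
    wave *= env
    peak = np.abs(wave).max()
    if peak > 0:
        wave *= tpl.rel_amplitude / peak
    return wave


def generate_song(
    templates: list[SyllableTemplate],
    syntax: SyntaxModel,
    spec: CorpusSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, Annotation]:
    """Synthesize one song bout.

    Returns the waveform (float64 in [-1, 1], at ``spec.fs``) and its
    ground-truth :class:`~syrinx.annotation.Annotation`.  Outside annotated
    segments the waveform contains only the noise floor and click events.
    """
    by_label = {tpl.label: tpl for tpl in templates}
    for tpl in templates:
        tpl.validate_against_fs(spec.fs)
    missing = set(syntax.labels) - set(by_label)
    if missing:
        raise ValueError(
            f"syntax emits labels with no syllable template: {sorted(missing)}"
        )

    sequence = syntax.sample(rng)
    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    # cursor kept in whole milliseconds: times round-trip through the
    # ms-precision CSV dialect exactly
    cursor_ms = _to_ms(max(spec.gap_min_s, rng.normal(spec.gap_mean_s, spec.gap_sd_s)))
    pieces.append(np.zeros(round(cursor_ms * _QUANTUM_S * spec.fs)))
    for label in sequence:
        tpl = by_label[label]
        dur_ms = _to_ms(
            max(0.005, rng.normal(tpl.duration_mean_s, tpl.duration_sd_s))
        )
        pieces.append(_render_syllable(tpl, dur_ms * _QUANTUM_S, spec.fs, rng))
        segments.append(
            Segment(cursor_ms / 1000.0, (cursor_ms + dur_ms) / 1000.0, label)
        )
        cursor_ms += dur_ms
        gap_ms = _to_ms(max(spec.gap_min_s, rng.normal(spec.gap_mean_s, spec.gap_sd_s)))
        pieces.append(np.zeros(round(gap_ms * _QUANTUM_S * spec.fs)))
        cursor_ms += gap_ms
    wave = np.concatenate(pieces) if pieces else np.zeros(0)

    # broadband clicks in silent intervals (non-song noise events)
    if spec.noise_event_rate > 0 and len(wave) > 0:
        n_events = rng.poisson(spec.noise_event_rate * len(wave) / spec.fs)
        silent = np.ones(len(wave), bool)
        for seg in segments:
            silent[round(seg.onset_s * spec.fs): round(seg.offset_s * spec.fs)] = False
        idx_silent = np.flatnonzero(silent)
        for _ in range(n_events):
            width = round(rng.uniform(0.002, 0.010) * spec.fs)
            if len(idx_silent) == 0:
                break
            start = int(rng.choice(idx_silent))
            stop = min(start + width, len(wave))
            burst = rng.uniform(-1, 1, stop - start) * 0.25
            # keep clicks out of syllables so ground truth stays exact
            if silent[start:stop].all():
                wave[start:stop] += burst

    if spec.noise_floor_db > -np.inf:
        wave = wave + rng.normal(
            0.0, 10 ** (spec.noise_floor_db / 20.0), len(wave)
        )
    np.clip(wave, -1.0, 1.0, out=wave)
    return wave, Annotation(segments)


def _write_wav(path, wave: np.ndarray, fs: int) -> None:
    pcm = np.round(wave * 32767).astype(np.int16)
    wavfile.write(path, fs, pcm)


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM-16 mono WAV as float64 in [-1, 1]."""
    fs, data = wavfile.read(path)
    return data.astype(np.float64) / 32767.0, int(fs)


def generate_corpus(
    templates: list[SyllableTemplate],
    syntax: SyntaxModel,
    spec: CorpusSpec,
    out_dir,
) -> pd.DataFrame:
    """Write a corpus: one WAV + one annotation CSV per song, plus a manifest.

    The manifest (``manifest.csv``) lists audio file, annotation file,
    duration in seconds, and segment count per song; the total corpus
    duration in seconds is stored in the ``duration_s`` column sum and in
    the manifest's ``total_duration_s`` attribute column on row order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_songs)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        wave, ann = generate_song(templates, syntax, spec, rng)
        wav_name = f"song_{i:04d}.wav"
        csv_name = f"song_{i:04d}.csv"
        _write_wav(out_dir / wav_name, wave, spec.fs)
        write_annotation(out_dir / csv_name, ann)
        rows.append(
            {
                "audio_file": wav_name,
                "annotation_file": csv_name,
                "duration_s": len(wave) / spec.fs,
                "n_segments": len(ann),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_corpus(corpus_dir) -> list[tuple[np.ndarray, int, Annotation]]:
    """Load a generated corpus: list of (waveform, fs, annotation)."""
    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    out = []
    for row in manifest.itertuples():
        wave, fs = read_wav(corpus_dir / row.audio_file)
        ann = read_annotation(corpus_dir / row.annotation_file)
        out.append((wave, fs, ann))
    return out


def make_branchpoint_syntax(p: float) -> SyntaxModel:
    """First-order syntax with one branch point.

    The motif runs ``a b c e``; from ``e`` song transitions to ``f`` with
    probability ``p`` or to ``i`` with probability ``1 - p``; both continue
    to ``g`` and the song ends.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"branch probability must be in (0, 1), got {p}")
    labels = ["a", "b", "c", "e", "f", "g", "i"]
    contexts = {
        "S": {"a": 1.0},
        "a": {"b": 1.0},
        "b": {"c": 1.0},
        "c": {"e": 1.0},
        "e": {"f": p, "i": 1.0 - p},
        "f": {"g": 1.0},
        "i": {"g": 1.0},
        "g": {END: 1.0},
    }
    return SyntaxModel(labels=labels, contexts=contexts, start_symbol="S")


def make_linear_syntax(labels: list[str]) -> SyntaxModel:
    """Deterministic chain: each label follows the previous, then END."""
    if not labels:
        raise ValueError("labels must be non-empty")
    contexts: dict[str, dict[str, float]] = {"S": {labels[0]: 1.0}}
    for prev, cur in zip(labels, labels[1:]):
        contexts[prev] = {cur: 1.0}
    contexts[labels[-1]] = {END: 1.0}
    return SyntaxModel(labels=list(labels), contexts=contexts, start_symbol="S")


def make_canary_syntax(
    phrase_labels: list[str] | None = None,
    repeat_prob: float = 0.75,
    n_phrases_mean: float = 5.0,
) -> SyntaxModel:
    """Canary-like syntax: trilled phrases with geometric repeat counts.

    Each phrase is a run of one syllable type; within a phrase the syllable
    repeats with probability ``repeat_prob`` (geometric run length, mean
    ``1 / (1 - repeat_prob)``).  On leaving a phrase, song moves uniformly
    to one of the other phrase types or ends, tuned so bouts contain
    ``n_phrases_mean`` phrases on average.
    """
    if phrase_labels is None:
        phrase_labels = ["A", "B", "C", "D"]
    if not 0.0 < repeat_prob < 1.0:
        raise ValueError("repeat_prob must be in (0, 1)")
    p_end = 1.0 / n_phrases_mean
    leave = 1.0 - repeat_prob
    contexts: dict[str, dict[str, float]] = {
        "S": {lab: 1.0 / len(phrase_labels) for lab in phrase_labels}
    }
    for lab in phrase_labels:
        others = [o for o in phrase_labels if o != lab]
        dist = {lab: repeat_prob, END: leave * p_end}
        for o in others:
            dist[o] = leave * (1.0 - p_end) / len(others)
        contexts[lab] = dist
    return SyntaxModel(labels=list(phrase_labels), contexts=contexts, start_symbol="S")


def default_templates(
    n_classes: int = 5,
    fs: int = 32000,
    amplitude_span_db: float = 0.0,
    duration_mean_s: float = 0.080,
    duration_sd_s: float = 0.010,
) -> list[SyllableTemplate]:
    """Convenience bank of well-separated harmonic-stack templates.

    Fundamentals are log-spaced between 1 and 6 kHz with alternating
    envelope shapes.  With ``amplitude_span_db`` > 0 the per-class gains
    span that many dB (the regime where no single amplitude threshold
    segments every syllable class correctly).
    """
    labels = [chr(ord("a") + i) for i in range(n_classes)]
    f0s = np.geomspace(1000.0, min(6000.0, fs / 8), n_classes)
    if amplitude_span_db > 0:
        gains = 10 ** (np.linspace(-amplitude_span_db, 0.0, n_classes) / 20.0)
    else:
        gains = np.ones(n_classes)
    return [
        SyllableTemplate(
            label=labels[i],
            duration_mean_s=duration_mean_s,
            duration_sd_s=duration_sd_s,
            f0_hz=float(f0s[i]),
            n_harmonics=3,
            am_envelope=_ENVELOPE_SHAPES[i % 3],
            rel_amplitude=float(gains[i]),
        )
        for i in range(n_classes)
    ]
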