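"""Shared fixtures: synthetic corpora and trained networks.

Everything is generated programmatically and seeded; the two trained
checkpoints are session-scoped because several tests interrogate the same
desk-scale training run from different angles.
"""

from __future__ import annotations

import numpy as np
import pytest

from syrinx.annotation import Annotation
from syrinx.dataset import LabelMap, Spectrogram, compute_spectrogram
from syrinx.network import Checkpoint, NetworkConfig, TrainConfig, train
from syrinx.synthetic_song import (
    CorpusSpec,
    default_templates,
    generate_song,
    make_canary_syntax,
)

# desk-scale analysis parameters used across the suite
FS = 32000
NFFT = 256
STEP = 64
WINDOW = 88


def make_songs(
    n_songs: int,
    seed: int,
    templates=None,
    syntax=None,
    spec: CorpusSpec | None = None,
) -> list[tuple[np.ndarray, Annotation]]:
    """Generate in-memory songs with varied (canary-like) 5-class syntax."""
    if templates is None:
        templates = default_templates(5, fs=FS)
    if syntax is None:
        syntax = make_canary_syntax(
            [t.label for t in templates], repeat_prob=0.4, n_phrases_mean=8
        )
    if spec is None:
        spec = CorpusSpec(n_songs=n_songs, fs=FS, seed=seed)
    # trailing silence keeps every bout at least one analysis window long
    min_samples = NFFT + STEP * (WINDOW + 8)
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_songs):
        rng = np.random.default_rng(child)
        wave, ann = generate_song(templates, syntax, spec, rng)
        if len(wave) < min_samples:
            wave = np.concatenate([wave, np.zeros(min_samples - len(wave))])
        out.append((wave, ann))
    return out


def to_spects(
    songs: list[tuple[np.ndarray, Annotation]],
) -> list[tuple[Spectrogram, Annotation]]:
    return [
        (compute_spectrogram(w, FS, nfft=NFFT, step=STEP), ann)
        for w, ann in songs
    ]


@pytest.fixture(scope="session")
def templates5():
    return default_templates(5, fs=FS)


@pytest.fixture(scope="session")
def labelmap5(templates5):
    return LabelMap([t.label for t in templates5])


@pytest.fixture(scope="session")
def train_corpus() -> list:
    """~60 s of 5-class song with phrase repeats and branching transitions."""
    songs = make_songs(45, seed=12345)
    total = sum(len(w) for w, _ in songs) / FS
    assert 45.0 < total < 90.0
    return to_spects(songs)


@pytest.fixture(scope="session")
def val_corpus() -> list:
    return to_spects(make_songs(6, seed=54321))


def _net_cfg(labelmap: LabelMap, corpus) -> NetworkConfig:
    return NetworkConfig(
        n_classes=labelmap.n_classes,
        n_freq_bins=corpus[0][0].n_freq,
        window_size=WINDOW,
    )


@pytest.fixture(scope="session")
def desk_checkpoint(train_corpus, val_corpus, labelmap5) -> Checkpoint:
    """A properly trained desk-scale network (low validation frame error)."""
    tc = TrainConfig(
        batch_size=8, val_step=50, patience=4, max_steps=200, seed=7
    )
    return train(train_corpus, val_corpus, labelmap5,
                 _net_cfg(labelmap5, train_corpus), tc)


@pytest.fixture(scope="session")
def weak_checkpoint(train_corpus, val_corpus, labelmap5) -> Checkpoint:
    """A deliberately under-trained network: scattered frame errors make the
    effect of post-processing visible."""
    tc = TrainConfig(
        batch_size=8, val_step=12, patience=4, max_steps=12, seed=7
    )
    return train(train_corpus, val_corpus, labelmap5,
                 _net_cfg(labelmap5, train_corpus), tc)
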