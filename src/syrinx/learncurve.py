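"""Benchmarking by learning curves: duration-budgeted training subsets,
replicate training runs, and evaluation on a fixed held-out test set.

For each target training duration, songs are drawn at random from a fixed
training pool until the target is reached; the final song is clipped at
the target (not dropped), and the draw is retried (boundedly) until every
syllable class is present.  Each (duration, replicate) cell trains a
fresh network — the initialization seed is a function of the cell, so
replicates differ in both data and initialization — and is evaluated on
the same fixed test set with and without post-processing, yielding the
four benchmark quantities: frame error and syllable error rate, raw and
post-processed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Segment
from .dataset import LabelMap, Spectrogram, annotation_to_frame_labels
from .metrics import frame_error, syllable_error_rate
from .network import (
    Checkpoint,
    NetworkConfig,
    TrainConfig,
    predict_frame_probabilities,
    train,
)
from .postprocess import (
    PostprocessConfig,
    default_min_segment_dur,
    postprocess,
    segments_raw,
)

__all__ = ["SongItem", "LearncurveConfig", "draw_training_subset",
           "run_learning_curve", "evaluate_checkpoint"]


@dataclass
class SongItem:
    """One song of a corpus: a name (file stem), its spectrogram, and its
    ground-truth annotation."""

    name: str
    spect: Spectrogram
    ann: Annotation

    @property
    def duration_s(self) -> float:
        return self.spect.n_time * self.spect.bin_dur_s


@dataclass(frozen=True)
class LearncurveConfig:
    train_durations_s: tuple[float, ...]
    n_replicates: int
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.train_durations_s:
            raise ValueError("need at least one training duration")


def _clip_song(item: SongItem, keep_s: float) -> SongItem:
    """Clip a song (spectrogram + annotation) at ``keep_s`` seconds."""
    n_bins = int(round(keep_s / item.spect.bin_dur_s))
    n_bins = max(1, min(n_bins, item.spect.n_time))
    sp = item.spect
    clipped_spect = Spectrogram(
        s=sp.s[:, :n_bins], f=sp.f, t=sp.t[:n_bins], bin_dur_s=sp.bin_dur_s
    )
    cut = float(sp.t[n_bins - 1] + sp.bin_dur_s)
    segs = []
    for seg in item.ann:
        if seg.onset_s >= cut:
            break
        if seg.offset_s <= cut:
            segs.append(seg)
        elif cut - seg.onset_s > 2 * sp.bin_dur_s:
            segs.append(Segment(seg.onset_s, cut, seg.label))
    return SongItem(name=item.name + "[clipped]", spect=clipped_spect,
                    ann=Annotation(segs))


def draw_training_subset(
    pool: list[SongItem],
    target_duration_s: float,
    rng: np.random.Generator,
    required_labels: list[str] | None = None,
    max_retries: int = 100,
) -> list[SongItem]:
    """Draw songs at random until the target duration is reached.

    The final song is clipped at the target, not dropped.  The draw is
    repeated (up to ``max_retries`` times) until every label in
    ``required_labels`` (default: every label in the pool) appears in the
    subset; if that never happens the error names the missing classes.
    """
    total = sum(item.duration_s for item in pool)
    if total < target_duration_s - 1e-9:
        raise ValueError(
            f"pool duration {total:.1f} s is shorter than target "
            f"{target_duration_s:.1f} s"
        )
    if required_labels is None:
        required_labels = sorted(
            {lab for item in pool for lab in item.ann.labels}
        )
    last_missing: list[str] = []
    for _ in range(max_retries):
        order = rng.permutation(len(pool))
        subset: list[SongItem] = []
        acc = 0.0
        for j in order:
            item = pool[j]
            if acc + item.duration_s >= target_duration_s - 1e-9:
                remaining = target_duration_s - acc
                subset.append(_clip_song(item, remaining))
                acc = target_duration_s
                break
            subset.append(item)
            acc += item.duration_s
        present = {lab for item in subset for lab in item.ann.labels}
        missing = [lab for lab in required_labels if lab not in present]
        if not missing:
            return subset
        last_missing = missing
    raise ValueError(
        f"could not draw a {target_duration_s} s subset containing all "
        f"syllable classes after {max_retries} tries; missing {last_missing}"
    )


def _corpus_hash(items: list[SongItem]) -> str:
    h = hashlib.sha256()
    for item in items:
        h.update(item.name.encode())
        h.update(np.ascontiguousarray(item.spect.s).tobytes())
    return h.hexdigest()


def evaluate_checkpoint(
    ckpt: Checkpoint,
    test_set: list[SongItem],
    pp_cfg: PostprocessConfig,
) -> dict[str, float]:
    """Mean frame error and SER over a test set, raw and post-processed."""
    fe_raw, fe_pp, ser_raw_l, ser_pp_l = [], [], [], []
    lm = ckpt.labelmap
    for item in test_set:
        scores = predict_frame_probabilities(ckpt, item.spect)
        y_pred = scores.argmax(axis=0)
        y_true = annotation_to_frame_labels(
            item.ann, item.spect.t, item.spect.bin_dur_s, lm
        )
        fe_raw.append(frame_error(y_pred, y_true))
        raw_labels = [
            lm.to_label(cls)
            for _, _, cls in segments_raw(y_pred, item.spect.t, item.spect.bin_dur_s)
        ]
        ann_pp = postprocess(y_pred, item.spect.t, item.spect.bin_dur_s, lm, pp_cfg)
        y_pp = annotation_to_frame_labels(
            ann_pp, item.spect.t, item.spect.bin_dur_s, lm
        )
        fe_pp.append(frame_error(y_pp, y_true))
        if len(item.ann) > 0:
            ser_raw_l.append(syllable_error_rate(item.ann.labels, raw_labels))
            ser_pp_l.append(syllable_error_rate(item.ann.labels, ann_pp.labels))
    return {
        "frame_error": float(np.mean(fe_raw)),
        "frame_error_postproc": float(np.mean(fe_pp)),
        "ser": float(np.mean(ser_raw_l)),
        "ser_postproc": float(np.mean(ser_pp_l)),
    }


def run_learning_curve(
    pool: list[SongItem],
    test_set: list[SongItem],
    labelmap: LabelMap,
    cfg: LearncurveConfig,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    results_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train the full (duration x replicate) grid and evaluate each cell on
    the fixed test set.

    The test set must be disjoint from the pool (checked by song name,
    error lists offenders) and is hash-checked to be bit-identical across
    all cells.  Results are persisted incrementally to ``results_csv`` if
    given, so an interrupted curve resumes where it stopped.  Returns the
    per-cell table (columns train_dur_s, replicate, frame_error,
    frame_error_postproc, ser, ser_postproc) and a mean/sd summary per
    duration.
    """
    overlap = {i.name for i in pool} & {i.name for i in test_set}
    if overlap:
        raise ValueError(f"pool and test set overlap: {sorted(overlap)}")
    test_hash = _corpus_hash(test_set)

    rows: list[dict] = []
    done: set[tuple[float, int]] = set()
    results_csv = Path(results_csv) if results_csv is not None else None
    if results_csv is not None and results_csv.exists():
        prev = pd.read_csv(results_csv)
        rows = prev.to_dict("records")
        done = {(r["train_dur_s"], r["replicate"]) for r in rows}

    for d_idx, dur in enumerate(cfg.train_durations_s):
        for rep in range(cfg.n_replicates):
            if (float(dur), rep) in done:
                continue
            # replicate seed: data draw and network init both vary per cell
            cell_seed = cfg.seed * 100003 + d_idx * 1009 + rep
            rng = np.random.default_rng(cell_seed)
            subset = draw_training_subset(
                pool, dur, rng, required_labels=labelmap.labels,
                max_retries=cfg.max_retries,
            )
            tc = dataclasses.replace(train_cfg, seed=cell_seed)
            ckpt = train(
                [(i.spect, i.ann) for i in subset],
                [(i.spect, i.ann) for i in subset],
                labelmap,
                net_cfg,
                tc,
            )
            pp_cfg = PostprocessConfig(
                min_segment_dur_s=default_min_segment_dur([i.ann for i in subset])
            )
            metrics = evaluate_checkpoint(ckpt, test_set, pp_cfg)
            rows.append({"train_dur_s": float(dur), "replicate": rep, **metrics})
            if results_csv is not None:
                pd.DataFrame(rows).to_csv(results_csv, index=False)
            if _corpus_hash(test_set) != test_hash:
                raise RuntimeError("test set was modified during the curve")

    results = pd.DataFrame(rows).sort_values(["train_dur_s", "replicate"])
    results = results.reset_index(drop=True)
    summary = (
        results.groupby("train_dur_s")
        .agg(["mean", "std"])
        .drop(columns=["replicate"])
    )
    return results, summary
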