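"""Evaluation metrics: frame error, syllable error rate, and error analyses.

The syllable error rate is the analogue of the word error rate from
speech recognition:

    SER = Levenshtein(reference, predicted) / len(reference)
        = (substitutions + insertions + deletions) / len(reference)

reported as a percent; it can exceed 100% when the prediction has many
more labels than the reference.  The frame error is the fraction of
spectrogram time bins whose predicted class differs from ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation
from .dataset import BACKGROUND

__all__ = [
    "EditDistanceResult",
    "levenshtein",
    "frame_error",
    "syllable_error_rate",
    "boundary_error_fraction",
    "rare_sequence_error_analysis",
    "evaluation_report",
]


@dataclass(frozen=True)
class EditDistanceResult:
    substitutions: int
    insertions: int
    deletions: int
    reference_length: int

    @property
    def distance(self) -> int:
        return self.substitutions + self.insertions + self.deletions


def levenshtein(reference, predicted) -> EditDistanceResult:
    """Unit-cost Levenshtein distance (no transpositions) with an
    operation breakdown recovered by backtracing the DP table.

    ``insertions`` are symbols present in the prediction but not the
    reference; ``deletions`` the reverse.
    """
    ref, pred = list(reference), list(predicted)
    n, m = len(ref), len(pred)
    d = np.zeros((n + 1, m + 1), dtype=np.int64)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if ref[i - 1] == pred[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
    subs = ins = dels = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and d[i, j] == d[i - 1, j - 1] + (ref[i - 1] != pred[j - 1]):
            subs += ref[i - 1] != pred[j - 1]
            i, j = i - 1, j - 1
        elif j > 0 and d[i, j] == d[i, j - 1] + 1:
            ins += 1
            j -= 1
        else:
            dels += 1
            i -= 1
    return EditDistanceResult(
        substitutions=int(subs),
        insertions=int(ins),
        deletions=int(dels),
        reference_length=n,
    )


def frame_error(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Fraction of time bins where prediction and ground truth disagree."""
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError(
            f"length mismatch: predicted {y_pred.shape} vs true {y_true.shape}"
        )
    return float((y_pred != y_true).mean())


def syllable_error_rate(reference, predicted) -> float:
    """Levenshtein distance divided by the reference length (a fraction;
    multiply by 100 to report percent)."""
    ref = list(reference)
    if len(ref) == 0:
        raise ValueError("syllable error rate is undefined for an empty reference")
    return levenshtein(ref, predicted).distance / len(ref)


def boundary_error_fraction(
    y_pred: np.ndarray,
    y_true: np.ndarray,
    annotation_true: Annotation,
    t: np.ndarray,
    bin_dur_s: float,
    tol_bins: int = 2,
) -> tuple[float, bool]:
    """Percent of frame errors that are background-vs-syllable disagreements
    within ``tol_bins`` bins of a true segment boundary.

    Returns ``(percent, had_errors)``; with a perfect prediction the
    percent is defined as 0 and ``had_errors`` is False.
    """
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    t = np.asarray(t)
    errors = y_pred != y_true
    n_errors = int(errors.sum())
    if n_errors == 0:
        return 0.0, False
    near_boundary = np.zeros(len(t), dtype=bool)
    centers = t + bin_dur_s / 2.0
    for seg in annotation_true:
        for edge in (seg.onset_s, seg.offset_s):
            edge_bin = int(np.argmin(np.abs(centers - edge)))
            lo = max(0, edge_bin - tol_bins)
            near_boundary[lo: edge_bin + tol_bins + 1] = True
    background_disagree = (y_pred == BACKGROUND) != (y_true == BACKGROUND)
    numerator = int((errors & near_boundary & background_disagree).sum())
    return 100.0 * numerator / n_errors, True


def rare_sequence_error_analysis(
    sequences: list[list[str]],
    segment_frame_errors: list[np.ndarray],
    rarity_ratio: float = 0.25,
    rarity_split: float = 1.0 / 8.0,
) -> tuple[pd.DataFrame, tuple[float, float], tuple[float, float]]:
    """Do rarely seen syllable sequences attract more frame errors?

    For every context bigram a-b, the most frequent following syllable
    a-b-x is found; every following syllable a-b-y at least ``1 /
    rarity_ratio`` times less frequent is a *rare trigram*.  For each rare
    trigram the table records its relative frequency P(aby)/P(abx) and the
    mean frame error inside the y syllables in that context
    (``segment_frame_errors[i][j]`` is the frame-error fraction within
    segment ``j`` of bout ``i``).

    Returns the table, the Pearson (r, p) between relative frequency and
    mean frame error across rare trigrams (NaN if fewer than 3), and a
    two-proportion z-test (z, p) comparing the fraction of trigrams whose
    error exceeds the median between the rarer and the more common group
    (split at relative frequency ``rarity_split``).
    """
    trigram_counts: dict[tuple[str, str, str], int] = {}
    trigram_errors: dict[tuple[str, str, str], list[float]] = {}
    for labels, errs in zip(sequences, segment_frame_errors):
        if len(labels) != len(errs):
            raise ValueError("per-segment errors do not align with labels")
        for k in range(len(labels) - 2):
            tri = (labels[k], labels[k + 1], labels[k + 2])
            trigram_counts[tri] = trigram_counts.get(tri, 0) + 1
            trigram_errors.setdefault(tri, []).append(float(errs[k + 2]))
    contexts = sorted({(a, b) for a, b, _ in trigram_counts})
    if len(contexts) < 2:
        raise ValueError("need at least 2 distinct trigram contexts")
    rows = []
    for a, b in contexts:
        followers = {y: c for (x, z, y), c in trigram_counts.items()
                     if (x, z) == (a, b)}
        top_count = max(followers.values())
        for y, c in followers.items():
            if c <= rarity_ratio * top_count:
                rows.append(
                    {
                        "context": a + b,
                        "syllable": y,
                        "count": c,
                        "relative_frequency": c / top_count,
                        "mean_frame_error": float(
                            np.mean(trigram_errors[(a, b, y)])
                        ),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["context", "syllable", "count", "relative_frequency",
                 "mean_frame_error"],
    )
    if len(table) >= 3 and table["mean_frame_error"].nunique() > 1:
        r, p_r = stats.pearsonr(
            table["relative_frequency"], table["mean_frame_error"]
        )
        pearson = (float(r), float(p_r))
    else:
        pearson = (float("nan"), float("nan"))
    ztest = _rarity_ztest(table, rarity_split)
    return table, pearson, ztest


def _rarity_ztest(table: pd.DataFrame, split: float) -> tuple[float, float]:
    """Two-proportion z-test: fraction of trigrams above the median error,
    rarer (< split) vs more common (>= split) groups."""
    if len(table) == 0:
        return float("nan"), float("nan")
    median = table["mean_frame_error"].median()
    exceed = (table["mean_frame_error"] > median).to_numpy()
    rare = (table["relative_frequency"] < split).to_numpy()
    n1, n2 = int(rare.sum()), int((~rare).sum())
    if n1 == 0 or n2 == 0:
        return float("nan"), float("nan")
    x1, x2 = int(exceed[rare].sum()), int(exceed[~rare].sum())
    p_pool = (x1 + x2) / (n1 + n2)
    denom = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if denom == 0:
        return 0.0, 1.0
    z = (x1 / n1 - x2 / n2) / denom
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def evaluation_report(
    bouts: list[tuple[Annotation, np.ndarray, np.ndarray, list[str]]],
) -> tuple[pd.DataFrame, dict]:
    """Per-bout evaluation table and corpus summary.

    ``bouts``: (true annotation, y_true, y_pred, predicted label sequence)
    per bout.  The summary reports both the per-bout mean SER (primary)
    and the pooled SER (total edits over total reference length).
    """
    rows = []
    total_edits = 0
    total_ref = 0
    for ann, y_true, y_pred, pred_labels in bouts:
        ed = levenshtein(ann.labels, pred_labels)
        total_edits += ed.distance
        total_ref += ed.reference_length
        rows.append(
            {
                "frame_error": frame_error(y_pred, y_true),
                "ser": ed.distance / ed.reference_length,
                "n_segments_true": len(ann),
                "n_segments_pred": len(pred_labels),
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "frame_error": float(df["frame_error"].mean()),
        "ser_per_bout_mean": float(df["ser"].mean()),
        "ser_pooled": total_edits / total_ref if total_ref else float("nan"),
        "n_bouts": len(df),
    }
    return df, summary
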