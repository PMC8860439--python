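"""Tests of the synthetic-song generator: determinism, syntax statistics,
corpus round trips, and the amplitude-variation property that motivates
learned segmentation."""

import numpy as np
import pytest
from scipy import stats

from syrinx.annotation import read_annotation
from syrinx.audio_segmentation import compute_envelope, segment_audio, SegParams
from syrinx.synthetic_song import (
    END,
    CorpusSpec,
    SyllableTemplate,
    SyntaxModel,
    default_templates,
    generate_corpus,
    generate_song,
    make_branchpoint_syntax,
    make_canary_syntax,
    make_linear_syntax,
    read_corpus,
    sample_sequences,
)

from conftest import FS


def _spec(**kw):
    defaults = dict(n_songs=3, fs=FS, seed=0)
    defaults.update(kw)
    return CorpusSpec(**defaults)


def test_degenerate_chain_single_syllable(templates5):
    syntax = SyntaxModel(labels=["a"], contexts={"S": {"a": 1.0}, "a": {END: 1.0}})
    wave, ann = generate_song(templates5, syntax, _spec(), np.random.default_rng(0))
    assert ann.labels == ["a"]


def test_generate_song_deterministic(templates5):
    syntax = make_linear_syntax([t.label for t in templates5])
    out = []
    for _ in range(2):
        rng = np.random.default_rng(42)
        out.append(generate_song(templates5, syntax, _spec(), rng))
    (w1, a1), (w2, a2) = out
    assert np.array_equal(w1, w2)
    assert a1 == a2


def test_unknown_label_raises(templates5):
    syntax = SyntaxModel(labels=["z"], contexts={"S": {"z": 1.0}, "z": {END: 1.0}})
    with pytest.raises(ValueError, match="z"):
        generate_song(templates5, syntax, _spec(), np.random.default_rng(0))


def test_markov_branch_frequencies_match_probabilities():
    """Empirical branch frequencies within 3 s.e. of the configured 0.7/0.3."""
    syntax = SyntaxModel(
        labels=["a", "b", "c"],
        contexts={
            "S": {"a": 1.0},
            "a": {"b": 0.7, "c": 0.3},
            "b": {END: 1.0},
            "c": {END: 1.0},
        },
    )
    rng = np.random.default_rng(1)
    seqs = sample_sequences(syntax, 2000, rng)
    n_b = sum(seq[1] == "b" for seq in seqs)
    se = np.sqrt(0.7 * 0.3 / 2000)
    assert abs(n_b / 2000 - 0.7) < 3 * se


def test_syntax_model_validation():
    with pytest.raises(ValueError, match="sums"):
        SyntaxModel(labels=["a"], contexts={"S": {"a": 0.5}, "a": {END: 1.0}})
    with pytest.raises(ValueError, match="unknown"):
        SyntaxModel(labels=["a"], contexts={"S": {"q": 1.0}, "a": {END: 1.0}})
    with pytest.raises(ValueError, match="END"):
        SyntaxModel(labels=["a"], contexts={"S": {"a": 1.0}, "a": {"a": 1.0}})


def test_branchpoint_syntax_construction():
    syntax = make_branchpoint_syntax(0.5)
    assert syntax.contexts["e"] == {"f": 0.5, "i": 0.5}
    make_branchpoint_syntax(1 - 1e-9)  # arbitrarily close to 1 is accepted
    for bad in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            make_branchpoint_syntax(bad)


def test_corpus_manifest_and_round_trip(tmp_path, templates5):
    syntax = make_linear_syntax([t.label for t in templates5])
    spec = _spec(n_songs=3)
    manifest = generate_corpus(templates5, syntax, spec, tmp_path)
    assert len(manifest) == 3
    assert manifest["duration_s"].sum() > 0
    # re-reading written annotations reproduces the in-memory ones exactly
    regenerated = []
    for child in np.random.SeedSequence(spec.seed).spawn(3):
        rng = np.random.default_rng(child)
        regenerated.append(generate_song(templates5, syntax, spec, rng)[1])
    for row, ann in zip(manifest.itertuples(), regenerated):
        assert read_annotation(tmp_path / row.annotation_file) == ann
    assert len(read_corpus(tmp_path)) == 3


def test_canary_mode_mean_repeats():
    """Geometric phrase repeats: mean run length within 3 s.e. of 1/(1-q)."""
    q = 0.75
    syntax = make_canary_syntax(["A", "B", "C"], repeat_prob=q, n_phrases_mean=5)
    rng = np.random.default_rng(3)
    runs = []
    for seq in sample_sequences(syntax, 500, rng):
        k = 0
        for i, sym in enumerate(seq):
            k += 1
            if i + 1 == len(seq) or seq[i + 1] != sym:
                runs.append(k)
                k = 0
    runs = np.asarray(runs, dtype=float)
    expected = 1.0 / (1.0 - q)
    se = runs.std(ddof=1) / np.sqrt(len(runs))
    assert abs(runs.mean() - expected) < 3 * se


def test_duration_and_gap_distributions_match_spec():
    """KS test on generated durations/gaps against the configured normal
    distributions: non-rejection at alpha=0.01 in >= 95% of seeds."""
    templates = [
        SyllableTemplate(label="a", duration_mean_s=0.080, duration_sd_s=0.010,
                         f0_hz=2000.0)
    ]
    syntax = SyntaxModel(
        labels=["a"],
        contexts={"S": {"a": 1.0}, "a": {"a": 0.99, END: 0.01}},
    )
    rejections = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = CorpusSpec(
            n_songs=1, fs=FS, gap_mean_s=0.040, gap_sd_s=0.008,
            gap_min_s=0.012, noise_event_rate=0.0, seed=seed,
        )
        durations, gaps = [], []
        rng = np.random.default_rng(seed)
        while len(gaps) < 1000:
            _, ann = generate_song(templates, syntax, spec, rng)
            durations.extend(ann.durations_s)
            gaps.extend(ann.gaps_s)
        # the generator quantizes times to 1 ms, which ties samples and
        # breaks the continuous KS test; dithering each sample uniformly
        # within its quantum restores a continuous sample whose law matches
        # the target normal to O((quantum/sd)^2), far below KS resolution
        dither = np.random.default_rng(1000 + seed)
        d = np.asarray(durations[:1000]) + dither.uniform(-5e-4, 5e-4, 1000)
        g = np.asarray(gaps[:1000]) + dither.uniform(-5e-4, 5e-4, 1000)
        d_p = stats.kstest(d, stats.norm(0.080, 0.010).cdf).pvalue
        g_p = stats.kstest(g, stats.norm(0.040, 0.008).cdf).pvalue
        if d_p < 0.01 or g_p < 0.01:
            rejections += 1
    assert rejections <= 0.05 * n_seeds


def test_gaps_at_least_two_bins_at_default_analysis(templates5):
    """Default gap floor keeps every ground-truth gap >= 2 spectrogram bins
    (bin duration step/fs = 2 ms at the default analysis parameters)."""
    syntax = make_linear_syntax([t.label for t in templates5])
    bin_dur = 64 / FS
    for seed in range(3):
        _, ann = generate_song(
            templates5, syntax, _spec(seed=seed), np.random.default_rng(seed)
        )
        assert all(g >= 2 * bin_dur for g in ann.gaps_s)


def test_no_single_threshold_segments_wide_amplitude_range():
    """With per-class amplitudes spanning >24 dB over a realistic noise
    floor, no amplitude threshold recovers every syllable's boundaries to
    within one spectrogram time bin (2 ms) — the failure mode that
    motivates learned segmentation."""
    templates = [
        SyllableTemplate(label=lab, duration_mean_s=0.080, duration_sd_s=0.005,
                         f0_hz=f0, am_envelope="bell", rel_amplitude=amp)
        for lab, f0, amp in [("a", 1000.0, 1.0), ("b", 2000.0, 0.25),
                             ("c", 4000.0, 0.05)]
    ]
    syntax = make_canary_syntax(["a", "b", "c"], repeat_prob=0.3, n_phrases_mean=9)
    spec = CorpusSpec(n_songs=1, fs=FS, noise_floor_db=-40.0,
                      noise_event_rate=0.0, seed=5)
    waves, anns = [], []
    for seed in range(4):
        rng = np.random.default_rng(seed)
        w, a = generate_song(templates, syntax, spec, rng)
        waves.append(w)
        anns.append(a)
    tol_s = 0.002

    def all_recovered(threshold) -> bool:
        for w, ann in zip(waves, anns):
            env = compute_envelope(w, FS)
            try:
                p = SegParams(threshold=threshold, min_silent_interval_s=0.005,
                              min_syllable_dur_s=0.01)
            except ValueError:
                return False
            segs = segment_audio(env, p)
            for seg in ann:
                ok = any(
                    abs(on - seg.onset_s) <= tol_s
                    and abs(off - seg.offset_s) <= tol_s
                    for on, off in segs
                )
                if not ok:
                    return False
        return True

    thresholds = np.geomspace(1e-4, 1.0, 40)
    assert not any(all_recovered(thr) for thr in thresholds)
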