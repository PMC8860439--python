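"""Architecture shape contract, gradient correctness, training loop
behavior, and whole-bout prediction tiling."""

import numpy as np
import pytest

from syrinx import _tensor as T
from syrinx.annotation import Annotation, Segment
from syrinx.dataset import LabelMap, Spectrogram
from syrinx.network import (
    Checkpoint,
    EarlyStopper,
    NetworkConfig,
    Normalizer,
    TrainConfig,
    TweetyNet,
    predict_frame_probabilities,
    train,
)

from conftest import NFFT, STEP, WINDOW, make_songs, to_spects


# ---- shape contract --------------------------------------------------------


def test_reference_window_shapes():
    """A 176-time-bin x 513-frequency-bin window: (176x513x32) after the
    first convolution, (176x64x32) after its pooling, 512 features per time
    bin after flattening, and 1024 after the bidirectional recurrent layer."""
    cfg = NetworkConfig(n_classes=11, n_freq_bins=513, window_size=176)
    model = TweetyNet(cfg, seed=0)
    x = np.random.default_rng(0).normal(size=(1, 1, 513, 176))
    out, shapes = model.forward(x, return_intermediates=True)
    assert shapes["conv1"] == (1, 32, 513, 176)
    assert shapes["pool1"] == (1, 32, 64, 176)
    assert shapes["conv2"] == (1, 64, 64, 176)
    assert shapes["pool2"] == (1, 64, 8, 176)
    assert shapes["flatten"] == (1, 176, 512)
    assert cfg.n_features == 512
    assert cfg.resolved_hidden_size == 512  # "auto" = flattened features
    assert shapes["lstm"] == (1, 176, 1024)  # forward + backward states
    assert out.shape == (1, 11, 176)


@pytest.mark.parametrize("n_freq,window", [(64, 5), (100, 9), (129, 12), (200, 7)])
def test_shape_contract_over_valid_configs(n_freq, window):
    cfg = NetworkConfig(n_classes=4, n_freq_bins=n_freq, window_size=window)
    model = TweetyNet(cfg, seed=1)
    x = np.zeros((2, 1, n_freq, window))
    out, shapes = model.forward(x, return_intermediates=True)
    f1 = n_freq // 8
    assert shapes["conv1"] == (2, 32, n_freq, window)
    assert shapes["pool1"] == (2, 32, f1, window)
    assert shapes["pool2"] == (2, 64, f1 // 8, window)
    assert shapes["flatten"] == (2, window, 64 * (f1 // 8))
    # the temporal dimension is never downsampled before the linear layer
    for name in ("conv1", "pool1", "conv2", "pool2", "output"):
        assert shapes[name][-1] == window
    for name in ("flatten", "lstm"):
        assert shapes[name][1] == window
    assert out.shape == (2, 4, window)


def test_too_few_frequency_bins_rejected_with_pooling_arithmetic():
    with pytest.raises(ValueError, match="floor"):
        NetworkConfig(n_classes=3, n_freq_bins=63, window_size=10)


def test_pooling_must_not_downsample_time():
    with pytest.raises(ValueError, match="temporal"):
        NetworkConfig(n_classes=3, n_freq_bins=64, window_size=10,
                      pool_size=(8, 2), pool_stride=(8, 2))


# ---- gradients -------------------------------------------------------------


class _TweetyNet64(TweetyNet):
    dtype = np.float64


def test_full_network_gradients_match_finite_differences():
    """Backpropagated gradients through conv blocks, pooling, BiLSTM and
    the linear layer agree with central finite differences."""
    cfg = NetworkConfig(n_classes=3, n_freq_bins=64, window_size=5,
                        conv_filters=(4, 6), hidden_size=7)
    model = _TweetyNet64(cfg, seed=0)
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 1, 64, 5))
    targets = rng.integers(0, 3, 2 * 5)

    def loss_value():
        scores = model.forward(x)
        b, c, w = scores.shape
        logits = scores.transpose(0, 2, 1).reshape(b * w, c)
        return T.softmax_cross_entropy(logits, targets)

    loss = loss_value()
    loss.backward()
    eps = 1e-6
    for name, p in model.params.items():
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            up = float(loss_value().data)
            flat[i] = orig - eps
            down = float(loss_value().data)
            flat[i] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(gflat[i], rel=1e-4, abs=1e-7), name


# ---- training loop ---------------------------------------------------------


def test_early_stopper_contract():
    """Validation errors [5, 5, 5, 5, 5] with patience 4: stop at the 5th."""
    stopper = EarlyStopper(patience=4)
    decisions = [stopper.update(5.0) for _ in range(5)]
    assert decisions == [False, False, False, False, True]


def test_early_stopper_resets_on_improvement():
    stopper = EarlyStopper(patience=2)
    assert not stopper.update(5.0)
    assert not stopper.update(5.0)
    assert not stopper.update(4.0)  # improvement resets the counter
    assert not stopper.update(4.5)
    assert stopper.update(4.2)


def _tiny_setup():
    songs = make_songs(4, seed=11)
    prepped = to_spects(songs)
    lm = LabelMap(sorted({s.label for _, ann in songs for s in ann}))
    cfg = NetworkConfig(n_classes=lm.n_classes,
                        n_freq_bins=prepped[0][0].n_freq, window_size=32)
    return prepped, lm, cfg


def test_training_deterministic_given_seed():
    prepped, lm, cfg = _tiny_setup()
    tc = TrainConfig(batch_size=4, val_step=4, patience=4, max_steps=8, seed=3)
    h1 = train(prepped[1:], prepped[:1], lm, cfg, tc).history
    h2 = train(prepped[1:], prepped[:1], lm, cfg, tc).history
    assert h1.equals(h2)


def test_missing_class_detected_before_training():
    prepped, lm, cfg = _tiny_setup()
    only_first = [prepped[0]]
    present = set(prepped[0][1].labels)
    missing = [lab for lab in lm.labels if lab not in present]
    if not missing:  # ensure scenario by dropping to a single segment
        ann = Annotation(prepped[0][1].segments[:1])
        only_first = [(prepped[0][0], ann)]
        missing = [lab for lab in lm.labels if lab != ann.segments[0].label]
    tc = TrainConfig(batch_size=2, val_step=2, patience=1, max_steps=2, seed=0)
    with pytest.raises(ValueError, match=missing[0]):
        train(only_first, only_first, lm, cfg, tc)


def test_training_loss_decreases_on_learnable_corpus(desk_checkpoint):
    h = desk_checkpoint.history
    assert len(h) >= 2
    assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]
    assert h["val_frame_error"].min() < 0.10


# ---- prediction tiling -----------------------------------------------------


def _spect_of(T_bins, F):
    rng = np.random.default_rng(6)
    return Spectrogram(s=rng.uniform(size=(F, T_bins)),
                       f=np.arange(float(F)), t=np.arange(T_bins) * 0.002,
                       bin_dur_s=0.002)


def _identity_checkpoint(cfg):
    model = TweetyNet(cfg, seed=5)
    return Checkpoint(
        state=model.state_dict(), net_cfg=cfg,
        labelmap=LabelMap(["a", "b"]),
        normalizer=Normalizer(mu=np.zeros(cfg.n_freq_bins),
                              sigma=np.ones(cfg.n_freq_bins)),
    ), model


def test_tiling_exact_multiple_matches_per_window_forward():
    cfg = NetworkConfig(n_classes=3, n_freq_bins=64, window_size=6)
    ckpt, model = _identity_checkpoint(cfg)
    sp = _spect_of(12, 64)
    out = predict_frame_probabilities(ckpt, sp)
    w0 = model.forward(sp.s[None, None, :, :6]).data[0]
    w1 = model.forward(sp.s[None, None, :, 6:]).data[0]
    assert np.allclose(out, np.concatenate([w0, w1], axis=1), atol=1e-6)


def test_tiling_single_window_is_plain_forward():
    cfg = NetworkConfig(n_classes=3, n_freq_bins=64, window_size=9)
    ckpt, model = _identity_checkpoint(cfg)
    sp = _spect_of(9, 64)
    out = predict_frame_probabilities(ckpt, sp)
    assert np.allclose(out, model.forward(sp.s[None, None]).data[0], atol=1e-6)


def test_tiling_tail_right_aligned_later_window_wins():
    cfg = NetworkConfig(n_classes=3, n_freq_bins=64, window_size=8)
    ckpt, model = _identity_checkpoint(cfg)
    sp = _spect_of(11, 64)  # W + 3
    out = predict_frame_probabilities(ckpt, sp)
    w0 = model.forward(sp.s[None, None, :, :8]).data[0]
    w1 = model.forward(sp.s[None, None, :, 3:]).data[0]
    oracle = np.concatenate([w0[:, :3], w1], axis=1)
    assert out.shape == (3, 11)
    assert np.allclose(out, oracle, atol=1e-6)


def test_prediction_rejects_mismatched_frequency_axis():
    cfg = NetworkConfig(n_classes=3, n_freq_bins=64, window_size=4)
    ckpt, _ = _identity_checkpoint(cfg)
    with pytest.raises(ValueError, match="128"):
        predict_frame_probabilities(ckpt, _spect_of(10, 128))


# ---- checkpoint ------------------------------------------------------------


def test_checkpoint_round_trip(tmp_path):
    cfg = NetworkConfig(n_classes=3, n_freq_bins=64, window_size=6)
    ckpt, _ = _identity_checkpoint(cfg)
    import pandas as pd

    ckpt.history = pd.DataFrame(
        {"step": [4], "train_loss": [1.0], "val_frame_error": [0.5]}
    )
    path = tmp_path / "ckpt.npz"
    ckpt.save(path)
    loaded = Checkpoint.load(path)
    assert loaded.net_cfg == cfg
    assert loaded.labelmap.labels == ["a", "b"]
    sp = _spect_of(6, 64)
    assert np.allclose(
        predict_frame_probabilities(loaded, sp),
        predict_frame_probabilities(ckpt, sp),
    )
    assert loaded.history["val_frame_error"].iloc[0] == 0.5
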