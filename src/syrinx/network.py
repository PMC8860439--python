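"""The frame-classification network, its training loop, and bout prediction.

The architecture (class :class:`TweetyNet`, after the model of that name
used for birdsong annotation) maps a spectrogram window of shape
``(F frequency bins, W time bins)`` to per-time-bin class scores
``(C, W)``:

1. two convolutional blocks — 5x5 convolution (stride 1, 'same' padding,
   32 then 64 filters, ReLU) followed by (8, 1) max pooling with (8, 1)
   stride, which downsamples frequency only and never the time axis;
2. the feature maps are flattened per time bin and fed to a bidirectional
   LSTM whose hidden size defaults to the flattened feature dimension;
3. a linear projection of the concatenated forward/backward hidden states
   onto the ``C`` classes (syllables plus background).

No operation changes the temporal dimension anywhere before the linear
layer, so each of the ``W`` input time bins receives a score vector.
Training uses per-bin cross-entropy (background bins contribute like any
other class), the Adam optimizer, random non-repeating window sampling,
and early stopping on validation frame error.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _tensor as T
from .annotation import Annotation
from .dataset import (
    LabelMap,
    Normalizer,
    Spectrogram,
    WindowSampler,
    annotation_to_frame_labels,
    apply_normalizer,
    fit_normalizer,
)

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TweetyNet",
    "Checkpoint",
    "EarlyStopper",
    "train",
    "predict_frame_probabilities",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architectural hyperparameters.

    ``hidden_size="auto"`` sets the LSTM hidden state equal to the
    flattened per-time-bin feature dimension.
    """

    n_classes: int
    n_freq_bins: int
    window_size: int
    conv_filters: tuple[int, ...] = (32, 64)
    kernel: tuple[int, int] = (5, 5)
    pool_size: tuple[int, int] = (8, 1)
    pool_stride: tuple[int, int] = (8, 1)
    hidden_size: int | str = "auto"
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.pool_size[1] != 1 or self.pool_stride[1] != 1:
            raise ValueError(
                "pooling must not downsample the temporal dimension "
                "(pool size and stride must be 1 along time)"
            )
        if self.pool_size[0] != self.pool_stride[0]:
            raise ValueError("pooling window and stride must match on frequency axis")
        k = self.pool_size[0]
        f_out = self.n_freq_bins
        for _ in self.conv_filters:
            f_out //= k
        if f_out < 1:
            raise ValueError(
                f"n_freq_bins={self.n_freq_bins} is too small: each of the "
                f"{len(self.conv_filters)} pooling layers divides the frequency "
                f"axis by {k}, leaving floor({self.n_freq_bins}/{k**len(self.conv_filters)})"
                f"={f_out} bins; at least {k**len(self.conv_filters)} frequency "
                "bins are required"
            )
        if not self.bidirectional:
            raise ValueError("only the bidirectional recurrent layer is supported")

    @property
    def freq_bins_after_pooling(self) -> int:
        f = self.n_freq_bins
        for _ in self.conv_filters:
            f //= self.pool_size[0]
        return f

    @property
    def n_features(self) -> int:
        """Flattened per-time-bin feature dimension entering the LSTM."""
        return self.conv_filters[-1] * self.freq_bins_after_pooling

    @property
    def resolved_hidden_size(self) -> int:
        if self.hidden_size == "auto":
            return self.n_features
        return int(self.hidden_size)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam + early stopping)."""

    lr: float = 0.001
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    batch_size: int = 8
    val_step: int = 250
    patience: int = 4
    max_epochs: int = 2
    max_steps: int | None = None
    monitor_ser: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if min(self.lr, self.eps, self.batch_size, self.val_step) <= 0:
            raise ValueError("lr, eps, batch_size and val_step must be positive")


class TweetyNet:
    """Convolutional-recurrent frame classifier (see module docstring)."""

    #: parameter/activation dtype; single precision is ample for training
    dtype = np.float32

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        kh, kw = cfg.kernel
        self.params: dict[str, T.Tensor] = {}

        def param(name, shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            self.params[name] = T.Tensor(
                rng.uniform(-bound, bound, shape).astype(self.dtype),
                requires_grad=True,
            )

        cin = 1
        for i, cout in enumerate(cfg.conv_filters):
            param(f"conv{i}.w", (cout, cin, kh, kw), cin * kh * kw)
            param(f"conv{i}.b", (cout,), cin * kh * kw)
            cin = cout
        d, h = cfg.n_features, cfg.resolved_hidden_size
        for direction in ("fw", "bw"):
            param(f"lstm.{direction}.w_ih", (d, 4 * h), h)
            param(f"lstm.{direction}.w_hh", (h, 4 * h), h)
            param(f"lstm.{direction}.b", (4 * h,), h)
        param("out.w", (2 * h, cfg.n_classes), 2 * h)
        param("out.b", (cfg.n_classes,), 2 * h)

    # -- forward ------------------------------------------------------------

    def _lstm_direction(self, steps: list[T.Tensor], direction: str, batch: int):
        h_dim = self.cfg.resolved_hidden_size
        w_ih = self.params[f"lstm.{direction}.w_ih"]
        w_hh = self.params[f"lstm.{direction}.w_hh"]
        b = self.params[f"lstm.{direction}.b"]
        h = T.Tensor(np.zeros((batch, h_dim), dtype=w_ih.data.dtype))
        c = T.Tensor(np.zeros((batch, h_dim), dtype=w_ih.data.dtype))
        outs = []
        for x_t in steps:
            gates = x_t.matmul(w_ih) + h.matmul(w_hh) + b
            i = gates[:, :h_dim].sigmoid()
            f = gates[:, h_dim: 2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim: 3 * h_dim].tanh()
            o = gates[:, 3 * h_dim:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs

    def forward(
        self, x: np.ndarray | T.Tensor, return_intermediates: bool = False
    ):
        """Map (B, 1, F, W) input windows to (B, C, W) class scores."""
        cfg = self.cfg
        if not isinstance(x, T.Tensor):
            x = T.Tensor(np.asarray(x, dtype=self.dtype))
        if x.shape[2] != cfg.n_freq_bins:
            raise ValueError(
                f"input has {x.shape[2]} frequency bins, network expects "
                f"{cfg.n_freq_bins}"
            )
        shapes: dict[str, tuple[int, ...]] = {"input": x.shape}
        out = x
        for i in range(len(cfg.conv_filters)):
            out = T.conv2d_same(
                out, self.params[f"conv{i}.w"], self.params[f"conv{i}.b"]
            ).relu()
            shapes[f"conv{i + 1}"] = out.shape
            out = T.maxpool_freq(out, cfg.pool_size[0])
            shapes[f"pool{i + 1}"] = out.shape
        b, c, f, w = out.shape
        feats = out.transpose(0, 3, 1, 2).reshape(b, w, c * f)
        shapes["flatten"] = feats.shape
        steps = [feats[:, t_i, :] for t_i in range(w)]
        fw = self._lstm_direction(steps, "fw", b)
        bw = self._lstm_direction(steps[::-1], "bw", b)[::-1]
        hidden = T.concat(
            [T.stack(fw, axis=1), T.stack(bw, axis=1)], axis=2
        )
        shapes["lstm"] = hidden.shape
        h2 = hidden.reshape(b * w, hidden.shape[2])
        logits = h2.matmul(self.params["out.w"]) + self.params["out.b"]
        scores = logits.reshape(b, w, cfg.n_classes).transpose(0, 2, 1)
        shapes["output"] = scores.shape
        if return_intermediates:
            return scores, shapes
        return scores

    __call__ = forward

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=self.dtype).copy()


class Adam:
    """Adam optimizer over a dict of parameter tensors."""

    def __init__(self, params: dict[str, T.Tensor], tc: TrainConfig) -> None:
        self.params = params
        self.lr, (self.b1, self.b2) = tc.lr, tc.betas
        self.eps, self.wd = tc.eps, tc.weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


class EarlyStopper:
    """Stop after ``patience`` consecutive validations without improvement."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.bad = 0

    def update(self, err: float) -> bool:
        """Record a validation error; return True when training should stop."""
        if err < self.best:
            self.best = err
            self.bad = 0
        else:
            self.bad += 1
        return self.bad >= self.patience


@dataclass
class Checkpoint:
    """Everything needed to reproduce a forward pass: learned parameters,
    architecture, label map, normalizer, and the training history."""

    state: dict[str, np.ndarray]
    net_cfg: NetworkConfig
    labelmap: LabelMap
    normalizer: Normalizer
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def build_model(self) -> TweetyNet:
        model = TweetyNet(self.net_cfg)
        model.load_state_dict(self.state)
        return model

    def save(self, path) -> None:
        meta = {
            "net_cfg": asdict(self.net_cfg),
            "labels": self.labelmap.labels,
            "history": self.history.to_json(orient="split"),
        }
        arrays = {f"param/{k}": v for k, v in self.state.items()}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            mu=self.normalizer.mu,
            sigma=self.normalizer.sigma,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg_dict = meta["net_cfg"]
            for key in ("conv_filters", "kernel", "pool_size", "pool_stride"):
                cfg_dict[key] = tuple(cfg_dict[key])
            state = {
                k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")
            }
            return cls(
                state=state,
                net_cfg=NetworkConfig(**cfg_dict),
                labelmap=LabelMap(labels=meta["labels"]),
                normalizer=Normalizer(mu=z["mu"], sigma=z["sigma"]),
                history=pd.read_json(io.StringIO(meta["history"]), orient="split"),
            )


def _tile_starts(n_time: int, window: int) -> list[int]:
    """Consecutive non-overlapping window starts; the final window is
    right-aligned when the length is not divisible, and overlapping bins
    take the later window's scores."""
    starts = list(range(0, n_time - window + 1, window))
    if starts[-1] != n_time - window:
        starts.append(n_time - window)
    return starts


def predict_frame_probabilities(
    checkpoint: Checkpoint, spect: Spectrogram, model: TweetyNet | None = None
) -> np.ndarray:
    """Per-time-bin class scores (C, T) for a whole bout.

    Applies the checkpoint's normalizer, feeds consecutive windows through
    the network, and concatenates the outputs; the tail window is
    right-aligned (see :func:`_tile_starts`).
    """
    cfg = checkpoint.net_cfg
    if spect.n_freq != cfg.n_freq_bins:
        raise ValueError(
            f"spectrogram has {spect.n_freq} frequency bins, checkpoint expects "
            f"{cfg.n_freq_bins}"
        )
    if spect.n_time < cfg.window_size:
        raise ValueError(
            f"spectrogram has {spect.n_time} time bins, shorter than the "
            f"network window ({cfg.window_size})"
        )
    if model is None:
        model = checkpoint.build_model()
    s = apply_normalizer(checkpoint.normalizer, spect).s
    out = np.empty((cfg.n_classes, spect.n_time))
    for start in _tile_starts(spect.n_time, cfg.window_size):
        window = s[None, None, :, start: start + cfg.window_size]
        scores = model.forward(window).data[0]
        out[:, start: start + cfg.window_size] = scores
    return out


def _frame_error_on_set(
    model: TweetyNet,
    checkpoint_like: Checkpoint,
    data: list[tuple[Spectrogram, np.ndarray]],
) -> float:
    errors, total = 0, 0
    for spect, y_true in data:
        scores = predict_frame_probabilities(checkpoint_like, spect, model=model)
        y_pred = scores.argmax(axis=0)
        errors += int((y_pred != y_true).sum())
        total += len(y_true)
    return errors / total


def train(
    train_data: list[tuple[Spectrogram, Annotation]],
    val_data: list[tuple[Spectrogram, Annotation]],
    labelmap: LabelMap,
    net_cfg: NetworkConfig,
    tc: TrainConfig,
) -> Checkpoint:
    """Train the network; return the checkpoint with the best validation
    frame error.

    The loss is per-bin cross-entropy over all classes including
    background.  Validation runs every ``tc.val_step`` optimization steps
    on the full validation set; training stops early after ``tc.patience``
    validations without improvement, or at the step budget
    (``tc.max_steps`` if set, else ``tc.max_epochs`` passes over every
    possible window).  Fully reproducible given ``tc.seed``.
    """
    present = set()
    for _, ann in train_data:
        present.update(ann.labels)
    missing = [lab for lab in labelmap.labels if lab not in present]
    if missing:
        raise ValueError(
            f"syllable classes absent from the training set: {missing}"
        )

    normalizer = fit_normalizer([sp for sp, _ in train_data])

    train_prepped = []
    for sp, ann in train_data:
        y = annotation_to_frame_labels(ann, sp.t, sp.bin_dur_s, labelmap)
        train_prepped.append((apply_normalizer(normalizer, sp), y))
    # validation keeps raw spectrograms: prediction normalizes internally
    val_prepped = [
        (sp, annotation_to_frame_labels(ann, sp.t, sp.bin_dur_s, labelmap))
        for sp, ann in val_data
    ]

    sampler = WindowSampler(
        train_prepped, net_cfg.window_size, tc.batch_size, seed=tc.seed
    )
    model = TweetyNet(net_cfg, seed=tc.seed)
    opt = Adam(model.params, tc)
    stopper = EarlyStopper(tc.patience)
    ckpt = Checkpoint(
        state=model.state_dict(),
        net_cfg=net_cfg,
        labelmap=labelmap,
        normalizer=normalizer,
    )

    steps_per_epoch = -(-sampler.windows_per_epoch // tc.batch_size)
    max_steps = tc.max_steps or tc.max_epochs * steps_per_epoch

    history_rows = []
    best_state = model.state_dict()
    running_loss: list[float] = []
    step = 0
    for x, y in sampler.infinite_batches():
        if step >= max_steps:
            break
        step += 1
        scores = model.forward(x)  # (B, C, W)
        b, c, w = scores.shape
        logits = scores.transpose(0, 2, 1).reshape(b * w, c)
        loss = T.softmax_cross_entropy(logits, y.reshape(-1))
        opt.zero_grad()
        loss.backward()
        opt.step()
        running_loss.append(float(loss.data))

        if step % tc.val_step == 0 or step == max_steps:
            val_err = _frame_error_on_set(model, ckpt, val_prepped)
            row = {
                "step": step,
                "train_loss": float(np.mean(running_loss)),
                "val_frame_error": val_err,
            }
            if tc.monitor_ser:
                row["val_ser"] = _val_ser(model, ckpt, val_data)
            history_rows.append(row)
            running_loss = []
            if val_err < stopper.best:
                best_state = model.state_dict()
            if stopper.update(val_err):
                break

    if not history_rows:  # budget smaller than one validation interval
        best_state = model.state_dict()
    ckpt.state = best_state
    ckpt.history = pd.DataFrame(history_rows)
    return ckpt


def _val_ser(model, ckpt, val_data) -> float:
    # local import: metrics depends on nothing here, avoid a cycle at import
    from .metrics import syllable_error_rate
    from .postprocess import segments_raw

    rates = []
    for spect, ann in val_data:
        scores = predict_frame_probabilities(ckpt, spect, model=model)
        y_pred = scores.argmax(axis=0)
        pred_labels = [
            ckpt.labelmap.to_label(cls)
            for _, _, cls in segments_raw(y_pred, spect.t, spect.bin_dur_s)
        ]
        if len(ann.labels) > 0:
            rates.append(syllable_error_rate(ann.labels, pred_labels))
    return float(np.mean(rates)) if rates else np.nan
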