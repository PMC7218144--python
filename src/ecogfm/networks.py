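"""Steps 2 & 4: the channel-classification network family.

Every variant maps a sub-block — a short sequence of per-window hand-crafted
feature vectors, optionally paired with its parent block's AR coefficient
vector — to the probability that the channel generating it responds to the
language task. The family mirrors an ablation ladder:

* ``AT1`` — fully convolutional time module: stacked same-padded 1-D
  convolutions over the window axis, global average pooling, FC, sigmoid.
* ``AT2`` — adds a parallel LSTM path whose final hidden state is merged
  with the pooled convolutional features before the head.
* ``AT_AR1`` — adds the frequency path: the AR vector through one fully
  connected layer, concatenated with the time representation at the head.
* ``AT_AR2`` — fusion by 1-D convolution: the frequency representation is
  tiled across time steps, concatenated with the convolutional sequence,
  convolved again, and pooled.
* ``AT_AR3`` — fusion by fully connected layers after concatenation.
* ``AT_AR4`` — as ``AT_AR3`` with a deeper (two-layer) frequency module.
* ``AT_AR3_EF`` — early feature fusion: several hand-crafted features enter
  as parallel input channels of one ``AT_AR3``.
* ``AT_AR3_LF1`` — late fusion: one time module per feature plus a single
  shared frequency module, all merged in the fusion head.
* ``AT_AR3_LF2`` — late fusion with the frequency representation injected
  into each per-feature path before the feature-fusion layer.
* ``PER_STORY`` — one ``AT_AR3`` backbone per story; the per-story
  representations are concatenated and fed through a final FC layer.

Control-data twins (``CT-AR2``/``CT-AR3`` in result tables) reuse these
architectures unchanged on control-block sub-blocks; that is a data
selection, not a different network.

Domain fusion is concatenation along the feature axis — never stacking or
an element-wise product — so the time and frequency vectors may have
different widths.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    ConfigurationError,
    TrainingDivergenceError,
    ValidationError,
)
from .nn.autodiff import (
    Tensor,
    concat,
    conv1d,
    dense,
    gap,
    lstm_last,
    mul_const,
    parameter,
    relu,
    tile_time,
)
from .nn.train import AdamOptimizer, TrainConfig, bce_with_logits, sigmoid
from .signal_io import NRC, PRC

VARIANTS = (
    "AT1",
    "AT2",
    "AT_AR1",
    "AT_AR2",
    "AT_AR3",
    "AT_AR4",
    "AT_AR3_EF",
    "AT_AR3_LF1",
    "AT_AR3_LF2",
    "PER_STORY",
)

_TIME_ONLY = {"AT1", "AT2"}
_PER_FEATURE = {"AT_AR3_LF1", "AT_AR3_LF2"}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture variant plus input shapes and layer hyperparameters.

    ``n_windows`` is the sub-block length in windows (the time axis),
    ``n_features`` the number of hand-crafted features entering the time
    path, ``ar_dim`` the width of the frequency path (None for the
    time-only variants). Layer sizes default to a standard small
    fully-convolutional-network recipe and are freely configurable; none of
    the pipeline's behaviour contracts depend on their exact values.
    """

    variant: str
    n_windows: int
    n_features: int = 1
    ar_dim: Optional[int] = None
    n_stories: int = 5
    conv_filters: tuple[int, ...] = (64, 128, 64)
    conv_kernels: tuple[int, ...] = (8, 5, 3)
    fusion_conv_filters: int = 64
    fusion_conv_kernel: int = 3
    lstm_units: int = 64
    fc_units: int = 64
    dropout: float = 0.3

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ConfigurationError("conv_filters and conv_kernels lengths differ")
        if self.n_windows < 1 or self.n_features < 1:
            raise ConfigurationError("n_windows and n_features must be >= 1")
        if self.variant in _TIME_ONLY:
            if self.ar_dim is not None:
                raise ConfigurationError(
                    f"{self.variant} has no frequency path; ar_dim must be None"
                )
        else:
            if self.ar_dim is None or self.ar_dim < 1:
                raise ConfigurationError(
                    f"{self.variant} needs a frequency path; set ar_dim"
                )


def small_spec(variant: str, n_windows: int, n_features: int = 1,
               ar_dim: Optional[int] = None, n_stories: int = 5) -> ModelSpec:
    """A deliberately small configuration for quick experiments and CI."""
    return ModelSpec(
        variant=variant,
        n_windows=n_windows,
        n_features=n_features,
        ar_dim=ar_dim,
        n_stories=n_stories,
        conv_filters=(8, 16),
        conv_kernels=(5, 3),
        fusion_conv_filters=16,
        fusion_conv_kernel=3,
        lstm_units=8,
        fc_units=16,
        dropout=0.2,
    )


def fuse_domains(time_repr: np.ndarray, freq_repr: np.ndarray) -> np.ndarray:
    """Concatenate time and frequency representations along the feature axis.

    ``time_repr`` is (..., F_t) — a vector or a time-step sequence — and
    ``freq_repr`` a matching-batch (..., F_f) vector, tiled across the time
    axis when the time representation is a sequence. The argument order is
    part of the contract: time first, frequency second.
    """
    t = np.asarray(time_repr, dtype=np.float64)
    f = np.asarray(freq_repr, dtype=np.float64)
    if not (np.isfinite(t).all() and np.isfinite(f).all()):
        raise ValidationError("non-finite values in fusion inputs")
    if t.ndim == f.ndim + 1:
        f = np.repeat(f[..., None, :], t.shape[-2], axis=-2)
    elif t.ndim != f.ndim:
        raise ValidationError(
            f"incompatible fusion ranks: time {t.ndim}, frequency {f.ndim}"
        )
    return np.concatenate([t, f], axis=-1)


# ---------------------------------------------------------------------------
# model


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Model:
    """An untrained network: parameter tensors plus a variant-specific forward."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        s = spec

        def add_conv(name: str, cin: int, cout: int, k: int):
            self.params[f"{name}.w"] = parameter(_glorot(rng, (k, cin, cout), k * cin, cout))
            self.params[f"{name}.b"] = parameter(np.zeros(cout))

        def add_dense(name: str, din: int, dout: int):
            self.params[f"{name}.w"] = parameter(_glorot(rng, (din, dout), din, dout))
            self.params[f"{name}.b"] = parameter(np.zeros(dout))

        def add_lstm(name: str, din: int, h: int):
            self.params[f"{name}.wx"] = parameter(_glorot(rng, (din, 4 * h), din, h))
            self.params[f"{name}.wh"] = parameter(_glorot(rng, (h, 4 * h), h, h))
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            self.params[f"{name}.b"] = parameter(b)

        def add_time_module(prefix: str, cin: int) -> int:
            c = cin
            for i, (co, k) in enumerate(zip(s.conv_filters, s.conv_kernels)):
                add_conv(f"{prefix}.conv{i}", c, co, k)
                c = co
            width = c
            if s.variant != "AT1":
                add_lstm(f"{prefix}.lstm", cin, s.lstm_units)
                width += s.lstm_units
            return width

        def add_freq_module(prefix: str) -> int:
            add_dense(f"{prefix}.fc0", s.ar_dim, s.fc_units)
            if s.variant == "AT_AR4":
                add_dense(f"{prefix}.fc1", s.fc_units, s.fc_units)
            return s.fc_units

        v = s.variant
        if v in _PER_FEATURE:
            widths = [add_time_module(f"time{j}", 1) for j in range(s.n_features)]
            fw = add_freq_module("freq")
            if v == "AT_AR3_LF1":
                add_dense("fusion.fc", sum(widths) + fw, s.fc_units)
                add_dense("head", s.fc_units, 1)
            else:  # AT_AR3_LF2: frequency joins each feature path pre-fusion
                for j, w in enumerate(widths):
                    add_dense(f"mix{j}", w + fw, s.fc_units)
                add_dense("fusion.fc", s.n_features * s.fc_units, s.fc_units)
                add_dense("head", s.fc_units, 1)
        elif v == "PER_STORY":
            for st in range(s.n_stories):
                w = add_time_module(f"story{st}.time", s.n_features)
                fw = add_freq_module(f"story{st}.freq")
                add_dense(f"story{st}.fusion", w + fw, s.fc_units)
            add_dense("merge", s.n_stories * s.fc_units, s.fc_units)
            add_dense("head", s.fc_units, 1)
        else:
            tw = add_time_module("time", s.n_features)
            if v in ("AT1", "AT2"):
                add_dense("head", tw, 1)
            elif v == "AT_AR1":
                fw = add_freq_module("freq")
                add_dense("head", tw + fw, 1)
            elif v == "AT_AR2":
                fw = add_freq_module("freq")
                # the conv fusion runs on the conv sequence + tiled frequency
                # vector; the LSTM path vector rejoins after pooling
                add_conv("fusion.conv", s.conv_filters[-1] + fw,
                         s.fusion_conv_filters, s.fusion_conv_kernel)
                add_dense("head", s.fusion_conv_filters + s.lstm_units, 1)
            else:  # AT_AR3 / AT_AR4 / AT_AR3_EF
                fw = add_freq_module("freq")
                add_dense("fusion.fc", tw + fw, s.fc_units)
                add_dense("head", s.fc_units, 1)

    # -- forward helpers ----------------------------------------------------

    def _conv_seq(self, x: Tensor, prefix: str) -> Tensor:
        h = x
        for i in range(len(self.spec.conv_filters)):
            h = relu(conv1d(h, self.params[f"{prefix}.conv{i}.w"],
                            self.params[f"{prefix}.conv{i}.b"]))
        return h

    def _time(self, x_np: np.ndarray, prefix: str) -> Tensor:
        x = Tensor(x_np)
        pooled = gap(self._conv_seq(x, prefix))
        if self.spec.variant == "AT1":
            return pooled
        h = lstm_last(x, self.params[f"{prefix}.lstm.wx"],
                      self.params[f"{prefix}.lstm.wh"], self.params[f"{prefix}.lstm.b"])
        return concat([pooled, h])

    def _freq(self, f_np: np.ndarray, prefix: str) -> Tensor:
        h = relu(dense(Tensor(f_np), self.params[f"{prefix}.fc0.w"],
                       self.params[f"{prefix}.fc0.b"]))
        if self.spec.variant == "AT_AR4":
            h = relu(dense(h, self.params[f"{prefix}.fc1.w"], self.params[f"{prefix}.fc1.b"]))
        return h

    def _dropout(self, h: Tensor, train: bool, rng: Optional[np.random.Generator]) -> Tensor:
        p = self.spec.dropout
        if not train or p <= 0 or rng is None:
            return h
        mask = (rng.random(h.data.shape) >= p) / (1.0 - p)
        return mul_const(h, mask)

    def _head(self, h: Tensor) -> Tensor:
        return dense(h, self.params["head.w"], self.params["head.b"])

    def forward(
        self,
        x_time: np.ndarray,
        x_freq: Optional[np.ndarray] = None,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Logits (B, 1) for a batch of sub-blocks.

        ``x_time`` is (B, T, F) — or (B, S, T, F) for the per-story variant —
        and ``x_freq`` (B, ar_dim) or (B, S, ar_dim) where the variant has a
        frequency path.
        """
        s = self.spec
        v = s.variant
        if v in _TIME_ONLY:
            if x_freq is not None:
                raise ValidationError(f"{v} takes no frequency input")
        elif x_freq is None:
            raise ValidationError(f"{v} requires a frequency input")
        self._check_shapes(x_time, x_freq)

        if v in _PER_FEATURE:
            freq = self._freq(x_freq, "freq")
            if v == "AT_AR3_LF1":
                reprs = [self._time(x_time[:, :, j : j + 1], f"time{j}")
                         for j in range(s.n_features)]
                h = concat(reprs + [freq])
                h = self._dropout(h, train, rng)
                h = relu(dense(h, self.params["fusion.fc.w"], self.params["fusion.fc.b"]))
            else:
                mixed = []
                for j in range(s.n_features):
                    tj = self._time(x_time[:, :, j : j + 1], f"time{j}")
                    hj = relu(dense(concat([tj, freq]), self.params[f"mix{j}.w"],
                                    self.params[f"mix{j}.b"]))
                    mixed.append(hj)
                h = concat(mixed)
                h = self._dropout(h, train, rng)
                h = relu(dense(h, self.params["fusion.fc.w"], self.params["fusion.fc.b"]))
            return self._head(h)

        if v == "PER_STORY":
            story_reprs = []
            for st in range(s.n_stories):
                t = self._time(x_time[:, st], f"story{st}.time")
                f = self._freq(x_freq[:, st], f"story{st}.freq")
                z = relu(dense(concat([t, f]), self.params[f"story{st}.fusion.w"],
                               self.params[f"story{st}.fusion.b"]))
                story_reprs.append(z)
            h = concat(story_reprs)
            h = self._dropout(h, train, rng)
            h = relu(dense(h, self.params["merge.w"], self.params["merge.b"]))
            return self._head(h)

        if v in ("AT1", "AT2"):
            h = self._time(x_time, "time")
            h = self._dropout(h, train, rng)
            return self._head(h)

        freq = self._freq(x_freq, "freq")
        if v == "AT_AR1":
            h = concat([self._time(x_time, "time"), freq])
            h = self._dropout(h, train, rng)
            return self._head(h)
        if v == "AT_AR2":
            x = Tensor(x_time)
            seq = self._conv_seq(x, "time")
            lstm_h = lstm_last(x, self.params["time.lstm.wx"],
                               self.params["time.lstm.wh"], self.params["time.lstm.b"])
            fused = concat([seq, tile_time(freq, x_time.shape[1])], axis=-1)
            fused = relu(conv1d(fused, self.params["fusion.conv.w"],
                                self.params["fusion.conv.b"]))
            h = concat([gap(fused), lstm_h])
            h = self._dropout(h, train, rng)
            return self._head(h)
        # AT_AR3 / AT_AR4 / AT_AR3_EF
        h = concat([self._time(x_time, "time"), freq])
        h = self._dropout(h, train, rng)
        h = relu(dense(h, self.params["fusion.fc.w"], self.params["fusion.fc.b"]))
        return self._head(h)

    def _check_shapes(self, x_time: np.ndarray, x_freq: Optional[np.ndarray]) -> None:
        s = self.spec
        if s.variant == "PER_STORY":
            want_t = (s.n_stories, s.n_windows, s.n_features)
            want_f = (s.n_stories, s.ar_dim)
        else:
            want_t = (s.n_windows, s.n_features)
            want_f = None if s.ar_dim is None else (s.ar_dim,)
        if tuple(x_time.shape[1:]) != want_t:
            raise ValidationError(
                f"time input shape {x_time.shape[1:]} != expected {want_t}"
            )
        if x_freq is not None and tuple(x_freq.shape[1:]) != want_f:
            raise ValidationError(
                f"frequency input shape {x_freq.shape[1:]} != expected {want_f}"
            )

    def parameter_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct an untrained network for the given variant and shapes."""
    return Model(spec, seed=seed)


# ---------------------------------------------------------------------------
# training


@dataclass
class SubblockDataset:
    """Labeled sub-block instances; every instance inherits its channel label."""

    x_time: np.ndarray  # (N, T, F) or (N, S, T, F)
    y: np.ndarray  # (N,) in {0, 1}; 1 = positive response
    channel_ids: np.ndarray  # (N,) channel identity, for grouped splits
    x_freq: Optional[np.ndarray] = None  # (N, A) or (N, S, A)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "SubblockDataset":
        return SubblockDataset(
            x_time=self.x_time[idx],
            y=self.y[idx],
            channel_ids=self.channel_ids[idx],
            x_freq=None if self.x_freq is None else self.x_freq[idx],
        )


@dataclass
class Normalizer:
    """Per-feature z-scoring fitted on the training fold only."""

    time_mean: np.ndarray
    time_std: np.ndarray
    freq_mean: Optional[np.ndarray] = None
    freq_std: Optional[np.ndarray] = None

    @classmethod
    def fit(cls, ds: SubblockDataset) -> "Normalizer":
        axes = tuple(range(ds.x_time.ndim - 1))
        tm = ds.x_time.mean(axis=axes)
        ts = ds.x_time.std(axis=axes)
        ts = np.where(ts > 0, ts, 1.0)
        fm = fs_ = None
        if ds.x_freq is not None:
            faxes = tuple(range(ds.x_freq.ndim - 1))
            fm = ds.x_freq.mean(axis=faxes)
            fs_ = ds.x_freq.std(axis=faxes)
            fs_ = np.where(fs_ > 0, fs_, 1.0)
        return cls(time_mean=tm, time_std=ts, freq_mean=fm, freq_std=fs_)

    def apply(self, x_time: np.ndarray, x_freq: Optional[np.ndarray]):
        xt = (x_time - self.time_mean) / self.time_std
        xf = None
        if x_freq is not None:
            xf = (x_freq - self.freq_mean) / self.freq_std
        return xt, xf


@dataclass
class TrainedModel:
    """A fitted network with its normalization statistics and history."""

    model: Model
    normalizer: Normalizer
    history: dict[str, list[float]]
    config: TrainConfig
    seed: int

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


def weights_hash(trained: TrainedModel) -> str:
    """Stable digest of all learned parameters (determinism checks)."""
    h = hashlib.sha256()
    for k in sorted(trained.model.params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(trained.model.params[k].data).tobytes())
    return h.hexdigest()


def save_model(trained: TrainedModel, path, extra: Optional[dict] = None) -> None:
    """Serialize a trained model (spec, weights, normalizer, config) to .npz."""
    import dataclasses
    import json

    meta = {
        "spec": dataclasses.asdict(trained.spec),
        "config": dataclasses.asdict(trained.config),
        "seed": trained.seed,
        "history": trained.history,
        "extra": extra or {},
    }
    arrays = {f"w:{k}": v.data for k, v in trained.model.params.items()}
    arrays["n:time_mean"] = trained.normalizer.time_mean
    arrays["n:time_std"] = trained.normalizer.time_std
    if trained.normalizer.freq_mean is not None:
        arrays["n:freq_mean"] = trained.normalizer.freq_mean
        arrays["n:freq_std"] = trained.normalizer.freq_std
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> tuple[TrainedModel, dict]:
    """Inverse of :func:`save_model`; returns the model and its extra metadata."""
    import json

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        spec_d = meta["spec"]
        for key in ("conv_filters", "conv_kernels"):
            spec_d[key] = tuple(spec_d[key])
        spec = ModelSpec(**spec_d)
        model = Model(spec, seed=meta["seed"])
        model.load_state_dict(
            {k[2:]: npz[k] for k in npz.files if k.startswith("w:")}
        )
        norm = Normalizer(
            time_mean=npz["n:time_mean"],
            time_std=npz["n:time_std"],
            freq_mean=npz["n:freq_mean"] if "n:freq_mean" in npz.files else None,
            freq_std=npz["n:freq_std"] if "n:freq_std" in npz.files else None,
        )
    trained = TrainedModel(
        model=model,
        normalizer=norm,
        history=meta["history"],
        config=TrainConfig(**meta["config"]),
        seed=meta["seed"],
    )
    return trained, meta["extra"]


def _grouped_val_split(ds: SubblockDataset, frac: float, rng: np.random.Generator):
    """Hold out whole channels (>=1 per class when possible) for early stopping."""
    chans = np.unique(ds.channel_ids)
    labels = {c: int(ds.y[ds.channel_ids == c][0]) for c in chans}
    pos = rng.permutation([c for c in chans if labels[c] == 1])
    neg = rng.permutation([c for c in chans if labels[c] == 0])
    n_pos = max(1, int(round(frac * len(pos)))) if len(pos) > 1 else 0
    n_neg = max(1, int(round(frac * len(neg)))) if len(neg) > 1 else 0
    if n_pos == 0 or n_neg == 0:
        return None
    val = set(pos[:n_pos]) | set(neg[:n_neg])
    val_mask = np.isin(ds.channel_ids, list(val))
    return ~val_mask, val_mask


def train_model(model: Model, dataset: SubblockDataset, config: TrainConfig) -> TrainedModel:
    """Fit a network on labeled sub-blocks with Adam + binary cross-entropy.

    Normalization statistics come from this (training) dataset alone. Early
    stopping monitors loss on a held-out channel-grouped slice of the
    training channels and restores the best parameters. Fully deterministic
    for a fixed seed.
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValidationError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)

    norm = Normalizer.fit(dataset)
    split = _grouped_val_split(dataset, config.val_fraction, rng)
    if split is not None:
        tr = dataset.subset(np.where(split[0])[0])
        va = dataset.subset(np.where(split[1])[0])
        if len(np.unique(tr.y)) < 2:
            tr, va, split = dataset, None, None
    else:
        tr, va = dataset, None

    xt_tr, xf_tr = norm.apply(tr.x_time, tr.x_freq)
    if va is not None:
        xt_va, xf_va = norm.apply(va.x_time, va.x_freq)

    opt = AdamOptimizer(model.parameter_list(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    stall = 0
    n = len(tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits = model.forward(
                xt_tr[idx],
                None if xf_tr is None else xf_tr[idx],
                train=True,
                rng=rng,
            )
            loss = bce_with_logits(logits, tr.y[idx])
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        history["train_loss"].append(total / n)

        if va is not None:
            logits = model.forward(xt_va, xf_va)
            vloss = float(bce_with_logits(logits, va.y).data)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = model.state_dict()
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if va is not None:
        model.load_state_dict(best_state)
    return TrainedModel(model=model, normalizer=norm, history=history,
                        config=config, seed=config.seed)


def predict_subblocks(
    trained: TrainedModel,
    x_time: np.ndarray,
    x_freq: Optional[np.ndarray] = None,
    batch_size: int = 512,
):
    """Per-sub-block probabilities and hard labels (PRC iff p > 0.5).

    A probability of exactly 0.5 is labelled negative: the positive call
    requires a strict majority of evidence, matching the channel-level
    voting rule.
    """
    xt, xf = trained.normalizer.apply(x_time, x_freq)
    probs = np.empty(len(xt))
    for lo in range(0, len(xt), batch_size):
        sl = slice(lo, lo + batch_size)
        logits = trained.model.forward(xt[sl], None if xf is None else xf[sl])
        probs[sl] = sigmoid(logits.data.ravel())
    labels = np.where(probs > 0.5, PRC, NRC)
    return probs, labels
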