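"""LSTM sequence classifier for subclinical tremor differentiation.

Architecture: feature-wise input normalization -> single LSTM layer over
the STFT frame sequence -> elementwise sum of the hidden activations over
time (each hidden unit's activation state is the sum of its per-step
values) -> ReLU -> a stack of 1-3 fully connected layers -> softmax over
the classes {0: normal, 1: PD, 2: ET} (or 2 classes for PD vs ET).

Training minimizes categorical cross-entropy with Adam (default) or SGD at
batch size 32, with dropout and L2 weight decay for regularization and
early stopping on validation accuracy.  A seeded random hyperparameter
search over the study's ranges (hidden units 10-300 step 10, dropout
1e-6..1, L2 1e-5..1, 1-3 FC layers of width 10-300 step 10, batch 16-128
step 4, SGD vs Adam) drives architecture selection.

A convolutional-LSTM reference model (two ReLU conv layers of 30 filters,
lengths 20 and 10, each followed by max pooling, then a fully connected
layer feeding an LSTM) is provided for comparison on the raw displacement
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._nn import (Adam, Conv1D, Dense, FeatureNormalizer, LSTMLayer,
                  MaxPool1D, SGD, cross_entropy_with_grad, sigmoid, softmax)
from .sampling import AugmentationConfig, Dataset, FoldPlan, oversample_balance

__all__ = [
    "lstm_step",
    "aggregate_hidden",
    "ModelConfig",
    "TrainConfig",
    "SearchSpace",
    "TremorLSTM",
    "BaselineConvLSTM",
    "build_baseline_convlstm",
    "train_model",
    "train_cv",
    "hyperparameter_search",
    "stack_sequences",
]


# ---------------------------------------------------------------------------
# equation-level cell, used by unit tests and as executable documentation
# ---------------------------------------------------------------------------

def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray,
              U: dict[str, np.ndarray], W: dict[str, np.ndarray],
              b: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """One LSTM cell update from per-gate weight matrices.

    Gates: I_t = sigma(x U_i + h_prev W_i), likewise f_t and O_t; the
    candidate Cbar_t = tanh(x U_c + h_prev W_c); the cell state
    C_t = f_t * C_{t-1} + I_t * Cbar_t; the hidden output
    h_t = O_t * tanh(C_t).  Biases are optional (zero when absent).

    Returns a dict with keys I, f, O, Cbar, C, h.
    """
    x_t, h_prev, C_prev = (np.atleast_1d(np.asarray(a, dtype=float))
                           for a in (x_t, h_prev, C_prev))
    if not all(np.all(np.isfinite(a)) for a in (x_t, h_prev, C_prev)):
        raise ValueError("non-finite cell inputs")

    def affine(gate: str) -> np.ndarray:
        z = x_t @ np.atleast_2d(U[gate]) + h_prev @ np.atleast_2d(W[gate])
        if b is not None:
            z = z + b[gate]
        return z

    I = sigmoid(affine("i"))
    f = sigmoid(affine("f"))
    O = sigmoid(affine("o"))
    Cbar = np.tanh(affine("c"))
    C = f * C_prev + I * Cbar
    h = O * np.tanh(C)
    return {"I": I, "f": f, "O": O, "Cbar": Cbar, "C": C, "h": h}


def aggregate_hidden(h_seq: np.ndarray) -> np.ndarray:
    """Sum the hidden activations over time, per hidden unit.

    h_seq: (T, H) or (B, T, H); the time axis is the second-to-last.
    """
    h_seq = np.asarray(h_seq, dtype=float)
    if h_seq.shape[-2] == 0:
        raise ValueError("empty hidden sequence")
    return h_seq.sum(axis=-2)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    n_features: int = 105
    n_classes: int = 3
    hidden_units: int = 50
    fc_widths: tuple[int, ...] = (50,)
    dropout: float = 0.2
    seed: int = 0


@dataclass
class TrainConfig:
    optimizer: str = "adam"          # {"adam", "sgd"}
    batch_size: int = 32
    learning_rate: float = 3e-3
    l2: float = 1e-4
    max_epochs: int = 80
    patience: int = 10               # validation checks without improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if not (16 <= self.batch_size <= 128):
            raise ValueError("batch size outside the searched range 16-128")


@dataclass
class SearchSpace:
    hidden_units: tuple[int, int, int] = (10, 300, 10)     # lo, hi, step
    dropout: tuple[float, float] = (1e-6, 1.0)             # log-uniform
    l2: tuple[float, float] = (1e-5, 1.0)                  # log-uniform
    fc_layers: tuple[int, int] = (1, 3)
    fc_width: tuple[int, int, int] = (10, 300, 10)
    batch_size: tuple[int, int, int] = (16, 128, 4)
    optimizers: tuple[str, ...] = ("sgd", "adam")

    def sample(self, rng: np.random.Generator) -> dict:
        def grid(lo, hi, step):
            return int(rng.choice(np.arange(lo, hi + 1, step)))

        def loguni(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        n_fc = int(rng.integers(self.fc_layers[0], self.fc_layers[1] + 1))
        return {
            "hidden_units": grid(*self.hidden_units),
            "dropout": loguni(*self.dropout),
            "l2": loguni(*self.l2),
            "fc_widths": tuple(grid(*self.fc_width) for _ in range(n_fc)),
            "batch_size": grid(*self.batch_size),
            "optimizer": str(rng.choice(self.optimizers)),
        }


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class TremorLSTM:
    """The proposed classifier: normalize -> LSTM -> sum over time -> ReLU
    -> FC stack -> softmax."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.normalizer = FeatureNormalizer()
        self.lstm = LSTMLayer(rng, config.n_features, config.hidden_units)
        widths = [config.hidden_units, *config.fc_widths]
        self.fc = [Dense(rng, widths[i], widths[i + 1], relu=True)
                   for i in range(len(widths) - 1)]
        self.out = Dense(rng, widths[-1], config.n_classes)

    @property
    def layers(self):
        return [self.lstm, *self.fc, self.out]

    def fit_normalizer(self, x: np.ndarray) -> None:
        self.normalizer.fit(x)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """x: (B, T, D) -> logits (B, n_classes)."""
        if x.shape[-1] != self.config.n_features:
            raise ValueError(
                f"feature width {x.shape[-1]} != model input {self.config.n_features}")
        xn = self.normalizer.forward(x)
        hs = self.lstm.forward(xn)
        agg = aggregate_hidden(hs)
        a = np.maximum(agg, 0.0)
        self._relu_mask = agg > 0
        self._drop_masks = []
        p = self.config.dropout if training else 0.0
        if p > 0:
            mask = (rng.random(a.shape) >= p) / (1.0 - p)
            a = a * mask
            self._drop_masks.append(mask)
        for layer in self.fc:
            a = layer.forward(a)
            if p > 0:
                mask = (rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
                self._drop_masks.append(mask)
        return self.out.forward(a)

    def backward(self, dlogits: np.ndarray) -> None:
        da = self.out.backward(dlogits)
        for i, layer in enumerate(reversed(self.fc)):
            if self._drop_masks:
                da = da * self._drop_masks[-(i + 1)]
            da = layer.backward(da)
        if self._drop_masks:
            da = da * self._drop_masks[0]
        dagg = da * self._relu_mask
        T = self.lstm._x_shape[1]
        dhs = np.repeat(dagg[:, None, :], T, axis=1)
        self.lstm.backward(dhs)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def state_dict(self) -> dict:
        state = {f"layer{i}.{k}": v.copy()
                 for i, layer in enumerate(self.layers)
                 for k, v in layer.params.items()}
        state["_norm"] = (None if self.normalizer.mean is None
                          else (self.normalizer.mean.copy(), self.normalizer.std.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}.{k}"]
        if state["_norm"] is not None:
            self.normalizer.mean, self.normalizer.std = (a.copy() for a in state["_norm"])


class BaselineConvLSTM:
    """Convolutional-LSTM reference model on raw displacement channels.

    conv(30 filters, length 20, ReLU) -> max-pool(2) -> conv(30 filters,
    length 10, ReLU) -> max-pool(2) -> time-distributed fully connected
    layer -> LSTM -> sum over time -> softmax head.
    """

    def __init__(self, n_channels: int = 3, input_length: int = 1300,
                 n_classes: int = 2, hidden_units: int = 30,
                 fc_width: int = 30, dropout: float = 0.0, seed: int = 0):
        if input_length < 20:
            raise ValueError("input shorter than the first convolution kernel")
        self.config = ModelConfig(n_features=n_channels, n_classes=n_classes,
                                  hidden_units=hidden_units, dropout=dropout,
                                  seed=seed)
        rng = np.random.default_rng(seed)
        self.normalizer = FeatureNormalizer()
        self.conv1 = Conv1D(rng, n_channels, 30, 20)
        self.pool1 = MaxPool1D(2)
        self.conv2 = Conv1D(rng, 30, 30, 10)
        self.pool2 = MaxPool1D(2)
        self.fc_td = Dense(rng, 30, fc_width, relu=True)
        self.lstm = LSTMLayer(rng, fc_width, hidden_units)
        self.out = Dense(rng, hidden_units, n_classes)
        self.layer_shapes: list[tuple[str, tuple[int, ...]]] = []

    @property
    def layers(self):
        return [self.conv1, self.pool1, self.conv2, self.pool2,
                self.fc_td, self.lstm, self.out]

    def fit_normalizer(self, x: np.ndarray) -> None:
        # (B, C, L): normalize per channel
        self.normalizer.fit(np.swapaxes(x, 1, 2))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        xn = np.swapaxes(self.normalizer.forward(np.swapaxes(x, 1, 2)), 1, 2)
        a = self.pool1.forward(self.conv1.forward(xn))
        a = self.pool2.forward(self.conv2.forward(a))
        seq = np.swapaxes(a, 1, 2)                   # (B, T, 30)
        B, T, _ = seq.shape
        self._seq_shape = seq.shape
        td = self.fc_td.forward(seq.reshape(B * T, -1)).reshape(B, T, -1)
        hs = self.lstm.forward(td)
        agg = aggregate_hidden(hs)
        self.layer_shapes = [
            ("conv1+pool1", self.pool1._x_shape),
            ("conv2+pool2", self.pool2._x_shape),
            ("sequence", seq.shape),
            ("lstm_hidden", hs.shape),
        ]
        return self.out.forward(agg)

    def backward(self, dlogits: np.ndarray) -> None:
        dagg = self.out.backward(dlogits)
        B, T, _ = self._seq_shape
        dhs = np.repeat(dagg[:, None, :], T, axis=1)
        dtd = self.lstm.backward(dhs)
        dseq = self.fc_td.backward(dtd.reshape(B * T, -1)).reshape(B, T, -1)
        da = np.swapaxes(dseq, 1, 2)
        da = self.conv2.backward(self.pool2.backward(da))
        self.conv1.backward(self.pool1.backward(da))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def state_dict(self) -> dict:
        state = {f"layer{i}.{k}": v.copy()
                 for i, layer in enumerate(self.layers)
                 for k, v in layer.params.items()}
        state["_norm"] = (None if self.normalizer.mean is None
                          else (self.normalizer.mean.copy(), self.normalizer.std.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}.{k}"]
        if state["_norm"] is not None:
            self.normalizer.mean, self.normalizer.std = (a.copy() for a in state["_norm"])


def build_baseline_convlstm(input_shape: tuple[int, int] = (3, 1300),
                            n_classes: int = 2, seed: int = 0) -> BaselineConvLSTM:
    """Construct the reference conv-LSTM for (channels, length) inputs."""
    return BaselineConvLSTM(n_channels=input_shape[0], input_length=input_shape[1],
                            n_classes=n_classes, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def stack_sequences(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a feature-sequence dataset into (N, T, D) inputs and labels."""
    x = np.stack([s.values for s in ds.sequences])
    y = np.array([s.label for s in ds.sequences], dtype=int)
    return x, y


def _accuracy(model, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(model.predict(x) == y))


def train_model(model, x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                config: TrainConfig | None = None) -> dict:
    """Minibatch training with early stopping on validation accuracy.

    Fits the input normalizer on the training inputs, minimizes categorical
    cross-entropy, checks validation accuracy every epoch, stops after
    `patience` checks without improvement and restores the best weights.
    Returns a history dict (loss, train/validation accuracy per epoch).
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    model.fit_normalizer(x_train)
    opt_cls = {"adam": Adam, "sgd": SGD}[config.optimizer]
    opt = opt_cls(model.layers, lr=config.learning_rate, l2=config.l2)
    n = x_train.shape[0]
    best_acc, best_state, since_best = -np.inf, None, 0
    history = {"loss": [], "train_acc": [], "val_acc": []}
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_train[idx], training=True, rng=rng)
            loss, _, dlogits = cross_entropy_with_grad(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history["loss"].append(epoch_loss / n)
        history["train_acc"].append(_accuracy(model, x_train, y_train))
        val_acc = _accuracy(model, x_val, y_val)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_val_acc"] = best_acc
    return history


def train_cv(trainval: Dataset, plan: FoldPlan,
             model_config: ModelConfig | None = None,
             train_config: TrainConfig | None = None,
             augmentation: AugmentationConfig | None = None) -> dict:
    """Run the full k-fold rotation: balance each training rotation by
    time-slice oversampling, train one model per rotation, collect
    histories.

    Returns {"models": [...], "histories": [...], "val_acc": [...]}.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    models, histories = [], []
    for i in range(plan.k):
        train_idx, val_idx = plan.rotation(i)
        balanced = oversample_balance(trainval.subset(train_idx), augmentation,
                                      seed=train_config.seed + i)
        x_tr, y_tr = stack_sequences(balanced)
        x_va, y_va = stack_sequences(trainval.subset(val_idx))
        model = TremorLSTM(replace(model_config, seed=model_config.seed + i))
        hist = train_model(model, x_tr, y_tr, x_va, y_va,
                           replace(train_config, seed=train_config.seed + i))
        models.append(model)
        histories.append(hist)
    return {
        "models": models,
        "histories": histories,
        "val_acc": [h["best_val_acc"] for h in histories],
    }


def hyperparameter_search(space: SearchSpace, objective, budget: int,
                          seed: int = 0) -> dict:
    """Seeded random search over the study's hyperparameter ranges.

    `objective` maps a sampled config dict to a scalar score (mean
    validation accuracy); the best-scoring trial wins.  Returns
    {"best": config, "best_score": float, "trials": [...]}.
    """
    if budget < 1:
        raise ValueError("search budget must be at least 1")
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(budget):
        cfg = space.sample(rng)
        score = float(objective(cfg))
        trials.append({"trial": t, "config": cfg, "score": score})
    best = max(trials, key=lambda tr: tr["score"])
    return {"best": best["config"], "best_score": best["score"], "trials": trials}
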