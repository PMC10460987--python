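"""Discrete-time neural survival models.

Two architectures predict the three per-bin conditional progression
probabilities (hazards):

* ``SurvivalMLP`` — input batch-normalization, one hidden affine layer with
  dropout, batch-normalization and leaky-ReLU, then an affine map to three
  sigmoid-bounded hazards. Operates on regional volume features.
* ``SurvivalSCNN`` — two [conv3x3x3 -> batch-norm -> leaky-ReLU -> max-pool 2]
  stages (10 then 20 filters), a flatten, and two dense layers ending in
  three sigmoid hazards. Operates on 3D volumes.

Both are trained by stochastic gradient descent on the negative discrete
survival log-likelihood (see :mod:`mcisurv.discrete`), with optional
inverse-propensity sample weights and L2 weight decay. Everything is plain
NumPy with hand-written backprop: the models are small enough that this is
fast, exactly reproducible, and gives direct access to input gradients for
the attribution analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discrete import (
    DEFAULT_BINS,
    TimeBins,
    hazards_to_survival,
    inverse_propensity_weights,
    survival_loss,
    survival_loss_grad,
)

# ---------------------------------------------------------------------------
# Layers


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, grad, need_param_grads: bool = True):
        raise NotImplementedError

    @property
    def decay_mask(self):
        """Which params receive weight decay (weights yes, biases/affine no)."""
        return [False] * len(self.params)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        # Kaiming-uniform fan-in initialization
        bound = np.sqrt(6.0 / n_in)
        w = rng.uniform(-bound, bound, size=(n_in, n_out))
        b = rng.uniform(-1.0 / np.sqrt(n_in), 1.0 / np.sqrt(n_in), size=n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad, need_param_grads: bool = True):
        if need_param_grads:
            self.grads[0][...] = self._x.T @ grad
            self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0].T

    @property
    def decay_mask(self):
        return [True, False]


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, no padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 27
        bound = np.sqrt(6.0 / fan_in)
        w = rng.uniform(-bound, bound, size=(c_out, c_in, 3, 3, 3))
        b = rng.uniform(-1.0 / np.sqrt(fan_in), 1.0 / np.sqrt(fan_in), size=c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train, rng):
        if min(x.shape[2:]) < 3:
            raise ValueError("input spatial dims too small for a 3x3x3 kernel")
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3, 3), axis=(2, 3, 4))
        self._win = win  # (B, C, OD, OH, OW, 3, 3, 3)
        out = np.einsum("bcdhwijk,fcijk->bfdhw", win, self.params[0], optimize=True)
        return out + self.params[1][None, :, None, None, None]

    def backward(self, grad, need_param_grads: bool = True):
        w = self.params[0]
        if need_param_grads:
            self.grads[0][...] = np.einsum(
                "bcdhwijk,bfdhw->fcijk", self._win, grad, optimize=True
            )
            self.grads[1][...] = grad.sum(axis=(0, 2, 3, 4))
        dx = np.zeros_like(self._x)
        od, oh, ow = grad.shape[2:]
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    dx[:, :, i : i + od, j : j + oh, k : k + ow] += np.einsum(
                        "bfdhw,fc->bcdhw", grad, w[:, :, i, j, k], optimize=True
                    )
        return dx

    @property
    def decay_mask(self):
        return [True, False]


class MaxPool3D(Layer):
    """Non-overlapping 2x2x2 max-pooling; odd trailing voxels are cropped."""

    def forward(self, x, train, rng):
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        blocks = xc.reshape(b, c, d2, 2, h2, 2, w2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d2, h2, w2, 8)
        self._argmax = blocks.argmax(axis=-1)
        return blocks.max(axis=-1)

    def backward(self, grad, need_param_grads: bool = True):
        b, c, d2, h2, w2 = grad.shape
        flat = np.zeros((b, c, d2, h2, w2, 8), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        blocks = flat.reshape(b, c, d2, h2, w2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = blocks.reshape(
            b, c, 2 * d2, 2 * h2, 2 * w2
        )
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 5-D input)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params = [np.ones(n_features), np.zeros(n_features)]  # gamma, beta
        self.grads = [np.zeros(n_features), np.zeros(n_features)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 5:
            return (0, 2, 3, 4), (1, -1, 1, 1, 1)
        raise ValueError("BatchNorm expects 2-D or 5-D input")

    def forward(self, x, train, rng):
        axes, shape = self._axes_and_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, train, x.shape)
        return self.params[0].reshape(shape) * xhat + self.params[1].reshape(shape)

    def backward(self, grad, need_param_grads: bool = True):
        xhat, inv, axes, shape, train, xshape = self._cache
        if need_param_grads:
            self.grads[0][...] = (grad * xhat).sum(axis=axes)
            self.grads[1][...] = grad.sum(axis=axes)
        g = grad * self.params[0].reshape(shape)
        if not train:
            return g * inv.reshape(shape)
        m = np.prod([xshape[a] for a in axes])
        return (
            inv.reshape(shape)
            / m
            * (
                m * g
                - g.sum(axis=axes).reshape(shape)
                - xhat * (g * xhat).sum(axis=axes).reshape(shape)
            )
        )


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad, need_param_grads: bool = True):
        return grad if self._mask is None else grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._pos = x > 0
        return np.where(self._pos, x, self.alpha * x)

    def backward(self, grad, need_param_grads: bool = True):
        return np.where(self._pos, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x, train, rng):
        from scipy.special import expit

        self._out = expit(x)
        return self._out

    def backward(self, grad, need_param_grads: bool = True):
        return grad * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, need_param_grads: bool = True):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# Network container


class Network:
    """A feed-forward stack of layers with SGD and state snapshots."""

    def __init__(self, layers: list, seed: int = 0):
        self.layers = layers
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def backward(self, grad_out: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        grad = grad_out
        for layer in reversed(self.layers):
            grad = layer.backward(grad, need_param_grads)
        return grad

    def sgd_step(self, lr: float, weight_decay: float = 0.0) -> None:
        for layer in self.layers:
            for p, g, decay in zip(layer.params, layer.grads, layer.decay_mask):
                if weight_decay and decay:
                    g = g + weight_decay * p
                p -= lr * g

    def get_state(self) -> list:
        state = []
        for layer in self.layers:
            entry = {"params": [p.copy() for p in layer.params]}
            if isinstance(layer, BatchNorm):
                entry["running"] = (layer.running_mean.copy(), layer.running_var.copy())
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for p, saved in zip(layer.params, entry["params"]):
                p[...] = saved
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = entry["running"][0]
                layer.running_var[...] = entry["running"][1]


# ---------------------------------------------------------------------------
# Model specifications


@dataclass
class ModelSpec:
    """Architecture descriptor plus training hyperparameters."""

    kind: str                               # "mlp" | "scnn"
    input_shape: tuple
    n_bins: int = 3
    hidden: int = 100
    dropout: float = 0.2
    filters: tuple = (10, 20)
    dense_hidden: int = 32
    epochs: int = 300
    lr: float = 0.01
    batch_size: int = 10
    weight_decay: float = 0.0
    sample_weight_mode: str = "standard"    # "standard" | "ipw"
    checkpoint: str = "val_loss"            # "val_loss" | "val_ci24"

    def output_dim(self) -> int:
        return self.n_bins


def build_mlp(input_width: int, hidden: int = 100, dropout: float = 0.2,
              **hyper) -> ModelSpec:
    """Spec for the feature-based survival MLP."""
    if input_width <= 0 or hidden <= 0:
        raise ValueError("widths must be positive")
    return ModelSpec(kind="mlp", input_shape=(input_width,), hidden=hidden,
                     dropout=dropout, **hyper)


def scnn_flat_width(shape: tuple, filters: tuple = (10, 20)) -> int:
    """Flattened width after two conv(3)+pool(2) stages."""
    dims = list(shape)
    for _ in range(2):
        dims = [(d - 2) // 2 for d in dims]
        if min(dims) < 1:
            raise ValueError(f"image shape {shape} too small for the S-CNN")
    return int(filters[-1] * np.prod(dims))


def build_scnn(image_shape: tuple, filters: tuple = (10, 20),
               dropout: float = 0.3, dense_hidden: int = 32, **hyper) -> ModelSpec:
    """Spec for the 3D survival convolutional network.

    Defaults follow the reference configuration: two convolutional stages
    with 10 and 20 filters (kernel 3, stride 1, no padding, batch-norm,
    leaky-ReLU, max-pool 2), two dense layers, dropout 0.3 and L2 weight
    decay 0.01, trained by SGD.
    """
    scnn_flat_width(image_shape, filters)  # validates the shape
    hyper.setdefault("weight_decay", 0.01)
    return ModelSpec(kind="scnn", input_shape=tuple(image_shape), filters=tuple(filters),
                     dropout=dropout, dense_hidden=dense_hidden, **hyper)


def build_network(spec: ModelSpec, seed: int = 0) -> Network:
    rng = np.random.default_rng(seed)
    if spec.kind == "mlp":
        w = spec.input_shape[0]
        layers = [
            BatchNorm(w),
            Dense(w, spec.hidden, rng),
            Dropout(spec.dropout),
            BatchNorm(spec.hidden),
            LeakyReLU(),
            Dense(spec.hidden, spec.n_bins, rng),
            Sigmoid(),
        ]
    elif spec.kind == "scnn":
        flat = scnn_flat_width(spec.input_shape, spec.filters)
        layers = [
            Conv3D(1, spec.filters[0], rng),
            BatchNorm(spec.filters[0]),
            LeakyReLU(),
            MaxPool3D(),
            Conv3D(spec.filters[0], spec.filters[1], rng),
            BatchNorm(spec.filters[1]),
            LeakyReLU(),
            MaxPool3D(),
            Flatten(),
            Dense(flat, spec.dense_hidden, rng),
            Dropout(spec.dropout),
            LeakyReLU(),
            Dense(spec.dense_hidden, spec.n_bins, rng),
            Sigmoid(),
        ]
    else:
        raise ValueError(f"unknown model kind: {spec.kind}")
    return Network(layers, seed=seed + 1)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: Network
    history: list
    best_epoch: int
    bins: TimeBins = DEFAULT_BINS

    def predict_hazards(self, x: np.ndarray) -> np.ndarray:
        return self.network.forward(np.asarray(x, dtype=float), train=False)

    def predict_survival(self, x: np.ndarray, grid=None) -> np.ndarray:
        return hazards_to_survival(self.predict_hazards(x), self.bins, grid=grid)


def _ci_at_24(hazards, times, events) -> float:
    from .evaluation import concordance_index

    risk = hazards[:, 0]  # 1 - S(24) = h_1
    try:
        return concordance_index(times, events, risk)
    except ValueError:
        return 0.5


def train_model(
    spec: ModelSpec,
    x_train: np.ndarray, s_train: np.ndarray, e_train: np.ndarray,
    x_val: np.ndarray, s_val: np.ndarray, e_val: np.ndarray,
    val_times: np.ndarray | None = None, val_events: np.ndarray | None = None,
    seed: int = 0, bins: TimeBins = DEFAULT_BINS,
) -> TrainedModel:
    """SGD training with per-epoch checkpointing.

    The checkpoint criterion is the spec's: lowest total survival loss on
    the validation split (``val_loss``) or highest concordance at 24 months
    (``val_ci24``, requires ``val_times``/``val_events``). Identical seeds
    give identical histories. Raises on an empty training set; a non-finite
    loss aborts with an error.
    """
    x_train = np.asarray(x_train, dtype=float)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if spec.checkpoint == "val_ci24" and (val_times is None or val_events is None):
        raise ValueError("val_ci24 checkpointing needs validation outcomes")
    net = build_network(spec, seed=seed)
    order_rng = np.random.default_rng(seed + 10_000)
    n = len(x_train)
    weights = (
        inverse_propensity_weights(s_train, e_train)
        if spec.sample_weight_mode == "ipw"
        else np.ones(n)
    )
    history = []
    best_metric, best_epoch, best_state = None, -1, net.get_state()
    # a zero learning rate is a null update: evaluate without touching
    # dropout or normalization statistics so the history is exactly constant
    train_mode = spec.lr > 0
    for epoch in range(spec.epochs):
        perm = order_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = perm[start : start + spec.batch_size]
            hz = net.forward(x_train[idx], train=train_mode)
            loss = survival_loss(hz, s_train[idx], e_train[idx], weights[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            # mean-normalized gradient: step size independent of batch size
            grad = survival_loss_grad(hz, s_train[idx], e_train[idx], weights[idx])
            net.backward(grad / len(idx))
            net.sgd_step(spec.lr, spec.weight_decay)
            epoch_loss += loss
        hz_val = net.forward(np.asarray(x_val, dtype=float), train=False)
        val_loss = survival_loss(hz_val, s_val, e_val)
        record = {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss}
        if spec.checkpoint == "val_ci24":
            metric = _ci_at_24(hz_val, val_times, val_events)
            record["val_ci24"] = metric
            better = best_metric is None or metric > best_metric
        else:
            metric = val_loss
            better = best_metric is None or metric < best_metric
        history.append(record)
        if better:
            best_metric, best_epoch, best_state = metric, epoch, net.get_state()
    net.set_state(best_state)
    return TrainedModel(spec=spec, network=net, history=history,
                        best_epoch=best_epoch, bins=bins)
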