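"""CNN-LSTM-Attention binary classifier for windowed multichannel gait signals.

Architecture (input: segments of ``frames × channels``):

    conv1d(64, k=5) + ReLU + max-pool(2)
    conv1d(128, k=3) + ReLU + max-pool(2) + dropout
    LSTM(64), full sequence output
    single-head scaled dot-product self-attention over time (Q = K = V = LSTM states)
    global average pooling over time
    dense(64) + ReLU → dense(2) → softmax

The CNN stage extracts local spatial patterns across channels, the LSTM
models their temporal evolution over the window, and the attention layer
re-weights timesteps so moments most indicative of fatigue dominate the
pooled representation. Training uses two-class cross-entropy with Adam, an
internal stratified 80:20 train/validation split, early stopping on
validation loss (best weights restored) and learning-rate reduction on
plateau.

The network, backpropagation and optimizer are implemented directly in
NumPy: convolution via im2col, LSTM by backpropagation through time, and
attention with the exact softmax Jacobian. All randomness (initialization,
shuffling, dropout, the validation split) derives from the config seed, so
identical config + data reproduce identical histories and predictions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import train_test_split

from gaitfatigue.segmentation import SegmentSet


@dataclass
class ModelConfig:
    """Hyperparameters. Defaults follow the reference architecture; ``small()``
    is a reduced preset for desk-scale cohorts and CI-sized experiments."""

    conv_filters: tuple[int, int] = (64, 128)
    kernel_sizes: tuple[int, int] = (5, 3)
    pool_size: int = 2
    lstm_units: int = 64
    dense_units: tuple[int, ...] = (64,)
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    early_stopping_patience: int = 10
    lr_factor: float = 0.5
    lr_patience: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def small(cls, seed: int = 0, max_epochs: int = 40) -> "ModelConfig":
        return cls(
            conv_filters=(8, 16), kernel_sizes=(5, 3), pool_size=4,
            lstm_units=24, dense_units=(16,), dropout=0.2,
            learning_rate=1e-3, batch_size=16, max_epochs=max_epochs,
            early_stopping_patience=8, lr_patience=4, seed=seed,
        )


# ---------------------------------------------------------------------------
# layers


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv1D(_Layer):
    """Same-padded 1-D convolution over time, via im2col."""

    def __init__(self, rng, c_in, c_out, k):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.params = {
            "W": _glorot(rng, k * c_in, c_out, (k * c_in, c_out)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train):
        B, T, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (B, T, c_in, k) → (B, T, k*c_in) with offset-major layout
        win = sliding_window_view(xp, self.k, axis=1)
        patches = win.transpose(0, 1, 3, 2).reshape(B, T, self.k * self.c_in)
        self._patches, self._T = patches, T
        return patches @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        B, T, _ = dy.shape
        self.grads["W"] = np.einsum("btf,bto->fo", self._patches, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dpatch = (dy @ self.params["W"].T).reshape(B, T, self.k, self.c_in)
        p = self.k // 2
        dxp = np.zeros((B, T + 2 * p, self.c_in))
        for off in range(self.k):
            dxp[:, off:off + T] += dpatch[:, :, off]
        return dxp[:, p:p + T]


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool1D(_Layer):
    """Non-overlapping temporal max-pool; a trailing remainder is cropped."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, train):
        B, T, C = x.shape
        tc = (T // self.p) * self.p
        if tc == 0:
            raise ValueError(
                f"sequence of {T} frames shorter than pool size {self.p}"
            )
        xr = x[:, :tc].reshape(B, tc // self.p, self.p, C)
        self._idx = xr.argmax(axis=2)
        self._shape = (B, T, C)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, T, C = self._shape
        tc = (T // self.p) * self.p
        dxr = np.zeros((B, tc // self.p, self.p, C))
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, T, C))
        dx[:, :tc] = dxr.reshape(B, tc, C)
        return dx


class _Dropout(_Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self._rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class _LSTM(_Layer):
    """Single-layer LSTM returning the full hidden sequence.

    Gate layout in the fused weight matrix is (input, forget, cell, output);
    the forget-gate bias starts at 1 so early gradients flow through time.
    """

    def __init__(self, rng, d_in, d_h):
        super().__init__()
        self.d_in, self.d_h = d_in, d_h
        W = _glorot(rng, d_in + d_h, 4 * d_h, (d_in + d_h, 4 * d_h))
        b = np.zeros(4 * d_h)
        b[d_h:2 * d_h] = 1.0
        self.params = {"W": W, "b": b}

    def forward(self, x, train):
        B, T, _ = x.shape
        H = self.d_h
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        out = np.empty((B, T, H))
        for t in range(T):
            zin = np.concatenate([x[:, t], h], axis=1)
            z = zin @ W + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            self._cache.append((zin, i, f, g, o, c, tc))
        self._c_prevs = [np.zeros((B, H))] + [cch[5] for cch in self._cache[:-1]]
        self._B, self._T = B, T
        return out

    def backward(self, dy):
        B, T, H = self._B, self._T, self.d_h
        W = self.params["W"]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dx = np.empty((B, T, self.d_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            zin, i, f, g, o, c, tc = self._cache[t]
            c_prev = self._c_prevs[t]
            dh = dy[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dW += zin.T @ dz
            db += dz.sum(axis=0)
            dzin = dz @ W.T
            dx[:, t] = dzin[:, :self.d_in]
            dh_next = dzin[:, self.d_in:]
            dc_next = dc * f
        self.grads = {"W": dW, "b": db}
        return dx


class _SelfAttention(_Layer):
    """Single-head scaled dot-product self-attention, Q = K = V = input."""

    def __init__(self):
        super().__init__()
        self.last_attention: np.ndarray | None = None

    @staticmethod
    def _softmax(s):
        s = s - s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x, train):
        d = x.shape[-1]
        self._scale = 1.0 / np.sqrt(d)
        s = np.matmul(x, x.transpose(0, 2, 1)) * self._scale
        a = self._softmax(s)
        self._x, self._a = x, a
        self.last_attention = a
        return np.matmul(a, x)

    def backward(self, dy):
        x, a = self._x, self._a
        dx = np.matmul(a.transpose(0, 2, 1), dy)          # through V
        da = np.matmul(dy, x.transpose(0, 2, 1))
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dx += (np.matmul(ds, x) + np.matmul(ds.transpose(0, 2, 1), x)) * self._scale
        return dx


class _GlobalAvgPool(_Layer):
    def forward(self, x, train):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._T, axis=1) / self._T


class _Dense(_Layer):
    def __init__(self, rng, d_in, d_out):
        super().__init__()
        self.params = {
            "W": _glorot(rng, d_in, d_out, (d_in, d_out)),
            "b": np.zeros(d_out),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


# ---------------------------------------------------------------------------
# network


class Network:
    """The untrained layer stack (see module docstring for the topology)."""

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int]):
        frames, channels = input_shape
        if frames <= 0 or channels <= 0:
            raise ValueError("input_shape must be positive")
        k1, k2 = cfg.kernel_sizes
        if frames < max(k1, k2):
            raise ValueError("window shorter than the convolutional receptive field")
        t_after = (frames // cfg.pool_size) // cfg.pool_size
        if t_after < 1:
            raise ValueError("window too short for two pooling stages")

        self.cfg = cfg
        self.input_shape = input_shape
        rng = np.random.default_rng(cfg.seed)
        self._train_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0]
        )

        f1, f2 = cfg.conv_filters
        layers: list[_Layer] = [
            _Conv1D(rng, channels, f1, k1), _ReLU(), _MaxPool1D(cfg.pool_size),
            _Conv1D(rng, f1, f2, k2), _ReLU(), _MaxPool1D(cfg.pool_size),
            _Dropout(cfg.dropout, self._train_rng),
            _LSTM(rng, f2, cfg.lstm_units),
            _SelfAttention(),
            _GlobalAvgPool(),
        ]
        d = cfg.lstm_units
        for u in cfg.dense_units:
            layers += [_Dense(rng, d, u), _ReLU()]
            d = u
        layers.append(_Dense(rng, d, 2))
        self.layers = layers
        self._attention = layers[8]
        assert isinstance(self._attention, _SelfAttention)

    # -- plumbing

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (batch, frames, channels) array."""
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"input {self.input_shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self) -> list[tuple[int, str, np.ndarray]]:
        return [(i, k, v) for i, l in enumerate(self.layers) for k, v in l.params.items()]

    def get_state(self) -> dict:
        return {(i, k): v.copy() for i, k, v in self.parameters()}

    def set_state(self, state: dict) -> None:
        for i, k, _ in self.parameters():
            self.layers[i].params[k] = state[(i, k)].copy()

    def parameter_count(self) -> int:
        return sum(v.size for _, _, v in self.parameters())

    def attention_matrix(self) -> np.ndarray:
        if self._attention.last_attention is None:
            raise RuntimeError("run a forward pass first")
        return self._attention.last_attention


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)).mean())


@dataclass
class TrainedModel:
    """A fitted network plus its training history and config snapshot."""

    net: Network
    config: ModelConfig
    history: dict = field(default_factory=dict)
    classes: tuple[int, int] = (0, 1)

    @property
    def input_shape(self) -> tuple[int, int]:
        return self.net.input_shape


def build_model(cfg: ModelConfig, input_shape: tuple[int, int]) -> Network:
    """Construct the seeded, untrained network for ``frames × channels`` input."""
    return Network(cfg, tuple(int(v) for v in input_shape))


class _Adam:
    def __init__(self, net: Network, lr: float):
        self.net, self.lr = net, lr
        self.t = 0
        self.m = {(i, k): np.zeros_like(v) for i, k, v in net.parameters()}
        self.v = {(i, k): np.zeros_like(v) for i, k, v in net.parameters()}

    def step(self, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, k, p in self.net.parameters():
            g = self.net.layers[i].grads[k]
            key = (i, k)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _eval_pass(net: Network, X: np.ndarray, y: np.ndarray,
               batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for s in range(0, len(X), batch):
        p = softmax(net.forward(X[s:s + batch], train=False))
        losses.append(_xent(p, y[s:s + batch]) * len(p))
        correct += int((p.argmax(axis=1) == y[s:s + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(model: Network, train_segments: SegmentSet,
          cfg: ModelConfig | None = None) -> TrainedModel:
    """Fit the network on a segment set.

    An internal stratified 80:20 split provides the validation track used
    for early stopping (patience on validation loss, best weights restored)
    and learning-rate reduction on plateau. History carries per-epoch
    train/validation loss and accuracy plus the learning rate.
    """
    cfg = cfg or model.cfg
    X, y = train_segments.data, train_segments.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=cfg.val_fraction,
        stratify=y, random_state=cfg.seed % (2 ** 32),
    )
    Xtr, ytr = X[idx_tr], y[idx_tr]
    Xva, yva = X[idx_va], y[idx_va]

    opt = _Adam(model, cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "lr": []}
    best_loss, best_state, best_epoch = np.inf, model.get_state(), -1
    since_improve, since_lr = 0, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, len(order), cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            probs = softmax(model.forward(xb, train=True))
            ep_loss += _xent(probs, yb) * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.backward(dlogits / len(yb))
            opt.step()

        val_loss, val_acc = _eval_pass(model, Xva, yva, cfg.batch_size)
        history["train_loss"].append(ep_loss / len(ytr))
        history["train_acc"].append(ep_correct / len(ytr))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)

        if val_loss < best_loss - 1e-6:
            best_loss, best_state, best_epoch = val_loss, model.get_state(), epoch
            since_improve, since_lr = 0, 0
        else:
            since_improve += 1
            since_lr += 1
            if since_lr >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                since_lr = 0
            if since_improve >= cfg.early_stopping_patience:
                break

    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    return TrainedModel(net=model, config=copy.deepcopy(cfg), history=history)


def predict(model: TrainedModel, segments) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment class probabilities and argmax labels (tie → class 0)."""
    X = segments.data if isinstance(segments, SegmentSet) else np.asarray(segments)
    if X.ndim != 3 or X.shape[1:] != model.input_shape:
        raise ValueError(
            f"segment shape {X.shape[1:]} does not match trained input "
            f"{model.input_shape}"
        )
    probs = np.concatenate([
        softmax(model.net.forward(X[s:s + 64], train=False))
        for s in range(0, len(X), 64)
    ])
    return probs, probs.argmax(axis=1)


def attention_weights(model: TrainedModel, segment: np.ndarray) -> np.ndarray:
    """Row-stochastic attention matrix (timesteps × timesteps) for one segment."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 2:
        seg = seg[None]
    model.net.forward(seg, train=False)
    return model.net.attention_matrix()[0]


def config_to_dict(cfg: ModelConfig) -> dict:
    return asdict(cfg)
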