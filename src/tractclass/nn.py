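"""A 1D residual convolutional network for tract-profile classification.

The architecture is the residual network of the time-series classification
literature: three residual blocks, each a series of 1D convolutions with
kernel sizes 8, 5 and 3 interspersed with batch normalization and ReLU,
with an additive shortcut from the block input; 64, 128 and 128 filters in
the three blocks; global average pooling and a sigmoid output unit.  Input
is (batch, 80 nodes, 6 channels); output is one probability per subject.

Implemented directly in numpy (forward and backward passes, Adam, binary
cross-entropy): convolutions are im2col + GEMM, so single-CPU training on
cohort-scale inputs takes seconds per epoch.  Everything is float32 and
seeded, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import as_strided

from . import evaluation

_DT = np.float32


def _im2col(x: np.ndarray, k: int, pad_l: int, pad_r: int) -> np.ndarray:
    """(N, L, C) → (N·L, k·C) patches for a stride-1 'same'-style conv."""
    xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    n, lp, c = xp.shape
    length = lp - k + 1
    s0, s1, s2 = xp.strides
    col = as_strided(xp, (n, length, k, c), (s0, s1, s1, s2))
    return np.ascontiguousarray(col).reshape(n * length, k * c)


class Conv1d:
    """Stride-1 'same' 1D convolution (asymmetric padding for even kernels)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad_l = (k - 1) // 2
        self.pad_r = k - 1 - self.pad_l
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = (rng.standard_normal((k, c_in, c_out)) * scale).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        self._col = _im2col(x, self.k, self.pad_l, self.pad_r)
        y = self._col @ self.W.reshape(self.k * self.c_in, self.c_out)
        y += self.b
        n, length, _ = x.shape
        return y.reshape(n, length, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, _ = self._shape
        dy2 = dy.reshape(n * length, self.c_out)
        self.dW = (self._col.T @ dy2).reshape(self.W.shape)
        self.db = dy2.sum(axis=0)
        # dx is the correlation of dy with the flipped kernel; computed as
        # k shifted GEMMs on the zero-padded dy to avoid another im2col copy
        pl = self.k - 1 - self.pad_l
        pr = self.k - 1 - self.pad_r
        dyp = np.pad(dy, ((0, 0), (pl, pr), (0, 0)))
        lp = dyp.shape[1]
        dyp2 = dyp.reshape(n * lp, self.c_out)
        dx = np.zeros((n, length, self.c_in), dtype=_DT)
        for j in range(self.k):
            z = (dyp2 @ self.W[self.k - 1 - j].T).reshape(n, lp, self.c_in)
            dx += z[:, j:j + length]
        self._col = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm:
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(c, dtype=_DT)
        self.beta = np.zeros(c, dtype=_DT)
        self.dgamma = np.zeros(c, dtype=_DT)
        self.dbeta = np.zeros(c, dtype=_DT)
        self.running_mean = np.zeros(c, dtype=_DT)
        self.running_var = np.ones(c, dtype=_DT)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(_DT)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(_DT)
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_DT)
        self._xhat = ((x - mu) * self._inv_std).astype(_DT)
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        prod = dy * xhat
        self.dgamma = prod.sum(axis=(0, 1))
        self.dbeta = dy.sum(axis=(0, 1))
        nl = dy.shape[0] * dy.shape[1]
        # dx = γ/σ · (dy − mean(dy) − xhat·mean(dy·xhat)), fused in place
        xhat *= self.dgamma / nl
        dx = dy - (self.dbeta / nl)
        dx -= xhat
        dx *= self.gamma * self._inv_std
        self._xhat = None
        return dx.astype(_DT, copy=False)

    def params(self):
        return [("gamma", self), ("beta", self)]


class ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class ResidualBlock:
    """conv8-BN-ReLU → conv5-BN-ReLU → conv3-BN, plus shortcut, add, ReLU.

    The shortcut is the identity when input and output channel counts
    match, otherwise a kernel-1 convolution followed by batch norm.
    """

    def __init__(self, c_in: int, c_out: int, kernel_sizes, rng):
        k1, k2, k3 = kernel_sizes
        self.conv1, self.bn1 = Conv1d(c_in, c_out, k1, rng), BatchNorm(c_out)
        self.conv2, self.bn2 = Conv1d(c_out, c_out, k2, rng), BatchNorm(c_out)
        self.conv3, self.bn3 = Conv1d(c_out, c_out, k3, rng), BatchNorm(c_out)
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        if c_in != c_out:
            self.short_conv = Conv1d(c_in, c_out, 1, rng)
            self.short_bn = BatchNorm(c_out)
        else:
            self.short_conv = self.short_bn = None

    def forward(self, x, training):
        h = self.relu1.forward(self.bn1.forward(
            self.conv1.forward(x, training), training), training)
        h = self.relu2.forward(self.bn2.forward(
            self.conv2.forward(h, training), training), training)
        h = self.bn3.forward(self.conv3.forward(h, training), training)
        if self.short_conv is not None:
            s = self.short_bn.forward(
                self.short_conv.forward(x, training), training)
        else:
            s = x
        return self.relu_out.forward(h + s, training)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        if self.short_conv is not None:
            dx_short = self.short_conv.backward(self.short_bn.backward(dsum))
        else:
            dx_short = dsum
        dh = self.conv3.backward(self.bn3.backward(dsum))
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dh)))
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        return dh + dx_short

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.short_conv is not None:
            out += [self.short_conv, self.short_bn]
        return out


@dataclass(frozen=True)
class CnnSpec:
    """Architecture constants of the residual classifier."""
    kernel_sizes: tuple[int, int, int] = (8, 5, 3)
    filters: tuple[int, int, int] = (64, 128, 128)
    n_input_channels: int = 6
    input_len: int = 80


class ResNet1dClassifier:
    """The 1D residual CNN: (batch, 80, 6) → probability per subject.

    The final dense layer is zero-initialized, so an untrained model
    outputs 0.5 everywhere — a fresh network is exactly at chance.
    """

    def __init__(self, spec: CnnSpec | None = None, seed: int = 0):
        self.spec = spec or CnnSpec()
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = self.spec.n_input_channels
        for f in self.spec.filters:
            self.blocks.append(ResidualBlock(c_in, f, self.spec.kernel_sizes, rng))
            c_in = f
        self.head_W = np.zeros((c_in, 1), dtype=_DT)
        self.head_b = np.zeros(1, dtype=_DT)
        self.dhead_W = np.zeros_like(self.head_W)
        self.dhead_b = np.zeros_like(self.head_b)

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, X: np.ndarray, training: bool) -> np.ndarray:
        if X.ndim != 3 or X.shape[1] != self.spec.input_len \
                or X.shape[2] != self.spec.n_input_channels:
            raise ValueError(
                f"expected input (batch, {self.spec.input_len}, "
                f"{self.spec.n_input_channels}), got {X.shape}")
        h = X.astype(_DT, copy=False)
        for block in self.blocks:
            h = block.forward(h, training)
        self._gap_in_len = h.shape[1]
        self._pooled = h.mean(axis=1)  # (N, C)
        return (self._pooled @ self.head_W + self.head_b)[:, 0]

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dpool = dlogits[:, None] @ self.head_W.T  # (N, C)
        self.dhead_W = self._pooled.T @ dlogits[:, None]
        self.dhead_b = dlogits.sum(keepdims=True)
        dh = (np.repeat(dpool[:, None, :], self._gap_in_len, axis=1)
              / self._gap_in_len).astype(_DT)
        for block in reversed(self.blocks):
            dh = block.backward(dh)

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        from scipy.special import expit
        out = []
        for i in range(0, len(X), batch_size):
            z = self.forward_logits(X[i:i + batch_size], training=False)
            out.append(expit(z))
        return np.concatenate(out) if out else np.empty(0)

    # -- parameter plumbing -------------------------------------------------

    def _param_slots(self):
        slots = []
        for block in self.blocks:
            for layer in block.layers():
                for name, owner in layer.params():
                    slots.append((owner, name, "d" + name))
        slots.append((self, "head_W", "dhead_W"))
        slots.append((self, "head_b", "dhead_b"))
        return slots

    @property
    def n_params(self) -> int:
        return int(sum(getattr(o, n).size for o, n, _ in self._param_slots()))

    def get_weights(self) -> list[np.ndarray]:
        """Copy of all state: trainable parameters plus batch-norm stats."""
        state = [getattr(o, n).copy() for o, n, _ in self._param_slots()]
        for block in self.blocks:
            for layer in block.layers():
                if isinstance(layer, BatchNorm):
                    state.append(layer.running_mean.copy())
                    state.append(layer.running_var.copy())
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for o, n, _ in self._param_slots():
            setattr(o, n, next(it).copy())
        for block in self.blocks:
            for layer in block.layers():
                if isinstance(layer, BatchNorm):
                    layer.running_mean = next(it).copy()
                    layer.running_var = next(it).copy()


def build_cnn(spec: CnnSpec | None = None, seed: int = 0) -> ResNet1dClassifier:
    """An untrained, seed-initialized residual classifier."""
    return ResNet1dClassifier(spec, seed=seed)


class _Adam:
    def __init__(self, slots, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = slots
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for o, n, _ in slots]
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in slots]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for i, (o, n, dn) in enumerate(self.slots):
            g = getattr(o, dn)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p = getattr(o, n)
            p -= (lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)).astype(p.dtype)


def _bce_and_grad(logits: np.ndarray, y: np.ndarray):
    from scipy.special import expit
    p = expit(logits)
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    dlogits = ((p - y) / len(y)).astype(_DT)
    return loss, p, dlogits


def bce_loss(model: ResNet1dClassifier, X: np.ndarray, y: np.ndarray) -> float:
    logits = model.forward_logits(X, training=False)
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (not architecture constants): defaults are
    this implementation's own choices and are freely tunable."""
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 40
    patience: int = 6
    seed: int = 0


def train_cnn(model: ResNet1dClassifier, train, validation,
              cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Train with Adam on binary cross-entropy; early-stop on validation loss.

    ``train`` / ``validation`` are FeatureTensors (already imputed and
    z-scored).  The model is left holding the weights of the best
    validation epoch.  Returns the epoch history (train loss, validation
    loss, validation AUC).  Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if cfg.max_epochs == 0:
        return pd.DataFrame(columns=["epoch", "train_loss", "val_loss", "val_auc"])
    if len(train.y) == 0 or len(validation.y) == 0:
        raise ValueError("train and validation sets must be non-empty")
    Xtr = train.X.astype(_DT, copy=False)
    ytr = train.y.astype(_DT)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model._param_slots(), cfg.lr)
    best_loss, best_state, best_epoch = np.inf, model.get_weights(), -1
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs more than one sample
            logits = model.forward_logits(Xtr[idx], training=True)
            loss, _, dlogits = _bce_and_grad(logits, ytr[idx])
            model.backward_from_logits(dlogits)
            opt.step()
            losses.append(loss)
        val_scores = model.predict_proba(validation.X)
        val_loss = float(np.mean(
            -validation.y * np.log(np.clip(val_scores, 1e-7, None))
            - (1 - validation.y) * np.log(np.clip(1 - val_scores, 1e-7, None))))
        val_auc = evaluation.mann_whitney_auc(val_scores, validation.y)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_auc": val_auc})
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.get_weights(), epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.set_weights(best_state)
    return pd.DataFrame(rows)
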