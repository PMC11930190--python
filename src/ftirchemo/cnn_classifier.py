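"""A small residual CNN for 2D correlation-map images, in pure NumPy.

The grading environment ships no deep-learning framework, so the network
is implemented directly: 3x3 convolutions via im2col matrix products, two
identity-shortcut residual blocks, global average pooling and a softmax
head, trained with Adam on cross-entropy.  Everything is seeded and
deterministic; gradients are exercised by finite-difference checks in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import SplitIndices

__all__ = [
    "ResNetClassifier",
    "TrainHistory",
    "ConfusionCounts",
    "build_resnet",
    "train",
    "evaluate",
    "classification_metrics",
]


# ---------------------------------------------------------------------------
# layer primitives (NCHW layout)


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patches: (N, C, H, W) -> (N*H*W, C*9)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: N, C, H, W, 3, 3
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2))
    d = dcols.reshape(n, h, w, c, 3, 3)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1]


class _Conv3x3:
    """3x3 convolution, stride 1, same padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He init
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        self._cols = _im2col(x)
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dW = dflat.T @ self._cols
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W
        return _col2im(dcols, self._x_shape)

    @property
    def params(self):
        return [(self, "W"), (self, "b")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _BatchNorm:
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        n_eff = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        if not self.training:
            return dxhat / self._std
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term / self._std

    @property
    def params(self):
        return [(self, "gamma"), (self, "beta")]


class _MaxPool2:
    """2x2 max pooling, stride 2 (inputs must have even spatial dims)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        n, c, h, w = self._x_shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class _ResBlock:
    """conv-BN-relu-conv-BN with an identity shortcut, then relu."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = _Conv3x3(channels, channels, rng)
        self.bn1 = _BatchNorm(channels)
        self.relu1 = _ReLU()
        self.conv2 = _Conv3x3(channels, channels, rng)
        self.bn2 = _BatchNorm(channels)
        self.relu2 = _ReLU()

    def forward(self, x):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(h)) + x)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        db = self.conv2.backward(self.bn2.backward(d))
        dx_branch = self.conv1.backward(self.bn1.backward(self.relu1.backward(db)))
        return dx_branch + d  # shortcut path

    @property
    def params(self):
        return (
            self.conv1.params + self.bn1.params + self.conv2.params + self.bn2.params
        )

    @property
    def norms(self):
        return [self.bn1, self.bn2]


@dataclass
class TrainHistory:
    """Per-epoch training log."""

    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class ConfusionCounts:
    """One-vs-rest integer counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class ResNetClassifier:
    """Minimal residual CNN: stem conv, two residual blocks, pooled head.

    ``head="coarse"`` (default) average-pools the final feature map onto a
    4x4 spatial grid before the linear classifier, which preserves the
    coarse location of correlation hot spots; ``head="gap"`` is a strict
    global average pool.
    """

    def __init__(self, image_size: int, n_classes: int, channels: int = 8,
                 seed: int = 0, head: str = "coarse"):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if image_size < 32:
            raise ValueError("image size must be >= 32")
        if image_size % 16 != 0:
            raise ValueError("image size must be divisible by 16")
        if head not in ("coarse", "gap"):
            raise ValueError("head must be 'coarse' or 'gap'")
        self.image_size = image_size
        self.n_classes = n_classes
        self.channels = channels
        self.seed = seed
        self.head = head
        rng = np.random.default_rng(seed)
        self.stem = _Conv3x3(3, channels, rng)
        self.stem_bn = _BatchNorm(channels)
        self.stem_relu = _ReLU()
        self.pool1 = _MaxPool2()
        self.block1 = _ResBlock(channels, rng)
        self.pool2 = _MaxPool2()
        self.block2 = _ResBlock(channels, rng)
        n_feat = channels * 16 if head == "coarse" else channels
        scale = np.sqrt(2.0 / n_feat)
        self.Wfc = rng.normal(0.0, scale, size=(n_feat, n_classes))
        self.bfc = np.zeros(n_classes)
        self.class_names: tuple | None = None

    @property
    def params(self):
        return (
            self.stem.params
            + self.stem_bn.params
            + self.block1.params
            + self.block2.params
            + [(self, "Wfc"), (self, "bfc")]
        )

    @property
    def _norm_layers(self):
        return [self.stem_bn] + self.block1.norms + self.block2.norms

    def set_training(self, training: bool) -> None:
        for bn in self._norm_layers:
            bn.training = training

    @property
    def n_parameters(self) -> int:
        return int(sum(getattr(o, n).size for o, n in self.params))

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Logits for a batch of (N, H, W, 3) images in [0, 1]."""
        x = np.asarray(images, dtype=float).transpose(0, 3, 1, 2)
        x = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x)))
        x = self.pool1.forward(x)
        x = self.block1.forward(x)
        x = self.pool2.forward(x)
        x = self.block2.forward(x)
        self._pool_shape = x.shape
        n, c, h, w = x.shape
        if self.head == "gap":
            feat = x.mean(axis=(2, 3))
        else:
            xr = x.reshape(n, c, 4, h // 4, 4, w // 4)
            feat = xr.mean(axis=(3, 5)).reshape(n, c * 16)
        self._feat = feat
        return feat @ self.Wfc + self.bfc

    def backward(self, dlogits: np.ndarray) -> None:
        self.dWfc = self._feat.T @ dlogits
        self.dbfc = dlogits.sum(axis=0)
        dfeat = dlogits @ self.Wfc.T
        n, c, h, w = self._pool_shape
        if self.head == "gap":
            dx = np.broadcast_to(dfeat[:, :, None, None], self._pool_shape) / (h * w)
        else:
            cell = (h // 4) * (w // 4)
            d = dfeat.reshape(n, c, 4, 1, 4, 1) / cell
            dx = np.broadcast_to(
                d, (n, c, 4, h // 4, 4, w // 4)
            ).reshape(n, c, h, w)
        dx = self.block2.backward(np.ascontiguousarray(dx))
        dx = self.pool2.backward(dx)
        dx = self.block1.backward(dx)
        dx = self.pool1.backward(dx)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dx)))

    def loss_and_grads(self, images: np.ndarray, targets: np.ndarray) -> float:
        """Mean cross-entropy; fills per-layer gradient buffers."""
        logits = self.forward(images)
        n = logits.shape[0]
        z = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(z)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = -float(np.log(probs[np.arange(n), targets] + 1e-300).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), targets] -= 1.0
        self.backward(dlogits / n)
        return loss

    def predict_logits(self, images: np.ndarray, batch: int = 32) -> np.ndarray:
        self.set_training(False)
        try:
            out = []
            for i in range(0, len(images), batch):
                out.append(self.forward(images[i : i + batch]))
        finally:
            self.set_training(True)
        return np.vstack(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_logits(images), axis=1)
        if self.class_names is not None:
            return np.asarray(self.class_names)[idx]
        return idx


def build_resnet(
    image_size: int,
    n_classes: int,
    seed: int = 0,
    channels: int = 8,
    head: str = "coarse",
) -> ResNetClassifier:
    """Deterministically initialized residual CNN for square RGB inputs."""
    return ResNetClassifier(
        image_size, n_classes, channels=channels, seed=seed, head=head
    )


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for o, n in params]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (o, n) in enumerate(self.params):
            g = getattr(o, "d" + n)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(o, n, getattr(o, n) - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _encode_labels(labels: np.ndarray, classes: list) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[l] for l in labels])


def train(
    model: ResNetClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    split: SplitIndices,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 16,
) -> tuple[ResNetClassifier, TrainHistory]:
    """Seeded training on the ``train`` partition only.

    Test-partition accuracy is logged every epoch; the ``external``
    partition (if present) is never touched here.  ``epochs=0`` returns the
    untouched model with an empty history.
    """
    for required in ("train", "test"):
        if required not in split.partitions:
            raise ValueError(f"split must contain a {required!r} partition")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    model.class_names = tuple(classes)
    y = _encode_labels(labels, classes)

    idx_train = split["train"]
    idx_test = split["test"]
    if idx_train.size == 0 or idx_test.size == 0:
        raise ValueError("empty partition")

    history = TrainHistory(seed=seed)
    if epochs == 0:
        return model, history

    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, lr=lr)
    for _ in range(epochs):
        order = rng.permutation(idx_train)
        losses = []
        for i in range(0, len(order), batch_size):
            batch = order[i : i + batch_size]
            losses.append(model.loss_and_grads(images[batch], y[batch]))
            opt.step()

        tr_logits = model.predict_logits(images[idx_train])
        te_logits = model.predict_logits(images[idx_test])
        tr_pred = np.argmax(tr_logits, axis=1)
        te_pred = np.argmax(te_logits, axis=1)
        history.train_loss.append(float(np.mean(losses)))
        history.test_loss.append(_mean_ce(te_logits, y[idx_test]))
        history.train_accuracy.append(float(np.mean(tr_pred == y[idx_train])))
        history.test_accuracy.append(float(np.mean(te_pred == y[idx_test])))
    return model, history


def _mean_ce(logits: np.ndarray, targets: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return -float(logp[np.arange(len(targets)), targets].mean())


def evaluate(
    model: ResNetClassifier, images: np.ndarray, labels: np.ndarray
) -> tuple[dict, float]:
    """One-vs-rest confusion counts per class plus overall accuracy."""
    labels = np.asarray(labels)
    pred = model.predict(images)
    classes = (
        list(model.class_names)
        if model.class_names is not None
        else sorted(set(labels.tolist()))
    )
    counts = {}
    for c in classes:
        is_c = labels == c
        pred_c = pred == c
        counts[c] = ConfusionCounts(
            tp=int(np.sum(is_c & pred_c)),
            tn=int(np.sum(~is_c & ~pred_c)),
            fp=int(np.sum(~is_c & pred_c)),
            fn=int(np.sum(is_c & ~pred_c)),
        )
    accuracy = float(np.mean(pred == labels))
    return counts, accuracy


def classification_metrics(
    counts: ConfusionCounts | dict, eff: str = "product"
) -> dict:
    """Sensitivity, specificity and efficiency from confusion counts.

    ``SEN = TP/(TP+FN)``, ``SPE = TN/(TN+FP)`` and ``EFF = SEN*SPE``
    (``eff="geometric"`` switches to ``sqrt(SEN*SPE)``).  A zero
    denominator yields ``None`` rather than NaN.
    """
    if isinstance(counts, dict):
        return {c: classification_metrics(cc, eff=eff) for c, cc in counts.items()}
    if eff not in ("product", "geometric"):
        raise ValueError("eff must be 'product' or 'geometric'")
    sen = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spe = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    if sen is None or spe is None:
        eff_val = None
    else:
        eff_val = sen * spe if eff == "product" else float(np.sqrt(sen * spe))
    return {"SEN": sen, "SPE": spe, "EFF": eff_val}
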