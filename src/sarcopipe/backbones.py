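"""Classifier backbones: a trainable NumPy CNN and the MobileNet-V2 reference architecture.

Two backbones are exposed:

``tiny_cnn``
    A small four-conv-block network implemented directly in NumPy with a
    hand-written AMSGrad optimizer. It trains a binary slice classifier on a
    single CPU in seconds-to-minutes, which is what the pipeline's desk-scale
    runs use.

``mobilenet_v2``
    The published inverted-residual architecture (width multiplier 1.0,
    224x224x3 input, 1000-class head), represented as a layer table. It backs
    :func:`count_parameters`, which reproduces the reference total of
    3,538,984 parameters when weights, biases and all four batch-norm
    parameters per channel (scale, shift, running mean, running variance) are
    summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "count_parameters",
    "mobilenet_v2_layers",
    "TinyCNN",
    "ConstantModel",
]


# ---------------------------------------------------------------------------
# MobileNet-V2 reference architecture
# ---------------------------------------------------------------------------

# (expansion factor t, output channels c, repeats n, first stride s)
_MOBILENETV2_CFG = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def mobilenet_v2_layers(num_classes: int = 1000) -> list[dict]:
    """Layer table of MobileNet-V2 (width 1.0).

    Each entry describes one parameterised layer as a dict with keys
    ``kind`` in {conv, dwconv, bn, fc} and the shapes needed to count its
    parameters. Convolutions are bias-free (batch norm follows each one);
    the final fully connected layer carries a bias.
    """
    layers: list[dict] = []

    def conv(cin, cout, k):
        layers.append({"kind": "conv", "cin": cin, "cout": cout, "k": k})
        layers.append({"kind": "bn", "channels": cout})

    def dwconv(c, k=3):
        layers.append({"kind": "dwconv", "channels": c, "k": k})
        layers.append({"kind": "bn", "channels": c})

    conv(3, 32, 3)  # stem, stride 2
    cin = 32
    for t, c, n, _s in _MOBILENETV2_CFG:
        for _ in range(n):
            hidden = cin * t
            if t != 1:
                conv(cin, hidden, 1)  # expand
            dwconv(hidden)
            conv(hidden, c, 1)  # project (linear bottleneck)
            cin = c
    conv(cin, 1280, 1)  # head conv
    layers.append({"kind": "fc", "cin": 1280, "cout": num_classes})
    return layers


def _layer_param_count(layer: dict, include_running_stats: bool) -> int:
    kind = layer["kind"]
    if kind == "conv":
        return layer["k"] * layer["k"] * layer["cin"] * layer["cout"]
    if kind == "dwconv":
        return layer["k"] * layer["k"] * layer["channels"]
    if kind == "bn":
        per_channel = 4 if include_running_stats else 2
        return per_channel * layer["channels"]
    if kind == "fc":
        return layer["cin"] * layer["cout"] + layer["cout"]
    raise ValueError(f"unknown layer kind: {kind!r}")


def count_parameters(
    backbone: str,
    *,
    input_size: tuple[int, int] = (224, 224),
    num_classes: int = 1000,
    n_inputs: int | None = None,
    include_running_stats: bool = True,
    conv_channels: tuple[int, ...] = (8, 16, 32, 32),
) -> int:
    """Total number of weight, bias and normalization parameters of a backbone.

    Parameters
    ----------
    backbone
        One of ``"mobilenet_v2"``, ``"tiny_cnn"`` or ``"linear"``.
    input_size
        Spatial input size; MobileNet-V2 is defined at 224x224 and the count
        is independent of it (global average pooling precedes the head).
    num_classes
        Classification-head width for mobilenet_v2 (reference head: 1000).
    n_inputs
        Input dimension for the ``"linear"`` backbone (a single unit with
        bias, ``n_inputs + 1`` parameters).
    include_running_stats
        Count batch-norm running mean/variance alongside scale/shift. The
        reference 3,538,984 total for MobileNet-V2 includes them.
    conv_channels
        Channel widths of the tiny_cnn conv blocks.
    """
    if backbone == "mobilenet_v2":
        return sum(
            _layer_param_count(layer, include_running_stats)
            for layer in mobilenet_v2_layers(num_classes)
        )
    if backbone == "tiny_cnn":
        total = 0
        cin = 3
        for cout in conv_channels:
            total += 3 * 3 * cin * cout + cout  # conv weight + bias
            cin = cout
        total += cin * 1 + 1  # sigmoid head
        return total
    if backbone == "linear":
        if n_inputs is None:
            raise ValueError("linear backbone requires n_inputs")
        return n_inputs + 1
    raise ValueError(f"unknown backbone: {backbone!r}")


# ---------------------------------------------------------------------------
# Tiny CNN in NumPy
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patches with zero padding, stride 1."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, k * k * c)


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Same-padding stride-1 convolution. w: (k,k,Cin,Cout)."""
    n, h, wid, cin = x.shape
    k = w.shape[0]
    cols = _im2col(x, k)
    out = cols @ w.reshape(k * k * cin, -1)
    out = out.reshape(n, h, wid, -1)
    if b is not None:
        out += b
    return out


def _rotate_kernel(w: np.ndarray) -> np.ndarray:
    """Kernel for the gradient wrt conv input: flip spatially, swap channels."""
    return w[::-1, ::-1].transpose(0, 1, 3, 2).copy()


@dataclass
class _AmsgradState:
    m: np.ndarray
    v: np.ndarray
    vhat: np.ndarray


class _Amsgrad:
    """AMSGrad variant of Adam (non-decreasing second-moment estimate)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {
            k: _AmsgradState(np.zeros_like(p), np.zeros_like(p), np.zeros_like(p))
            for k, p in params.items()
        }

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            s = self.state[k]
            s.m = b1 * s.m + (1 - b1) * g
            s.v = b2 * s.v + (1 - b2) * g * g
            np.maximum(s.vhat, s.v, out=s.vhat)
            mhat = s.m / (1 - b1 ** self.t)
            vhat = s.vhat / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TinyCNN:
    """Four-conv-block binary classifier trained with AMSGrad.

    Architecture: [conv3x3 -> ReLU -> maxpool2] x 4, global average pooling,
    then a single sigmoid unit. Input is (N, H, W, 3) float in [0, 1]; H and W
    must be divisible by 16. The network is deliberately small so a full
    cross-validated model matrix trains on one CPU in minutes.
    """

    def __init__(self, input_size: tuple[int, int] = (64, 64),
                 channels: tuple[int, ...] = (8, 16, 32, 32),
                 seed: int = 0):
        h, w = input_size
        if h % (2 ** len(channels)) or w % (2 ** len(channels)):
            raise ValueError(
                f"input size {input_size} not divisible by {2 ** len(channels)}"
            )
        self.input_size = (h, w)
        self.channels = tuple(channels)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = 3
        for i, cout in enumerate(self.channels):
            fan_in = 3 * 3 * cin
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(3, 3, cin, cout)
            )
            self.params[f"b{i}"] = np.zeros(cout)
            cin = cout
        self.params["w_fc"] = rng.normal(0.0, np.sqrt(1.0 / cin), size=(cin, 1))
        self.params["b_fc"] = np.zeros(1)

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        for i in range(len(self.channels)):
            pre = _conv2d(x, self.params[f"w{i}"], self.params[f"b{i}"])
            act = np.maximum(pre, 0.0)
            n, h, w, c = act.shape
            win = (
                act.reshape(n, h // 2, 2, w // 2, 2, c)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, h // 2, w // 2, c, 4)
            )
            idx = win.argmax(axis=-1)
            out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
            if cache is not None:
                cache.append((x, pre, idx))
            x = out
        feats = x.mean(axis=(1, 2))
        logits = feats @ self.params["w_fc"] + self.params["b_fc"]
        if cache is not None:
            cache.append((x, feats))
        return logits[:, 0]

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sarcoma probability per image; images (N,H,W,3) in [0,1]."""
        images = np.asarray(images, dtype=np.float64)
        out = np.empty(len(images))
        for i in range(0, len(images), batch_size):
            z = self._forward(images[i:i + batch_size])
            out[i:i + batch_size] = 1.0 / (1.0 + np.exp(-z))
        return out

    def _backward(self, x_batch: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        cache: list = []
        logits = self._forward(x_batch, cache)
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        n = len(y)
        grads: dict[str, np.ndarray] = {}

        dlogits = (p - y) / n  # sigmoid + BCE combined
        x_last, feats = cache[-1]
        grads["w_fc"] = feats.T @ dlogits[:, None]
        grads["b_fc"] = dlogits.sum(keepdims=True)
        dfeats = dlogits[:, None] @ self.params["w_fc"].T
        nh, nw = x_last.shape[1:3]
        dx = np.broadcast_to(
            dfeats[:, None, None, :] / (nh * nw), x_last.shape
        ).copy()

        for i in reversed(range(len(self.channels))):
            x_in, pre, idx = cache[i]
            n, h, w, c = pre.shape
            dwin = np.zeros((n, h // 2, w // 2, c, 4))
            np.put_along_axis(dwin, idx[..., None], dx[..., None], axis=-1)
            # invert the pooling reshape: (n,h/2,w/2,c,2,2) -> (n,h,w,c)
            dact = (
                dwin.reshape(n, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h, w, c)
            )
            dpre = dact * (pre > 0)
            k = 3
            cols = _im2col(x_in, k)
            cin = x_in.shape[3]
            grads[f"w{i}"] = (
                cols.T @ dpre.reshape(-1, dpre.shape[3])
            ).reshape(k, k, cin, -1)
            grads[f"b{i}"] = dpre.sum(axis=(0, 1, 2))
            if i > 0:
                dx = _conv2d(dpre, _rotate_kernel(self.params[f"w{i}"]))
        return loss, grads

    # -- training -----------------------------------------------------------

    def fit_epochs(
        self,
        sample_batches,
        n_epochs: int,
        learning_rate: float,
        log: list | None = None,
    ) -> None:
        """Train with AMSGrad over ``n_epochs`` epochs.

        ``sample_batches(epoch)`` yields (images, labels) batches for one
        epoch; this indirection lets the caller materialize augmented crops
        lazily and implement per-epoch subsampling.
        """
        opt = _Amsgrad(self.params, lr=learning_rate)
        for epoch in range(n_epochs):
            losses, correct, seen = [], 0, 0
            for xb, yb in sample_batches(epoch):
                loss, grads = self._backward(xb, yb)
                opt.step(grads)
                losses.append(loss)
                p = 1.0 / (1.0 + np.exp(-self._forward(xb)))
                correct += int(np.sum((p >= 0.5) == (yb >= 0.5)))
                seen += len(yb)
            if log is not None:
                log.append(
                    {
                        "epoch": epoch + 1,
                        "loss": float(np.mean(losses)) if losses else np.nan,
                        "acc": correct / seen if seen else np.nan,
                    }
                )

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        meta = np.array(
            [self.input_size[0], self.input_size[1], len(self.channels), *self.channels]
        )
        np.savez(path, _meta=meta, **self.params)

    @classmethod
    def load(cls, path) -> "TinyCNN":
        data = np.load(path)
        meta = data["_meta"].astype(int)
        model = cls(
            input_size=(int(meta[0]), int(meta[1])),
            channels=tuple(int(c) for c in meta[3 : 3 + meta[2]]),
        )
        for k in model.params:
            model.params[k] = data[k]
        return model


@dataclass
class ConstantModel:
    """Stub classifier emitting a fixed probability; used for plumbing tests."""

    probability: float = 0.5

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return np.full(len(images), self.probability)
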