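"""The class-scoring network: three convolutional blocks on the 64 x 64
class-average image, merged with the 18-feature vector in a two-layer
fully connected head, squashed to a score in [0, 1].

Block b maps C1 -> C2 with two 3x3 convolutions (ReLU) and then halves
the box while doubling the channels with a strided 3x3 convolution:
1->8->8->16, 16->16->16->32, 32->32->32->64; global average pooling of
the final 64 x 8 x 8 activation gives a 64-vector, concatenated with the
18 features and passed through Linear(82 -> 64), ReLU, Linear(64 -> 1),
sigmoid.  Kernel sizes and channel counts are this package's convention.

Implemented in NumPy (im2col convolutions with exact backprop) with an
Adam trainer; weights are a plain dict of arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ScoreNet", "score_classes", "train_scorer"]

N_FEATURES = 18
_BLOCKS = [(1, 8, 16), (16, 16, 32), (32, 32, 64)]
_HIDDEN = 64


def _im2col(x: np.ndarray, stride: int) -> tuple[np.ndarray, int]:
    """x: (N, C, H, W), 3x3 kernel, pad 1.  Returns (cols, H_out) with
    cols of shape (N, C*9, H_out*W_out)."""
    n, c, h, _ = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    h_out = (h + 2 - 3) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, c, 3, 3, h_out, h_out),
        (s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False)
    return view.reshape(n, c * 9, h_out * h_out).copy(), h_out


def _col2im(cols: np.ndarray, x_shape: tuple, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    h_out = (h + 2 - 3) // stride + 1
    xp = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    cols = cols.reshape(n, c, 3, 3, h_out, h_out)
    for ky in range(3):
        for kx in range(3):
            xp[:, :, ky:ky + stride * h_out:stride,
               kx:kx + stride * h_out:stride] += cols[:, :, ky, kx]
    return xp[:, :, 1:h + 1, 1:w + 1]


class ScoreNet:
    """Forward/backward scoring network with a plain-dict parameter set."""

    def __init__(self, weights: dict | None = None, seed: int = 0):
        self.params = weights if weights is not None else self.init_params(seed)
        self._check_shapes()

    # ---- parameters ------------------------------------------------------
    @staticmethod
    def param_shapes() -> dict:
        shapes = {}
        for b, (c_in, c_mid, c_out) in enumerate(_BLOCKS):
            shapes[f"b{b}c0_w"] = (c_mid, c_in * 9)
            shapes[f"b{b}c0_b"] = (c_mid,)
            shapes[f"b{b}c1_w"] = (c_mid, c_mid * 9)
            shapes[f"b{b}c1_b"] = (c_mid,)
            shapes[f"b{b}c2_w"] = (c_out, c_mid * 9)
            shapes[f"b{b}c2_b"] = (c_out,)
        shapes["fc0_w"] = (_HIDDEN, _BLOCKS[-1][2] + N_FEATURES)
        shapes["fc0_b"] = (_HIDDEN,)
        shapes["fc1_w"] = (1, _HIDDEN)
        shapes["fc1_b"] = (1,)
        return shapes

    @classmethod
    def init_params(cls, seed: int = 0) -> dict:
        rng = np.random.default_rng(seed)
        params = {}
        for name, shape in cls.param_shapes().items():
            if name.endswith("_b"):
                params[name] = np.zeros(shape)
            else:
                fan_in = shape[1]
                params[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        return params

    @classmethod
    def zeros(cls) -> "ScoreNet":
        return cls({n: np.zeros(s) for n, s in cls.param_shapes().items()})

    def _check_shapes(self) -> None:
        for name, shape in self.param_shapes().items():
            if name not in self.params:
                raise ValueError(f"missing weight '{name}'")
            if tuple(self.params[name].shape) != shape:
                raise ValueError(
                    f"weight '{name}' has shape {self.params[name].shape}, "
                    f"expected {shape}")

    # ---- forward ---------------------------------------------------------
    def forward(self, images: np.ndarray, features: np.ndarray,
                keep_cache: bool = False):
        """images (N, 64, 64), features (N, 18) -> scores (N,) in [0, 1]."""
        n = images.shape[0]
        if features.shape != (n, N_FEATURES):
            raise ValueError(f"features must be (N, {N_FEATURES})")
        x = images.reshape(n, 1, 64, 64)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float64)
        cache = {"convs": []}
        p = self.params
        for b, (c_in, c_mid, c_out) in enumerate(_BLOCKS):
            for layer, stride in (("c0", 1), ("c1", 1), ("c2", 2)):
                w, bias = p[f"b{b}{layer}_w"], p[f"b{b}{layer}_b"]
                cols, h_out = _im2col(x, stride)
                pre = np.matmul(w.astype(x.dtype), cols) + bias[None, :, None]
                out = np.maximum(pre, 0.0)
                if keep_cache:
                    cache["convs"].append((x.shape, cols, pre > 0, w, stride))
                x = out.reshape(n, w.shape[0], h_out, h_out)
        pooled = x.mean(axis=(2, 3))                       # (N, 64)
        z = np.concatenate([pooled, features], axis=1)     # (N, 82)
        h_pre = z @ p["fc0_w"].T + p["fc0_b"]
        h = np.maximum(h_pre, 0.0)
        logit = (h @ p["fc1_w"].T + p["fc1_b"]).ravel()
        score = 1.0 / (1.0 + np.exp(-logit))
        if keep_cache:
            cache.update(x_last=x, z=z, h_pre=h_pre, h=h, score=score)
            return score, cache
        return score

    # ---- backward --------------------------------------------------------
    def backward(self, cache: dict, dscore: np.ndarray) -> dict:
        """Gradients of a scalar loss given d loss / d score."""
        p = self.params
        n = dscore.shape[0]
        grads = {}
        s = cache["score"]
        dlogit = dscore * s * (1.0 - s)                    # (N,)
        grads["fc1_w"] = (dlogit[:, None] * cache["h"]).sum(0, keepdims=True)
        grads["fc1_b"] = np.array([dlogit.sum()])
        dh = dlogit[:, None] * p["fc1_w"][0][None, :]
        dh_pre = dh * (cache["h_pre"] > 0)
        grads["fc0_w"] = dh_pre.T @ cache["z"]
        grads["fc0_b"] = dh_pre.sum(0)
        dz = dh_pre @ p["fc0_w"]
        c_last = _BLOCKS[-1][2]
        dpooled = dz[:, :c_last]
        x_last = cache["x_last"]
        dx = (dpooled[:, :, None, None]
              * np.ones_like(x_last) / (x_last.shape[2] * x_last.shape[3]))
        conv_caches = cache["convs"]
        names = [f"b{b}{layer}" for b in range(len(_BLOCKS))
                 for layer in ("c0", "c1", "c2")]
        for name, (x_shape, cols, relu_mask, w, stride) in zip(
                reversed(names), reversed(conv_caches)):
            h_out = int(np.sqrt(cols.shape[2]))
            dout = dx.reshape(n, w.shape[0], h_out * h_out) * relu_mask
            grads[f"{name}_w"] = np.matmul(
                dout, cols.transpose(0, 2, 1)).sum(axis=0)
            grads[f"{name}_b"] = dout.sum(axis=(0, 2))
            dcols = np.matmul(w.T.astype(dout.dtype), dout)
            dx = _col2im(dcols, x_shape, stride)
        return grads


def score_classes(images: np.ndarray, features: np.ndarray,
                  weights: dict | ScoreNet) -> np.ndarray:
    """Score each class (prepared 64 x 64 image + 18 features) in [0, 1]."""
    net = weights if isinstance(weights, ScoreNet) else ScoreNet(weights)
    return net.forward(np.asarray(images), np.asarray(features))


def train_scorer(images: np.ndarray, features: np.ndarray,
                 targets: np.ndarray, epochs: int = 30, lr: float = 1e-3,
                 batch_size: int = 32, seed: int = 0,
                 net: ScoreNet | None = None) -> tuple[ScoreNet, list[float]]:
    """Fit the scoring network to target scores with Adam on MSE loss.

    Returns (net, per-epoch training MSE).  Intended for small synthetic
    training sets; the published tool ships a network trained on a large
    curated corpus, which is out of scope here.
    """
    rng = np.random.default_rng(seed)
    net = net or ScoreNet(seed=seed)
    images = np.asarray(images, dtype=np.float32)
    features = np.asarray(features, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(val) for k, val in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    n = len(images)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            score, cache = net.forward(images[idx], features[idx],
                                       keep_cache=True)
            err = score - targets[idx]
            losses.append(float((err ** 2).mean()))
            dscore = 2.0 * err / len(idx)
            grads = net.backward(cache, dscore)
            step += 1
            for k in net.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                net.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        history.append(float(np.mean(losses)))
    return net, history
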