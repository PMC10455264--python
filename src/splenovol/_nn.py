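"""Minimal NumPy building blocks for the 2D U-Net segmenter.

Convolutions are evaluated as im2col matrix products in float32 (BLAS does
the heavy lifting); gradients are derived by hand.  The backward pass of a
stride-1 same-padded correlation is itself a same-padded correlation with
the spatially flipped, channel-transposed kernel, so the forward kernel is
reused for input gradients and no scatter-add is needed.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "UNet2D", "Adam", "sigmoid", "segmentation_loss"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) → (N*H*W, C*k*k) patch matrix with same padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    return v.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Stride-1 same-padded correlation; x (N,C,H,W), weight (F,C,k,k)."""
    n, c, h, w = x.shape
    f = weight.shape[0]
    cols = _im2col(x, weight.shape[2])
    out = cols @ weight.reshape(f, -1).T
    out += bias
    return out.transpose(1, 0).reshape(f, n, h, w).transpose(1, 0, 2, 3)


class Conv2d:
    """Same-padded stride-1 convolution layer with He initialization."""

    def __init__(self, cin: int, cout: int, ksize: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * ksize * ksize))
        self.weight = (rng.standard_normal((cout, cin, ksize, ksize)) * scale).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        f, _, k, _ = self.weight.shape
        self._cols = _im2col(x, k)
        self._xshape = x.shape
        out = self._cols @ self.weight.reshape(f, -1).T
        out += self.bias
        return out.transpose(1, 0).reshape(f, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        f, _, k, _ = self.weight.shape
        gm = grad.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.dweight = (gm.T @ self._cols).reshape(self.weight.shape)
        self.dbias = gm.sum(axis=0)
        flipped = np.ascontiguousarray(self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx = conv2d(grad, flipped, np.zeros(c, dtype=np.float32))
        self._cols = None
        return dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2×2 max pooling; returns pooled output and the argmax indicator.

    Ties within a window route the gradient to the first position in
    window scan order, keeping backward deterministic.
    """
    n, c, h, w = x.shape
    windows = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    first = np.zeros(flat.shape, dtype=bool)
    np.put_along_axis(first, idx[..., None], True, axis=-1)
    ind = (
        first.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )
    return out, ind


def maxpool2_backward(grad: np.ndarray, ind: np.ndarray) -> np.ndarray:
    n, c, hh, ww = grad.shape
    up = grad[:, :, :, None, :, None] * np.ones((1, 1, 1, 2, 1, 2), dtype=grad.dtype)
    up = up.reshape(n, c, hh * 2, ww * 2)
    return up * ind


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor ×2 upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(grad: np.ndarray) -> np.ndarray:
    n, c, h, w = grad.shape
    return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def segmentation_loss(logits: np.ndarray, targets: np.ndarray, kind: str = "combined"
                      ) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for binary segmentation.

    ``kind``: "cross-entropy" (pixel-mean BCE with logits), "dice"
    (1 − soft Dice over the batch) or "combined" (equal-weight sum).
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    p = sigmoid(z)
    nel = z.size
    grad = np.zeros_like(z)
    loss = 0.0
    if kind in ("cross-entropy", "combined"):
        bce = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
        loss += float(bce.mean())
        grad += (p - y) / nel
    if kind in ("dice", "combined"):
        eps = 1.0
        inter = float((p * y).sum())
        den = float(p.sum() + y.sum()) + eps
        num = 2.0 * inter + eps
        loss += 1.0 - num / den
        dldp = -(2.0 * y * den - num) / (den * den)
        grad += dldp * p * (1.0 - p)
    if kind not in ("cross-entropy", "dice", "combined"):
        raise ValueError(f"unknown loss kind: {kind}")
    return loss, grad.astype(np.float32)


class _Block:
    """Conv→ReLU stage, optionally doubled (residual style for the
    resnet-flavored encoder: two 3×3 convs with an identity/projection
    shortcut)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 residual: bool = False):
        self.residual = residual
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.conv2 = Conv2d(cout, cout, 3, rng) if residual else None
        self.proj = Conv2d(cin, cout, 1, rng) if (residual and cin != cout) else None

    def layers(self) -> list[Conv2d]:
        out = [self.conv1]
        if self.conv2 is not None:
            out.append(self.conv2)
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        a1 = self.conv1.forward(x)
        h1 = relu(a1)
        if not self.residual:
            self._cache = (a1,)
            return h1
        a2 = self.conv2.forward(h1)
        shortcut = self.proj.forward(x) if self.proj is not None else x
        a3 = a2 + shortcut
        self._cache = (a1, a3)
        return relu(a3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if not self.residual:
            (a1,) = self._cache
            return self.conv1.backward(grad * (a1 > 0))
        a1, a3 = self._cache
        g3 = grad * (a3 > 0)
        gx = self.proj.backward(g3) if self.proj is not None else g3
        gh1 = self.conv2.backward(g3)
        gx = gx + self.conv1.backward(gh1 * (a1 > 0))
        return gx


class UNet2D:
    """2D encoder–decoder segmenter with skip connections.

    The encoder halves resolution ``depth`` times with 2×2 max pooling,
    doubling channels each stage; the decoder upsamples back with
    nearest-neighbor ×2 followed by a channel-reducing convolution, and
    each decoder stage is concatenated with the matching encoder feature
    map (skip connection) before its conv block.  A 1×1 convolution maps
    to per-pixel spleen logits; probabilities are ``sigmoid(logits)``.
    """

    def __init__(self, depth: int = 3, base_channels: int = 8, in_channels: int = 1,
                 seed: int = 0, residual_encoder: bool = False):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * (2 ** i) for i in range(depth + 1)]
        self.enc = [_Block(in_channels if i == 0 else chans[i - 1], chans[i], rng,
                           residual=residual_encoder) for i in range(depth)]
        self.bottleneck = _Block(chans[depth - 1], chans[depth], rng, residual=residual_encoder)
        self.upconv = [Conv2d(chans[i + 1], chans[i], 3, rng) for i in reversed(range(depth))]
        self.dec = [_Block(2 * chans[i], chans[i], rng) for i in reversed(range(depth))]
        self.head = Conv2d(chans[0], 1, 1, rng)

    # -- parameter plumbing ------------------------------------------------
    def _conv_layers(self) -> list[Conv2d]:
        layers: list[Conv2d] = []
        for b in self.enc:
            layers += b.layers()
        layers += self.bottleneck.layers()
        for u, d in zip(self.upconv, self.dec):
            layers.append(u)
            layers += d.layers()
        layers.append(self.head)
        return layers

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self._conv_layers())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._conv_layers()):
            out[f"w{i}"] = layer.weight
            out[f"b{i}"] = layer.bias
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._conv_layers()):
            layer.weight = np.asarray(state[f"w{i}"], dtype=np.float32)
            layer.bias = np.asarray(state[f"b{i}"], dtype=np.float32)

    # -- forward / backward ------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        h, w = x.shape[2:]
        div = 2 ** self.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {div}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) float32 → logits (N, 1, H, W)."""
        self._check_shape(x)
        skips = []
        pool_inds = []
        h = x.astype(np.float32)
        for block in self.enc:
            h = block.forward(h)
            skips.append(h)
            h, ind = maxpool2(h)
            pool_inds.append(ind)
        h = self.bottleneck.forward(h)
        self._pool_inds = pool_inds
        self._skip_channels = [s.shape[1] for s in skips]
        for level, (up, dec) in enumerate(zip(self.upconv, self.dec)):
            h = upsample2(h)
            h = relu(up.forward(h))
            up._act = h  # post-ReLU activation needed for backward gate
            skip = skips[self.depth - 1 - level]
            h = dec.forward(np.concatenate([skip, h], axis=1))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads: list[np.ndarray | None] = [None] * self.depth
        for level in reversed(range(self.depth)):
            dec = self.dec[level]
            up = self.upconv[level]
            gcat = dec.backward(g)
            cskip = self._skip_channels[self.depth - 1 - level]
            skip_grads[self.depth - 1 - level] = gcat[:, :cskip]
            gup = gcat[:, cskip:]
            gup = up.backward(gup * (up._act > 0))
            g = upsample2_backward(gup)
        g = self.bottleneck.backward(g)
        for i in reversed(range(self.depth)):
            g = maxpool2_backward(g, self._pool_inds[i])
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x))


class Adam:
    """Adam optimizer over all convolution parameters of a network."""

    def __init__(self, net: UNet2D, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [
            (np.zeros_like(l.weight), np.zeros_like(l.bias)) for l in net._conv_layers()
        ]
        self._v = [
            (np.zeros_like(l.weight), np.zeros_like(l.bias)) for l in net._conv_layers()
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, (mw, mb), (vw, vb) in zip(self.net._conv_layers(), self._m, self._v):
            for param, grad, m, v in (
                (layer.weight, layer.dweight, mw, vw),
                (layer.bias, layer.dbias, mb, vb),
            ):
                m *= self.beta1
                m += (1 - self.beta1) * grad
                v *= self.beta2
                v += (1 - self.beta2) * grad * grad
                param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
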