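"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small 3-D convolutional classifier: tensors on a
dynamically built tape, dense 3-D convolution via an im2col lowering,
average pooling, batch normalization, concatenation (the dense-connectivity
primitive), affine layers and a class-weighted softmax cross-entropy head.
All gradients are checked against central finite differences in the test
suite.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.grad_fn is None:
                continue
            for parent, g in zip(t.parents, t.grad_fn(t.grad)):
                if parent.requires_grad and g is not None:
                    parent.grad = parent.grad + g


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, np.float64), requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def grad_fn(g):
        return (g * mask,)

    return Tensor(x.data * mask, (x,), grad_fn)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def grad_fn(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor(a.data @ b.data, (a, b), grad_fn)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """x + b with b broadcast over all axes except the last."""
    def grad_fn(g):
        axes = tuple(range(g.ndim - 1))
        return g, g.sum(axis=axes)

    return Tensor(x.data + b.data, (x, b), grad_fn)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def grad_fn(g):
        return (g.reshape(old),)

    return Tensor(x.data.reshape(shape), (x,), grad_fn)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate along axis 1 (the channel axis)."""
    sizes = [t.data.shape[1] for t in tensors]
    cuts = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, cuts, axis=1))

    return Tensor(np.concatenate([t.data for t in tensors], axis=1),
                  tuple(tensors), grad_fn)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """3-D convolution, stride 1.  x: (N,C,D,H,W); w: (O,C,k,k,k)."""
    N, C, D, H, W = x.data.shape
    O, Cw, k, _, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    Do, Ho, Wo = D + 2 * p - k + 1, H + 2 * p - k + 1, W + 2 * p - k + 1
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # (N, C, Do, Ho, Wo, k, k, k) -> (N*L, C*k^3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                                ).reshape(N * Do * Ho * Wo, C * k ** 3)
    Wm = w.data.reshape(O, C * k ** 3)
    out = cols @ Wm.T
    if b is not None:
        out = out + b.data
    out = out.reshape(N, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)

    def grad_fn(g):
        gf = g.transpose(0, 2, 3, 4, 1).reshape(N * Do * Ho * Wo, O)
        gw = (gf.T @ cols).reshape(w.data.shape)
        gb = gf.sum(axis=0) if b is not None else None
        gcols = (gf @ Wm).reshape(N, Do, Ho, Wo, C, k, k, k)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for c2 in range(k):
                for e in range(k):
                    gxp[:, :, a:a + Do, c2:c2 + Ho, e:e + Wo] += \
                        gcols[:, :, :, :, :, a, c2, e].transpose(0, 4, 1, 2, 3)
        gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
        if b is not None:
            return gx, gw, gb
        return gx, gw

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, grad_fn)


def avgpool3d(x: Tensor) -> Tensor:
    """2x2x2 average pooling, stride 2; spatial dims must be even."""
    N, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("avgpool3d needs even spatial dimensions")
    out = x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2).mean(
        axis=(3, 5, 7))

    def grad_fn(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None, :, None] / 8.0,
            (N, C, D // 2, 2, H // 2, 2, W // 2, 2),
        ).reshape(N, C, D, H, W)
        return (gx,)

    return Tensor(out, (x,), grad_fn)


class BatchNorm:
    """Per-channel batch normalization over (N, C, ...) tensors.

    Holds gamma/beta parameters and running statistics; call as a function
    with ``training`` switching between batch and running moments.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = parameter(np.ones(channels))
        self.beta = parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = (0,) + tuple(range(2, x.data.ndim))
        shape = (1, -1) + (1,) * (x.data.ndim - 2)
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean \
                + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var \
                + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(shape)) * inv_sd.reshape(shape)
        out = xhat * self.gamma.data.reshape(shape) \
            + self.beta.data.reshape(shape)
        m = x.data.size / x.data.shape[1]
        gamma, beta = self.gamma, self.beta

        def grad_fn(g):
            ggamma = (g * xhat).sum(axis=axes)
            gbeta = g.sum(axis=axes)
            if training:
                gxhat = g * gamma.data.reshape(shape)
                gx = (inv_sd.reshape(shape) / m) * (
                    m * gxhat
                    - gxhat.sum(axis=axes).reshape(shape)
                    - xhat * (gxhat * xhat).sum(axis=axes).reshape(shape)
                )
            else:
                gx = g * gamma.data.reshape(shape) * inv_sd.reshape(shape)
            return gx, ggamma, gbeta

        return Tensor(out, (x, gamma, beta), grad_fn)


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           class_weights: np.ndarray) -> Tensor:
    """Mean class-weighted softmax cross-entropy over the batch."""
    labels = np.asarray(labels, int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    w = np.asarray(class_weights, float)[labels]
    n = len(labels)
    loss = -np.sum(w * logp[np.arange(n), labels]) / n
    probs = np.exp(logp)
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0

    def grad_fn(g):
        return (g * w[:, None] * (probs - onehot) / n,)

    return Tensor(loss, (logits,), grad_fn)
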