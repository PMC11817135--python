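"""Trainable NumPy realization of an :class:`~actimage.cnn.ArchitectureSpec`.

Forward and backward passes are written with im2col-style matrix products so
training a cohort-sized dataset stays fast on one CPU.  All randomness
(weight initialization, dropout masks) flows from explicit seeds, and
inference applies no dropout, so two inference passes on the same weights and
input are bitwise identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .cnn import ArchitectureSpec, LayerKind, softmax


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv2D(_Layer):
    """Valid (optionally zero-padded) stride-1 convolution, NHWC layout."""

    def __init__(self, c_in, filters, kernel, padding, rng, dtype):
        super().__init__()
        self.k = kernel
        self.p = padding
        fan_in = kernel * kernel * c_in
        limit = np.sqrt(6.0 / fan_in)
        self.W = rng.uniform(-limit, limit, (kernel, kernel, c_in, filters)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        if self.p:
            x = np.pad(x, ((0, 0), (self.p, self.p), (self.p, self.p), (0, 0)))
        n, h, w, c = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        # im2col in (c, k, k) minor order so no transpose copy is needed
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (n, ho, wo, c, k, k)
        cols = win.reshape(n * ho * wo, c * k * k)
        Wmat = self.W.transpose(2, 0, 1, 3).reshape(c * k * k, -1)
        out = cols @ Wmat + self.b
        self._cols = cols
        self._xshape = (n, h, w, c)
        self._oshape = (n, ho, wo)
        return out.reshape(n, ho, wo, -1)

    def backward(self, g):
        n, ho, wo = self._oshape
        k = self.k
        f = self.W.shape[-1]
        _, h, w, c = self._xshape
        gm = g.reshape(n * ho * wo, f)
        dW = (self._cols.T @ gm).reshape(c, k, k, f).transpose(1, 2, 0, 3)
        self.grads[0][...] = dW
        self.grads[1][...] = gm.sum(axis=0)
        dx = np.zeros(self._xshape, dtype=g.dtype)
        # accumulate kernel-position contributions; stride is 1 so each
        # (i, j) offset of the kernel touches a contiguous input slab
        Wr = self.W  # (k, k, c, f)
        g4 = gm.reshape(n, ho, wo, f)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + ho, j : j + wo, :] += g4 @ Wr[i, j].T
        if self.p:
            dx = dx[:, self.p : -self.p, self.p : -self.p, :]
        return dx


class _MaxPool(_Layer):
    def __init__(self, kernel, stride, padding=0):
        super().__init__()
        self.k, self.s, self.p = kernel, stride, padding

    def forward(self, x, train):
        if self.p:
            x = np.pad(
                x,
                ((0, 0), (self.p, self.p), (self.p, self.p), (0, 0)),
                constant_values=-np.inf,
            )
        n, h, w, c = x.shape
        k, s = self.k, self.s
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        # elementwise maximum over the k*k shifted slices; avoids copying
        # strided window views
        slices = [
            x[:, i : i + (ho - 1) * s + 1 : s, j : j + (wo - 1) * s + 1 : s, :]
            for i in range(k)
            for j in range(k)
        ]
        out = slices[0].copy()
        for sl in slices[1:]:
            np.maximum(out, sl, out=out)
        self._padded_shape = (n, h, w, c)
        if train:
            # argmax with first-occurrence tie-break, matching row-major
            # window order; only needed for the backward pass
            arg = np.zeros((n, ho, wo, c), dtype=np.int8)
            assigned = np.zeros((n, ho, wo, c), dtype=bool)
            for idx, sl in enumerate(slices):
                hit = (sl == out) & ~assigned
                arg[hit] = idx
                assigned |= hit
            self._arg = arg
        else:
            self._arg = None
        return out

    def backward(self, g):
        if self._arg is None:
            raise RuntimeError("backward requires a forward pass in training mode")
        n, h, w, c = self._padded_shape
        k, s = self.k, self.s
        ho, wo = g.shape[1], g.shape[2]
        di, dj = self._arg // k, self._arg % k
        ii = np.arange(ho)[None, :, None, None] * s + di
        jj = np.arange(wo)[None, None, :, None] * s + dj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, None, None, :]
        idx = ((nn * h + ii) * w + jj) * c + cc
        dx = np.bincount(
            idx.ravel(), weights=g.ravel().astype(np.float64), minlength=n * h * w * c
        ).reshape(n, h, w, c)
        if self.p:
            dx = dx[:, self.p : -self.p, self.p : -self.p, :]
        return dx.astype(g.dtype)


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g):
        return np.where(self._mask, g, 0)


class _Dropout(_Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng, dtype):
        super().__init__()
        limit = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class NumpyCNN:
    """A feed-forward CNN instantiated from an architecture description.

    The trailing softmax of the spec is folded into the loss during training
    (cross-entropy on logits); :meth:`predict_proba` applies it explicitly.
    """

    def __init__(self, arch: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        trace = arch.validate()
        init_rng, self.dropout_rng = [
            np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
        ]
        self.layers: list[_Layer] = []
        shape = trace.entries[0][1]
        for i, spec in enumerate(arch.layers):
            out_shape = trace.entries[i + 1][1]
            if spec.kind is LayerKind.CONV:
                self.layers.append(
                    _Conv2D(shape[2], spec.filters, spec.kernel, spec.padding, init_rng, dtype)
                )
            elif spec.kind is LayerKind.MAXPOOL:
                self.layers.append(_MaxPool(spec.kernel, spec.stride, spec.padding))
            elif spec.kind is LayerKind.RELU:
                self.layers.append(_ReLU())
            elif spec.kind is LayerKind.DROPOUT:
                self.layers.append(_Dropout(spec.rate if spec.rate is not None else 0.5, self.dropout_rng))
            elif spec.kind is LayerKind.FLATTEN:
                self.layers.append(_Flatten())
            elif spec.kind is LayerKind.DENSE:
                self.layers.append(_Dense(shape[0], spec.width, init_rng, dtype))
            elif spec.kind is LayerKind.SOFTMAX:
                continue  # folded into the loss / predict_proba
            shape = out_shape

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of (n, H, W, C) inputs."""
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            probs.append(softmax(logits, axis=1))
        return np.concatenate(probs)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- training ----------------------------------------------------------
    def loss_and_backward(
        self, x: np.ndarray, y: np.ndarray, train: bool = True
    ) -> tuple[float, int]:
        """Mean cross-entropy on a batch; fills layer gradients.

        Returns the loss and the number of correct argmax predictions on the
        batch (with dropout active when ``train`` is set, as curve
        conventions report it).
        """
        logits = self.forward(x, train=train)
        n = len(y)
        p = softmax(logits, axis=1)
        eps = np.finfo(np.float64).tiny
        loss = float(-np.log(p[np.arange(n), y] + eps).mean())
        correct = int((logits.argmax(axis=1) == y).sum())
        g = p.astype(self.dtype)
        g[np.arange(n), y] -= 1.0
        g /= n
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss, correct

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        total = 0.0
        for start in range(0, len(x), batch_size):
            xb, yb = x[start : start + batch_size], y[start : start + batch_size]
            p = softmax(self.forward(xb, train=False), axis=1)
            eps = np.finfo(np.float64).tiny
            total += float(-np.log(p[np.arange(len(yb)), yb] + eps).sum())
        return total / len(y)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path, manifest: dict | None = None) -> Path:
        """Save weights as .npz with a JSON sidecar manifest."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{f"param_{i}": p for i, p in enumerate(self.parameters)})
        side = dict(manifest or {})
        side["architecture"] = self.arch.to_yaml()
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))
        return path

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.parameters):
                arr = data[f"param_{i}"]
                if arr.shape != p.shape:
                    raise ValueError(f"checkpoint shape mismatch at parameter {i}")
                p[...] = arr.astype(p.dtype)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g64 = g.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g64
            v *= self.b2
            v += (1 - self.b2) * g64 * g64
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
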