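"""Backend-neutral model adapter contract and numpy reference backends.

The training and interpretation machinery only sees a ``ModelAdapter``:
a trainable predictor mapping one-hot batches ``(n, L, 4)`` to per-task
scalars ``(n, T)`` that can also differentiate its output with respect to
the input. Only scalar single- or multi-task outputs are supported;
profile/coverage outputs would require label transformations and are out
of scope.

Two reference backends are implemented directly on the numeric array
layer so the whole package runs and is testable on a plain scientific
Python stack:

* ``LinearAdapter`` — f(x) = <w, x> + b per task; its input gradient is
  the weight tensor itself, which makes it the analytic oracle for the
  attribution code.
* ``ConvNetAdapter`` — a small convolutional network (conv -> ReLU ->
  max-pool -> flatten -> dense -> ReLU -> dense) trained by plain SGD on
  mean-squared error, with hand-written forward/backward passes. The
  flatten/dense head is deliberately position-sensitive, like the enhancer
  models used for STARR-seq regression, so translational augmentations
  have an invariance prior to teach.

Adapters for deep-learning frameworks can wrap any model behind the same
five methods; nothing else in the package would change.
"""

from __future__ import annotations

import abc
from typing import Sequence

import numpy as np

from .seqdata import OneHotBatch

__all__ = ["ModelAdapter", "LinearAdapter", "ConvNetAdapter"]


def _as_array(batch, dtype=np.float64) -> np.ndarray:
    if isinstance(batch, OneHotBatch):
        return np.asarray(batch.data, dtype=dtype)
    return np.asarray(batch, dtype=dtype)


class ModelAdapter(abc.ABC):
    """Contract wrapping a trainable scalar-output predictor."""

    input_length: int
    n_tasks: int

    @abc.abstractmethod
    def predict(self, batch) -> np.ndarray:
        """Per-task scalar predictions, shape (n, n_tasks). Deterministic
        given fixed weights."""

    @abc.abstractmethod
    def train_on_batch(self, batch, labels) -> float:
        """One gradient step on the batch; returns the batch loss."""

    @abc.abstractmethod
    def input_gradient(self, batch, task_index: int = 0) -> np.ndarray:
        """Gradient of the selected scalar output w.r.t. the one-hot input,
        shaped like the batch (summed over the batch axis per sequence)."""

    @abc.abstractmethod
    def get_weights(self) -> list[np.ndarray]: ...

    @abc.abstractmethod
    def set_weights(self, weights: Sequence[np.ndarray]) -> None: ...

    # learning-rate control
    learning_rate: float

    def evaluate(self, batch, labels) -> float:
        """Mean-squared error of predictions against labels."""
        pred = self.predict(batch)
        return float(np.mean((pred - np.asarray(labels, dtype=np.float64)) ** 2))


class LinearAdapter(ModelAdapter):
    """f(x) = sum(w * x) + b per task, trained by SGD on MSE."""

    def __init__(self, input_length: int, n_tasks: int = 1, learning_rate: float = 0.01,
                 seed: int = 0):
        self.input_length = input_length
        self.n_tasks = n_tasks
        self.learning_rate = learning_rate
        rng = np.random.default_rng(seed)
        self.w = rng.normal(0, 0.01, size=(n_tasks, input_length, 4))
        self.b = np.zeros(n_tasks)

    def predict(self, batch) -> np.ndarray:
        x = _as_array(batch)
        return np.tensordot(x, self.w, axes=([1, 2], [1, 2])) + self.b

    def train_on_batch(self, batch, labels) -> float:
        x = _as_array(batch)
        y = np.asarray(labels, dtype=np.float64)
        pred = self.predict(x)
        err = pred - y
        n = x.shape[0]
        grad_w = np.tensordot(err, x, axes=([0], [0])) * (2.0 / (n * self.n_tasks))
        grad_b = err.mean(axis=0) * 2.0 / self.n_tasks
        self.w -= self.learning_rate * grad_w
        self.b -= self.learning_rate * grad_b
        return float(np.mean(err ** 2))

    def input_gradient(self, batch, task_index: int = 0) -> np.ndarray:
        x = _as_array(batch)
        if not 0 <= task_index < self.n_tasks:
            raise IndexError(f"task_index {task_index} out of range [0, {self.n_tasks})")
        return np.broadcast_to(self.w[task_index], x.shape).copy()

    def get_weights(self) -> list[np.ndarray]:
        return [self.w.copy(), self.b.copy()]

    def set_weights(self, weights) -> None:
        self.w = weights[0].copy()
        self.b = weights[1].copy()


class ConvNetAdapter(ModelAdapter):
    """Small convolutional network with hand-written numpy backprop.

    Architecture: conv1d(4 -> n_filters, width) -> ReLU -> max-pool(pool)
    -> flatten -> dense(hidden) -> ReLU -> dense(n_tasks). Trained by
    SGD with classical momentum on mean-squared error (momentum=0 gives
    plain SGD). Arithmetic runs in float32 by default for speed; pass
    ``dtype=np.float64`` when input gradients must agree with finite
    differences to high precision (e.g. gradient checking).
    """

    def __init__(
        self,
        input_length: int,
        n_tasks: int = 1,
        n_filters: int = 32,
        filter_width: int = 15,
        pool: int = 4,
        hidden: int = 64,
        learning_rate: float = 0.02,
        momentum: float = 0.9,
        grad_clip: float = 5.0,
        leak: float = 0.1,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.input_length = input_length
        self.n_tasks = n_tasks
        self.n_filters = n_filters
        self.filter_width = filter_width
        self.pool = pool
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.grad_clip = grad_clip
        self.leak = leak
        self.dtype = np.dtype(dtype)
        conv_len = input_length - filter_width + 1
        self.pooled_len = conv_len // pool
        if self.pooled_len < 1:
            raise ValueError("input too short for the chosen filter width and pool size")
        flat = self.pooled_len * n_filters
        rng = np.random.default_rng(seed)
        he = lambda fan_in, shape: rng.normal(0, np.sqrt(2.0 / fan_in), size=shape).astype(self.dtype)
        self.Wc = he(filter_width * 4, (filter_width * 4, n_filters))
        self.bc = np.zeros(n_filters, dtype=self.dtype)
        self.W1 = he(flat, (flat, hidden))
        self.b1 = np.zeros(hidden, dtype=self.dtype)
        self.W2 = he(hidden, (hidden, n_tasks))
        self.b2 = np.zeros(n_tasks, dtype=self.dtype)

    # -- forward ----------------------------------------------------------

    def _windows(self, x: np.ndarray) -> np.ndarray:
        """im2col view: (n, conv_len, filter_width * 4)."""
        n, L, c = x.shape
        k = self.filter_width
        v = np.lib.stride_tricks.sliding_window_view(x, (k, c), axis=(1, 2))
        return v.reshape(n, L - k + 1, k * c)

    def _act(self, z: np.ndarray) -> np.ndarray:
        # leaky ReLU: the small negative slope keeps units recoverable
        return np.where(z > 0, z, self.leak * z)

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        return np.where(z > 0, 1.0, self.leak).astype(self.dtype)

    def _forward(self, x: np.ndarray):
        win = self._windows(x)                       # (n, Lc, k*4)
        conv = win @ self.Wc + self.bc               # (n, Lc, F)
        relu1 = self._act(conv)
        Lp = self.pooled_len
        blocks = relu1[:, : Lp * self.pool].reshape(x.shape[0], Lp, self.pool, -1)
        argmax = np.argmax(blocks, axis=2)
        pooled = np.take_along_axis(blocks, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(x.shape[0], -1)
        h = flat @ self.W1 + self.b1
        relu2 = self._act(h)
        out = relu2 @ self.W2 + self.b2
        cache = (x, win, conv, blocks, argmax, flat, h, relu2)
        return out, cache

    def predict(self, batch) -> np.ndarray:
        out, _ = self._forward(_as_array(batch, self.dtype))
        return out.astype(np.float64)

    # -- backward ---------------------------------------------------------

    def _backward(self, cache, dout: np.ndarray, want_input_grad: bool = False):
        x, win, conv, blocks, argmax, flat, h, relu2 = cache
        n, L, c = x.shape
        Lp, p, F = self.pooled_len, self.pool, self.n_filters
        grads = {}
        grads["W2"] = relu2.T @ dout
        grads["b2"] = dout.sum(axis=0)
        dh = (dout @ self.W2.T) * self._act_grad(h)
        grads["W1"] = flat.T @ dh
        grads["b1"] = dh.sum(axis=0)
        dflat = dh @ self.W1.T
        dpooled = dflat.reshape(n, Lp, F)
        dblocks = np.zeros_like(blocks)
        np.put_along_axis(dblocks, argmax[:, :, None, :], dpooled[:, :, None, :], axis=2)
        drelu1 = np.zeros_like(conv)
        drelu1[:, : Lp * p] = dblocks.reshape(n, Lp * p, F)
        dconv = drelu1 * self._act_grad(conv)
        grads["Wc"] = np.tensordot(win, dconv, axes=([0, 1], [0, 1]))
        grads["bc"] = dconv.sum(axis=(0, 1))
        if want_input_grad:
            dwin = dconv @ self.Wc.T                  # (n, Lc, k*4)
            dx = np.zeros_like(x)
            k = self.filter_width
            dwin = dwin.reshape(n, -1, k, c)
            for j in range(k):
                dx[:, j : j + dwin.shape[1]] += dwin[:, :, j, :]
            grads["x"] = dx
        return grads

    def train_on_batch(self, batch, labels) -> float:
        x = _as_array(batch, self.dtype)
        y = np.asarray(labels, dtype=self.dtype)
        if y.ndim == 1:
            y = y[:, None]
        out, cache = self._forward(x)
        err = out - y
        loss = float(np.mean(err ** 2))
        dout = (err * (2.0 / err.size)).astype(self.dtype)
        grads = self._backward(cache, dout)
        names = ("Wc", "bc", "W1", "b1", "W2", "b2")
        # global-norm clipping keeps occasional huge minibatch gradients from
        # blowing up the momentum buffer
        gnorm = np.sqrt(sum(float(np.sum(grads[k] ** 2)) for k in names))
        scale = min(1.0, self.grad_clip / max(gnorm, 1e-12)) * self.learning_rate
        if not hasattr(self, "_velocity"):
            self._velocity = {k: np.zeros_like(getattr(self, k)) for k in names}
        for name in names:
            v = self._velocity[name]
            v *= self.momentum
            v -= scale * grads[name]
            setattr(self, name, getattr(self, name) + v)
        return loss

    def input_gradient(self, batch, task_index: int = 0) -> np.ndarray:
        x = _as_array(batch, self.dtype)
        if not 0 <= task_index < self.n_tasks:
            raise IndexError(f"task_index {task_index} out of range [0, {self.n_tasks})")
        out, cache = self._forward(x)
        dout = np.zeros_like(out)
        dout[:, task_index] = 1.0
        return self._backward(cache, dout, want_input_grad=True)["x"].astype(np.float64)

    def get_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in (self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2)]

    def set_weights(self, weights) -> None:
        self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2 = [
            np.asarray(a, dtype=self.dtype).copy() for a in weights
        ]
        # restoring a checkpoint invalidates any accumulated momentum
        if hasattr(self, "_velocity"):
            del self._velocity
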