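"""AdamW over named parameter dictionaries."""

from __future__ import annotations

import numpy as np

from . import _kernels as _k
from .autodiff import Tensor


class AdamW:
    """Decoupled-weight-decay Adam.

    Operates in place on a ``{name: Tensor}`` parameter dictionary. Default
    moments follow the common (0.9, 0.999) choice; weight decay defaults to
    zero, in which case the update is plain Adam. Moment buffers are kept in
    one flat array so the update runs as a handful of vectorized operations
    rather than one pass per parameter.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._order = list(params)
        self._slices: dict[str, tuple[int, int, tuple]] = {}
        offset = 0
        for k in self._order:
            n = params[k].data.size
            self._slices[k] = (offset, offset + n, params[k].data.shape)
            offset += n
        self._n = offset
        dtype = np.result_type(*(p.data.dtype for p in params.values()))
        self._m = np.zeros(offset, dtype=dtype)
        self._v = np.zeros(offset, dtype=dtype)
        self._g = np.zeros(offset, dtype=dtype)

    def step(self) -> None:
        """Apply one update from the gradients currently stored on the tensors."""
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        g = self._g
        for k in self._order:
            lo, hi, _ = self._slices[k]
            grad = self.params[k].grad
            if grad is None:
                g[lo:hi] = 0.0
            else:
                g[lo:hi] = grad.reshape(-1)
        # p -= lr * (m/bc1) / (sqrt(v/bc2) + eps), refactored so the kernel
        # needs a single scale and shifted epsilon
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        step_scale = self.lr * np.sqrt(bc2) / bc1
        decrement = _k.adam_update(
            self._m, self._v, g, b1, b2, step_scale, self.eps * np.sqrt(bc2)
        )
        for k in self._order:
            p = self.params[k]
            lo, hi, shape = self._slices[k]
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= decrement[lo:hi].reshape(shape)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class SGD:
    """Plain (optionally momentum) stochastic gradient descent."""

    def __init__(self, params: dict[str, Tensor], lr: float, momentum: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        if self.lr == 0.0:
            return
        for name, p in self.params.items():
            if p.grad is None:
                continue
            if self.momentum:
                v = self._v[name]
                v *= self.momentum
                v += p.grad
                p.data = p.data - self.lr * v
            else:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def make_optimizer(name: str, params: dict[str, Tensor], lr: float, **kwargs):
    name = name.lower()
    if name == "adamw":
        return AdamW(params, lr=lr, **kwargs)
    if name == "sgd":
        return SGD(params, lr=lr, **kwargs)
    raise ValueError(f"unknown optimizer {name!r}; choose 'adamw' or 'sgd'")
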