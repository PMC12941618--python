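"""Neural-network building blocks and the Adam optimizer.

Thin module system over :mod:`cgad.autodiff`: layers own parameter
:class:`~cgad.autodiff.Tensor` objects, ``Module.parameters()`` walks the
attribute tree, and state dicts are plain name->array mappings so model
state can be saved as ``.npz``.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "Identity",
    "Adam",
    "log_softmax",
    "softmax_np",
    "cosine_lr",
]


class Module:
    """Base class; submodules and parameters are discovered by attribute walk."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Linear(Module):
    """Dense layer. ``init`` selects He-normal ("he"), small-normal ("small",
    sd 0.01, for score heads whose outputs seed the diffusion state) or
    all-zero ("zero", for heads that must start neutral: the auxiliary
    classifier, so initial confidence is exactly 1/K, and the denoiser
    output)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, init: str = "he"):
        if init == "he":
            scale = math.sqrt(2.0 / n_in)
            w = rng.normal(0.0, scale, size=(n_in, n_out))
        elif init == "small":
            w = rng.normal(0.0, 0.01, size=(n_in, n_out))
        elif init == "zero":
            w = np.zeros((n_in, n_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """Same-padded stride-1 convolution; He-normal init, zero bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dilation: int = 1):
        scale = math.sqrt(2.0 / (c_in * kernel * kernel))
        self.w = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, dilation=self.dilation)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most max_norm."""
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad**2).sum())
        norm = math.sqrt(total)
        if norm > max_norm > 0:
            scale = max_norm / norm
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return norm


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (max-shift treated as a constant)."""
    shift = logits.data.max(axis=axis, keepdims=True)
    z = logits - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax_np(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from lr0 to 0 over the run."""
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * epoch / max(total_epochs, 1)))
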