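"""Conditional noise-prediction network for label-space diffusion.

Predicts the injected Gaussian noise from the noisy class-score vector y_t,
the diffusion step t (sinusoidal embedding), the image latent rho(x), and a
guidance vector (the sum of the prior branches, or a single branch for the
multi-view paths). The image latent passes through a small encoder–decoder
with a skip connection; all conditioning signals are concatenated and mixed
by a residual multilayer head. One shared network serves the main target
branch and the per-prior branches — they differ only in the guidance input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import Linear, Module

__all__ = ["DenoiserConfig", "sinusoidal_embedding", "ConditionalDenoiser"]


@dataclass
class DenoiserConfig:
    n_classes: int = 2
    latent_dim: int = 32
    width: int = 128
    depth: int = 3
    time_dim: int = 64


def sinusoidal_embedding(t, dim: int) -> np.ndarray:
    """Standard sinusoidal position embedding of integer steps.

    Interleaves sin and cos at geometrically spaced frequencies; injective
    over any practical step range. Returns (N, dim) for array input.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t_arr[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:  # odd dim: pad a zero column
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb


class ConditionalDenoiser(Module):
    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        self.config = config
        K, D, W = config.n_classes, config.latent_dim, config.width
        # encoder-decoder over the conditioning latent, with a skip connection
        self.enc1 = Linear(D, W, rng)
        self.enc2 = Linear(W, W // 2, rng)
        self.dec = Linear(W // 2, W, rng)
        self.merge = Linear(2 * K + W + config.time_dim, W, rng)
        self.hidden = [Linear(W, W, rng) for _ in range(config.depth)]
        self.out = Linear(W, K, rng, init="zero")

    def _condition(self, rho_x: Tensor) -> Tensor:
        e1 = self.enc1(rho_x).relu()
        e2 = self.enc2(e1).relu()
        return (self.dec(e2) + e1).relu()

    def forward(self, y_t, t, rho_x, guidance) -> Tensor:
        yt = y_t if isinstance(y_t, Tensor) else Tensor(np.atleast_2d(y_t))
        if yt.ndim == 1:
            yt = yt.reshape(1, -1)
        g = guidance if isinstance(guidance, Tensor) else Tensor(np.atleast_2d(guidance))
        if g.ndim == 1:
            g = g.reshape(1, -1)
        rho = rho_x if isinstance(rho_x, Tensor) else Tensor(np.atleast_2d(rho_x))
        if rho.ndim == 1:
            rho = rho.reshape(1, -1)
        K = self.config.n_classes
        if yt.shape[-1] != K or g.shape[-1] != K:
            raise ValueError(
                f"state/guidance length mismatch: got {yt.shape[-1]}/{g.shape[-1]}, expected K={K}"
            )
        n = max(yt.shape[0], rho.shape[0], g.shape[0])
        t_arr = np.asarray(t)
        if t_arr.ndim == 0:
            t_arr = np.full(n, int(t_arr))
        temb = Tensor(sinusoidal_embedding(t_arr, self.config.time_dim))
        cond = self._condition(rho)

        def _tile(m: Tensor) -> Tensor:
            return m if m.shape[0] == n else m + Tensor(np.zeros((n, 1)))

        h = self.merge(concat([_tile(yt), _tile(g), _tile(cond), temb], axis=1)).relu()
        for layer in self.hidden:
            h = (layer(h).relu() + h)
        return self.out(h)

    def as_numpy_fn(self):
        """Gradient-free callable (y_t, t, rho_x, guidance) -> ndarray for sampling."""

        def fn(y_t, t, rho_x, guidance):
            out = self.forward(
                np.atleast_2d(np.asarray(y_t, dtype=np.float64)),
                t,
                np.atleast_2d(np.asarray(rho_x, dtype=np.float64)),
                np.atleast_2d(np.asarray(guidance, dtype=np.float64)),
            ).data
            return out[0] if np.asarray(y_t).ndim == 1 else out

        return fn
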