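"""Confidence-guided label-space diffusion.

The classifier's target lives in class-score space: a clean K-vector y0
(one-hot during training) is corrupted by a forward Markov chain and
recovered by a learned reverse chain. The departure from a textbook DDPM is
confidence-guided adaptive noise injection (CG-ANI): the Gaussian noise term
is scaled per sample by (1 - c), where c is the classifier's maximum softmax
probability, and a prior-derived guidance vector G shifts the state,

    y_t = sqrt(abar_t) * y0 + sqrt(1 - abar_t) * (1 - c) * eps + (1 - abar_t) * G.

Low-confidence samples are perturbed strongly (exploration), high-confidence
samples barely at all; at c = 1 the chain is noiseless. The clean-state
estimator algebraically inverts this forward map, and the reverse transition
applies the standard DDPM posterior to the guidance-shifted variable
z_t = y_t - (1 - abar_t) * G, shifting back by (1 - abar_{t-1}) * G — the
unique construction under which a noiseless chain is consistent with the
forward marginals.

All functions accept plain numpy arrays or autodiff Tensors (training flows
gradients through y0, eps and guidance; c is always a detached scalar) and
scalar or per-sample-vector step indices / confidences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "NoiseSchedule",
    "build_schedule",
    "confidence",
    "forward_diffuse",
    "perturb_interpolated",
    "estimate_clean",
    "posterior_step",
    "reverse_sample",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step rates beta_t, cumulative products abar_t and posterior variances.

    Arrays are indexed 0-based for steps t = 1..T. The convention abar_0 = 1
    makes the t = 1 posterior degenerate (posterior_var[0] == 0).
    """

    T: int
    beta: np.ndarray
    alpha_bar: np.ndarray
    posterior_var: np.ndarray

    def abar(self, t):
        """abar_t for scalar or integer-array t in [1, T]."""
        return self.alpha_bar[np.asarray(t) - 1]

    def abar_prev(self, t):
        """abar_{t-1} with abar_0 = 1."""
        t = np.asarray(t)
        return np.where(t > 1, self.alpha_bar[np.maximum(t - 2, 0)], 1.0)


def build_schedule(
    T: int, beta_start: float = 1e-4, beta_end: float = 0.02, kind: str = "linear"
) -> NoiseSchedule:
    """Construct a linear noise schedule of T steps.

    beta interpolates beta_start -> beta_end; abar_t is the running product
    of (1 - beta_s); the posterior variance is
    beta_tilde_t = (1 - abar_{t-1}) / (1 - abar_t) * beta_t with abar_0 = 1.
    """
    if not (isinstance(T, (int, np.integer)) and T >= 1):
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    beta = np.linspace(beta_start, beta_end, T)
    alpha_bar = np.cumprod(1.0 - beta)
    abar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    posterior_var = (1.0 - abar_prev) / (1.0 - alpha_bar) * beta
    return NoiseSchedule(T=int(T), beta=beta, alpha_bar=alpha_bar, posterior_var=posterior_var)


def confidence(probs) -> float | np.ndarray:
    """Maximum posterior probability of a softmax output.

    The returned value is a plain float (or float array for a batch): using
    it to modulate noise cannot leak gradient back into the classifier —
    detachment is by construction.
    """
    p = probs.data if isinstance(probs, Tensor) else np.asarray(probs, dtype=np.float64)
    if p.ndim not in (1, 2):
        raise ValueError("probs must be a vector or a batch of vectors")
    if p.shape[-1] < 2:
        raise ValueError("need at least two classes")
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be nonnegative")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probabilities must sum to 1 (tolerance 1e-6)")
    c = p.max(axis=-1)
    return float(c) if p.ndim == 1 else c


def _check_t(t, T: int) -> None:
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > T):
        raise ValueError(f"step index t={t} outside [1, {T}]")


def _col(x, ref):
    """Reshape a per-sample scalar array to broadcast over (N, K) states."""
    arr = np.asarray(x, dtype=np.float64)
    ref_ndim = ref.data.ndim if isinstance(ref, Tensor) else np.asarray(ref).ndim
    if arr.ndim == 1 and ref_ndim == 2:
        return arr[:, None]
    return arr


def _check_len(name_a, a, name_b, b) -> None:
    ka = (a.data if isinstance(a, Tensor) else np.asarray(a)).shape[-1]
    kb = (b.data if isinstance(b, Tensor) else np.asarray(b)).shape[-1]
    if ka != kb:
        raise ValueError(f"length mismatch: {name_a} has K={ka}, {name_b} has K={kb}")


def forward_diffuse(y0, t, c, eps, guidance, schedule: NoiseSchedule):
    """Forward corruption at step t with confidence-scaled noise.

    y_t = sqrt(abar_t)*y0 + sqrt(1-abar_t)*(1-c)*eps + (1-abar_t)*guidance.
    """
    _check_t(t, schedule.T)
    _check_len("y0", y0, "eps", eps)
    _check_len("y0", y0, "guidance", guidance)
    abar = _col(schedule.abar(t), y0)
    cc = _col(c, y0)
    return (
        np.sqrt(abar) * y0
        + np.sqrt(1.0 - abar) * (1.0 - cc) * eps
        + (1.0 - abar) * guidance
    )


def perturb_interpolated(y_pred, y0, t_norm: float, c, eps):
    """Simplified confidence-guided perturbation on a normalized time axis.

    y_t = t*y_pred + (1-t)*y0 + (1-c)*eps, t in [0, 1]. A pedagogical
    single-shot form of the adaptive injection; the training loop uses
    :func:`forward_diffuse`.
    """
    t_arr = np.asarray(t_norm, dtype=np.float64)
    if np.any(t_arr < 0.0) or np.any(t_arr > 1.0):
        raise ValueError(f"t_norm={t_norm} outside [0, 1]")
    _check_len("y_pred", y_pred, "y0", y0)
    tt = _col(t_arr, y0)
    cc = _col(c, y0)
    return tt * y_pred + (1.0 - tt) * y0 + (1.0 - cc) * eps


def estimate_clean(y_t, t, c, eps_pred, guidance, schedule: NoiseSchedule):
    """Invert the forward map given a noise prediction.

    y0_hat = (y_t - (1-abar_t)*guidance - (1-c)*sqrt(1-abar_t)*eps_pred)
             / sqrt(abar_t).

    With eps_pred equal to the injected noise and matching guidance this is
    the exact algebraic inverse of :func:`forward_diffuse`. The (1-c) factor
    adaptively modulates denoising strength exactly as it modulated
    injection.
    """
    _check_t(t, schedule.T)
    _check_len("y_t", y_t, "eps_pred", eps_pred)
    _check_len("y_t", y_t, "guidance", guidance)
    abar = _col(schedule.abar(t), y_t)
    cc = _col(c, y_t)
    return (
        y_t - (1.0 - abar) * guidance - (1.0 - cc) * np.sqrt(1.0 - abar) * eps_pred
    ) / np.sqrt(abar)


def posterior_step(y0_hat, y_t, t, guidance, noise, schedule: NoiseSchedule):
    """One reverse transition y_t -> y_{t-1}.

    The Bayesian posterior mean of the guidance-shifted state
    z_t = y_t - (1-abar_t)*guidance under the standard DDPM posterior
    q(z_{t-1} | z_t, z_0 = y0_hat), shifted back by (1-abar_{t-1})*guidance,
    plus sqrt(beta_tilde_t) * noise. At t = 1 the posterior is degenerate and
    the step returns y0_hat exactly.
    """
    _check_t(t, schedule.T)
    _check_len("y0_hat", y0_hat, "y_t", y_t)
    t_arr = np.asarray(t)
    beta = _col(schedule.beta[t_arr - 1], y_t)
    abar = _col(schedule.abar(t), y_t)
    abar_prev = _col(schedule.abar_prev(t), y_t)
    alpha = 1.0 - beta
    coef_clean = np.sqrt(abar_prev) * beta / (1.0 - abar)
    coef_state = np.sqrt(alpha) * (1.0 - abar_prev) / (1.0 - abar)
    pvar = _col(schedule.posterior_var[t_arr - 1], y_t)
    mu = (
        coef_clean * y0_hat
        + coef_state * (y_t - (1.0 - abar) * guidance)
        + (1.0 - abar_prev) * guidance
    )
    return mu + np.sqrt(pvar) * noise


def reverse_sample(
    rho_x,
    guidance,
    denoiser,
    classifier_probs,
    schedule: NoiseSchedule,
    seed: int,
    y_init=None,
    return_trajectory: bool = False,
):
    """Run the full reverse chain and return the final clean estimate.

    The confidence is computed from ``classifier_probs`` only — no
    ground-truth access at inference. ``denoiser`` maps
    (y_t, t, rho_x, guidance) -> predicted noise. The chain starts from the
    guidance-centred terminal marginal
    y_T ~ N((1-abar_T)*G, (1-abar_T)*(1-c)^2 I) unless ``y_init`` is given.

    Supports a single sample (1-D guidance) or a batch (2-D); deterministic
    given ``seed``.

    Returns ``(y0_hat_final, trajectory)`` where ``trajectory`` is the
    stacked sequence [y_T, y_{T-1}, ..., y_1, y0_hat] when requested, else
    ``None``.
    """
    g = np.asarray(guidance, dtype=np.float64)
    single = g.ndim == 1
    if single:
        g = g[None, :]
    n, K = g.shape
    probs = np.asarray(classifier_probs, dtype=np.float64)
    if single and probs.ndim == 1:
        probs = probs[None, :]
    c = np.atleast_1d(confidence(probs))[:, None]
    rng = np.random.default_rng(seed)
    T = schedule.T
    abar_T = schedule.alpha_bar[-1]
    if y_init is None:
        y_t = (1.0 - abar_T) * g + math.sqrt(1.0 - abar_T) * (1.0 - c) * rng.standard_normal(
            (n, K)
        )
    else:
        y_t = np.array(y_init, dtype=np.float64, copy=True)
        if single and y_t.ndim == 1:
            y_t = y_t[None, :]
    traj = [y_t.copy()] if return_trajectory else None
    y0_hat = y_t
    for t in range(T, 0, -1):
        eps_pred = np.asarray(denoiser(y_t, t, rho_x, g[0] if single else g), dtype=np.float64)
        if single and eps_pred.ndim == 1:
            eps_pred = eps_pred[None, :]
        if eps_pred.shape[-1] != K:
            raise ValueError(
                f"denoiser returned length {eps_pred.shape[-1]}, expected K={K}"
            )
        y0_hat = estimate_clean(y_t, t, c, eps_pred, g, schedule)
        # confidence also regulates sampling stochasticity: high-confidence
        # samples take a near-deterministic reverse path
        noise = (1.0 - c) * rng.standard_normal((n, K)) if t > 1 else np.zeros((n, K))
        y_t = posterior_step(y0_hat, y_t, t, g, noise, schedule)
        if return_trajectory:
            traj.append(y_t.copy())
    y0_final = np.asarray(y0_hat)
    if return_trajectory:
        trajectory = np.stack(traj)
        if single:
            trajectory = trajectory[:, 0, :]
    else:
        trajectory = None
    if single:
        y0_final = y0_final[0]
    return y0_final, trajectory
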