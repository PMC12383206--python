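"""Shared diffusion machinery: noise schedules, the forward (noising) process,
the simplified noise-matching loss, classifier-free guidance combination, and
the ancestral (DDPM) and accelerated (DDIM) reverse samplers.

Conventions
-----------
Timesteps run t = 1..T with ᾱ_0 ≡ 1 (clean data).  The forward marginal is

    y_t = √ᾱ_t · y_0 + √(1 − ᾱ_t) · ε,      ε ~ N(0, I),

with ᾱ_t = ∏_{i≤t} α_i and α_t = 1 − β_t.  The reverse ancestral update is

    y_{t−1} = (1/√α_t) · (y_t − (1−α_t)/√(1−ᾱ_t) · ε̂) + σ_t · z,

with σ_1 = 0 so the final step is deterministic.  Schedule arithmetic is done
in float64; network tensors are float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule {α_t} with derived running products and noise scales.

    ``alphas``, ``alpha_bars`` and ``sigmas`` are indexed 0..T-1 for steps
    1..T; use :meth:`alpha`, :meth:`alpha_bar` and :meth:`sigma` for 1-based
    access.  ``alpha_bar(0)`` returns 1 by convention.
    """

    T: int
    alphas: np.ndarray
    alpha_bars: np.ndarray
    sigmas: np.ndarray
    sigma_kind: str = "beta"

    def __post_init__(self):
        a = np.asarray(self.alphas, dtype=np.float64)
        if a.ndim != 1 or len(a) != self.T:
            raise ValueError("alphas must be a length-T vector")
        if np.any(a <= 0) or np.any(a >= 1):
            raise ValueError("all alphas must lie in (0, 1)")
        ab = np.asarray(self.alpha_bars, dtype=np.float64)
        if np.any(np.diff(ab) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")

    def alpha(self, t: int) -> float:
        self._check_t(t)
        return float(self.alphas[t - 1])

    def alpha_bar(self, t: int) -> float:
        if t == 0:
            return 1.0
        self._check_t(t)
        return float(self.alpha_bars[t - 1])

    def sigma(self, t: int) -> float:
        self._check_t(t)
        if t == 1:
            return 0.0  # deterministic final reverse step
        return float(self.sigmas[t - 1])

    def _check_t(self, t: int):
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep {t} out of range 1..{self.T}")

    def to_dict(self) -> dict:
        return {"T": self.T, "kind": "linear", "sigma_kind": self.sigma_kind,
                "beta_start": float(1.0 - self.alphas[0]),
                "beta_end": float(1.0 - self.alphas[-1])}


def make_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                  kind: str = "linear", sigma_kind: str = "beta") -> NoiseSchedule:
    """Build a linear β schedule: β_t interpolated from beta_start to beta_end.

    ``sigma_kind`` selects the fixed reverse-process noise scale: ``"beta"``
    uses σ_t² = β_t, ``"posterior"`` uses the Markov posterior variance
    σ̃_t² = (1−ᾱ_{t−1})/(1−ᾱ_t)·β_t (the choice under which a full-length
    η=1 DDIM trajectory coincides with ancestral sampling).
    """
    if kind != "linear":
        raise ValueError(f"unknown schedule kind: {kind!r}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 <= beta_start <= beta_end < 1):
        raise ValueError("need 0 <= beta_start <= beta_end < 1")
    betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    # clip the degenerate beta=0 endpoint so alphas stay inside (0, 1)
    betas = np.clip(betas, 1e-12, 1 - 1e-12)
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    if sigma_kind == "beta":
        sigmas = np.sqrt(betas)
    elif sigma_kind == "posterior":
        ab_prev = np.concatenate([[1.0], alpha_bars[:-1]])
        sigmas = np.sqrt((1.0 - ab_prev) / (1.0 - alpha_bars) * betas)
    else:
        raise ValueError(f"unknown sigma_kind: {sigma_kind!r}")
    return NoiseSchedule(T=T, alphas=alphas, alpha_bars=alpha_bars,
                         sigmas=sigmas, sigma_kind=sigma_kind)


def scaled_schedule(T: int, reference_T: int = 1000, beta_start: float = 1e-4,
                    beta_end: float = 0.02, sigma_kind: str = "beta") -> NoiseSchedule:
    """Linear schedule for a shortened chain with the reference terminal noise.

    The (1e−4, 0.02) β range is tuned for T=1000; used verbatim at smaller T
    the chain never reaches the noise prior (ᾱ_T stays far from 0) and
    samples drawn from N(0, I) are off-distribution.  Scaling both endpoints
    by reference_T/T preserves Σβ_t and hence ᾱ_T.  For T = reference_T this
    is exactly the reference schedule.
    """
    s = reference_T / T
    return make_schedule(T, beta_start=beta_start * s, beta_end=beta_end * s,
                         sigma_kind=sigma_kind)


def schedule_from_alphas(alphas: Sequence[float], sigma_kind: str = "beta") -> NoiseSchedule:
    """Build a schedule directly from per-step α values (mainly for tests)."""
    alphas = np.asarray(alphas, dtype=np.float64)
    alpha_bars = np.cumprod(alphas)
    betas = 1.0 - alphas
    if sigma_kind == "posterior":
        ab_prev = np.concatenate([[1.0], alpha_bars[:-1]])
        sigmas = np.sqrt((1.0 - ab_prev) / (1.0 - alpha_bars) * betas)
    else:
        sigmas = np.sqrt(betas)
    return NoiseSchedule(T=len(alphas), alphas=alphas, alpha_bars=alpha_bars,
                         sigmas=sigmas, sigma_kind=sigma_kind)


# -- forward process ---------------------------------------------------------

def forward_diffuse(y0: np.ndarray, t: int, eps: np.ndarray, sched: NoiseSchedule) -> np.ndarray:
    """Closed-form jump to step t: y_t = √ᾱ_t·y_0 + √(1−ᾱ_t)·ε."""
    y0 = np.asarray(y0)
    eps = np.asarray(eps)
    try:
        np.broadcast_shapes(eps.shape, y0.shape)
    except ValueError:
        raise ValueError(f"eps shape {eps.shape} incompatible with data shape {y0.shape}")
    ab = sched.alpha_bar(t)
    return np.sqrt(ab) * y0 + np.sqrt(1.0 - ab) * eps


def diffuse_batch(y0: np.ndarray, t: np.ndarray, eps: np.ndarray,
                  sched: NoiseSchedule) -> np.ndarray:
    """Vectorised forward_diffuse with a per-example timestep vector."""
    t = np.asarray(t)
    ab = sched.alpha_bars[t - 1].reshape((-1,) + (1,) * (y0.ndim - 1))
    return (np.sqrt(ab) * y0 + np.sqrt(1.0 - ab) * eps).astype(np.float32)


def iterate_forward(y0: np.ndarray, t: int, eps_sequence: Sequence[np.ndarray],
                    sched: NoiseSchedule) -> np.ndarray:
    """Stepwise Markov form: y_i = √α_i·y_{i−1} + √(1−α_i)·ε_{i−1}, i = 1..t."""
    if len(eps_sequence) != t:
        raise ValueError(f"need {t} noise tensors, got {len(eps_sequence)}")
    y = np.asarray(y0, dtype=np.float64)
    for i in range(1, t + 1):
        a = sched.alpha(i)
        y = np.sqrt(a) * y + np.sqrt(1.0 - a) * np.asarray(eps_sequence[i - 1])
    return y


def predict_x0(y_t: np.ndarray, eps_hat: np.ndarray, t: int, sched: NoiseSchedule) -> np.ndarray:
    """Invert the forward marginal: x̂_0 = (y_t − √(1−ᾱ_t)·ε̂) / √ᾱ_t."""
    ab = sched.alpha_bar(t)
    if ab <= 0:
        raise ValueError("alpha_bar(t) must be positive")
    return (np.asarray(y_t) - np.sqrt(1.0 - ab) * np.asarray(eps_hat)) / np.sqrt(ab)


# -- losses and guidance -----------------------------------------------------

def simple_loss(eps, eps_hat):
    """Mean squared error between true and predicted noise (mean reduction).

    Accepts numpy arrays (returns a float) or autograd Tensors (returns a
    scalar Tensor suitable for backward).
    """
    from .nn import autograd as ag
    if isinstance(eps, ag.Tensor) or isinstance(eps_hat, ag.Tensor):
        eps_t = ag.as_tensor(eps)
        hat_t = ag.as_tensor(eps_hat)
        if eps_t.shape != hat_t.shape:
            raise ValueError(f"shape mismatch: {eps_t.shape} vs {hat_t.shape}")
        d = hat_t - eps_t
        return ag.tmean(d * d)
    eps = np.asarray(eps)
    eps_hat = np.asarray(eps_hat)
    if eps.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch: {eps.shape} vs {eps_hat.shape}")
    return float(np.mean((eps_hat - eps) ** 2))


def cfg_combine(eps_uncond: np.ndarray, eps_cond: np.ndarray, w: float) -> np.ndarray:
    """Classifier-free guidance: ε = ε_u + w·(ε_c − ε_u)."""
    eps_uncond = np.asarray(eps_uncond)
    eps_cond = np.asarray(eps_cond)
    if eps_uncond.shape != eps_cond.shape:
        raise ValueError("guidance inputs must share shape")
    if w < 0:
        raise ValueError("guidance weight must be >= 0")
    return eps_uncond + w * (eps_cond - eps_uncond)


# -- reverse samplers --------------------------------------------------------

def ddpm_step(y_t: np.ndarray, eps_hat: np.ndarray, t: int, z: np.ndarray,
              sched: NoiseSchedule) -> np.ndarray:
    """One ancestral reverse step; σ_1 = 0 makes the last step deterministic."""
    y_t = np.asarray(y_t)
    z = np.asarray(z)
    if z.shape != y_t.shape:
        raise ValueError("noise shape mismatch")
    a = sched.alpha(t)
    ab = sched.alpha_bar(t)
    mean = (y_t - (1.0 - a) / np.sqrt(1.0 - ab) * np.asarray(eps_hat)) / np.sqrt(a)
    return mean + sched.sigma(t) * z


def ddim_timesteps(T: int, n_steps: int) -> np.ndarray:
    """Evenly spaced decreasing timestep subsequence from T down to 1."""
    if not 1 <= n_steps <= T:
        raise ValueError(f"n_steps must be in 1..{T}")
    ts = np.unique(np.round(np.linspace(T, 1, n_steps)).astype(int))[::-1]
    return ts


def ddim_step(y_t: np.ndarray, eps_hat: np.ndarray, t: int, t_prev: int,
              eta: float, z: np.ndarray, sched: NoiseSchedule,
              clip_x0: Optional[float] = None) -> np.ndarray:
    """One DDIM update from step t to t_prev (t_prev < t, 0 means clean).

    ``clip_x0`` bounds the intermediate clean-data estimate to ±clip_x0, the
    usual stabilisation when the data range is known (e.g. ±1 mask encodings);
    the noise direction is recomputed from the clipped estimate.
    """
    ab_t = sched.alpha_bar(t)
    ab_prev = sched.alpha_bar(t_prev)
    x0 = (y_t - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
    if clip_x0 is not None:
        x0 = np.clip(x0, -clip_x0, clip_x0)
        eps_hat = (y_t - np.sqrt(ab_t) * x0) / np.sqrt(1.0 - ab_t)
    sigma = eta * np.sqrt((1.0 - ab_prev) / (1.0 - ab_t)) * np.sqrt(max(0.0, 1.0 - ab_t / ab_prev))
    dir_coeff = np.sqrt(max(0.0, 1.0 - ab_prev - sigma ** 2))
    return np.sqrt(ab_prev) * x0 + dir_coeff * eps_hat + sigma * z


DenoiserFn = Callable[..., np.ndarray]


def _call_denoiser(denoiser, y, t_vec, condition):
    from .nn import autograd as ag
    with ag.no_grad():
        if condition is None:
            out = denoiser(y, t_vec)
        else:
            out = denoiser(y, t_vec, condition)
    return out.numpy() if isinstance(out, ag.Tensor) else np.asarray(out)


def ddim_sample(denoiser: DenoiserFn, sched: NoiseSchedule, n_steps: int,
                eta: float, shape: tuple, seed: int,
                condition: Optional[np.ndarray] = None,
                guidance_w: Optional[float] = None,
                null_condition: Optional[np.ndarray] = None,
                noise_sequence: Optional[list[np.ndarray]] = None,
                init_noise: Optional[np.ndarray] = None,
                clip_x0: Optional[float] = None) -> np.ndarray:
    """Run the DDIM sampler over an evenly spaced timestep subsequence.

    With ``eta=0`` the trajectory is a deterministic function of the initial
    noise, the condition and the denoiser parameters.  ``guidance_w`` enables
    classifier-free guidance (two denoiser calls per step) using
    ``null_condition`` as the unconditional input.
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(shape).astype(np.float32) if init_noise is None else np.asarray(init_noise, dtype=np.float32)
    ts = ddim_timesteps(sched.T, n_steps)
    for i, t in enumerate(ts):
        t_prev = int(ts[i + 1]) if i + 1 < len(ts) else 0
        t_vec = np.full(shape[0], t, dtype=np.int64)
        if guidance_w is not None and condition is not None:
            eps_c = _call_denoiser(denoiser, y, t_vec, condition)
            eps_u = _call_denoiser(denoiser, y, t_vec, null_condition)
            eps_hat = cfg_combine(eps_u, eps_c, guidance_w)
        else:
            eps_hat = _call_denoiser(denoiser, y, t_vec, condition)
        if eta > 0:
            if noise_sequence is not None:
                z = np.asarray(noise_sequence[i])
            else:
                z = rng.standard_normal(shape).astype(np.float32)
        else:
            z = np.zeros(shape, dtype=np.float32)
        if t_prev == 0:  # final step: deterministic projection to x0
            ab_t = sched.alpha_bar(int(t))
            x0 = (y - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
            if clip_x0 is not None:
                x0 = np.clip(x0, -clip_x0, clip_x0)
            y = x0.astype(np.float32)
        else:
            y = ddim_step(y, eps_hat, int(t), t_prev, eta, z, sched,
                          clip_x0=clip_x0).astype(np.float32)
    return y


def ddpm_sample(denoiser: DenoiserFn, sched: NoiseSchedule, shape: tuple, seed: int,
                condition: Optional[np.ndarray] = None,
                guidance_w: Optional[float] = None,
                null_condition: Optional[np.ndarray] = None,
                clip_x0: Optional[float] = None) -> np.ndarray:
    """Full-length ancestral sampling (T reverse steps).

    With ``clip_x0`` the noise prediction is re-derived from the clipped
    clean-data estimate before the ancestral update (clip-denoised sampling).
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(shape).astype(np.float32)
    for t in range(sched.T, 0, -1):
        t_vec = np.full(shape[0], t, dtype=np.int64)
        if guidance_w is not None and condition is not None:
            eps_c = _call_denoiser(denoiser, y, t_vec, condition)
            eps_u = _call_denoiser(denoiser, y, t_vec, null_condition)
            eps_hat = cfg_combine(eps_u, eps_c, guidance_w)
        else:
            eps_hat = _call_denoiser(denoiser, y, t_vec, condition)
        if clip_x0 is not None:
            ab = sched.alpha_bar(t)
            x0 = np.clip(predict_x0(y, eps_hat, t, sched), -clip_x0, clip_x0)
            eps_hat = (y - np.sqrt(ab) * x0) / np.sqrt(1.0 - ab)
        z = rng.standard_normal(shape).astype(np.float32) if t > 1 else np.zeros(shape, dtype=np.float32)
        y = ddpm_step(y, eps_hat, t, z, sched).astype(np.float32)
    return y
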