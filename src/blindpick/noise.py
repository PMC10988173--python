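"""Closed-form Bayesian denoising machinery.

Each pixel's clean signal x is given a univariate Gaussian prior
N(mu_x, sigma_x^2) predicted from the blind-spot context, and the observation
y = x + n carries zero-mean Gaussian noise of per-pixel std sigma_n — either
directly (Gaussian model) or with a signal-dependent variance
sigma_n^2 = a * max(mu_x, eps) that approximates Poisson shot noise with
gain a.  Because everything is Gaussian the marginal of y and the posterior
of x are available in closed form:

    -log p(y) = 1/2 log v + (y - mu_x)^2 / (2 v) + const,   v = sigma_x^2 + sigma_n^2
    E[x | y]  = (y * sigma_x^2 + mu_x * sigma_n^2) / v

The additive constant of the marginal is dropped from all reported losses.
Functions accept either plain numpy arrays or autodiff Tensors and preserve
the type, so the same code serves training (with gradients) and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from . import autodiff as ad

__all__ = ["PriorStats", "NoiseParams", "POSITIVITY_FLOOR",
           "marginal_nll", "posterior_mean", "poisson_sigma", "noise_variance"]

#: Floor added after the softplus positivity map for sigma_x, sigma_n and gain.
POSITIVITY_FLOOR = 1e-4


@dataclass
class PriorStats:
    """Per-pixel Gaussian prior of the clean signal: mean and std (std > 0)."""
    mu: Any
    sigma: Any


@dataclass
class NoiseParams:
    """Noise model: per-pixel std (gaussian) or gain a with var = a*signal."""
    kind: str                     # "gaussian" | "poisson_approx"
    sigma_n: Any = None
    gain: Any = None
    floor: float = POSITIVITY_FLOOR

    def __post_init__(self):
        if self.kind not in ("gaussian", "poisson_approx"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma_n is None:
            raise ValueError("gaussian noise requires sigma_n")
        if self.kind == "poisson_approx" and self.gain is None:
            raise ValueError("poisson_approx noise requires gain")


def _data(x):
    return x.data if isinstance(x, ad.Tensor) else np.asarray(x)


def poisson_sigma(prior_mu, gain, floor: float = POSITIVITY_FLOOR):
    """Signal-dependent noise std sqrt(gain * max(mu, floor)); gain > 0."""
    if np.any(_data(gain) <= 0):
        raise ValueError("gain must be positive")
    return ad.sqrt(gain * ad.maximum(prior_mu, floor))


def noise_variance(prior: PriorStats, noise: NoiseParams):
    """Per-pixel noise variance sigma_n^2 under either model."""
    if noise.kind == "gaussian":
        return noise.sigma_n * noise.sigma_n
    # Poisson-like: the predicted prior mean is the clean-signal surrogate
    return noise.gain * ad.maximum(prior.mu, noise.floor)


def _check(y, prior: PriorStats):
    yd, md = _data(y), _data(prior.mu)
    if yd.shape != md.shape:
        raise ValueError(f"shape mismatch: y {yd.shape} vs mu {md.shape}")
    if not (np.isfinite(yd).all() and np.isfinite(md).all()
            and np.isfinite(_data(prior.sigma)).all()):
        raise ValueError("non-finite inputs")


def marginal_nll(y, prior: PriorStats, noise: NoiseParams):
    """Per-pixel negative log marginal likelihood of the noisy observation.

    0.5*log(v) + (y - mu)^2 / (2 v) with v = sigma_x^2 + sigma_n^2; the
    constant term is dropped.  Mean over pixels is the denoising loss.
    """
    _check(y, prior)
    v = prior.sigma * prior.sigma + noise_variance(prior, noise)
    if np.any(_data(v) <= 0):
        raise ValueError("total variance must be positive")
    r = y - prior.mu
    return 0.5 * ad.log(v) + (r * r) / (2.0 * v)


def posterior_mean(y, prior: PriorStats, noise: NoiseParams):
    """Bayes-optimal denoised value E[x | y] (convex combination of y and mu)."""
    _check(y, prior)
    sx2 = prior.sigma * prior.sigma
    sn2 = noise_variance(prior, noise)
    return (y * sx2 + prior.mu * sn2) / (sx2 + sn2)
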