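"""Positive-unlabeled detection supervision.

Particle centers are supervised as a keypoint heatmap: each annotated center
is splatted as a Gaussian bump (value exactly 1 at the center, overlaps
resolved by max), and the detector output is a per-pixel probability of
"center here".  With only a sparse positive set annotated, the remaining
pixels are unlabeled rather than negative, so the training signal has two
parts:

* a penalty-reduced focal term on the annotated centers, weighted by the
  class prior pi (the probability that a random pixel belongs to a particle);
* a generalized-expectation (GE) term asking the *count* of predicted
  positives among K randomly subsampled unlabeled pixels to be distributed
  like Binomial(K, pi).  The count distribution induced by per-pixel
  probabilities is Poisson-binomial; we provide both the exact O(K^2)
  dynamic program (KL divergence against the binomial prior) and a cheap
  moment-matching surrogate used during optimization.

Pixels under a labeled splat are known positives and are excluded from the
unlabeled pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.stats import binom

from . import autodiff as ad

__all__ = ["HeatmapPair", "PUConfig", "splat_heatmap", "labeled_support",
           "focal_loss", "poisson_binomial_pmf", "binomial_pmf",
           "ge_binomial_loss", "pu_detection_loss"]

PRED_EPS = 1e-7          # probability clipping for the focal log terms
PMF_EPS = 1e-12          # pmf clipping inside the KL
#: splat values below this are treated as outside the labeled support (3-sigma)
SUPPORT_LEVEL = float(np.exp(-4.5))


@dataclass
class PUConfig:
    """Class prior and loss hyperparameters.

    alpha/beta are the penalty-reduced focal exponents; K is the number of
    unlabeled pixels subsampled per step for the GE-binomial term.
    """
    pi: float
    alpha: float = 2.0
    beta: float = 4.0
    K: int = 1024
    count_mode: str = "exact_dp"      # or "gaussian_approx"

    def __post_init__(self):
        if not 0.0 < self.pi < 0.5:
            raise ValueError("pi must be in (0, 0.5)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("focal exponents must be >= 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.count_mode not in ("exact_dp", "gaussian_approx"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class HeatmapPair:
    """Splatted ground truth, its labeled support, and the prediction."""
    target: np.ndarray          # Y in [0,1], exactly 1 at annotated centers
    labeled_mask: np.ndarray    # True where a labeled splat was applied
    pred: Any                   # probabilities in (0,1); numpy or Tensor


def splat_heatmap(coords, shape, sigma_p: float) -> np.ndarray:
    """Render centers as Gaussian bumps, combined by pixel-wise max."""
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    rows, cols = shape
    bad = [(r, c) for (r, c) in coords
           if not (0 <= r < rows and 0 <= c < cols)]
    if bad:
        raise ValueError(f"coordinates out of bounds for shape {shape}: {bad}")
    target = np.zeros(shape, dtype=np.float64)
    if not coords:
        return target
    rr, cc = np.mgrid[0:rows, 0:cols]
    for (r, c) in coords:
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        np.maximum(target, np.exp(-d2 / (2.0 * sigma_p ** 2)), out=target)
    return target


def labeled_support(target: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels under any labeled splat (3-sigma support)."""
    return target >= SUPPORT_LEVEL


def focal_loss(pred, target: np.ndarray, alpha: float = 2.0, beta: float = 4.0):
    """Penalty-reduced keypoint focal loss.

    At pixels with Y == 1:  -(1 - p)^alpha * log p
    elsewhere:              -(1 - Y)^beta * p^alpha * log(1 - p)
    summed, normalized by max(1, #{Y == 1}).  Accepts numpy or Tensor pred.
    """
    target = np.asarray(target, dtype=np.float64)
    pd = pred.data if isinstance(pred, ad.Tensor) else np.asarray(pred)
    if pd.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pd.shape} vs target {target.shape}")
    pos = (target == 1.0).astype(np.float64)
    npos = max(1.0, pos.sum())
    p = ad.clip(pred, PRED_EPS, 1.0 - PRED_EPS)
    pos_term = pos * ((1.0 - p) ** alpha) * (-1.0 * ad.log(p))
    neg_term = (1.0 - pos) * ((1.0 - target) ** beta) * (p ** alpha) \
        * (-1.0 * ad.log(1.0 - p))
    total = (pos_term + neg_term).sum()
    return total * (1.0 / npos)


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli(probs).

    O(K^2) dynamic program; returns an array of length K+1 summing to 1.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(pmf.size + 1)
        nxt[:-1] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def binomial_pmf(K: int, pi: float) -> np.ndarray:
    """Binomial(K, pi) pmf over counts 0..K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    return binom.pmf(np.arange(K + 1), K, pi)


def _leave_one_out_pmfs(pb: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """q[i, k] = pmf of the count excluding Bernoulli i (deconvolution).

    pb = q^(i) convolved with (1-p_i, p_i), so q^(i) follows from a linear
    recurrence; the forward recurrence is stable for p_i <= 1/2 and the
    backward one for p_i > 1/2.  Vectorized over i, O(K^2) total.
    """
    K = probs.size
    q = np.zeros((K, K))
    lo = probs <= 0.5
    if lo.any():
        p = probs[lo][:, None]
        ql = np.zeros((int(lo.sum()), K))
        ql[:, 0] = pb[0] / (1.0 - probs[lo])
        for k in range(1, K):
            ql[:, k] = (pb[k] - ql[:, k - 1] * p[:, 0]) / (1.0 - p[:, 0])
        q[lo] = ql
    hi = ~lo
    if hi.any():
        p = probs[hi]
        qh = np.zeros((int(hi.sum()), K))
        qh[:, K - 1] = pb[K] / p
        for k in range(K - 1, 0, -1):
            qh[:, k - 1] = (pb[k] - qh[:, k] * (1.0 - p)) / p
        q[hi] = qh
    return q


def ge_binomial_loss(pred_unlabeled, pi: float, count_mode: str = "exact_dp"):
    """Divergence between predicted-positive counts and Binomial(K, pi).

    exact_dp: KL(Poisson-binomial || Binomial) over counts 0..K via the
    O(K^2) dynamic program, differentiable (analytic leave-one-out gradient)
    when given a Tensor.  The divergence runs empirical-first: a confident
    classifier whose positive rate matches pi then pays only a small,
    entropy-like penalty instead of the exploding prior-first KL.
    gaussian_approx: squared mean gap plus squared variance gap of the two
    count distributions, each normalized by the binomial variance — the
    cheap moment-matching surrogate.  Both are 0 when every prediction
    equals pi.
    """
    is_tensor = isinstance(pred_unlabeled, ad.Tensor)
    pd = (pred_unlabeled.data if is_tensor
          else np.asarray(pred_unlabeled, dtype=np.float64))
    K = pd.size
    if K < 1:
        raise ValueError("need at least one unlabeled prediction")
    if count_mode == "exact_dp":
        probs = np.clip(pd.ravel().astype(np.float64), PRED_EPS, 1 - PRED_EPS)
        pb = poisson_binomial_pmf(probs)
        b = np.clip(binomial_pmf(K, pi), PMF_EPS, None)
        pbc = np.clip(pb, PMF_EPS, None)
        val = float(np.sum(pb * (np.log(pbc) - np.log(b))))
        if not is_tensor:
            return val
        x = pred_unlabeled
        out = ad.Tensor(np.float64(val), parents=(x,))

        def bwd(g):
            if not x.requires_grad:
                return
            # dL/dp_i = sum_k q[i,k] * (c_{k+1} - c_k), c_k = log(pb_k/b_k)+1
            c = np.log(pbc) - np.log(b) + 1.0
            q = _leave_one_out_pmfs(pb, probs)
            grad = (q * np.diff(c)[None, :]).sum(axis=1)
            x._accumulate((float(g) * grad).reshape(x.data.shape)
                          .astype(x.data.dtype))
        out._backward = bwd if out.requires_grad else None
        return out
    if count_mode != "gaussian_approx":
        raise ValueError(f"unknown count_mode {count_mode!r}")
    p = pred_unlabeled if is_tensor else pd
    m_hat = (p * 1.0).sum() if is_tensor else p.sum()
    v_hat = (p * (1.0 - p)).sum()
    m = K * pi
    v = K * pi * (1.0 - pi)
    return ((m_hat - m) ** 2) * (1.0 / v) + ((v_hat - v) ** 2) * (1.0 / v)


def pu_detection_loss(pair: HeatmapPair, cfg: PUConfig,
                      rng: np.random.Generator | None = None):
    """pi-weighted positive focal term + GE-binomial term on unlabeled pixels.

    The focal contribution uses the positive-target branch at the annotated
    centers (Y == 1); the GE term sees K unlabeled pixels subsampled
    uniformly outside the labeled splat support.
    """
    target = np.asarray(pair.target, dtype=np.float64)
    mask = np.asarray(pair.labeled_mask, dtype=bool)
    pred = pair.pred
    pd = pred.data if isinstance(pred, ad.Tensor) else np.asarray(pred)
    if pd.shape != target.shape or mask.shape != target.shape:
        raise ValueError("target / labeled_mask / pred shapes disagree")
    pos_idx = np.flatnonzero(target.ravel() == 1.0)
    if pos_idx.size == 0:
        raise ValueError("no labeled centers in this sample; the training "
                         "sampler must provide at least one")
    flat = pred.reshape(-1) if isinstance(pred, ad.Tensor) else pd.ravel()
    p_pos = ad.clip(flat[pos_idx], PRED_EPS, 1.0 - PRED_EPS)
    focal_pos = (((1.0 - p_pos) ** cfg.alpha) * (-1.0 * ad.log(p_pos))).sum() \
        * (1.0 / pos_idx.size)
    unl_idx = np.flatnonzero(~mask.ravel())
    if unl_idx.size == 0:
        raise ValueError("no unlabeled pixels available")
    if unl_idx.size > cfg.K:
        rng = rng or np.random.default_rng(0)
        unl_idx = rng.choice(unl_idx, size=cfg.K, replace=False)
        unl_idx.sort()
    ge = ge_binomial_loss(flat[unl_idx], cfg.pi, cfg.count_mode)
    return cfg.pi * focal_pos + ge
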