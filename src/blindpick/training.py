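"""Joint training loop: augmentation group, consistency loss, total objective.

The total objective is

    L = lambda_den * L_denoise + lambda_det * L_detect + lambda_cons * L_cons

where L_denoise is the mean marginal negative log-likelihood of the noisy
pixels, L_detect the positive-unlabeled heatmap loss, and L_cons an
equivariance consistency term: the same patch is pushed through the network
twice, once plainly and once after a random dihedral transform, and the
transformed plain outputs (heatmap probabilities and posterior-mean denoised
image) are asked to match the outputs of the transformed input.  Denoising
is the dominant task by default (lambda_den = 1 vs 0.1 for the others).

Optimization is Adam with a linear warm-up from zero to lr_peak followed by
cosine decay, batches of particle-containing patches, and early stopping on
a small relative change of the windowed loss.  Single-task modes switch the
other head off entirely: in denoise_only the detection head receives neither
loss nor updates, and symmetrically for detect_only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .backbone import BackboneConfig, JointModel, NetworkOutputs
from .noise import marginal_nll, posterior_mean
from .pu import HeatmapPair, PUConfig, labeled_support, pu_detection_loss, \
    splat_heatmap

__all__ = ["Transform", "DIHEDRAL", "apply_transform", "transform_coords",
           "TrainConfig", "TrainScene", "consistency_loss", "total_loss",
           "sample_patches", "lr_schedule", "EarlyStopper", "TrainResult",
           "train", "standardize_image", "equivariance_gap",
           "heatmap_separation", "sigma_p_for_radius"]


# --------------------------------------------------------------- augmentation
@dataclass(frozen=True)
class Transform:
    """Element r^k f^s of the dihedral group D4 acting on square images.

    f is a horizontal flip (columns reversed), r a counter-clockwise quarter
    turn; the action is: flip first (if s), then rotate k times.
    """
    k: int = 0
    flip: bool = False

    def __post_init__(self):
        if self.k not in (0, 1, 2, 3):
            raise ValueError("k must be 0..3")

    def compose(self, other: "Transform") -> "Transform":
        """self o other (apply `other` first)."""
        sign = -1 if self.flip else 1
        return Transform((self.k + sign * other.k) % 4, self.flip ^ other.flip)

    def inverse(self) -> "Transform":
        k = self.k if self.flip else (-self.k) % 4
        return Transform(k % 4, self.flip)


DIHEDRAL = tuple(Transform(k, f) for f in (False, True) for k in range(4))


def _spatial_axes(ndim: int):
    # 2-D arrays act on (0, 1); batched NHW / NHWC tensors on (1, 2)
    return (0, 1) if ndim == 2 else (1, 2)


def apply_transform(image, t: Transform):
    """Apply a dihedral transform to a 2-D array, an (N,H,W[,C]) array or Tensor."""
    nd = image.ndim
    axes = _spatial_axes(nd)
    h = image.shape[axes[0]]
    w = image.shape[axes[1]]
    if t.k % 2 == 1 and h != w:
        raise ValueError("90-degree rotations require square patches")
    out = image
    if t.flip:
        out = ad.flip(out, axis=axes[1])
    if t.k:
        out = ad.rot90(out, t.k, axes=axes)
    return out


def transform_coords(coords, n: int, t: Transform):
    """Transform (row, col) centers on an n x n grid along with the image."""
    out = []
    for (r, c) in coords:
        if t.flip:
            c = n - 1 - c
        for _ in range(t.k):
            r, c = n - 1 - c, r
        out.append((r, c))
    return out


# ------------------------------------------------------------- configuration
@dataclass
class TrainConfig:
    mode: str = "joint"               # joint | denoise_only | detect_only
    lambda_denoise: float = 1.0
    lambda_detect: float = 0.1
    lambda_cons: float = 0.1
    lr_peak: float = 2e-3
    warmup_frac: float = 0.1
    max_iters: int = 1000
    early_stop_tol: float = 0.01
    early_stop_window: int = 200
    batch_size: int = 16
    patch_size: int = 64
    seed: int = 0
    noise_kind: str = "gaussian"      # gaussian | poisson_approx
    pi: float = 0.05
    alpha: float = 2.0
    beta: float = 4.0
    K: int = 256
    count_mode: str = "exact_dp"
    depth: int = 3
    base_channels: int = 32
    sigma_x_shrinkage: float = 1e-3
    max_grad_norm: float = 10.0
    input_augmentation: bool = True
    cons_on_heatmap: bool = True
    cons_on_denoised: bool = True

    def __post_init__(self):
        if self.mode not in ("joint", "denoise_only", "detect_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("lambda_denoise", "lambda_detect", "lambda_cons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode == "joint" and (self.lambda_denoise <= 0
                                     or self.lambda_detect <= 0):
            raise ValueError("joint mode requires positive denoise and detect weights")
        if self.patch_size % 2 ** self.depth:
            raise ValueError(f"patch_size must be divisible by {2 ** self.depth}")


@dataclass
class TrainScene:
    """A noisy micrograph with its sparse positive annotations."""
    image: np.ndarray                 # observed noisy micrograph (raw units)
    labeled_coords: list              # [(row, col), ...] annotated centers
    radius_px: float                  # half major-axis convention
    clean: np.ndarray | None = None   # ground truth, for evaluation only


def sigma_p_for_radius(radius_px: float) -> float:
    """Heatmap splat std from the particle size: 3-sigma support at the radius."""
    return max(1.0, radius_px / 3.0)


def standardize_image(image: np.ndarray, noise_kind: str = "gaussian"):
    """Return (standardized, offset, scale).

    Gaussian model: subtract mean, divide by std.  Signal-dependent model:
    divide by std only — the variance law var = gain * signal is preserved
    under pure scaling but not under shifts.
    """
    image = np.asarray(image, dtype=np.float64)
    scale = max(float(image.std()), 1e-8)
    offset = float(image.mean()) if noise_kind == "gaussian" else 0.0
    return (image - offset) / scale, offset, scale


# ------------------------------------------------------------------- losses
def consistency_loss(out_plain: NetworkOutputs, out_aug: NetworkOutputs,
                     t: Transform, on_heatmap: bool = True,
                     on_denoised: bool = True):
    """Equivariance penalty: MSE(T(f(x)), f(T(x))) for the selected outputs."""
    terms = []
    if on_heatmap:
        hp = ad.sigmoid(out_plain.heatmap_logits)
        ha = ad.sigmoid(out_aug.heatmap_logits)
        d = apply_transform(hp, t) - ha
        terms.append((d * d).mean())
    if on_denoised:
        if out_plain.denoised is None or out_aug.denoised is None:
            raise ValueError("denoised outputs required for the denoise term")
        d = apply_transform(out_plain.denoised, t) - out_aug.denoised
        terms.append((d * d).mean())
    if not terms:
        return Tensor(np.float64(0.0))
    total = terms[0]
    for x in terms[1:]:
        total = total + x
    return total


def _nan_check(name, term):
    val = term.data if isinstance(term, Tensor) else term
    if not np.isfinite(val):
        raise FloatingPointError(f"non-finite {name} loss term")


def total_loss(denoise_term, detect_term, cons_term, cfg: TrainConfig):
    """Weighted sum of the three tasks, with single-task modes zeroing the rest."""
    lam_den = cfg.lambda_denoise if cfg.mode != "detect_only" else 0.0
    lam_det = cfg.lambda_detect if cfg.mode != "denoise_only" else 0.0
    total = None
    for lam, term, name in ((lam_den, denoise_term, "denoise"),
                            (lam_det, detect_term, "detect"),
                            (cfg.lambda_cons, cons_term, "consistency")):
        if lam == 0.0 or term is None:
            continue
        _nan_check(name, term)
        piece = term * lam
        total = piece if total is None else total + piece
    if total is None:
        raise ValueError("all loss terms are switched off")
    return total


# ------------------------------------------------------------------ sampling
def sample_patches(scenes, cfg: TrainConfig, step_seed: int):
    """Draw `batch_size` square patches, each containing >= 1 labeled center.

    A labeled particle is chosen uniformly over all annotations, then the
    patch origin uniformly over positions that keep it inside.  Returns a
    list of (scene_index, (r0, c0), coords_in_patch) — images are cut by the
    caller so patches can come from any per-scene representation.
    """
    labeled = [(i, r, c) for i, s in enumerate(scenes)
               for (r, c) in s.labeled_coords]
    if not labeled:
        raise ValueError("no labeled particles in the dataset")
    rng = np.random.default_rng(step_seed)
    ps = cfg.patch_size
    batch = []
    for _ in range(cfg.batch_size):
        i, r, c = labeled[rng.integers(len(labeled))]
        H, W = scenes[i].image.shape
        if H < ps or W < ps:
            raise ValueError("scene smaller than patch_size")
        r0 = int(rng.integers(max(0, r - ps + 1), min(H - ps, r) + 1))
        c0 = int(rng.integers(max(0, c - ps + 1), min(W - ps, c) + 1))
        coords = [(rr - r0, cc - c0) for (rr, cc) in scenes[i].labeled_coords
                  if r0 <= rr < r0 + ps and c0 <= cc < c0 + ps]
        batch.append((i, (r0, c0), coords))
    return batch


# ------------------------------------------------------------------ schedule
def lr_schedule(it: int, cfg: TrainConfig) -> float:
    """Linear 0 -> lr_peak warm-up, then cosine decay to 0 at max_iters."""
    if not 0 <= it < cfg.max_iters:
        raise ValueError("iteration index out of range")
    warm = max(1, int(round(cfg.warmup_frac * cfg.max_iters)))
    if it < warm:
        return cfg.lr_peak * it / warm
    span = max(1, cfg.max_iters - warm)
    progress = (it - warm) / span
    return cfg.lr_peak * 0.5 * (1.0 + np.cos(np.pi * progress))


class EarlyStopper:
    """Stop when the windowed mean loss changes by less than `tol` (relative)."""

    def __init__(self, window: int, tol: float):
        self.window = window
        self.tol = tol
        self.history: list[float] = []

    def update(self, loss: float) -> bool:
        self.history.append(float(loss))
        w = self.window
        if len(self.history) < 2 * w:
            return False
        prev = float(np.mean(self.history[-2 * w:-w]))
        curr = float(np.mean(self.history[-w:]))
        return abs(curr - prev) / max(abs(prev), 1e-12) < self.tol


# -------------------------------------------------------------------- train
@dataclass
class TrainResult:
    model: JointModel
    history: pd.DataFrame
    stop_reason: str                  # max_iters | early_stop | diverged
    scene_scales: list = field(default_factory=list)


def train(scenes, cfg: TrainConfig, log_csv=None) -> TrainResult:
    """Run the optimization loop; reproducible for a fixed cfg.seed."""
    master = np.random.default_rng(cfg.seed)
    model = JointModel(
        BackboneConfig(depth=cfg.depth, base_channels=cfg.base_channels,
                       blindspot=True, noise_kind=cfg.noise_kind,
                       heatmap_bias=float(np.log(cfg.pi / (1.0 - cfg.pi)))),
        seed=int(master.integers(2 ** 31)))
    std_scenes, scales = [], []
    for s in scenes:
        img, off, sc = standardize_image(s.image, cfg.noise_kind)
        std_scenes.append(img.astype(np.float32))
        scales.append((off, sc))
    sigma_p = sigma_p_for_radius(scenes[0].radius_px)
    pu_cfg = PUConfig(pi=cfg.pi, alpha=cfg.alpha, beta=cfg.beta, K=cfg.K,
                      count_mode=cfg.count_mode)
    if cfg.mode == "denoise_only":
        params = model.trunk_params() + model.estimator_params()
    elif cfg.mode == "detect_only":
        params = model.trunk_params() + model.detection_params()
    else:
        params = model.params()
    opt = Adam(params, lr=cfg.lr_peak)
    need_denoise = cfg.mode != "detect_only"
    need_detect = cfg.mode != "denoise_only"
    cons_hm = cfg.cons_on_heatmap and need_detect
    cons_den = cfg.cons_on_denoised and need_denoise
    need_cons = cfg.lambda_cons > 0 and (cons_hm or cons_den)

    have_labels = any(s.labeled_coords for s in scenes)
    if not have_labels and need_detect:
        raise ValueError("detection training requires labeled particles")

    def uniform_patches(rng):
        ps = cfg.patch_size
        out = []
        for _ in range(cfg.batch_size):
            i = int(rng.integers(len(scenes)))
            H, W = scenes[i].image.shape
            r0 = int(rng.integers(0, H - ps + 1))
            c0 = int(rng.integers(0, W - ps + 1))
            out.append((i, (r0, c0), []))
        return out

    rows = []
    last_good = model.state_dict()
    stop_reason = "max_iters"
    stopper = EarlyStopper(cfg.early_stop_window, cfg.early_stop_tol)
    for it in range(cfg.max_iters):
        step_seed = int(master.integers(2 ** 31))
        rng = np.random.default_rng(step_seed)
        if have_labels:
            batch = sample_patches(scenes, cfg, int(rng.integers(2 ** 31)))
        else:
            batch = uniform_patches(rng)
        ps = cfg.patch_size
        # per-sample dihedral input augmentation (flips/rotations), with the
        # annotated centers moved along
        t_in = [DIHEDRAL[rng.integers(8)] if cfg.input_augmentation
                else DIHEDRAL[0] for _ in batch]
        X = np.stack([apply_transform(std_scenes[i][r0:r0 + ps, c0:c0 + ps],
                                      t_in[b])
                      for b, (i, (r0, c0), _) in enumerate(batch)])
        batch = [(i, origin, transform_coords(coords, ps, t_in[b]))
                 for b, (i, origin, coords) in enumerate(batch)]
        ts = [DIHEDRAL[rng.integers(8)] for _ in batch]

        out = model.forward(X)
        noise = model.noise_forward(X) if (need_denoise or cons_den) else None
        den_term = det_term = cons_term = None
        if need_denoise:
            den_term = marginal_nll(X, out.prior, noise).mean()
            if cfg.sigma_x_shrinkage > 0:
                # the marginal only constrains sigma_x^2 + sigma_n^2; a small
                # shrinkage on the prior std attributes the tie to the noise
                den_term = den_term + cfg.sigma_x_shrinkage \
                    * (out.prior.sigma * out.prior.sigma).mean()
        if need_detect:
            det_pieces = []
            pred = ad.sigmoid(out.heatmap_logits)
            for b, (_, _, coords) in enumerate(batch):
                target = splat_heatmap(coords, (ps, ps), sigma_p)
                pair = HeatmapPair(target=target,
                                   labeled_mask=labeled_support(target),
                                   pred=pred[b])
                det_pieces.append(pu_detection_loss(pair, pu_cfg, rng))
            det_term = det_pieces[0]
            for piece in det_pieces[1:]:
                det_term = det_term + piece
            det_term = det_term * (1.0 / len(det_pieces))
        if need_cons:
            Xa = np.stack([apply_transform(X[b], ts[b]) for b in range(len(batch))])
            out_aug = model.forward(Xa)
            if cons_den:
                out.denoised = posterior_mean(X, out.prior, noise)
                noise_aug = model.noise_forward(Xa)
                out_aug.denoised = posterior_mean(Xa, out_aug.prior, noise_aug)
            pieces = []
            for b, t in enumerate(ts):
                plain_b = NetworkOutputs(
                    prior=out.prior, heatmap_logits=out.heatmap_logits[b:b + 1],
                    denoised=None if not cons_den else out.denoised[b:b + 1])
                aug_b = NetworkOutputs(
                    prior=out_aug.prior,
                    heatmap_logits=out_aug.heatmap_logits[b:b + 1],
                    denoised=None if not cons_den else out_aug.denoised[b:b + 1])
                pieces.append(consistency_loss(plain_b, aug_b, t,
                                               on_heatmap=cons_hm,
                                               on_denoised=cons_den))
            cons_term = pieces[0]
            for piece in pieces[1:]:
                cons_term = cons_term + piece
            cons_term = cons_term * (1.0 / len(pieces))

        try:
            total = total_loss(den_term, det_term, cons_term, cfg)
        except FloatingPointError:
            model.load_state_dict(last_good)
            stop_reason = "diverged"
            break
        lr = lr_schedule(it, cfg)
        opt.zero_grad()
        total.backward()
        if cfg.max_grad_norm > 0:
            gsq = sum(float((p.grad ** 2).sum()) for p in params
                      if p.grad is not None)
            gnorm = np.sqrt(gsq)
            if gnorm > cfg.max_grad_norm:
                scale = cfg.max_grad_norm / gnorm
                for p in params:
                    if p.grad is not None:
                        p.grad *= scale
        opt.step(lr)
        tval = total.item()
        rows.append({
            "iter": it, "lr": lr, "total": tval,
            "denoise": den_term.item() if den_term is not None else np.nan,
            "detect": det_term.item() if det_term is not None else np.nan,
            "consistency": cons_term.item() if cons_term is not None else np.nan,
        })
        if not np.isfinite(tval):
            model.load_state_dict(last_good)
            stop_reason = "diverged"
            break
        last_good = model.state_dict()
        if stopper.update(tval):
            stop_reason = "early_stop"
            break

    history = pd.DataFrame(rows)
    if log_csv is not None:
        history.to_csv(log_csv, index=False)
    return TrainResult(model=model, history=history, stop_reason=stop_reason,
                       scene_scales=scales)


# ----------------------------------------------------------------- analysis
def heatmap_separation(model: JointModel, images: np.ndarray,
                       coords_per_image, exclusion_radius: float) -> float:
    """Separation of mean heatmap logits: particle centers vs background.

    The frozen-detection-head diagnostic: even with an untrained detection
    head, features learned through denoising alone should make particle
    centers and background increasingly separable.  Background pixels are
    those farther than `exclusion_radius` from every center; the statistic
    is |mean logit at centers - mean logit at background|.  Raw micrographs
    are standardized internally.
    """
    X = np.stack([standardize_image(im, model.cfg.noise_kind)[0]
                  for im in images]).astype(np.float32)
    logits = model.forward(X).heatmap_logits.data
    center_vals, bg_vals = [], []
    for b, coords in enumerate(coords_per_image):
        lm = logits[b]
        H, W = lm.shape
        rr, cc = np.mgrid[0:H, 0:W]
        bg = np.ones((H, W), dtype=bool)
        for (r, c) in coords:
            center_vals.append(lm[r, c])
            bg &= (rr - r) ** 2 + (cc - c) ** 2 > exclusion_radius ** 2
        bg_vals.append(lm[bg])
    return float(abs(np.mean(center_vals) - np.mean(np.concatenate(bg_vals))))


def equivariance_gap(model: JointModel, images) -> float:
    """Mean squared heatmap equivariance error over the 8 dihedral transforms.

    Raw micrographs are standardized internally; images must be square.
    """
    images = np.stack([standardize_image(im, model.cfg.noise_kind)[0]
                       for im in images]).astype(np.float32)
    gaps = []
    base = ad.sigmoid(model.forward(images).heatmap_logits).data
    for t in DIHEDRAL:
        if t.k == 0 and not t.flip:
            continue
        Xa = np.stack([apply_transform(im, t) for im in images])
        aug = ad.sigmoid(model.forward(Xa).heatmap_logits).data
        moved = np.stack([apply_transform(b, t) for b in base])
        gaps.append(float(np.mean((moved - aug) ** 2)))
    return float(np.mean(gaps))
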