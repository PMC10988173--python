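"""Canonical desk-scale synthetic studies.

These functions pin down the reference conditions used to exercise the
whole pipeline on a single CPU in minutes: small micrographs, a
16-channel three-level backbone, short schedules.  They exist so that the
test-suite and the reproduction script run the very same experiment
definitions.

Study conditions: 128x128 micrographs with 22 Gaussian-blob particles of
radius 6 px (minimum center distance 20 px), Gaussian noise at a chosen
SNR = var(clean - background)/sigma_n^2, 10% of particles annotated, class
prior from the particles-times-area heuristic.
"""

from __future__ import annotations

import numpy as np

from .evalio import (Micrograph, denoise_micrograph, estimate_prior,
                     match_precision_recall, pick_particles, psnr)
from .synthetic import (ParticleSpec, corrupt_gaussian, make_clean_micrograph,
                        make_sparse_labels, sigma_for_snr)
from .training import TrainConfig, TrainScene, train

SCENE_SIZE = 128
N_SCENES = 6
N_PARTICLES = 22
RADIUS = 6.0
MIN_DIST = 20
LABEL_FRACTION = 0.10
PIXELS_PER_PARTICLE = np.pi * RADIUS ** 2
CLASS_PRIOR = estimate_prior(N_PARTICLES, PIXELS_PER_PARTICLE, SCENE_SIZE ** 2)

MATCH_RADIUS = RADIUS / 2          # 3 px tolerance when scoring picks
PICK_THRESHOLD = 0.5
NMS_RADIUS = RADIUS                # half major-axis length

FLAT_SIGMA = 2.0                   # known noise std for the recovery study
FLAT_BACKGROUND = 10.0


def make_scene_set(snr: float, seed: int, n_scenes: int = N_SCENES):
    """Noisy labeled scenes at the given SNR, plus full ground-truth centers."""
    spec = ParticleSpec(radius_px=RADIUS)
    scenes, truths = [], []
    for i in range(n_scenes):
        clean = make_clean_micrograph((SCENE_SIZE, SCENE_SIZE), spec,
                                      N_PARTICLES, min_dist=MIN_DIST,
                                      seed=seed + i)
        sigma = sigma_for_snr(clean, snr)
        noisy = corrupt_gaussian(clean.image, sigma, seed=1000 + seed + i)
        labels = make_sparse_labels(clean.coords, LABEL_FRACTION,
                                    seed=2000 + seed + i)
        scenes.append(TrainScene(image=noisy, labeled_coords=labels,
                                 radius_px=RADIUS, clean=clean.image))
        truths.append(clean.coords)
    return scenes, truths


def desk_cfg(**overrides) -> TrainConfig:
    """Desk-scale training defaults shared by all reference runs."""
    base = dict(mode="joint", patch_size=48, batch_size=4, base_channels=16,
                depth=3, max_iters=300, pi=CLASS_PRIOR, seed=0,
                lambda_denoise=1.0, lambda_detect=0.1, lambda_cons=0.1,
                K=256, count_mode="exact_dp")
    base.update(overrides)
    return TrainConfig(**base)


def detection_report(model, scenes, truths, threshold: float = PICK_THRESHOLD,
                     nms_radius: float = NMS_RADIUS,
                     match_radius: float = MATCH_RADIUS):
    """Pooled precision/recall/F1 of picks over a scene set."""
    tp = fp = fn = 0
    for scene, truth in zip(scenes, truths):
        ps = pick_particles(model, Micrograph(scene.image),
                            threshold=threshold, radius=nms_radius)
        rep = match_precision_recall(ps, truth, match_radius)
        tp += rep.tp
        fp += rep.fp
        fn += rep.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) \
        if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def denoising_report(model, scenes):
    """Mean PSNR of noisy and denoised images against the clean signal."""
    noisy_db, den_db = [], []
    for scene in scenes:
        den = denoise_micrograph(model, Micrograph(scene.image))
        noisy_db.append(psnr(scene.image, scene.clean))
        den_db.append(psnr(den.data, scene.clean))
    return {"psnr_noisy_db": float(np.mean(noisy_db)),
            "psnr_denoised_db": float(np.mean(den_db)),
            "psnr_gain_db": float(np.mean(den_db) - np.mean(noisy_db))}


def flat_noise_scenes(seed: int, n_scenes: int = 8, size: int = 128):
    """Featureless micrographs carrying pure Gaussian noise of known std."""
    return [TrainScene(
        image=corrupt_gaussian(np.full((size, size), FLAT_BACKGROUND),
                               FLAT_SIGMA, seed=seed + i),
        labeled_coords=[], radius_px=RADIUS) for i in range(n_scenes)]


def noise_recovery_cfg(seed: int = 0) -> TrainConfig:
    return TrainConfig(mode="denoise_only", patch_size=64, batch_size=2,
                       base_channels=32, depth=3, max_iters=200,
                       early_stop_window=40, early_stop_tol=0.01,
                       lambda_cons=0.0, seed=seed)


def recovered_sigma(model, scenes) -> float:
    """Spatial median of the predicted noise std, in raw image units."""
    from .evalio import _forward_full
    vals = []
    for scene in scenes:
        maps = _forward_full(model, Micrograph(scene.image))
        vals.append(np.median(maps["sigma_or_gain"]) * maps["scale"])
    return float(np.median(vals))
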