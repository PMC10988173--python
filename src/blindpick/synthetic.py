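"""Synthetic micrographs with known particle positions.

Emulates the regime the method is built for: fields of blob-like particles on
a flat background, buried in noise whose power can greatly exceed the
signal's.  Two corruption models are provided — additive zero-mean Gaussian
noise of fixed std, and signal-dependent Gaussian noise with variance
gain * signal approximating Poisson counting statistics — together with
sparse positive-only label subsets, so the whole pipeline is testable with
no external data.

SNR convention used throughout the package:  var(clean - background) / sigma_n^2,
reported by `scene_snr` / solved for by `sigma_for_snr`.  No CTF, atomic-model
projection or tilt geometry is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["ParticleSpec", "SyntheticScene", "make_clean_micrograph",
           "corrupt_gaussian", "corrupt_signal_dependent", "make_sparse_labels",
           "scene_snr", "sigma_for_snr", "PlacementError", "write_scene"]

PLACEMENT_RETRIES = 10_000


class PlacementError(RuntimeError):
    """Raised when particles cannot be placed at the requested minimum distance."""


@dataclass(frozen=True)
class ParticleSpec:
    """Shape of a synthetic particle.

    radius_px is the half major-axis length convention used downstream for
    the NMS radius and the heatmap kernel width; intensity is the peak
    amplitude above background.
    """
    radius_px: float
    intensity: float = 1.0
    profile: str = "gaussian_blob"

    def __post_init__(self):
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.profile not in ("gaussian_blob", "disk"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class SyntheticScene:
    """Clean signal, its particle centers, and the generating spec."""
    image: np.ndarray                  # 2-D float64, the clean signal x
    coords: list                       # [(row, col), ...] integer centers
    spec: ParticleSpec
    background: float = 0.0


def _render(shape, coords, spec: ParticleSpec, background: float) -> np.ndarray:
    img = np.full(shape, float(background), dtype=np.float64)
    if not coords:
        return img
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for (r, c) in coords:
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        if spec.profile == "gaussian_blob":
            s = spec.radius_px / 2.0      # blob std: 2-sigma support at the radius
            img += spec.intensity * np.exp(-d2 / (2.0 * s * s))
        else:
            img += spec.intensity * (d2 <= spec.radius_px ** 2)
    return img


def make_clean_micrograph(shape, spec: ParticleSpec, n_particles: int,
                          min_dist: float, background: float = 0.0,
                          seed: int = 0) -> SyntheticScene:
    """Place `n_particles` centers at pairwise distance >= min_dist and render.

    Placement is rejection sampling, deterministic for a fixed seed; a
    PlacementError is raised after PLACEMENT_RETRIES failed proposals for
    any single particle.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"invalid shape {shape}")
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    rng = np.random.default_rng(seed)
    margin = int(np.ceil(spec.radius_px))
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise ValueError("shape too small for the particle radius")
    coords: list[tuple[int, int]] = []
    placed = np.empty((0, 2))
    for _ in range(n_particles):
        for attempt in range(PLACEMENT_RETRIES):
            r = int(rng.integers(margin, rows - margin))
            c = int(rng.integers(margin, cols - margin))
            if placed.size == 0 or np.all(
                    np.hypot(placed[:, 0] - r, placed[:, 1] - c) >= min_dist):
                coords.append((r, c))
                placed = np.vstack([placed, [r, c]])
                break
        else:
            raise PlacementError(
                f"could not place particle {len(coords) + 1}/{n_particles} "
                f"at min_dist={min_dist} after {PLACEMENT_RETRIES} tries")
    return SyntheticScene(image=_render(shape, coords, spec, background),
                          coords=coords, spec=spec, background=background)


def corrupt_gaussian(image, sigma: float, seed: int = 0) -> np.ndarray:
    """Add iid zero-mean Gaussian noise of std `sigma` (sigma >= 0)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


def corrupt_signal_dependent(image, gain: float, floor: float = 1e-3,
                             seed: int = 0) -> np.ndarray:
    """Signal-dependent Gaussian noise: per-pixel std sqrt(gain*max(x, floor)).

    Approximates Poisson counting noise with gain `gain`; sub-floor signal
    values use the floor for the variance so the noise never vanishes.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    std = np.sqrt(gain * np.maximum(image, floor))
    return image + rng.normal(0.0, 1.0, size=image.shape) * std


def make_sparse_labels(coords, fraction: float, seed: int = 0) -> list:
    """Uniform subset of round(fraction * n) centers, without replacement."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    coords = list(coords)
    k = int(round(fraction * len(coords)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(coords), size=k, replace=False) if k else []
    return [coords[i] for i in sorted(idx)]


def scene_snr(scene: SyntheticScene, sigma_n: float) -> float:
    """SNR = var(clean - background) / sigma_n^2."""
    return float(np.var(scene.image - scene.background)) / sigma_n ** 2


def sigma_for_snr(scene: SyntheticScene, snr: float) -> float:
    """Noise std that puts the scene at the requested SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.sqrt(np.var(scene.image - scene.background) / snr))


def write_scene(scene: SyntheticScene, prefix):
    """Write <prefix>.mrc (float32), <prefix>.coords (x<TAB>y) and <prefix>.yaml."""
    from .evalio import Micrograph, write_micrograph, write_coords_list
    write_micrograph(Micrograph(scene.image.astype(np.float32)), f"{prefix}.mrc")
    write_coords_list(scene.coords, f"{prefix}.coords")
    with open(f"{prefix}.yaml", "w") as fh:
        yaml.safe_dump({
            "radius_px": scene.spec.radius_px,
            "intensity": scene.spec.intensity,
            "profile": scene.spec.profile,
            "background": scene.background,
            "n_particles": len(scene.coords),
        }, fh)
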