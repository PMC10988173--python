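"""Full-micrograph inference, evaluation metrics and file I/O.

Coordinate convention, used by every reader and writer in this module:
0-based, x = column, y = row.  EMAN-style .box entries (corner + box size)
are converted to centers relative to the same convention.

Micrograph images travel as MRC2014 (modes 0/1/2/6; written as float32 mode
2 with the pixel size in the cell header) or TIFF.  The MRC codec here is a
direct implementation of the fixed 1024-byte header layout.
"""

from __future__ import annotations

import math
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .backbone import JointModel
from .noise import posterior_mean
from .training import standardize_image

__all__ = ["Micrograph", "ParticleSet", "EvalReport", "denoise_micrograph",
           "predict_heatmap", "nms", "pick_particles", "match_precision_recall",
           "psnr", "fsc", "fsc_resolution", "estimate_prior", "read_micrograph",
           "write_micrograph", "read_coords", "write_coords", "write_coords_list",
           "bin_image", "gaussian_denoise_baseline"]


@dataclass
class Micrograph:
    """A single 2-D image with pixel-size metadata (Angstrom/pixel)."""
    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("micrograph data must be 2-D")


@dataclass
class ParticleSet:
    """Picked centers: (x=column, y=row, score), scores descending after NMS."""
    particles: list                    # [(x, y, score), ...]
    radius_px: float = 1.0
    source: str = ""

    def coords_rc(self):
        return [(y, x) for (x, y, _) in self.particles]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    match_radius: float


# ------------------------------------------------------------------ inference
def _pad_to_divisible(image: np.ndarray, d: int):
    H, W = image.shape
    ph = (-H) % d
    pw = (-W) % d
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    return image, (H, W)


def _forward_full(model: JointModel, micrograph: Micrograph):
    """Standardize, pad, run both networks, crop; returns numpy maps + scale."""
    img = np.asarray(micrograph.data, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("micrograph contains non-finite values")
    std, off, sc = standardize_image(img, model.cfg.noise_kind)
    padded, (H, W) = _pad_to_divisible(std.astype(np.float32), model.cfg.divisor)
    out = model.forward(padded[None])
    noise = model.noise_forward(padded[None])
    den = posterior_mean(padded[None], out.prior, noise)
    crop = lambda t: t.data[0, :H, :W]
    return {
        "denoised_std": crop(den),
        "heatmap": ad.sigmoid(out.heatmap_logits).data[0, :H, :W],
        "sigma_or_gain": crop(noise.sigma_n if model.cfg.noise_kind == "gaussian"
                              else noise.gain),
        "offset": off, "scale": sc,
    }


def denoise_micrograph(model: JointModel, micrograph: Micrograph) -> Micrograph:
    """Posterior-mean denoising of a whole micrograph (shape preserved)."""
    maps = _forward_full(model, micrograph)
    out = maps["denoised_std"] * maps["scale"] + maps["offset"]
    return Micrograph(out.astype(np.float64), pixel_size=micrograph.pixel_size)


def predict_heatmap(model: JointModel, micrograph: Micrograph) -> np.ndarray:
    """Per-pixel particle-center probability for a whole micrograph."""
    return _forward_full(model, micrograph)["heatmap"]


def estimated_noise_scale(model: JointModel, micrograph: Micrograph) -> np.ndarray:
    """Predicted per-pixel noise std (gaussian) or gain, in raw image units.

    Standardization divides the image by its std s, so both the Gaussian std
    (sigma = s * sigma_std) and the Poisson gain (a = s * a_std, since
    variance and signal each scale by s) un-standardize by the same factor.
    """
    maps = _forward_full(model, micrograph)
    return maps["sigma_or_gain"] * maps["scale"]


def nms(heatmap: np.ndarray, radius: float, threshold: float) -> ParticleSet:
    """Greedy non-maximum suppression over supra-threshold pixels.

    Candidates are visited in descending score (ties broken by row-major
    position); one is accepted iff no previously accepted peak lies within
    Euclidean distance `radius`.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    hm = np.asarray(heatmap, dtype=np.float64)
    rr, cc = np.nonzero(hm >= threshold)
    scores = hm[rr, cc]
    order = np.lexsort((cc, rr, -scores))   # score desc, then row-major
    kept_r, kept_c, kept_s = [], [], []
    for i in order:
        r, c, s = rr[i], cc[i], scores[i]
        if kept_r:
            d2 = (np.array(kept_r) - r) ** 2 + (np.array(kept_c) - c) ** 2
            if d2.min() <= radius ** 2:
                continue
        kept_r.append(int(r))
        kept_c.append(int(c))
        kept_s.append(float(s))
    particles = [(c, r, s) for r, c, s in zip(kept_r, kept_c, kept_s)]
    return ParticleSet(particles=particles, radius_px=radius)


def pick_particles(model: JointModel, micrograph: Micrograph,
                   threshold: float = 0.5, radius: float | None = None,
                   source: str = "") -> ParticleSet:
    """Heatmap inference followed by NMS at the particle radius."""
    hm = predict_heatmap(model, micrograph)
    radius = 1.0 if radius is None else radius
    ps = nms(hm, radius, threshold)
    ps.source = source
    return ps


# ----------------------------------------------------------------- evaluation
def match_precision_recall(pred: ParticleSet, truth, match_radius: float) -> EvalReport:
    """Greedy one-to-one matching in descending prediction score.

    Each prediction claims the nearest unmatched truth center within
    `match_radius`; precision = TP/(TP+FP), recall = TP/(TP+FN), with the
    0/0 -> 0 convention for empty sets.
    """
    if match_radius < 0:
        raise ValueError("match_radius must be >= 0")
    truth = [(float(r), float(c)) for (r, c) in truth]
    preds = sorted(pred.particles, key=lambda p: -p[2])
    taken = np.zeros(len(truth), dtype=bool)
    tarr = np.array(truth) if truth else np.empty((0, 2))
    tp = fp = 0
    for (x, y, _) in preds:
        if tarr.size:
            d = np.hypot(tarr[:, 0] - y, tarr[:, 1] - x)
            d[taken] = np.inf
            j = int(np.argmin(d))
            if d[j] <= match_radius:
                taken[j] = True
                tp += 1
                continue
        fp += 1
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return EvalReport(precision=precision, recall=recall, f1=f1,
                      tp=tp, fp=fp, fn=fn, match_radius=match_radius)


def psnr(test: np.ndarray, reference: np.ndarray) -> float:
    """10*log10(range^2 / MSE); range = max - min of the reference."""
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    rng = float(reference.max() - reference.min())
    if rng == 0:
        raise ValueError("constant reference image: PSNR range undefined")
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(rng ** 2 / mse)


def fsc(vol_a: np.ndarray, vol_b: np.ndarray, shell_width: float = 1.0):
    """Fourier shell correlation between two volumes.

    Per radial shell r: Re(sum F_a conj(F_b)) / sqrt(sum|F_a|^2 sum|F_b|^2).
    Returns (shell_radii_in_cycles_per_voxel, fsc_values); empty shells are
    skipped.
    """
    a = np.asarray(vol_a, dtype=np.float64)
    b = np.asarray(vol_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("volume shapes differ")
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)
    freqs = [np.fft.fftfreq(n) for n in a.shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    radius = np.sqrt(sum(g ** 2 for g in grids))
    n = min(a.shape)
    # shells indexed in units of one Fourier voxel of the smallest dimension
    shell = np.floor(radius * n / shell_width).astype(int)
    nshells = int(shell.max()) + 1
    num = np.real(Fa * np.conj(Fb)).ravel()
    pa = (np.abs(Fa) ** 2).ravel()
    pb = (np.abs(Fb) ** 2).ravel()
    sh = shell.ravel()
    radii, values = [], []
    max_shell = n // 2
    for s in range(min(nshells, max_shell + 1)):
        m = sh == s
        if not m.any():
            continue
        denom = math.sqrt(pa[m].sum() * pb[m].sum())
        if denom == 0:
            continue
        radii.append(s * shell_width / n)
        values.append(float(num[m].sum() / denom))
    return np.array(radii), np.array(values)


def fsc_resolution(radii: np.ndarray, values: np.ndarray, voxel_size: float,
                   cutoff: float = 0.143) -> float:
    """Resolution (same units as voxel_size) at the first crossing below cutoff."""
    for i in range(1, len(values)):
        if values[i] < cutoff <= values[i - 1]:
            # linear interpolation between shells i-1 and i
            f = radii[i - 1] + (radii[i] - radii[i - 1]) * \
                (values[i - 1] - cutoff) / (values[i - 1] - values[i])
            return voxel_size / f
    return math.inf if values[-1] >= cutoff else voxel_size / radii[0]


def estimate_prior(particles_per_micrograph: float, pixels_per_particle: float,
                   pixels_per_micrograph: float) -> float:
    """Class prior pi = n_particles * pixels_per_particle / total_pixels.

    The visual-inspection heuristic for choosing the positive prior; the
    result is clipped into (1e-6, 0.49).
    """
    if particles_per_micrograph <= 0 or pixels_per_particle <= 0 \
            or pixels_per_micrograph <= 0:
        raise ValueError("all inputs must be positive")
    pi = particles_per_micrograph * pixels_per_particle / pixels_per_micrograph
    return float(np.clip(pi, 1e-6, 0.49))


# ------------------------------------------------------------------------ I/O
_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_micrograph(path) -> Micrograph:
    """Read MRC2014 (modes 0/1/2/6) or TIFF into a Micrograph."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        data = np.asarray(tifffile.imread(path), dtype=np.float64)
        return Micrograph(data)
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"{path}: missing MAP stamp; not an MRC2014 file")
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode} "
                             f"(supported: {sorted(_MRC_MODES)})")
        mx = struct.unpack("<i", header[28:32])[0]
        cella_x = struct.unpack("<f", header[40:44])[0]
        nsymbt = struct.unpack("<i", header[92:96])[0]
        fh.seek(1024 + nsymbt)
        data = np.frombuffer(fh.read(), dtype=_MRC_MODES[mode],
                             count=nx * ny * nz).reshape(nz, ny, nx)
    pixel_size = cella_x / mx if mx > 0 and cella_x > 0 else 1.0
    img = data[0] if nz == 1 else data.mean(axis=0)
    return Micrograph(np.asarray(img, dtype=np.float64), pixel_size=pixel_size)


def write_micrograph(micrograph: Micrograph, path):
    """Write a float32 mode-2 MRC2014 file (or TIFF by extension)."""
    path = str(path)
    data = np.asarray(micrograph.data, dtype=np.float32)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, data)
        return
    ny, nx = data.shape
    ps = float(micrograph.pixel_size)
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)           # nx ny nz mode
    struct.pack_into("<3i", header, 28, nx, ny, 1)             # mx my mz
    struct.pack_into("<3f", header, 40, nx * ps, ny * ps, ps)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)      # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)               # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])          # little-endian
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def read_coords(path) -> list:
    """Read particle centers as (row, col) pairs.

    Tab/space-separated "x y [score]" with an optional header line, or
    EMAN-style .box (x_corner y_corner w h -> center).  Out-of-bounds
    checking is left to consumers; suspicious negative entries only warn.
    """
    path = str(path)
    is_box = path.lower().endswith(".box")
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue          # header line
            if is_box:
                x, y, w = vals[0], vals[1], vals[2]
                h = vals[3] if len(vals) > 3 else w
                out.append((y + h / 2.0, x + w / 2.0))
            else:
                out.append((vals[1], vals[0]))
    if any(r < 0 or c < 0 for (r, c) in out):
        warnings.warn(f"{path}: negative coordinates retained; "
                      "bounds are enforced downstream")
    return out


def write_coords(particles: ParticleSet, path):
    """Write "x<TAB>y<TAB>score" with a convention header line."""
    with open(str(path), "w") as fh:
        fh.write("# x\ty\tscore (0-based; x=column, y=row)\n")
        for (x, y, s) in particles.particles:
            fh.write(f"{x}\t{y}\t{s:.6f}\n")


def write_coords_list(coords_rc, path):
    """Write bare (row, col) centers as "x<TAB>y"."""
    with open(str(path), "w") as fh:
        fh.write("# x\ty (0-based; x=column, y=row)\n")
        for (r, c) in coords_rc:
            fh.write(f"{c}\t{r}\n")


# ------------------------------------------------------------------ utilities
def bin_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-average binning; trailing rows/cols beyond a full block drop."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    image = np.asarray(image, dtype=np.float64)
    if factor == 1:
        return image.copy()
    H, W = image.shape
    h, w = H - H % factor, W - W % factor
    return image[:h, :w].reshape(h // factor, factor,
                                 w // factor, factor).mean(axis=(1, 3))


def gaussian_denoise_baseline(image: np.ndarray, sigma: float) -> np.ndarray:
    """Plain Gaussian low-pass filter, the naive denoising baseline."""
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma)
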