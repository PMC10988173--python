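"""Blind-spot U-Net backbone with denoising and detection heads.

The feature extractor is a U-Net (three encoder / three decoder levels with
skip connections) whose convolutions can be made *vertically causal*: a 3x3
kernel padded (2, 0) on top/bottom sees only rows <= i.  Running the causal
net on the four quarter-turn rotations of the input, shifting every branch
down by one row, rotating back and mixing with 1x1 convolutions yields a
receptive field that is the union of four half-planes — everything except
the pixel itself.  That makes the per-pixel outputs (clean-signal prior
mean/std and detection logits) mathematically independent of the observed
value at the same location, which is what lets the denoiser train on single
noisy micrographs.

The auxiliary noise estimator reuses the same U-Net with ordinary
(non-causal) convolutions and a single positive output map: the noise
standard deviation for the Gaussian model, or the gain of the
signal-dependent (Poisson-like) model.

Causality bookkeeping: a plain 2x2 max-pool lets the receptive field leak
one row downward through the downsample/upsample round trip, so each
blind-spot branch shifts its features down one row before every pool.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .noise import PriorStats, NoiseParams, POSITIVITY_FLOOR

__all__ = ["BackboneConfig", "NetworkOutputs", "UNet", "JointModel",
           "save_checkpoint", "load_checkpoint"]

LEAKY_SLOPE = 0.1


@dataclass
class BackboneConfig:
    """Architecture knobs shared by the blind-spot net and the noise estimator."""
    depth: int = 3
    base_channels: int = 32
    blindspot: bool = True
    noise_kind: str = "gaussian"          # or "poisson_approx"
    sigma_x_bias: float = -4.0            # pre-softplus init of the prior-std head
    noise_bias: float = 0.54              # pre-softplus init of the noise head (~1.0)
    heatmap_bias: float = -2.9            # detection-head bias: logit of the prior

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")

    @property
    def divisor(self) -> int:
        return 2 ** self.depth


@dataclass
class NetworkOutputs:
    """Per-pixel maps produced by one forward pass (Tensors, NHW after squeeze)."""
    prior: PriorStats
    heatmap_logits: Tensor
    noise: NoiseParams | None = None
    denoised: Tensor | None = None


def _he_init(rng: np.random.Generator, kh, kw, cin, cout) -> np.ndarray:
    std = np.sqrt(2.0 / (kh * kw * cin))
    return rng.normal(0.0, std, size=(cin, kh, kw, cout)).astype(np.float32)


class _Conv:
    def __init__(self, rng, kh, kw, cin, cout, causal: bool, bias: float = 0.0):
        self.w = Tensor(_he_init(rng, kh, kw, cin, cout), requires_grad=True)
        self.b = Tensor(np.full(cout, bias, dtype=np.float32), requires_grad=True)
        if causal:
            # receptive field rows i-kh+1 .. i
            self.pads = (kh - 1, 0, (kw - 1) // 2, (kw - 1) // 2)
        else:
            self.pads = ((kh - 1) // 2, (kh - 1) // 2, (kw - 1) // 2, (kw - 1) // 2)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, self.pads)

    def params(self):
        return [self.w, self.b]


class UNet:
    """Encoder-decoder trunk; `blindspot` switches causal convolutions on."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        self.cfg = cfg
        c = cfg.base_channels
        causal = cfg.blindspot
        widths = [min(c * 2 ** d, 4 * c) for d in range(cfg.depth)]
        self.widths = widths
        self.conv_in = _Conv(rng, 3, 3, in_channels, widths[0], causal)
        self.enc = []
        for d in range(1, cfg.depth):
            self.enc.append(_Conv(rng, 3, 3, widths[d - 1], widths[d], causal))
        self.bottleneck = _Conv(rng, 3, 3, widths[-1], widths[-1], causal)
        self.dec = []
        for d in range(cfg.depth - 1, -1, -1):
            cin = widths[min(d + 1, cfg.depth - 1)] + widths[d]
            self.dec.append(_Conv(rng, 3, 3, cin, widths[d], causal))
        self.out_channels = widths[0]

    def params(self):
        ps = self.conv_in.params()
        for m in self.enc + [self.bottleneck] + self.dec:
            ps += m.params()
        return ps

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, H, W, Cin) with H, W divisible by 2**depth."""
        causal = self.cfg.blindspot

        def down(t):
            if causal:
                t = ad.shift_rows(t, 1)
            return ad.maxpool2x2(t)

        skips = []
        h = ad.leaky_relu(self.conv_in(x), LEAKY_SLOPE)
        skips.append(h)
        for conv in self.enc:
            h = ad.leaky_relu(conv(down(h)), LEAKY_SLOPE)
            skips.append(h)
        h = ad.leaky_relu(self.bottleneck(down(h)), LEAKY_SLOPE)
        for conv, skip in zip(self.dec, reversed(skips)):
            h = ad.concat([ad.upsample2x(h), skip], axis=-1)
            h = ad.leaky_relu(conv(h), LEAKY_SLOPE)
        return h


class _Head:
    """Two-layer 1x1 convolution stack on recombined features.

    The final layer starts near zero so each head's output is initially its
    bias — the prior mean starts at 0, the stds at their softplus biases and
    the detection logit at the class-prior logit — which keeps the first
    optimization steps of the likelihood loss well-scaled.
    """

    def __init__(self, rng, cin, cmid, bias_out: float = 0.0):
        self.c1 = _Conv(rng, 1, 1, cin, cmid, causal=False)
        self.c2 = _Conv(rng, 1, 1, cmid, 1, causal=False, bias=bias_out)
        self.c2.w.data *= 0.01

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(ad.leaky_relu(self.c1(x), LEAKY_SLOPE))

    def params(self):
        return self.c1.params() + self.c2.params()


class JointModel:
    """Blind-spot trunk + (mu, sigma_x, heatmap) heads + noise estimator.

    Inputs are expected standardized (zero mean, unit std per image); the
    inference wrappers in `evalio` own the (un)standardization convention.
    """

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.trunk = UNet(cfg, rng)
        feat = 4 * self.trunk.out_channels if cfg.blindspot else self.trunk.out_channels
        mid = 2 * self.trunk.out_channels
        self.head_mu = _Head(rng, feat, mid)
        self.head_sigma = _Head(rng, feat, mid, bias_out=cfg.sigma_x_bias)
        self.head_heatmap = _Head(rng, feat, mid, bias_out=cfg.heatmap_bias)
        est_cfg = BackboneConfig(depth=cfg.depth, base_channels=cfg.base_channels,
                                 blindspot=False, noise_kind=cfg.noise_kind)
        self.estimator = UNet(est_cfg, rng)
        self.head_noise = _Head(rng, self.estimator.out_channels,
                                self.estimator.out_channels, bias_out=cfg.noise_bias)

    # ------------------------------------------------------------------ params
    def trunk_params(self):
        return (self.trunk.params() + self.head_mu.params()
                + self.head_sigma.params())

    def detection_params(self):
        return self.head_heatmap.params()

    def estimator_params(self):
        return self.estimator.params() + self.head_noise.params()

    def params(self):
        return self.trunk_params() + self.detection_params() + self.estimator_params()

    # ----------------------------------------------------------------- forward
    def _features(self, x: Tensor) -> Tensor:
        if not self.cfg.blindspot:
            return self.trunk(x)
        n = x.shape[0]
        if x.shape[1] == x.shape[2]:
            # square input: batch the four rotations through one trunk pass
            branches = ad.concat([ad.rot90(x, k, axes=(1, 2)) for k in range(4)],
                                 axis=0)
            feats = ad.shift_rows(self.trunk(branches), 1)
            back = [ad.rot90(feats[k * n:(k + 1) * n], -k, axes=(1, 2))
                    for k in range(4)]
        else:
            back = [ad.rot90(ad.shift_rows(self.trunk(ad.rot90(x, k, axes=(1, 2))), 1),
                             -k, axes=(1, 2)) for k in range(4)]
        return ad.concat(back, axis=-1)

    def forward(self, images) -> NetworkOutputs:
        """images: (N, H, W) standardized array or Tensor; H, W divisible by 2**depth.

        With `blindspot=True`, prior.mu, prior.sigma and heatmap_logits at
        pixel (i, j) are exactly independent of images[:, i, j] — the
        defining contract of the architecture.
        """
        x = ad.as_tensor(images)
        if np.isnan(x.data).any():
            raise ValueError("NaN values in network input")
        if x.ndim != 3:
            raise ValueError("expected a batch of 2-D images (N, H, W)")
        d = self.cfg.divisor
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(f"spatial dims must be divisible by {d}; pad first")
        x4 = x.reshape(x.shape[0], x.shape[1], x.shape[2], 1)
        f = self._features(x4)
        mu = self.head_mu(f)[..., 0]
        sigma = ad.softplus(self.head_sigma(f))[..., 0] + POSITIVITY_FLOOR
        logits = self.head_heatmap(f)[..., 0]
        return NetworkOutputs(prior=PriorStats(mu=mu, sigma=sigma),
                              heatmap_logits=logits)

    def noise_forward(self, images) -> NoiseParams:
        """Auxiliary noise estimator: per-pixel sigma_n (gaussian) or gain.

        The raw estimate is pooled to one value per image and broadcast back:
        the noise scale (or Poisson gain) is homoscedastic within a
        micrograph.  An unpooled per-pixel scale fed the noisy image itself
        would let the likelihood collapse onto sigma_n(i,j) ~ |residual(i,j)|
        pointwise, which destroys the noise-level estimate.
        """
        x = ad.as_tensor(images)
        if x.ndim != 3:
            raise ValueError("expected a batch of 2-D images (N, H, W)")
        x4 = x.reshape(x.shape[0], x.shape[1], x.shape[2], 1)
        raw = self.head_noise(self.estimator(x4))[..., 0]
        pos = ad.softplus(raw) + POSITIVITY_FLOOR
        pooled = pos.mean(axis=(1, 2), keepdims=True) \
            * np.ones((1,) + x.shape[1:3])
        if self.cfg.noise_kind == "gaussian":
            return NoiseParams(kind="gaussian", sigma_n=pooled)
        return NoiseParams(kind="poisson_approx", gain=pooled)

    # ------------------------------------------------------------- state dict
    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict):
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint/config mismatch: parameter count differs")
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint/config mismatch: shape of parameter "
                                 f"{i} is {arr.shape}, expected {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)


STANDARDIZATION = "per-image: subtract mean, divide by std (floor 1e-8)"


def save_checkpoint(path, model: JointModel, extra: dict | None = None):
    """Single-archive checkpoint: weights (npy entries) + YAML config."""
    meta = {
        "config": {
            "depth": model.cfg.depth,
            "base_channels": model.cfg.base_channels,
            "blindspot": model.cfg.blindspot,
            "noise_kind": model.cfg.noise_kind,
            "sigma_x_bias": model.cfg.sigma_x_bias,
            "noise_bias": model.cfg.noise_bias,
            "heatmap_bias": model.cfg.heatmap_bias,
        },
        "standardization": STANDARDIZATION,
        "extra": extra or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.yaml", yaml.safe_dump(meta))
        for name, arr in model.state_dict().items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_checkpoint(path) -> tuple[JointModel, dict]:
    with zipfile.ZipFile(path, "r") as zf:
        meta = yaml.safe_load(zf.read("config.yaml"))
        cfg = BackboneConfig(**meta["config"])
        model = JointModel(cfg, seed=0)
        state = {}
        for name in zf.namelist():
            if name.endswith(".npy"):
                state[name[:-4]] = np.load(io.BytesIO(zf.read(name)))
        model.load_state_dict(state)
    return model, meta
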