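"""Training losses: L1, SSIM (as similarity and as loss), perceptual distance.

Four compositions are used to train the translation network: L1 alone,
L1 + perceptual (LP), L1 + SSIM (LS) and L1 + perceptual + SSIM (LPS), each
summed with configurable non-negative weights (unit weights by default).

Conventions
-----------
* Images entering a loss are expected in normalised units: HU clipped to
  [-1000, 2000] and affinely mapped to [-1, 1] (dynamic range L = 2).
* SSIM is the similarity (max 1); the trainable loss is ``1 - SSIM``.
* SSIM stabilisation constants follow the universal convention
  ``c1 = (0.01 L)^2``, ``c2 = (0.03 L)^2``.
* The perceptual distance is the mean squared Euclidean distance between
  feature maps of a fixed (non-trainable) convolutional feature extractor.
  The default extractor is a seeded-random four-stage stack, so no weight
  download is ever required; an adapter accepts externally trained
  convolutional weights (e.g. VGG) when available.

Every function accepts either plain ndarrays (returning floats, for
evaluation) or autodiff Tensors shaped (N, 1, H, W) (returning scalar
Tensors, for training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, conv2d
from .nn.autodiff import maxpool2x2

__all__ = [
    "NORM_WINDOW_HU",
    "hu_to_unit",
    "unit_to_hu",
    "SSIMParams",
    "LossConfig",
    "FeatureExtractor",
    "l1_loss",
    "ssim_value",
    "ssim_loss",
    "perceptual_loss",
    "combined_loss",
    "loss_components",
]

NORM_WINDOW_HU = (-1000.0, 2000.0)

# fixed seed for the default random feature extractor: descriptors of the
# loss landscape must be identical across runs and machines
DEFAULT_EXTRACTOR_SEED = 0x5C7F0DE


def hu_to_unit(values: np.ndarray) -> np.ndarray:
    """Clip HU to the normalisation window and map affinely onto [-1, 1]."""
    lo, hi = NORM_WINDOW_HU
    v = np.clip(values, lo, hi)
    return (2.0 * (v - lo) / (hi - lo) - 1.0).astype(np.float32)


def unit_to_hu(values: np.ndarray) -> np.ndarray:
    lo, hi = NORM_WINDOW_HU
    return (np.asarray(values, dtype=np.float64) + 1.0) * (hi - lo) / 2.0 + lo


def _to_tensor4d(x) -> tuple[Tensor, bool]:
    """Coerce ndarray/Tensor input to an (N,1,H,W) Tensor."""
    if isinstance(x, Tensor):
        t = x
        was_array = False
    else:
        t = Tensor(np.asarray(x, dtype=np.float32))
        was_array = True
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, *t.shape[1:])
    elif t.ndim != 4:
        raise ValueError("expected 2-D, 3-D or 4-D image input")
    return t, was_array


def _ret(value: Tensor, as_float: bool):
    return value.item() if as_float else value


@dataclass
class SSIMParams:
    """SSIM window and stabilisation settings.

    window="gaussian" computes mean local SSIM over an 11x11 Gaussian window
    (sigma 1.5, valid region only); window="global" evaluates the formula
    once from image-wide moments.
    """

    window: str = "gaussian"
    window_size: int = 11
    sigma: float = 1.5
    data_range: float = 2.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.window not in ("gaussian", "global"):
            raise ValueError("window must be 'gaussian' or 'global'")
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        if self.data_range <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("data_range and k constants must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    def kernel(self) -> np.ndarray:
        half = self.window_size // 2
        ax = np.arange(-half, half + 1, dtype=np.float64)
        g = np.exp(-(ax**2) / (2 * self.sigma**2))
        k = np.outer(g, g)
        return k / k.sum()


def l1_loss(x, gx):
    """Mean absolute difference (resolution-independent)."""
    xt, ax = _to_tensor4d(x)
    gt, ag = _to_tensor4d(gx)
    if xt.shape != gt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {gt.shape}")
    return _ret((xt - gt).abs().mean(), ax and ag)


def _ssim_numpy(x: np.ndarray, gx: np.ndarray, p: SSIMParams) -> float:
    """Float64 evaluation path (2-D arrays); same math as the tensor path."""
    from scipy import signal

    x = np.asarray(x, np.float64)
    gx = np.asarray(gx, np.float64)
    c1, c2 = p.c1, p.c2
    if p.window == "global":
        mx, mg = x.mean(), gx.mean()
        vx = ((x - mx) ** 2).mean()
        vg = ((gx - mg) ** 2).mean()
        cov = ((x - mx) * (gx - mg)).mean()
        return float(
            ((2 * mx * mg + c1) * (2 * cov + c2))
            / ((mx**2 + mg**2 + c1) * (vx + vg + c2))
        )
    k = p.kernel()

    def smooth(a):
        return signal.fftconvolve(a, k, mode="valid")

    mu_x, mu_g = smooth(x), smooth(gx)
    var_x = smooth(x * x) - mu_x**2
    var_g = smooth(gx * gx) - mu_g**2
    cov = smooth(x * gx) - mu_x * mu_g
    num = (2 * mu_x * mu_g + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_g**2 + c1) * (var_x + var_g + c2)
    return float((num / den).mean())


def ssim_value(x, gx, params: SSIMParams | None = None):
    """Structural similarity in (-1, 1]; 1 iff the images are identical."""
    p = params or SSIMParams()
    if not isinstance(x, Tensor) and not isinstance(gx, Tensor):
        xa, ga = np.asarray(x, float), np.asarray(gx, float)
        if xa.shape != ga.shape:
            raise ValueError(f"shape mismatch: {xa.shape} vs {ga.shape}")
        if xa.ndim == 2:
            return _ssim_numpy(xa, ga, p)
        return float(np.mean([_ssim_numpy(a, b, p) for a, b in zip(xa, ga)]))
    xt, ax = _to_tensor4d(x)
    gt, ag = _to_tensor4d(gx)
    if xt.shape != gt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {gt.shape}")
    c1, c2 = p.c1, p.c2
    if p.window == "global":
        mu_x = xt.mean(axis=(2, 3), keepdims=True)
        mu_g = gt.mean(axis=(2, 3), keepdims=True)
        dx = xt - mu_x
        dg = gt - mu_g
        var_x = (dx * dx).mean(axis=(2, 3), keepdims=True)
        var_g = (dg * dg).mean(axis=(2, 3), keepdims=True)
        cov = (dx * dg).mean(axis=(2, 3), keepdims=True)
        num = (2.0 * mu_x * mu_g + c1) * (2.0 * cov + c2)
        den = (mu_x * mu_x + mu_g * mu_g + c1) * (var_x + var_g + c2)
        return _ret((num / den).mean(), ax and ag)
    # gaussian-window mean SSIM (valid region)
    w = Tensor(p.kernel().astype(np.float32)[None, None])
    mu_x = conv2d(xt, w)
    mu_g = conv2d(gt, w)
    mu_xx = conv2d(xt * xt, w)
    mu_gg = conv2d(gt * gt, w)
    mu_xg = conv2d(xt * gt, w)
    var_x = mu_xx - mu_x * mu_x
    var_g = mu_gg - mu_g * mu_g
    cov = mu_xg - mu_x * mu_g
    num = (2.0 * mu_x * mu_g + c1) * (2.0 * cov + c2)
    den = (mu_x * mu_x + mu_g * mu_g + c1) * (var_x + var_g + c2)
    return _ret((num / den).mean(), ax and ag)


def ssim_loss(x, gx, params: SSIMParams | None = None):
    """``1 - SSIM``: zero iff the pair is structurally identical."""
    v = ssim_value(x, gx, params)
    return 1.0 - v if isinstance(v, float) else 1.0 - v


class FeatureExtractor:
    """Fixed convolutional feature stages for the perceptual distance.

    Each stage is conv3x3 -> ELU -> 2x2 max-pool. Parameters are immutable
    during training (gradients flow through them to the input, never into
    them). ``provenance_tag`` records whether the weights are the package's
    seeded-random defaults or externally trained (e.g. VGG-derived) weights
    loaded through :meth:`from_weights`.
    """

    def __init__(self, weights: list[tuple[np.ndarray, np.ndarray]],
                 provenance_tag: str, in_channels: int = 1):
        if not weights:
            raise ValueError("extractor needs at least one stage")
        self.stages = [
            (Tensor(np.asarray(w, np.float32)), Tensor(np.asarray(b, np.float32)))
            for w, b in weights
        ]
        self.provenance_tag = provenance_tag
        self.in_channels = in_channels

    @classmethod
    def seeded_random(cls, seed: int = DEFAULT_EXTRACTOR_SEED,
                      channels: tuple[int, ...] = (8, 16, 32, 64),
                      in_channels: int = 1) -> "FeatureExtractor":
        rng = np.random.default_rng(seed)
        weights = []
        cin = in_channels
        for cout in channels:
            std = np.sqrt(2.0 / (cin * 9))
            w = rng.normal(0, std, size=(cout, cin, 3, 3))
            b = np.zeros(cout)
            weights.append((w, b))
            cin = cout
        return cls(weights, provenance_tag="seeded-random", in_channels=in_channels)

    @classmethod
    def from_weights(cls, weights, in_channels: int = 3) -> "FeatureExtractor":
        return cls(weights, provenance_tag="pretrained-vgg", in_channels=in_channels)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def features(self, x: Tensor, layers: list[int]) -> list[Tensor]:
        """Feature maps after each requested stage index (0-based)."""
        if any(i < 0 or i >= self.n_stages for i in layers):
            raise ValueError(f"layer index out of range 0..{self.n_stages - 1}")
        if x.shape[1] != self.in_channels:
            if x.shape[1] == 1:
                from .nn import concat

                x = concat([x] * self.in_channels, axis=1)
            else:
                raise ValueError("channel count incompatible with extractor")
        out = []
        last = max(layers)
        for i, (w, b) in enumerate(self.stages[: last + 1]):
            x = conv2d(x, w, b, padding=1).elu()
            h, wd = x.shape[2], x.shape[3]
            if h >= 2 and wd >= 2:
                if h % 2 or wd % 2:  # crop to even before pooling
                    x = x[:, :, : h - h % 2, : wd - wd % 2]
                x = maxpool2x2(x)
            if i in layers:
                out.append(x)
        return out


def perceptual_loss(x, gx, extractor: FeatureExtractor,
                    layers: list[int] | None = None):
    """Mean squared distance between fixed feature maps of the two images."""
    xt, ax = _to_tensor4d(x)
    gt, ag = _to_tensor4d(gx)
    if xt.shape != gt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {gt.shape}")
    layers = list(layers) if layers is not None else list(range(extractor.n_stages))
    fx = extractor.features(xt, layers)
    fg = extractor.features(gt, layers)
    total = None
    for a, b in zip(fx, fg):
        d = ((a - b) ** 2).mean()
        total = d if total is None else total + d
    total = total * (1.0 / len(layers))
    return _ret(total, ax and ag)


@dataclass
class LossConfig:
    """Which loss components are active and how they are weighted."""

    use_l1: bool = True
    use_ssim: bool = False
    use_perceptual: bool = False
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (w_l1, w_ssim, w_perc)
    ssim_params: SSIMParams = field(default_factory=SSIMParams)
    perceptual_layers: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self):
        if not (self.use_l1 or self.use_ssim or self.use_perceptual):
            raise ValueError("at least one loss component must be enabled")
        if any(w < 0 for w in self.weights):
            raise ValueError("loss weights must be non-negative")
        for enabled, w in zip(
            (self.use_l1, self.use_ssim, self.use_perceptual), self.weights
        ):
            if enabled and w <= 0:
                raise ValueError("enabled components need positive weights")

    @property
    def tag(self) -> str:
        return {
            (True, False, False): "L1",
            (True, False, True): "LP",
            (True, True, False): "LS",
            (True, True, True): "LPS",
        }.get((self.use_l1, self.use_ssim, self.use_perceptual), "custom")

    @classmethod
    def preset(cls, tag: str) -> "LossConfig":
        tag = tag.upper()
        table = {
            "L1": dict(use_l1=True),
            "LP": dict(use_l1=True, use_perceptual=True),
            "LS": dict(use_l1=True, use_ssim=True),
            "LPS": dict(use_l1=True, use_ssim=True, use_perceptual=True),
        }
        if tag not in table:
            raise ValueError(f"unknown loss preset {tag!r}; use L1/LP/LS/LPS")
        return cls(**table[tag])


def loss_components(x, gx, cfg: LossConfig,
                    extractor: FeatureExtractor | None = None) -> dict:
    """Unweighted values of each enabled component."""
    out = {}
    if cfg.use_l1:
        out["l1"] = l1_loss(x, gx)
    if cfg.use_ssim:
        out["ssim"] = ssim_loss(x, gx, cfg.ssim_params)
    if cfg.use_perceptual:
        if extractor is None:
            raise ValueError("perceptual loss enabled but no extractor given")
        out["perceptual"] = perceptual_loss(x, gx, extractor, list(cfg.perceptual_layers))
    return out


def combined_loss(x, gx, cfg: LossConfig,
                  extractor: FeatureExtractor | None = None):
    """Weighted sum of the enabled components (the training objective)."""
    comps = loss_components(x, gx, cfg, extractor)
    w = {"l1": cfg.weights[0], "ssim": cfg.weights[1], "perceptual": cfg.weights[2]}
    total = None
    for name, value in comps.items():
        term = w[name] * value
        total = term if total is None else total + term
    return total
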