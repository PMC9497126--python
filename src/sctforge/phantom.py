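"""Seeded head-phantom simulator producing paired CT/CBCT slices and dose grids.

The generator emulates the statistical structure of paired planning-CT /
cone-beam-CT axial head slices: shared anatomy (air background, skull ring,
brain soft tissue, low-contrast lesions, air cavities) with the CBCT copy
degraded by the classic cone-beam artifact families — low-frequency
cupping/shading (multiplicative bias field), scatter haze (wide-kernel blur
leak-through), stochastic noise, and a global HU calibration shift. Anatomy
is never deformed, so pairs are born aligned.

Everything is driven by ``numpy.random.default_rng`` seeded from
``(seed, case_index)``: one seed reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import HU_MAX, HU_MIN, DoseGrid, ImageSlice, PairedSample

__all__ = [
    "ArtifactParams",
    "PhantomConfig",
    "DosePerturbation",
    "generate_anatomy",
    "corrupt_to_cbct",
    "generate_pair",
    "generate_dataset",
    "generate_dose_pair",
]


@dataclass
class ArtifactParams:
    """Amplitudes of the simulated cone-beam artifact components.

    bias_amplitude : HU, peak magnitude of the cupping/shading field at
        water-equivalent density (0 HU).
    bias_scale : pixels, correlation length of the random part of the bias.
    scatter_fraction : unitless fraction of wide-blurred object signal added
        back as haze.
    noise_sigma : HU, standard deviation of additive Gaussian noise.
    hu_shift : HU, constant calibration offset.
    """

    bias_amplitude: float = 35.0
    bias_scale: float = 40.0
    scatter_fraction: float = 0.02
    noise_sigma: float = 12.0
    hu_shift: float = 12.0

    def validate(self) -> None:
        for name in ("bias_amplitude", "bias_scale", "scatter_fraction", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PhantomConfig:
    image_size: int = 270
    pixel_spacing_mm: float = 1.0
    seed: int = 0
    n_cases: int = 65
    split: tuple[int, int, int] = (50, 5, 10)
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 2:
            raise ValueError("image_size must be even and >= 32")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if sum(self.split) != self.n_cases:
            raise ValueError("split must sum to n_cases")
        self.artifact_params.validate()


def _ellipse_mask(shape, center, semi_axes, angle_rad) -> np.ndarray:
    rows, cols = np.indices(shape).astype(np.float64)
    dr = rows - center[0]
    dc = cols - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def generate_anatomy(cfg: PhantomConfig, case_index: int) -> ImageSlice:
    """A randomized head-like slice: nested ellipses on an air background.

    Deterministic given ``(cfg.seed, case_index)``; per-case geometry
    (head size, tilt, lesions, cavities) is jittered so cases differ.
    """
    if case_index >= cfg.n_cases or case_index < 0:
        raise ValueError("case_index out of range for this configuration")
    rng = np.random.default_rng([cfg.seed, case_index])
    n = cfg.image_size
    img = np.full((n, n), -1000.0)

    center = (n / 2 + rng.uniform(-0.03, 0.03) * n, n / 2 + rng.uniform(-0.03, 0.03) * n)
    a = rng.uniform(0.33, 0.40) * n
    b = rng.uniform(0.28, 0.35) * n
    tilt = rng.uniform(-0.3, 0.3)

    head = _ellipse_mask(img.shape, center, (a, b), tilt)
    inner = _ellipse_mask(img.shape, center, (a * 0.88, b * 0.88), tilt)
    skull_hu = rng.uniform(700.0, 1200.0)
    brain_hu = rng.uniform(20.0, 50.0)
    img[head] = skull_hu
    img[inner] = brain_hu

    # low-contrast lesions inside the brain
    for _ in range(rng.integers(2, 5)):
        lc = (
            center[0] + rng.uniform(-0.5, 0.5) * b * 0.7,
            center[1] + rng.uniform(-0.5, 0.5) * a * 0.7,
        )
        lax = (rng.uniform(0.04, 0.10) * n, rng.uniform(0.04, 0.10) * n)
        lesion = _ellipse_mask(img.shape, lc, lax, rng.uniform(0, np.pi)) & inner
        sign = rng.choice([-1.0, 1.0])
        img[lesion] = brain_hu + sign * rng.uniform(10.0, 30.0)

    # air cavities (sinus-like), lower half of the head
    for _ in range(rng.integers(1, 3)):
        cc = (
            center[0] + rng.uniform(0.15, 0.45) * b,
            center[1] + rng.uniform(-0.3, 0.3) * a,
        )
        cax = (rng.uniform(0.02, 0.05) * n, rng.uniform(0.02, 0.06) * n)
        cavity = _ellipse_mask(img.shape, cc, cax, rng.uniform(0, np.pi)) & inner
        img[cavity] = -1000.0

    # soften structure boundaries slightly (partial-volume-like)
    img = ndimage.gaussian_filter(img, sigma=0.8)
    img = np.clip(img, HU_MIN, HU_MAX)
    spacing = (cfg.pixel_spacing_mm, cfg.pixel_spacing_mm)
    return ImageSlice(img, spacing_mm=spacing, modality_tag="CT")


def _bias_field(shape, bias_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Cupping-style radial polynomial plus seeded smoothed noise, max|B| = 1."""
    rows, cols = np.indices(shape).astype(np.float64)
    cr, cc = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    r2 = ((rows - cr) / cr) ** 2 + ((cols - cc) / cc) ** 2
    radial = 1.0 - 2.0 * np.clip(r2, 0, 1)  # +1 at centre, -1 at corners
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(bias_scale, 1e-6))
    peak = np.abs(noise).max()
    if peak > 0:
        noise = noise / peak
    field_ = 0.6 * radial + 0.4 * noise
    return field_ / np.abs(field_).max()


def corrupt_to_cbct(ct: ImageSlice, cfg: PhantomConfig,
                    rng: np.random.Generator) -> ImageSlice:
    """Degrade a CT slice into its CBCT counterpart (anatomy unchanged).

    Applied in order: multiplicative bias field scaled by local density,
    scatter haze, Gaussian noise, constant HU shift; result clipped to the
    representable HU range. With all amplitudes zero the output equals the
    input exactly.
    """
    p = cfg.artifact_params
    vals = ct.values.copy()
    density = np.clip((ct.values + 1000.0) / 1000.0, 0.0, None)

    bias = _bias_field(vals.shape, p.bias_scale, rng)
    vals = vals + p.bias_amplitude * bias * density

    if p.scatter_fraction > 0:
        haze = ndimage.gaussian_filter(ct.values + 1000.0, sigma=vals.shape[0] / 8.0)
        vals = vals + p.scatter_fraction * haze

    vals = vals + rng.normal(0.0, p.noise_sigma, size=vals.shape)

    vals = np.clip(vals + p.hu_shift, HU_MIN, HU_MAX)
    return ImageSlice(vals, spacing_mm=ct.spacing_mm, modality_tag="CBCT")


def generate_pair(cfg: PhantomConfig, case_index: int) -> PairedSample:
    ct = generate_anatomy(cfg, case_index)
    rng = np.random.default_rng([cfg.seed, case_index, 1])
    cbct = corrupt_to_cbct(ct, cfg, rng)
    return PairedSample(cbct=cbct, dct=ct, case_id=f"case{case_index:03d}")


def generate_dataset(cfg: PhantomConfig) -> dict[str, list[PairedSample]]:
    """All cases, partitioned into train/valid/test per ``cfg.split``."""
    n_train, n_valid, n_test = cfg.split
    pairs = [generate_pair(cfg, i) for i in range(cfg.n_cases)]
    return {
        "train": pairs[:n_train],
        "valid": pairs[n_train : n_train + n_valid],
        "test": pairs[n_train + n_valid :],
    }


@dataclass
class DosePerturbation:
    """Controllable surrogate for synthetic-CT-induced dose error."""

    shift_mm: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    noise_frac: float = 0.0


def generate_dose_pair(ct: ImageSlice, perturbation: DosePerturbation,
                       rng: np.random.Generator) -> tuple[DoseGrid, DoseGrid]:
    """Reference and perturbed-evaluated dose grids on a phantom slice.

    The reference is a superposition of 2-5 anisotropic Gaussian beam lobes
    centred inside the anatomy, normalised to a maximum of 1.0 arbitrary
    dose units. The evaluated grid is the reference shifted by ``shift_mm``,
    multiplied by ``scale`` and corrupted by proportional noise.
    """
    shift = np.atleast_1d(np.asarray(perturbation.shift_mm, dtype=float))
    if shift.size == 1:
        shift = np.array([shift[0], 0.0])
    if not np.all(np.isfinite([*shift, perturbation.scale, perturbation.noise_frac])):
        raise ValueError("perturbation values must be finite")
    extent = np.array(ct.shape) * np.array(ct.spacing_mm)
    if np.any(np.abs(shift) >= extent):
        raise ValueError("shift exceeds grid extent")

    n_lobes = int(rng.integers(2, 6))
    body = ct.values > -400.0
    coords = np.argwhere(body)
    if coords.size == 0:  # degenerate slice: aim at the centre
        coords = np.array([[s // 2 for s in ct.shape]])
    ref = np.zeros(ct.shape)
    rows, cols = np.indices(ct.shape).astype(np.float64)
    for _ in range(n_lobes):
        cr, cc = coords[rng.integers(len(coords))]
        sr = rng.uniform(0.04, 0.12) * ct.shape[0]
        sc = rng.uniform(0.04, 0.12) * ct.shape[1]
        th = rng.uniform(0, np.pi)
        amp = rng.uniform(0.5, 1.0)
        dr, dc = rows - cr, cols - cc
        u = np.cos(th) * dr + np.sin(th) * dc
        v = -np.sin(th) * dr + np.cos(th) * dc
        ref += amp * np.exp(-0.5 * ((u / sr) ** 2 + (v / sc) ** 2))
    ref /= ref.max()

    shift_px = shift / np.array(ct.spacing_mm)
    if np.any(shift_px != 0):
        ev = ndimage.shift(ref, shift_px, order=1, mode="nearest")
    else:
        ev = ref.copy()
    ev = ev * perturbation.scale
    if perturbation.noise_frac > 0:
        ev = ev * (1.0 + perturbation.noise_frac * rng.standard_normal(ev.shape))
    ev = np.clip(ev, 0.0, None)

    spacing = tuple(ct.spacing_mm)
    return (
        DoseGrid(ref, spacing_mm=spacing, role="reference"),
        DoseGrid(ev, spacing_mm=spacing, role="evaluated"),
    )
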