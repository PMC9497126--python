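"""Conventional image-similarity metrics (MAE in HU, SSIM, PSNR) and the
per-case/aggregate report container.

Metrics are computed in HU, never in normalised units. PSNR uses a fixed
3000 HU data range (the width of the normalisation clip window) so values
are comparable across cases; per-image ranges would not be. The default
evaluation region is the whole slice; an optional body mask (HU > -400
threshold, largest connected component) is provided because an air
background common to both images can inflate similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .losses import SSIMParams, ssim_value
from .types import ImageSlice

__all__ = [
    "PSNR_DATA_RANGE_HU",
    "mae_hu",
    "psnr_db",
    "ssim_metric",
    "body_mask",
    "MetricReport",
]

PSNR_DATA_RANGE_HU = 3000.0


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ImageSlice) else np.asarray(img, float)


def mae_hu(sct, dct, mask: np.ndarray | None = None) -> float:
    """Mean absolute HU difference over the mask (default: whole slice)."""
    a, b = _values(sct), _values(dct)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        return float(np.mean(np.abs(a - b)))
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return float(np.mean(np.abs(a[mask] - b[mask])))


def psnr_db(sct, dct, data_range: float = PSNR_DATA_RANGE_HU) -> float:
    """Peak signal-to-noise ratio; ``inf`` for identical images."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    a, b = _values(sct), _values(dct)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim_metric(sct, dct, params: SSIMParams | None = None) -> float:
    """Structural similarity with evaluation defaults (gaussian window 11,
    HU data range); delegates to the loss-side SSIM implementation."""
    if params is None:
        params = SSIMParams(window="gaussian", data_range=PSNR_DATA_RANGE_HU)
    return ssim_value(_values(sct), _values(dct), params)


def body_mask(img, threshold_hu: float = -400.0) -> np.ndarray:
    """Largest connected component of above-threshold pixels."""
    v = _values(img) > threshold_hu
    labels = measure.label(v)
    if labels.max() == 0:
        raise ValueError("no body found above threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


@dataclass
class MetricReport:
    """Per-case metric values and their aggregate for one loss configuration.

    ``per_case`` maps case_id -> {metric name -> value}; ``aggregate`` holds
    (mean, sd) per metric, with sd the sample standard deviation across
    cases (n-1 denominator).
    """

    config_tag: str = ""
    per_case: dict[str, dict[str, float]] = field(default_factory=dict)

    def add_case(self, case_id: str, **metrics: float) -> None:
        self.per_case[case_id] = dict(metrics)

    @property
    def metric_names(self) -> list[str]:
        names: list[str] = []
        for row in self.per_case.values():
            for k in row:
                if k not in names:
                    names.append(k)
        return names

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in self.metric_names:
            vals = np.array([row[name] for row in self.per_case.values()
                             if name in row], dtype=float)
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[name] = (float(vals.mean()), sd)
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for case_id, metrics in self.per_case.items():
            rows.append({"config": self.config_tag, "case_id": case_id, **metrics})
        return rows
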