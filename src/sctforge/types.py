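"""Core domain containers: HU image slices, paired samples, dose grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = ["ImageSlice", "PairedSample", "DoseGrid", "HU_MIN", "HU_MAX"]


@dataclass
class ImageSlice:
    """A 2-D axial slice in Hounsfield units.

    values : (rows, cols) float array, finite, within the 12-bit CT range
    spacing_mm : (row, col) pixel spacing in millimetres
    modality_tag : "CT", "CBCT" or "SCT"
    """

    values: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    modality_tag: str = "CT"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ImageSlice requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageSlice values must be finite")
        if self.values.min() < HU_MIN - 1e-6 or self.values.max() > HU_MAX + 1e-6:
            raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("pixel spacing must be positive")
        if self.modality_tag not in ("CT", "CBCT", "SCT"):
            raise ValueError(f"unknown modality tag {self.modality_tag!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PairedSample:
    """An aligned (CBCT input, deformed-CT target) slice pair."""

    cbct: ImageSlice
    dct: ImageSlice
    case_id: str = ""

    def __post_init__(self):
        if self.cbct.shape != self.dct.shape:
            raise ValueError("paired slices must share a shape")
        if self.cbct.spacing_mm != self.dct.spacing_mm:
            raise ValueError("paired slices must share pixel spacing")


@dataclass
class DoseGrid:
    """A 2-D or 3-D absorbed-dose grid (Gy or arbitrary units)."""

    values: np.ndarray
    spacing_mm: tuple = (1.0, 1.0)
    role: str = "reference"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError("DoseGrid must be 2-D or 3-D")
        if len(self.spacing_mm) != self.values.ndim:
            raise ValueError("spacing must have one entry per axis")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("dose values must be finite and non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.role not in ("reference", "evaluated"):
            raise ValueError(f"unknown dose role {self.role!r}")

    @property
    def shape(self):
        return self.values.shape
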