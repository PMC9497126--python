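"""Shared I/O: NIfTI/DICOM volume reading, dataset writing, run manifests,
and network checkpoints.

NIfTI is the interchange default; DICOM (series and RTDOSE) is read-only.
Conventions: 0-based indices, (row, col) = array axes, spacing in mm.
DICOM rescale slope/intercept is always applied; missing rescale tags are
an explicit error, never a silent default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .fcdensenet import FCDenseNet, NetworkConfig
from .types import DoseGrid, ImageSlice
from .phantom import PhantomConfig, generate_dataset

__all__ = [
    "read_volume",
    "write_volume",
    "write_dataset",
    "load_dataset",
    "RunManifest",
    "save_checkpoint",
    "load_checkpoint",
    "config_hash",
]


def write_volume(path, values: np.ndarray, spacing_mm) -> None:
    """Write a 2-D or 3-D array as NIfTI with the given spacing."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    affine = np.diag(list(spacing_mm) + [1.0] * (4 - values.ndim))
    nib.save(nib.Nifti1Image(values, affine), str(path))


def _read_dicom_dir(path: Path):
    import pydicom

    files = sorted(path.glob("*.dcm")) or sorted(
        p for p in path.iterdir() if p.is_file()
    )
    if not files:
        raise ValueError(f"no DICOM files in {path}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise ValueError(f"{f.name}: missing RescaleSlope/RescaleIntercept")
        arr = ds.pixel_array * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append((int(getattr(ds, "InstanceNumber", 0)), arr, ds))
    slices.sort(key=lambda t: t[0])
    ds0 = slices[0][2]
    spacing = tuple(float(s) for s in ds0.PixelSpacing)
    vol = np.stack([s[1] for s in slices])
    return vol, spacing


def _read_rtdose(path: Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(ds.DoseGridScaling)
    vals = ds.pixel_array * scaling
    row_sp, col_sp = (float(s) for s in ds.PixelSpacing)
    if vals.ndim == 3:
        offsets = [float(x) for x in ds.GridFrameOffsetVector]
        dz = abs(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
        return DoseGrid(vals, spacing_mm=(dz, row_sp, col_sp), role="reference")
    return DoseGrid(vals, spacing_mm=(row_sp, col_sp), role="reference")


def read_volume(path):
    """Read a NIfTI file, DICOM series directory, or RTDOSE file.

    Returns ``(values, spacing_mm)`` for images or a :class:`DoseGrid` for
    RTDOSE. HU rescaling is applied for DICOM images.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return data, spacing
    if path.is_dir():
        return _read_dicom_dir(path)
    if name.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        if getattr(ds, "Modality", "") == "RTDOSE":
            return _read_rtdose(path)
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise ValueError(f"{path.name}: missing RescaleSlope/RescaleIntercept")
        arr = ds.pixel_array * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        return arr, tuple(float(s) for s in ds.PixelSpacing)
    raise ValueError(f"unknown volume format: {path}")


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    dataset_path: str = ""
    splits: dict = field(default_factory=dict)  # split -> list of case ids
    seed: int = 0
    config_hashes: dict = field(default_factory=dict)
    version: str = __version__

    def validate(self) -> None:
        ids = [set(v) for v in self.splits.values()]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if ids[i] & ids[j]:
                    raise ValueError("split case lists must be disjoint")

    def save(self, path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        m = cls(**json.loads(Path(path).read_text()))
        m.validate()
        return m


def write_dataset(cfg: PhantomConfig, out_dir) -> RunManifest:
    """Generate the phantom dataset and write it as NIfTI plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(cfg)
    splits = {}
    for split, pairs in data.items():
        splits[split] = [p.case_id for p in pairs]
        for p in pairs:
            sp = (cfg.pixel_spacing_mm, cfg.pixel_spacing_mm)
            write_volume(out / f"{p.case_id}_cbct.nii", p.cbct.values, sp)
            write_volume(out / f"{p.case_id}_dct.nii", p.dct.values, sp)
    manifest = RunManifest(
        dataset_path=str(out),
        splits=splits,
        seed=cfg.seed,
        config_hashes={"phantom": config_hash(cfg.__dict__)},
    )
    manifest.save(out / "manifest.json")
    return manifest


def load_dataset(data_dir):
    """Load a written dataset back into split -> list of PairedSample."""
    from .types import PairedSample

    data_dir = Path(data_dir)
    manifest = RunManifest.load(data_dir / "manifest.json")
    out = {}
    for split, ids in manifest.splits.items():
        pairs = []
        for case_id in ids:
            cb, sp = read_volume(data_dir / f"{case_id}_cbct.nii")
            dc, _ = read_volume(data_dir / f"{case_id}_dct.nii")
            pairs.append(
                PairedSample(
                    cbct=ImageSlice(cb, spacing_mm=sp, modality_tag="CBCT"),
                    dct=ImageSlice(dc, spacing_mm=sp, modality_tag="CT"),
                    case_id=case_id,
                )
            )
        out[split] = pairs
    return out


def save_checkpoint(path, net: FCDenseNet, train_seed: int | None = None) -> None:
    """Parameters + NetworkConfig + training seed in one .npz file."""
    state = net.state_dict()
    meta = {"config": net.cfg.to_dict(), "train_seed": train_seed,
            "version": __version__}
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> FCDenseNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    net = FCDenseNet(NetworkConfig.from_dict(meta["config"]))
    net.load_state_dict(state)
    net.eval()
    return net
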