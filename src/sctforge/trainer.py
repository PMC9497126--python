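"""Training loop for the CBCT -> synthetic-CT network.

Protocol: Adam optimisation (default initial learning rate 2e-5, 150
epochs) with on-the-fly augmentation — horizontal flip and random rotation
applied with identical geometric parameters to input and target (pair
integrity), random Gaussian blur applied to the input only, since blur
emulates imaging degradation and must not alter the learning target.

Model selection keeps the checkpoint with the best validation MAE. All
randomness (batch shuffling, augmentation, dropout) descends from the
config seed, so a run is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fcdensenet import FCDenseNet
from .losses import (
    FeatureExtractor,
    LossConfig,
    combined_loss,
    hu_to_unit,
    loss_components,
    unit_to_hu,
)
from .nn import Adam, Tensor
from .types import HU_MAX, HU_MIN, ImageSlice, PairedSample

__all__ = ["AugmentConfig", "TrainConfig", "augment_pair", "train", "synthesize"]


@dataclass
class AugmentConfig:
    hflip_prob: float = 0.5
    rotation_max_deg: float = 10.0
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    apply_prob: float = 0.5


@dataclass
class TrainConfig:
    epochs: int = 150
    learning_rate: float = 2e-5
    optimizer: str = "adam"
    batch_size: int = 8
    seed: int = 0
    loss: LossConfig = field(default_factory=lambda: LossConfig.preset("LPS"))
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    valid_fraction: float = 0.1  # used only when no explicit valid set is given

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def augment_pair(sample: PairedSample, augment_cfg: AugmentConfig,
                 rng: np.random.Generator) -> PairedSample:
    """Randomly flip/rotate the pair jointly and blur the input only."""
    if rng.random() >= augment_cfg.apply_prob:
        return sample
    cb = sample.cbct.values
    dc = sample.dct.values
    if rng.random() < augment_cfg.hflip_prob:
        cb = cb[:, ::-1]
        dc = dc[:, ::-1]
    theta = rng.uniform(-augment_cfg.rotation_max_deg, augment_cfg.rotation_max_deg)
    if abs(theta) > 1e-9:
        cb = ndimage.rotate(cb, theta, reshape=False, order=1, cval=-1000.0)
        dc = ndimage.rotate(dc, theta, reshape=False, order=1, cval=-1000.0)
    lo, hi = augment_cfg.blur_sigma_range
    sigma = rng.uniform(lo, hi)
    if sigma > 1e-6:
        cb = ndimage.gaussian_filter(cb, sigma)
    cb = np.clip(cb, HU_MIN, HU_MAX)
    dc = np.clip(dc, HU_MIN, HU_MAX)
    return PairedSample(
        cbct=ImageSlice(cb.copy(), sample.cbct.spacing_mm, "CBCT"),
        dct=ImageSlice(dc.copy(), sample.dct.spacing_mm, "CT"),
        case_id=sample.case_id,
    )


def _batch_tensor(samples: list[PairedSample]) -> tuple[Tensor, Tensor]:
    xs = np.stack([hu_to_unit(s.cbct.values) for s in samples])[:, None]
    ys = np.stack([hu_to_unit(s.dct.values) for s in samples])[:, None]
    return Tensor(xs), Tensor(ys)


def _validation_mae_hu(net: FCDenseNet, samples: list[PairedSample]) -> float:
    net.eval()
    errs = []
    for s in samples:
        sct = synthesize(net, s.cbct)
        errs.append(float(np.mean(np.abs(sct.values - s.dct.values))))
    net.train()
    return float(np.mean(errs))


def train(dataset: list[PairedSample], net: FCDenseNet, cfg: TrainConfig,
          valid: list[PairedSample] | None = None,
          extractor: FeatureExtractor | None = None):
    """Train the network; returns ``(net, history)``.

    ``history`` is a list of per-epoch dicts holding the mean of every
    enabled loss component and the validation MAE in HU. The parameters of
    the best-validation epoch are restored into ``net`` before returning.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    if valid is None:
        n_valid = max(1, int(round(cfg.valid_fraction * len(dataset))))
        if n_valid >= len(dataset):
            raise ValueError("dataset too small to carve out a validation split")
        valid = dataset[-n_valid:]
        dataset = dataset[:-n_valid]
    if cfg.loss.use_perceptual and extractor is None:
        extractor = FeatureExtractor.seeded_random()

    rng = np.random.default_rng(cfg.seed)
    net.drop_rng = np.random.default_rng([cfg.seed, 0xD0])
    _reseed_dropout(net, net.drop_rng)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)

    history: list[dict] = []
    best = (math.inf, None)
    net.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [augment_pair(dataset[i], cfg.augment, rng) for i in idx]
            x, y = _batch_tensor(batch)
            pred = net(x)
            comps = loss_components(y, pred, cfg.loss, extractor)
            total = None
            w = {"l1": cfg.loss.weights[0], "ssim": cfg.loss.weights[1],
                 "perceptual": cfg.loss.weights[2]}
            for name, val in comps.items():
                term = w[name] * val
                total = term if total is None else total + term
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            for name, val in comps.items():
                sums[name] = sums.get(name, 0.0) + val.item()
            sums["total"] = sums.get("total", 0.0) + total.item()
            n_batches += 1
        record = {k: v / n_batches for k, v in sums.items()}
        record["epoch"] = epoch
        record["valid_mae_hu"] = _validation_mae_hu(net, valid)
        history.append(record)
        if record["valid_mae_hu"] < best[0]:
            best = (record["valid_mae_hu"], net.state_dict())
    if best[1] is not None:
        net.load_state_dict(best[1])
    net.eval()
    return net, history


def _reseed_dropout(module, rng: np.random.Generator) -> None:
    from .nn.layers import Dropout

    if isinstance(module, Dropout):
        module.rng = rng
    for child in module._children.values():
        _reseed_dropout(child, rng)


def synthesize(net: FCDenseNet, cbct: ImageSlice) -> ImageSlice:
    """Run inference on one CBCT slice and return the synthetic CT in HU."""
    was_training = net.training
    net.eval()
    x = Tensor(hu_to_unit(cbct.values)[None, None])
    out = net(x).data[0, 0]
    if was_training:
        net.train()
    hu = np.clip(unit_to_hu(out), HU_MIN, HU_MAX)
    return ImageSlice(hu, spacing_mm=cbct.spacing_mm, modality_tag="SCT")
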