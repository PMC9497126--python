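"""Feature mapping ratio (FMR): feature detection in a nonlinear scale
space, binary descriptors, brute-force Hamming matching, and the ratio of
matched to detected features.

The pipeline follows the KAZE/A-KAZE family. A nonlinear scale space is
built by conductance-weighted (Perona-Malik g2) diffusion, which smooths
homogeneous regions while preserving edges. Feature points are local
extrema of adjacent-level difference images over 3x3 spatial x 3-level
neighbourhoods. Each keypoint gets a 256-bit binary descriptor of pairwise
brightness/gradient comparisons over a grid of sub-regions in a
scale-proportional patch ("b brighter than a" -> bit 1), sampled from the
keypoint's evolution level; the comparison schedule is fixed by a package
constant so descriptors are stable across runs and machines. Matching is
brute force: nearest neighbour by Hamming distance, accepted when the
normalised distance (fraction of differing bits) is below the threshold
(default 0.8) and the pair is mutual-nearest, yielding one-to-one matches.

FMR = n_matched / n_detected. "Detected" defaults to the first (synthetic)
image's keypoint count; ``min`` and ``mean`` denominators are provided
because the convention is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageSlice

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleSpaceConfig",
    "ScaleSpace",
    "FeatureSet",
    "MatchResult",
    "build_nonlinear_scale_space",
    "detect_features",
    "describe",
    "match_bruteforce",
    "fmr",
]

# Fixed seed of the descriptor comparison schedule; a package constant so
# that descriptors are byte-identical across runs and machines.
DESCRIPTOR_SCHEDULE_SEED = 0xA5CA1E

_POPCOUNT = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(1)


@dataclass
class ScaleSpaceConfig:
    n_octaves: int = 3
    n_sublevels: int = 4
    diffusivity: str = "pm_g2"
    contrast_percentile: float = 70.0
    detection_threshold: float = 1e-3
    sigma0: float = 1.6
    max_keypoints: int = 2000
    descriptor_bits: int = 256
    patch_scale: float = 3.0

    def __post_init__(self):
        if self.n_octaves < 1 or self.n_sublevels < 1:
            raise ValueError("n_octaves and n_sublevels must be >= 1")
        if self.detection_threshold < 0 or self.contrast_percentile <= 0:
            raise ValueError("thresholds must be non-negative")
        if self.diffusivity != "pm_g2":
            raise ValueError("only the Perona-Malik g2 diffusivity is provided")


@dataclass
class ScaleSpace:
    levels: list[np.ndarray]  # smoothed images, increasing scale
    sigmas: list[float]
    contrast_k: float


def _normalize(img) -> np.ndarray:
    v = img.values if isinstance(img, ImageSlice) else np.asarray(img, float)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _diffusion_step(L: np.ndarray, g: np.ndarray, tau: float) -> np.ndarray:
    """One conservative explicit step of div(g grad L), Neumann boundaries.

    Fluxes are evaluated at half points with averaged conductance; zero
    flux through the boundary makes the total intensity sum invariant.
    """
    gr = 0.5 * (g[1:, :] + g[:-1, :])  # vertical half-point conductance
    gc = 0.5 * (g[:, 1:] + g[:, :-1])
    fr = gr * (L[1:, :] - L[:-1, :])  # flux across row interfaces
    fc = gc * (L[:, 1:] - L[:, :-1])
    out = L.copy()
    out[:-1, :] += tau * fr
    out[1:, :] -= tau * fr
    out[:, :-1] += tau * fc
    out[:, 1:] -= tau * fc
    return out


def _conductance(L: np.ndarray, k: float) -> np.ndarray:
    gy, gx = np.gradient(L)
    return 1.0 / (1.0 + (gx**2 + gy**2) / (k**2))


def estimate_contrast(img, cfg: ScaleSpaceConfig | None = None) -> float:
    """Perona-Malik contrast parameter k: a percentile of the gradient
    magnitude of the lightly smoothed, normalised image."""
    cfg = cfg or ScaleSpaceConfig()
    v = _normalize(img)
    grad = np.hypot(*np.gradient(ndimage.gaussian_filter(v, 1.0)))
    nz = grad[grad > 0]
    k = float(np.percentile(nz, cfg.contrast_percentile)) if nz.size else 1e-2
    # floor at 1% contrast per pixel: a percentile over a nearly flat
    # image would otherwise freeze the diffusion entirely
    return max(k, 1e-2)


def build_nonlinear_scale_space(img, cfg: ScaleSpaceConfig | None = None,
                                contrast_k: float | None = None) -> ScaleSpace:
    """Evolve the image through increasing diffusion times t = sigma^2 / 2.

    ``contrast_k`` overrides the image-adaptive contrast parameter; when
    two images are compared, a shared k diffuses them identically.
    """
    cfg = cfg or ScaleSpaceConfig()
    v = _normalize(img)
    if min(v.shape) < 32:
        raise ValueError("image too small for scale-space analysis (min side 32)")
    base = ndimage.gaussian_filter(v, 1.0)  # lightly smoothed input, level 0
    k = contrast_k if contrast_k is not None else estimate_contrast(img, cfg)

    n_levels = cfg.n_octaves * cfg.n_sublevels
    sigmas = [cfg.sigma0 * 2.0 ** (i / cfg.n_sublevels) for i in range(n_levels)]
    times = [0.5 * s**2 for s in sigmas]

    levels = [base]
    L = base
    t_prev = 0.0
    tau_max = 0.24  # just under the 0.25 explicit-scheme stability limit
    for t in times:
        dt = t - t_prev
        n_steps = max(1, int(np.ceil(dt / tau_max)))
        tau = dt / n_steps
        for _ in range(n_steps):
            g = _conductance(L, k)
            L = _diffusion_step(L, g, tau)
        levels.append(L)
        t_prev = t
    return ScaleSpace(levels=levels[1:], sigmas=sigmas, contrast_k=k)


def detect_features(space: ScaleSpace, cfg: ScaleSpaceConfig | None = None,
                    border_margin: int = 8) -> np.ndarray:
    """Keypoints as an (n, 4) array of (row, col, level_index, response).

    Extrema of adjacent-level difference images over 3x3x3 neighbourhoods
    with |response| above the detection threshold; a spatial border margin
    is excluded. Sorted by decreasing |response| (row, col tie-break) and
    capped at ``max_keypoints``.
    """
    cfg = cfg or ScaleSpaceConfig()
    if len(space.levels) < 3:
        raise ValueError("need at least 3 scale-space levels")
    D = np.stack([b - a for a, b in zip(space.levels[:-1], space.levels[1:])])
    if D.shape[0] < 3:
        return np.empty((0, 4))
    mx = ndimage.maximum_filter(D, size=(3, 3, 3), mode="nearest")
    mn = ndimage.minimum_filter(D, size=(3, 3, 3), mode="nearest")
    is_ext = ((D == mx) | (D == mn)) & (np.abs(D) > cfg.detection_threshold)
    is_ext[0] = is_ext[-1] = False  # need a full 3-level neighbourhood
    m = border_margin
    mask = np.zeros_like(is_ext)
    if D.shape[1] > 2 * m and D.shape[2] > 2 * m:
        mask[:, m:-m, m:-m] = True
    is_ext &= mask
    lev, rows, cols = np.nonzero(is_ext)
    resp = D[lev, rows, cols]
    kps = np.column_stack([rows, cols, lev, resp]).astype(float)
    order = np.lexsort((cols, rows, -np.abs(resp)))
    return kps[order][: cfg.max_keypoints]


def _comparison_schedule(n_values: int, n_bits: int) -> np.ndarray:
    rng = np.random.default_rng(DESCRIPTOR_SCHEDULE_SEED)
    pairs = []
    seen = set()
    while len(pairs) < n_bits:
        i, j = rng.integers(0, n_values, size=2)
        if i == j or (i, j) in seen:
            continue
        seen.add((int(i), int(j)))
        pairs.append((int(i), int(j)))
    return np.array(pairs, dtype=int)


@dataclass
class FeatureSet:
    """Keypoints plus their fixed-length binary descriptors."""

    keypoints: np.ndarray  # (n, 4): row, col, scale(sigma), response
    descriptors: np.ndarray  # (n, n_bits) bool

    def __post_init__(self):
        if len(self.keypoints) != len(self.descriptors):
            raise ValueError("keypoints and descriptors must align")

    def __len__(self):
        return len(self.keypoints)

    @property
    def packed(self) -> np.ndarray:
        return np.packbits(self.descriptors.astype(np.uint8), axis=1)


def describe(space: ScaleSpace, keypoints: np.ndarray,
             cfg: ScaleSpaceConfig | None = None) -> FeatureSet:
    """Binary descriptors from pairwise comparisons of sub-region statistics.

    For each keypoint a square patch of half-width ``patch_scale * sigma``
    (>= 4 px) at the keypoint's evolution level is sampled on a 12x12 grid,
    grouped into 4x4 cells; each cell contributes its mean intensity and
    mean first derivatives (48 values). Bit i is 1 iff value p_i > value
    q_i under the fixed seeded comparison schedule. Comparisons of means
    are invariant to global additive intensity offsets. Keypoints whose
    patch leaves the image are dropped (logged).
    """
    cfg = cfg or ScaleSpaceConfig()
    n_cells = 4
    n_sub = 3  # samples per cell side
    n_values = 3 * n_cells * n_cells
    schedule = _comparison_schedule(n_values, cfg.descriptor_bits)

    if len(keypoints) == 0:
        return FeatureSet(np.empty((0, 4)), np.empty((0, cfg.descriptor_bits), bool))

    H, W = space.levels[0].shape
    grads = {}
    out_kps, out_desc = [], []
    # process per level so each image/derivative is interpolated once
    for lev in sorted(set(int(k[2]) for k in keypoints)):
        sel = keypoints[keypoints[:, 2].astype(int) == lev]
        sigma = space.sigmas[lev]
        R = max(4.0, cfg.patch_scale * sigma)
        inside = (
            (sel[:, 0] - R >= 0) & (sel[:, 0] + R <= H - 1)
            & (sel[:, 1] - R >= 0) & (sel[:, 1] + R <= W - 1)
        )
        if not inside.all():
            logger.debug("dropping %d border keypoints at level %d",
                         int((~inside).sum()), lev)
        sel = sel[inside]
        if len(sel) == 0:
            continue
        if lev not in grads:
            gy, gx = np.gradient(space.levels[lev])
            grads[lev] = (space.levels[lev], gy, gx)
        L, gy, gx = grads[lev]
        grid = np.linspace(-R, R, n_cells * n_sub)
        rr = sel[:, 0][:, None, None] + grid[None, :, None]  # (n, 12, 1)
        cc = sel[:, 1][:, None, None] + grid[None, None, :]  # (n, 1, 12)
        coords = np.stack(np.broadcast_arrays(rr, cc))  # (2, n, 12, 12)
        vals = []
        for ch in (L, gy, gx):
            s = ndimage.map_coordinates(ch, coords.reshape(2, -1), order=1)
            s = s.reshape(len(sel), n_cells, n_sub, n_cells, n_sub)
            vals.append(s.mean(axis=(2, 4)).reshape(len(sel), -1))  # (n, 16)
        v = np.concatenate(vals, axis=1)  # (n, 48)
        bits = v[:, schedule[:, 0]] > v[:, schedule[:, 1]]
        for k, b in zip(sel, bits):
            out_kps.append([k[0], k[1], sigma, k[3]])
            out_desc.append(b)
    if not out_kps:
        return FeatureSet(np.empty((0, 4)), np.empty((0, cfg.descriptor_bits), bool))
    return FeatureSet(np.array(out_kps), np.array(out_desc))


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (index_a, index_b, normalised distance)
    n_detected_a: int
    n_detected_b: int


def _hamming_matrix(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances (bit counts) between packed descriptors."""
    x = np.bitwise_xor(pa[:, None, :], pb[None, :, :])
    return _POPCOUNT[x].sum(axis=2)


def match_bruteforce(fa: FeatureSet, fb: FeatureSet,
                     threshold: float = 0.8, mode: str = "hamming") -> MatchResult:
    """One-to-one descriptor matching by exhaustive comparison.

    mode="hamming": accept the nearest neighbour when its normalised
    Hamming distance (fraction of differing bits) is strictly below
    ``threshold`` and the pair is mutual-nearest. mode="ratio" applies the
    Lowe ratio test (best/second-best < threshold) instead of the absolute
    threshold, still requiring mutual nearest. Ties break to the lowest
    index.
    """
    if mode not in ("hamming", "ratio"):
        raise ValueError("mode must be 'hamming' or 'ratio'")
    na, nb = len(fa), len(fb)
    if na == 0 or nb == 0:
        return MatchResult([], na, nb)
    if fa.descriptors.shape[1] != fb.descriptors.shape[1]:
        raise ValueError("descriptor bit lengths differ")
    n_bits = fa.descriptors.shape[1]
    D = _hamming_matrix(fa.packed, fb.packed)
    row_min = D.min(axis=1)
    col_min = D.min(axis=0)
    # mutual-nearest candidates, keeping all ties: D[i,j] must be minimal
    # in both its row and its column; ties are then resolved one-to-one
    # greedily by increasing (distance, index)
    cand_i, cand_j = np.nonzero((D == row_min[:, None]) & (D == col_min[None, :]))
    cand_d = D[cand_i, cand_j]
    order = np.lexsort((cand_j, cand_i, cand_d))
    used_a = np.zeros(na, bool)
    used_b = np.zeros(nb, bool)
    pairs = []
    for k in order:
        ia, ib, d = int(cand_i[k]), int(cand_j[k]), int(cand_d[k])
        if used_a[ia] or used_b[ib]:
            continue
        dist = d / n_bits
        if mode == "hamming":
            accept = dist < threshold
        else:  # Lowe ratio against the second-best in the row
            row = D[ia].astype(float).copy()
            row[ib] = np.inf
            second = row.min()
            accept = (d == 0) if second == 0 else (d / second) < threshold
        if accept:
            used_a[ia] = used_b[ib] = True
            pairs.append((ia, ib, float(dist)))
    return MatchResult(pairs, na, nb)


def fmr(img_a, img_b, cfg: ScaleSpaceConfig | None = None,
        threshold: float = 0.8, denominator: str = "first") -> float:
    """Feature mapping ratio between two images (first = synthetic by
    convention): matched feature count over detected feature count."""
    cfg = cfg or ScaleSpaceConfig()
    # one contrast scale for both images: diffusing each with its own
    # adaptive k would smooth a degraded image harder and mask degradation
    k = estimate_contrast(img_a, cfg)
    sa = build_nonlinear_scale_space(img_a, cfg, contrast_k=k)
    sb = build_nonlinear_scale_space(img_b, cfg, contrast_k=k)
    fa = describe(sa, detect_features(sa, cfg), cfg)
    fb = describe(sb, detect_features(sb, cfg), cfg)
    if len(fa) == 0:
        logger.warning("no features detected in first image; FMR set to 0")
        return 0.0
    res = match_bruteforce(fa, fb, threshold=threshold)
    if denominator == "first":
        den = len(fa)
    elif denominator == "min":
        den = min(len(fa), len(fb)) or 1
    elif denominator == "mean":
        den = 0.5 * (len(fa) + len(fb))
    else:
        raise ValueError("denominator must be 'first', 'min' or 'mean'")
    return len(res.pairs) / den
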