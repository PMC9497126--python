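"""Nonlinear scale space, detection, binary descriptors, Hamming matching,
and the feature-mapping-ratio statistic."""

import numpy as np
import pytest
from scipy import ndimage

from sctforge.feature_fmr import (
    FeatureSet,
    MatchResult,
    ScaleSpaceConfig,
    build_nonlinear_scale_space,
    describe,
    detect_features,
    estimate_contrast,
    fmr,
    match_bruteforce,
)


def match_oracle(fa: FeatureSet, fb: FeatureSet, threshold: float = 0.8):
    """Plain-Python O(n^2) re-implementation of the acceptance rule:
    mutual row/column-minimal candidates, greedy one-to-one by increasing
    (distance, index), accepted below the normalised threshold."""
    na, nb = len(fa), len(fb)
    if na == 0 or nb == 0:
        return []
    n_bits = fa.descriptors.shape[1]
    D = [[int(np.sum(fa.descriptors[i] != fb.descriptors[j])) for j in range(nb)]
         for i in range(na)]
    row_min = [min(row) for row in D]
    col_min = [min(D[i][j] for i in range(na)) for j in range(nb)]
    cands = sorted(
        (D[i][j], i, j)
        for i in range(na)
        for j in range(nb)
        if D[i][j] == row_min[i] and D[i][j] == col_min[j]
    )
    used_a, used_b, pairs = set(), set(), []
    for d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        if d / n_bits < threshold:
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j, d / n_bits))
    return pairs


def _random_featureset(rng, n, n_bits=256):
    return FeatureSet(
        keypoints=np.column_stack(
            [rng.uniform(10, 50, n), rng.uniform(10, 50, n),
             np.full(n, 1.6), rng.normal(size=n)]
        ),
        descriptors=rng.random((n, n_bits)) < 0.5,
    )


class TestScaleSpace:
    def test_constant_image_is_fixed_point(self):
        space = build_nonlinear_scale_space(np.full((64, 64), 200.0))
        for lev in space.levels:
            assert np.allclose(lev, lev[0, 0])

    def test_intensity_sum_conserved(self, head_image):
        """Zero-flux boundaries conserve the total intensity through the
        whole evolution to within 0.1%."""
        space = build_nonlinear_scale_space(head_image)
        first = space.levels[0].sum()
        for lev in space.levels[1:]:
            assert abs(lev.sum() - first) <= 1e-3 * abs(first)

    def test_edge_survives_better_than_gaussian(self):
        """A step edge keeps a sharper gradient under conductance-weighted
        diffusion than under Gaussian blur of equivalent scale."""
        img = np.zeros((64, 64))
        img[:, 32:] = 1000.0
        cfg = ScaleSpaceConfig()
        space = build_nonlinear_scale_space(img, cfg)
        late = space.levels[-1]
        sigma_eq = space.sigmas[-1]
        gauss = ndimage.gaussian_filter(space.levels[0], sigma_eq)
        edge_nl = np.abs(np.gradient(late, axis=1))[:, 28:36].max()
        edge_g = np.abs(np.gradient(gauss, axis=1))[:, 28:36].max()
        assert edge_nl / edge_g > 1.0

    def test_scales_increase(self, head_image):
        space = build_nonlinear_scale_space(head_image)
        assert all(b > a for a, b in zip(space.sigmas, space.sigmas[1:]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_nonlinear_scale_space(np.zeros((16, 16)))


class TestDetection:
    def test_constant_image_yields_no_keypoints(self):
        space = build_nonlinear_scale_space(np.full((64, 64), 10.0))
        assert len(detect_features(space)) == 0

    def test_bright_blob_detected_near_center(self):
        img = np.zeros((64, 64))
        rows, cols = np.indices(img.shape)
        img += 800 * np.exp(-((rows - 31) ** 2 + (cols - 33) ** 2) / (2 * 3.0**2))
        space = build_nonlinear_scale_space(img)
        kps = detect_features(space)
        assert len(kps) >= 1
        d = np.hypot(kps[:, 0] - 31, kps[:, 1] - 33)
        assert d.min() <= 2.0

    def test_infinite_threshold_suppresses_all(self, head_image):
        cfg = ScaleSpaceConfig(detection_threshold=np.inf)
        space = build_nonlinear_scale_space(head_image, cfg)
        assert len(detect_features(space, cfg)) == 0


class TestDescriptors:
    def test_identical_keypoints_identical_descriptors(self, head_image):
        space = build_nonlinear_scale_space(head_image)
        kps = detect_features(space)
        a = describe(space, kps)
        b = describe(space, kps)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_invariant_to_additive_offset(self, head_image):
        cfg = ScaleSpaceConfig()
        k = estimate_contrast(head_image, cfg)
        sa = build_nonlinear_scale_space(head_image, cfg, contrast_k=k)
        sb = build_nonlinear_scale_space(head_image + 100.0, cfg, contrast_k=k)
        fa = describe(sa, detect_features(sa, cfg), cfg)
        fb = describe(sb, detect_features(sb, cfg), cfg)
        assert len(fa) == len(fb) > 0
        assert np.array_equal(fa.descriptors, fb.descriptors)

    def test_contrast_inversion_complements_descriptors(self, rng):
        """Negating the image flips every strict pairwise comparison, so
        descriptors become bitwise complements (ties excluded by using a
        smooth random patch)."""
        img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0) * 500
        cfg = ScaleSpaceConfig()
        k = estimate_contrast(img, cfg)
        sa = build_nonlinear_scale_space(img, cfg, contrast_k=k)
        kps = detect_features(sa, cfg)
        fa = describe(sa, kps, cfg)
        # evolve the negated image through the identical diffusion
        sb_levels = [-lev for lev in sa.levels]
        sb = type(sa)(levels=sb_levels, sigmas=sa.sigmas, contrast_k=sa.contrast_k)
        fb = describe(sb, kps, cfg)
        assert len(fa) > 0
        assert np.array_equal(fa.descriptors, ~fb.descriptors)


class TestMatching:
    def test_self_match_all_zero_distance(self, rng):
        fa = _random_featureset(rng, 40)
        res = match_bruteforce(fa, fa)
        assert len(res.pairs) == 40
        assert all(d == 0.0 for _, _, d in res.pairs)

    def test_complemented_descriptor_at_maximal_distance(self, rng):
        """A descriptor and its bitwise complement differ in every bit:
        normalised distance exactly 1.0, which the 0.8 threshold rejects."""
        fa = _random_featureset(rng, 1)
        fb = FeatureSet(fa.keypoints.copy(), ~fa.descriptors)
        assert int((fa.descriptors[0] != fb.descriptors[0]).sum()) == 256
        assert match_bruteforce(fa, fb).pairs == []

    def test_accepted_matches_respect_threshold(self, rng):
        fa = _random_featureset(rng, 30)
        fb = FeatureSet(fa.keypoints.copy(), ~fa.descriptors)
        res = match_bruteforce(fa, fb, threshold=0.4)
        assert all(d < 0.4 for _, _, d in res.pairs)

    def test_one_to_one(self, rng):
        fa = _random_featureset(rng, 60)
        fb = _random_featureset(np.random.default_rng(7), 80)
        res = match_bruteforce(fa, fb, threshold=0.9)
        assert len({p[0] for p in res.pairs}) == len(res.pairs)
        assert len({p[1] for p in res.pairs}) == len(res.pairs)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(20, 200, size=2)
        fa = _random_featureset(rng, int(na))
        fb = _random_featureset(rng, int(nb))
        # embed some true correspondences with light corruption
        n_true = 15
        fb.descriptors[:n_true] = fa.descriptors[:n_true]
        flip = rng.random((n_true, 256)) < 0.03
        fb.descriptors[:n_true] ^= flip
        fast = match_bruteforce(fa, fb)
        slow = match_oracle(fa, fb)
        assert sorted(fast.pairs) == sorted(slow)

    def test_bitlength_mismatch_rejected(self, rng):
        fa = _random_featureset(rng, 5, n_bits=256)
        fb = _random_featureset(rng, 5, n_bits=128)
        with pytest.raises(ValueError):
            match_bruteforce(fa, fb)


class TestFMR:
    def test_self_fmr_is_one(self, head_image):
        assert fmr(head_image, head_image) == 1.0

    def test_bounded_in_unit_interval(self, head_image, rng):
        for _ in range(5):
            noisy = np.clip(
                head_image + rng.normal(0, 40, head_image.shape), -1024, 3071
            )
            v = fmr(head_image, noisy)
            assert 0.0 <= v <= 1.0

    def test_pure_noise_reduces_fmr(self, head_image, rng):
        noise = rng.normal(0, 300, head_image.shape)
        v = fmr(head_image, np.clip(noise, -1024, 3071))
        assert v < fmr(head_image, head_image)

    def test_featureless_first_image_gives_zero(self, head_image):
        assert fmr(np.full((64, 64), 30.0), head_image[:64, :64]) == 0.0

    def test_noise_degrades_fmr_monotonically(self, head_image):
        """Mean FMR over seeds decreases across rising noise levels."""
        means = []
        for sigma in (0, 20, 60):
            vals = [
                fmr(head_image, np.clip(
                    head_image
                    + np.random.default_rng(s).normal(0, sigma, head_image.shape),
                    -1024, 3071))
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
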