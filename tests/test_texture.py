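"""Texture features: exclusion rule, LoG filter, histogram and GLCM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from texturesurv import (
    FilterSpec,
    LesionImage,
    apply_exclusion_rule,
    build_glcm,
    extract_features,
    glcm_features,
    histogram_features,
    log_filter,
    log_kernel,
)
from texturesurv.synthetic import SyntheticConfig, generate_lesion
from texturesurv.texture import (
    DEFAULT_OFFSETS,
    DegenerateROIError,
    NoAnalyzablePixelsError,
)

from conftest import naive_glcm, naive_glcm_features, random_masked_image


class TestExclusionRule:
    def test_all_at_or_above_zero_hu_is_noop(self):
        lesion = LesionImage(np.full((4, 4), 1100), np.ones((4, 4), bool))
        assert (apply_exclusion_rule(lesion) == lesion.mask).all()

    def test_subzero_pixels_are_dropped(self):
        px = np.full((2, 5), 1100)
        px[0, :3] = 500  # -524 HU
        lesion = LesionImage(px, np.ones((2, 5), bool))
        refined = lesion.mask.copy()
        assert apply_exclusion_rule(lesion).sum() == 7
        assert (lesion.mask == refined).all(), "original mask must be untouched"

    def test_injected_subzero_fraction_removed(self):
        cfg = SyntheticConfig(subzero_fraction=0.2, seed=0)
        lesion = generate_lesion(cfg, heterogeneity=15.0, seed=3)
        refined = apply_exclusion_rule(lesion)
        n0 = lesion.roi_size
        # Oracle: per-pixel threshold scan.
        expect = int((lesion.in_mask_values() >= 1024).sum())
        assert refined.sum() == expect
        assert abs(refined.sum() / n0 - 0.8) < 0.02  # rounding of the 20% count

    def test_fully_subzero_roi_errors(self):
        lesion = LesionImage(np.full((3, 3), 10), np.ones((3, 3), bool))
        with pytest.raises(NoAnalyzablePixelsError):
            apply_exclusion_rule(lesion)


class TestLogFilter:
    @pytest.mark.parametrize("sigma", [1.0, 1.5, 2.0, 2.5])
    def test_constant_image_has_zero_response(self, sigma):
        img = np.full((24, 24), 1088.0)
        resp = log_filter(img, FilterSpec(sigma=sigma, mode="response"))
        assert np.abs(resp).max() < 1e-10

    @pytest.mark.parametrize("sigma", [1.0, 2.5])
    def test_constant_image_unchanged_in_band_plus_dc(self, sigma):
        img = np.full((24, 24), 1088.0)
        out = log_filter(img, FilterSpec(sigma=sigma, mode="band-plus-dc"))
        assert np.abs(out - img).max() < 1e-10

    def test_sigma_zero_is_identity_in_both_modes(self, rng):
        img = rng.normal(1088, 20, (10, 10))
        for mode in ("response", "band-plus-dc"):
            assert (log_filter(img, FilterSpec(sigma=0, mode=mode)) == img).all()

    @pytest.mark.parametrize("sigma", [1.0, 1.5, 2.0, 2.5])
    def test_raw_kernel_is_zero_sum_to_truncation_tolerance(self, sigma):
        k = log_kernel(sigma, zero_dc=False)
        assert abs(k.sum()) / np.abs(k).sum() < 1e-3

    def test_nonstandard_sigma_rejected_unless_overridden(self, rng):
        img = rng.normal(size=(8, 8))
        with pytest.raises(ValueError):
            log_filter(img, FilterSpec(sigma=0.7))
        log_filter(img, FilterSpec(sigma=0.7), allow_any_sigma=True)

    def test_interior_response_sums_to_zero(self, rng):
        # The zero-DC kernel conserves total intensity away from borders.
        img = rng.normal(1088, 20, (60, 60))
        resp = log_filter(img, FilterSpec(sigma=1.0, mode="response"))
        inner = resp[10:-10, 10:-10]
        raw = img[10:-10, 10:-10]
        assert abs(inner.sum()) / np.abs(raw).sum() < 1e-2


class TestHistogramFeatures:
    @pytest.mark.parametrize("values, expected", [
        ([5, 5, 5], (5.0, 0.0, 0.0, 0.0)),
        # Oracle: direct moment summation over {1,2,3,4}.
        ([1, 2, 3, 4], (2.5, 1.118033988749895, 0.0, -1.36)),
    ])
    def test_known_values(self, values, expected):
        got = histogram_features(values)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            histogram_features([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, pyrandom):
        base = histogram_features(values)
        shuffled = list(values)
        pyrandom.shuffle(shuffled)
        assert histogram_features(shuffled) == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestGlcm:
    def test_two_by_two_hand_enumeration(self):
        # [[0,1],[0,1]], horizontal offset: ordered pairs (0,1),(0,1); transpose
        # added by symmetry -> p(0,1) = p(1,0) = 0.5.
        m = build_glcm(np.array([[0, 1], [0, 1]]), np.ones((2, 2), bool),
                       offsets=((0, 1),), symmetric=True)
        assert m.levels.tolist() == [0.0, 1.0]
        assert m.probabilities.tolist() == [[0.0, 0.5], [0.5, 0.0]]
        asm, ent, con, cor = glcm_features(m)
        assert (asm, ent, con, cor) == pytest.approx((0.5, 1.0, 1.0, -1.0))

    def test_constant_region_single_cell(self):
        m = build_glcm(np.full((4, 4), 7), np.ones((4, 4), bool))
        assert m.probabilities.shape == (1, 1)
        assert m.probabilities[0, 0] == 1.0
        assert glcm_features(m) == pytest.approx((1.0, 0.0, 0.0, 0.0))

    def test_uniform_matrix_features(self):
        from texturesurv.texture import CoocMatrix
        # Oracle: direct summation over the 16 equal cells of a uniform 4x4 GLCM.
        m = CoocMatrix(levels=np.arange(4), probabilities=np.full((4, 4), 1 / 16),
                       offsets_used=((0, 1),), symmetric=True)
        asm, ent, con, cor = glcm_features(m)
        assert asm == pytest.approx(1 / 16)
        assert ent == pytest.approx(4.0)
        assert cor == pytest.approx(0.0, abs=1e-12)

    def test_probabilities_sum_to_one_and_symmetry(self, rng):
        for _ in range(20):
            img, mask = random_masked_image(rng)
            try:
                m = build_glcm(img, mask)
            except DegenerateROIError:
                continue
            assert m.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
            assert (m.probabilities == m.probabilities.T).all()

    def test_degenerate_roi_errors(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        mask[4, 4] = True  # no offset connects the two pixels
        with pytest.raises(DegenerateROIError):
            build_glcm(np.ones((5, 5)), mask)

    def test_matches_skimage_on_unmasked_image(self, rng):
        # Independent library cross-check where both conventions apply.
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        mine = build_glcm(img, np.ones((12, 12), bool), offsets=((0, 1),),
                          symmetric=True)
        ref = graycomatrix(img, distances=[1], angles=[0], levels=8,
                           symmetric=True, normed=True)[:, :, 0, 0]
        # Restrict the reference to the observed levels.
        lv = mine.levels.astype(int)
        assert np.allclose(mine.probabilities, ref[np.ix_(lv, lv)], atol=1e-12)

    def test_feature_ranges(self, rng):
        for _ in range(30):
            img, mask = random_masked_image(rng, levels=5)
            try:
                m = build_glcm(img, mask)
            except DegenerateROIError:
                continue
            asm, ent, con, cor = glcm_features(m)
            assert 0 < asm <= 1
            assert con >= 0
            assert -1 - 1e-12 <= cor <= 1 + 1e-12
            assert -1e-12 <= ent <= np.log2(np.count_nonzero(m.probabilities)) + 1e-9


class TestOracleEquivalence:
    def test_naive_enumeration_matches_pipeline(self, rng):
        """Histogram + GLCM features equal a naive pair-enumeration oracle."""
        checked = 0
        while checked < 200:
            img, mask = random_masked_image(rng)
            try:
                m = build_glcm(img, mask)
            except DegenerateROIError:
                continue
            probs = naive_glcm(img, mask, DEFAULT_OFFSETS, symmetric=True)
            ref = naive_glcm_features(probs)
            assert glcm_features(m) == pytest.approx(ref, abs=1e-9)
            from conftest import naive_histogram_features

            vals = img[mask]
            assert histogram_features(vals) == pytest.approx(
                naive_histogram_features(vals), abs=1e-9)
            checked += 1


class TestExtractFeatures:
    def test_constant_lesion_degenerate_features(self):
        lesion = LesionImage(np.full((20, 20), 1100), np.ones((20, 20), bool))
        fv = extract_features(lesion, sigmas=(0.0,))[0.0]
        assert fv.standard_deviation == 0
        assert fv.contrast == 0
        assert fv.asm == 1
        assert fv.average == 1100

    def test_sigma_zero_equals_direct_computation(self, rng):
        cfg = SyntheticConfig(seed=0)
        lesion = generate_lesion(cfg, heterogeneity=18.0, seed=9)
        fv = extract_features(lesion, sigmas=(0.0,))[0.0]
        refined = apply_exclusion_rule(lesion)
        vals = np.asarray(lesion.pixels, float)[refined]
        avg, sd, skew, kurt = histogram_features(vals)
        assert (fv.average, fv.standard_deviation) == pytest.approx((avg, sd))
        m = build_glcm(np.asarray(lesion.pixels, float), refined)
        assert (fv.asm, fv.entropy, fv.contrast, fv.correlation) == \
            pytest.approx(glcm_features(m))

    def test_contrast_decreases_with_filter_scale(self):
        """Coarser LoG response on fine-grained noise has lower local variation.

        Sign test over 20 independent lesions: contrast must be monotonically
        non-increasing across sigma 1.0 -> 2.5 in every replicate.
        """
        cfg = SyntheticConfig(correlation_length=0.6, seed=0)
        wins = 0
        for s in range(20):
            lesion = generate_lesion(cfg, heterogeneity=20.0, seed=400 + s)
            fv = extract_features(lesion, sigmas=(1.0, 1.5, 2.0, 2.5), mode="response")
            con = [fv[sg].contrast for sg in (1.0, 1.5, 2.0, 2.5)]
            wins += all(con[i] >= con[i + 1] for i in range(3))
        assert wins >= 18

    def test_all_scales_present_with_all_features(self):
        cfg = SyntheticConfig(seed=0)
        lesion = generate_lesion(cfg, heterogeneity=15.0, seed=1)
        fv = extract_features(lesion)
        assert set(fv) == {0.0, 1.0, 1.5, 2.0, 2.5}
        for vec in fv.values():
            assert len(vec.as_dict()) == 8
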