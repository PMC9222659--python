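import numpy as np
import pytest

from medfuse.network import encode
from medfuse.phantoms import PhantomSpec, annulus_mask
from medfuse.saliency import (
    FusionParams,
    ct_weight_map,
    fuse_baseline,
    fuse_features,
    l1_activity,
    minmax_normalize,
    vsm,
    vsm_bruteforce,
)


class TestActivityAndNormalize:
    def test_l1_activity_examples(self):
        assert np.all(l1_activity(np.ones((4, 4, 4))) == 4)
        single = np.array([[-1.0, 2.0]] * 8).reshape(8, 2, 1)
        assert np.array_equal(l1_activity(single), np.abs(single[:, :, 0]))
        assert np.all(l1_activity(np.zeros((4, 4, 3))) == 0)
        with pytest.raises(ValueError):
            l1_activity(np.zeros((4, 4, 0)))

    def test_minmax_endpoints_and_degenerate(self):
        out = minmax_normalize(np.array([[2.0, 4.0], [6.0, 6.0]]))
        assert out[0, 0] == 0 and out[0, 1] == 0.5 and out[1, 0] == 1
        assert np.all(minmax_normalize(np.full((3, 3), 5.0)) == 0)
        ident = np.array([[0.0, 0.25], [0.75, 1.0]])
        assert np.array_equal(minmax_normalize(ident), ident)
        with pytest.raises(ValueError):
            minmax_normalize(np.array([[np.nan, 1.0]]))


class TestVSM:
    def test_constant_image_has_zero_saliency(self):
        assert np.all(vsm(np.full((5, 5), 7, dtype=np.int64), 256) == 0)

    def test_worked_two_by_two_case(self):
        img = np.array([[0, 0], [0, 255]], dtype=np.int64)
        out = vsm(img, 256)
        assert np.array_equal(out, np.array([[255, 255], [255, 765]]))

    def test_matches_bruteforce_exactly_on_random_images(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = rng.integers(0, 256, size=(16, 16))
            assert np.array_equal(vsm(img, 256), vsm_bruteforce(img, 256))

    def test_depends_only_on_histogram(self, rng):
        img = rng.integers(0, 64, size=(12, 12))
        perm = rng.permutation(img.size)
        shuffled = img.ravel()[perm].reshape(img.shape)
        assert np.array_equal(vsm(img, 64).ravel()[perm], vsm(shuffled, 64).ravel())

    def test_rejects_out_of_range_and_float_input(self):
        with pytest.raises(ValueError):
            vsm(np.array([[0, 300]]), 256)
        with pytest.raises(ValueError):
            vsm(np.array([[0.5, 0.2]]), 256)


class TestCtWeightMap:
    def test_constant_stack_gives_zero_map(self):
        w = ct_weight_map(np.full((8, 8, 4), 3.0))
        assert np.all(w == 0)

    def test_bounded_in_unit_interval(self, rng):
        w = ct_weight_map(rng.normal(size=(16, 16, 6)))
        assert w.min() >= 0 and w.max() <= 1

    def test_high_on_dense_structure_of_phantom_features(self, clean_pair, small_weights):
        spec = PhantomSpec(size=64, seed=3, noise_sd=0.0, n_lesions=0)
        features = encode(clean_pair.ct, small_weights)
        w1 = ct_weight_map(features)
        ring = annulus_mask(spec)
        assert w1[ring].mean() > w1[~ring].mean()


class TestFuseFeatures:
    def test_weight_extremes_select_sources(self, rng):
        a, b = rng.normal(size=(8, 8, 3)), rng.normal(size=(8, 8, 3))
        np.testing.assert_allclose(fuse_features(a, b, np.ones((8, 8)), 1.0), a)
        np.testing.assert_allclose(fuse_features(a, b, np.zeros((8, 8)), 0.7), b)

    def test_identical_stacks_are_fixed_point(self, rng):
        f = rng.normal(size=(8, 8, 3))
        for _ in range(50):
            w1 = rng.random((8, 8))
            gamma = rng.random()
            np.testing.assert_allclose(fuse_features(f, f, w1, gamma), f, atol=1e-12)

    def test_coefficients_sum_to_one(self, rng):
        w1, gamma = rng.random((8, 8)), 0.3
        coeff_sum = gamma * w1 + (1 - gamma) * w1 + (1 - w1)
        np.testing.assert_allclose(coeff_sum, 1.0)

    def test_output_affine_in_weight_map(self, rng):
        a, b = rng.normal(size=(8, 8, 2)), rng.normal(size=(8, 8, 2))
        w0, w1 = rng.random((8, 8)), rng.random((8, 8))
        f = lambda w: fuse_features(a, b, w, 0.4)
        mid = f((w0 + w1) / 2)
        np.testing.assert_allclose(mid, (f(w0) + f(w1)) / 2, atol=1e-12)

    def test_literal_reading_differs_unless_weights_saturate(self, rng):
        a, b = rng.normal(size=(8, 8, 2)), rng.normal(size=(8, 8, 2))
        w = rng.random((8, 8)) * 0.5 + 0.25
        convex = fuse_features(a, b, w, 0.4, mri_coefficient="convex")
        literal = fuse_features(a, b, w, 0.4, mri_coefficient="literal")
        assert not np.allclose(convex, literal)
        ones = np.ones((8, 8))
        np.testing.assert_allclose(
            fuse_features(a, b, ones, 1.0, mri_coefficient="literal"),
            fuse_features(a, b, ones, 1.0, mri_coefficient="convex"),
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_features(np.zeros((8, 8, 2)), np.zeros((8, 8, 3)), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            fuse_features(np.zeros((8, 8, 2)), np.zeros((8, 8, 2)), np.zeros((4, 4)))


class TestBaselines:
    def test_algebraic_identities(self, rng):
        f = rng.normal(size=(8, 8, 3))
        np.testing.assert_allclose(fuse_baseline(f, f, "avg"), f)
        np.testing.assert_allclose(fuse_baseline(f, f - 1.0, "max"), f)
        np.testing.assert_allclose(fuse_baseline(f, np.zeros_like(f), "sum"), f)

    def test_l1norm_is_convex_combination(self, rng):
        a = np.abs(rng.normal(size=(8, 8, 3)))
        b = np.abs(rng.normal(size=(8, 8, 3)))
        out = fuse_baseline(a, b, "l1norm")
        assert np.all(out <= np.maximum(a, b) + 1e-12)
        assert np.all(out >= np.minimum(a, b) - 1e-12)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            fuse_baseline(np.zeros((8, 8, 1)), np.zeros((8, 8, 1)), "nuclear")


def test_fusion_params_validation():
    with pytest.raises(ValueError):
        FusionParams(gamma=1.5)
    with pytest.raises(ValueError):
        FusionParams(levels=1)
    with pytest.raises(ValueError):
        FusionParams(strategy="bogus")
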