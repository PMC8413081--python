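import numpy as np
import pytest

import oracles
from conftest import random_images
from morphedge import (
    GrayImage,
    OperatorParams,
    ValidationError,
    close_,
    combined_Q,
    dilate,
    erode,
    gradient_p,
    gradient_q,
    make_structuring_element,
    open_,
)
from morphedge.morphology import DIRECTIONS

ALL_DIRECTIONS = sorted(DIRECTIONS) + ["isotropic"]


class TestStructuringElementFactory:
    @pytest.mark.parametrize(
        "scale,direction,expected",
        [
            (3, "E", {(0, 0), (0, 1)}),
            (5, "N", {(0, 0), (-1, 0), (-2, 0)}),
            (3, "SW", {(0, 0), (1, -1)}),
        ],
    )
    def test_half_line_supports(self, scale, direction, expected):
        se = make_structuring_element(scale, direction)
        assert set(se.support) == expected

    def test_isotropic_is_full_square(self):
        se = make_structuring_element(3, "isotropic")
        assert len(se.support) == 9
        assert set(se.support) == {(r, c) for r in (-1, 0, 1) for c in (-1, 0, 1)}

    @pytest.mark.parametrize("scale", [2, 1, 4, -3])
    def test_rejects_even_or_small_scales(self, scale):
        with pytest.raises(ValidationError):
            make_structuring_element(scale, "E")

    def test_rejects_unknown_direction(self):
        with pytest.raises(ValidationError):
            make_structuring_element(3, "up")

    def test_reflection_negates_support(self):
        se = make_structuring_element(5, "NE")
        assert set(se.reflected().support) == {(-r, -c) for r, c in se.support}


class TestErodeDilate:
    def test_constant_image_fixed_point(self):
        img = GrayImage(np.full((6, 6), 42, dtype=np.uint8))
        for direction in ALL_DIRECTIONS:
            se = make_structuring_element(3, direction)
            assert erode(img, se) == img
            assert dilate(img, se) == img

    def test_erosion_absorbs_impulse(self):
        px = np.zeros((7, 7), dtype=np.uint8)
        px[3, 3] = 255
        se = make_structuring_element(3, "isotropic")
        assert np.all(erode(GrayImage(px), se).pixels == 0)

    def test_dilation_spreads_impulse_to_block(self):
        px = np.zeros((7, 7), dtype=np.uint8)
        px[3, 3] = 255
        se = make_structuring_element(3, "isotropic")
        out = dilate(GrayImage(px), se).pixels
        assert np.all(out[2:5, 2:5] == 255)
        assert out.sum() == 9 * 255

    @pytest.mark.parametrize("direction", ALL_DIRECTIONS)
    @pytest.mark.parametrize("scale", [3, 5])
    def test_matches_exhaustive_oracle(self, direction, scale):
        se = make_structuring_element(scale, direction)
        for img in random_images(3, (8, 8), seed=scale):
            assert np.array_equal(
                erode(img, se).as_float(), oracles.oracle_erode(img.pixels, se.support)
            )
            assert np.array_equal(
                dilate(img, se).as_float(), oracles.oracle_dilate(img.pixels, se.support)
            )


class TestOpenClose:
    def test_idempotence(self):
        se = make_structuring_element(3, "isotropic")
        for img in random_images(5, (10, 10), seed=7):
            once = open_(img, se)
            assert open_(once, se) == once
            once_c = close_(img, se)
            assert close_(once_c, se) == once_c

    def test_opening_removes_salt_closing_removes_pepper(self):
        se = make_structuring_element(3, "isotropic")
        salt = np.full((7, 7), 10, dtype=np.uint8)
        salt[3, 3] = 255
        assert np.all(open_(GrayImage(salt), se).pixels == 10)
        pepper = np.full((7, 7), 200, dtype=np.uint8)
        pepper[3, 3] = 0
        assert np.all(close_(GrayImage(pepper), se).pixels == 200)

    def test_ordering_chain(self):
        """dilate >= close >= g >= open >= erode pixelwise (isotropic SE)."""
        se = make_structuring_element(3, "isotropic")
        for img in random_images(20, (12, 12), seed=3):
            g = img.as_float()
            d = dilate(img, se).as_float()
            c = close_(img, se).as_float()
            o = open_(img, se).as_float()
            e = erode(img, se).as_float()
            assert np.all(d >= c) and np.all(c >= g)
            assert np.all(g >= o) and np.all(o >= e)


class TestDuality:
    @pytest.mark.parametrize("direction", ALL_DIRECTIONS)
    def test_dilation_is_complement_erosion(self, direction):
        se = make_structuring_element(3, direction)
        for img in random_images(3, (9, 9), seed=11):
            complement = GrayImage(255 - img.pixels)
            lhs = dilate(img, se).as_float()
            rhs = 255.0 - erode(complement, se.reflected()).as_float()
            assert np.array_equal(lhs, rhs)


class TestGradientP:
    def test_constant_image_zero_response(self):
        img = GrayImage(np.full((6, 6), 99, dtype=np.uint8))
        se = make_structuring_element(3, "isotropic")
        for which in range(1, 7):
            assert np.all(gradient_p(img, se, which).values == 0)

    def test_p3_decomposes_into_p1_plus_p2(self):
        se = make_structuring_element(3, "isotropic")
        for img in random_images(10, (10, 10), seed=5):
            p1 = gradient_p(img, se, 1).values
            p2 = gradient_p(img, se, 2).values
            p3 = gradient_p(img, se, 3).values
            assert np.array_equal(p3, p1 + p2)

    def test_p6_bounded_by_p3(self):
        se = make_structuring_element(3, "isotropic")
        for img in random_images(10, (10, 10), seed=6):
            assert np.all(
                gradient_p(img, se, 6).values <= gradient_p(img, se, 3).values
            )

    def test_step_edge_response_matches_oracle(self):
        px = np.zeros((8, 8), dtype=np.uint8)
        px[:, 4:] = 200
        se = make_structuring_element(3, "isotropic")
        p3 = gradient_p(GrayImage(px), se, 3).values
        assert np.array_equal(p3, oracles.oracle_gradient_p(px, se.support, 3))
        # two columns flanking the step carry the full contrast
        assert np.all(p3[:, 3:5] == 200)
        assert np.all(p3[:, :3] == 0) and np.all(p3[:, 5:] == 0)

    def test_rejects_bad_selector(self, random_image):
        se = make_structuring_element(3, "E")
        with pytest.raises(ValidationError):
            gradient_p(random_image, se, 7)

    @pytest.mark.parametrize("which", range(1, 7))
    def test_nonnegative_for_directional_elements(self, which):
        for direction in ALL_DIRECTIONS:
            se = make_structuring_element(3, direction)
            for img in random_images(2, (8, 8), seed=which):
                assert gradient_p(img, se, which).values.min() >= 0


class TestGradientQ:
    def test_constant_image_zero_response(self):
        img = GrayImage(np.full((6, 6), 50, dtype=np.uint8))
        se = make_structuring_element(3, "isotropic")
        assert np.all(gradient_q(img, se, 1).values == 0)
        assert np.all(gradient_q(img, se, 2).values == 0)

    def test_q2_ignores_salt_impulse(self):
        """The opening removes the bright impulse before differencing."""
        px = np.full((9, 9), 10, dtype=np.uint8)
        px[4, 4] = 255
        se = make_structuring_element(3, "isotropic")
        q2 = gradient_q(GrayImage(px), se, 2).values
        assert q2[4, 4] == 0
        assert np.all(q2 == 0)

    def test_q1_ignores_pepper_impulse(self):
        px = np.full((9, 9), 200, dtype=np.uint8)
        px[4, 4] = 0
        se = make_structuring_element(3, "isotropic")
        assert np.all(gradient_q(GrayImage(px), se, 1).values == 0)

    def test_step_edge_localized_within_se_width(self):
        px = np.zeros((10, 10), dtype=np.uint8)
        px[:, 5:] = 180
        se = make_structuring_element(3, "isotropic")
        for which in (1, 2):
            q = gradient_q(GrayImage(px), se, which).values
            assert np.array_equal(q, oracles.oracle_gradient_q(px, se.support, which))
            assert np.all(q[:, :3] == 0) and np.all(q[:, 7:] == 0)
            assert q[:, 3:7].max() > 0

    @pytest.mark.parametrize("direction", ALL_DIRECTIONS)
    @pytest.mark.parametrize("which", (1, 2))
    def test_matches_oracle_composition(self, direction, which):
        se = make_structuring_element(3, direction)
        for img in random_images(3, (8, 8), seed=13):
            assert np.array_equal(
                gradient_q(img, se, which).values,
                oracles.oracle_gradient_q(img.pixels, se.support, which),
            )

    def test_rejects_bad_selector(self, random_image):
        se = make_structuring_element(3, "E")
        with pytest.raises(ValidationError):
            gradient_q(random_image, se, 3)


class TestCombinedQ:
    def test_kappa_endpoint_gives_qmax(self, random_image):
        se = make_structuring_element(3, "isotropic")
        q1 = gradient_q(random_image, se, 1).values
        q2 = gradient_q(random_image, se, 2).values
        q = combined_Q(random_image, se, OperatorParams(kappa=1.0, lam=0.0)).values
        assert np.array_equal(q, np.maximum(q1, q2))

    def test_balanced_params_average_cascades(self, random_image):
        se = make_structuring_element(3, "isotropic")
        q1 = gradient_q(random_image, se, 1).values
        q2 = gradient_q(random_image, se, 2).values
        q = combined_Q(random_image, se, OperatorParams(kappa=0.5, lam=0.5)).values
        assert np.allclose(q, (q1 + q2) / 2, atol=0, rtol=0)

    def test_rejects_params_not_summing_to_one(self):
        with pytest.raises(ValidationError):
            OperatorParams(kappa=0.7, lam=0.7)
        with pytest.raises(ValidationError):
            OperatorParams(kappa=1.2, lam=-0.2)
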