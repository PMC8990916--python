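"""Water-equivalent area and diameter."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssdekit import (
    BodyMask,
    CTImage,
    render_phantom,
    segment_body,
    water_equivalent_area_pixels,
    wed_from_area,
    wed_from_roi_stats,
)
from ssdekit.wed import fitted_ellipse_roi


def _uniform_roi(hu: float, n: int = 20, spacing: float = 0.5):
    img = CTImage(np.full((n, n), hu), (spacing, spacing))
    mask = BodyMask(np.ones((n, n), dtype=bool))
    return img, mask


class TestWaterEquivalentArea:
    def test_water_identity(self):
        img, mask = _uniform_roi(0.0)
        assert water_equivalent_area_pixels(img, mask) == pytest.approx(
            mask.area_cm2(img)
        )

    def test_air_contributes_nothing(self):
        img, mask = _uniform_roi(-1000.0)
        assert water_equivalent_area_pixels(img, mask) == pytest.approx(0.0)

    def test_two_region_hand_sum(self):
        """Half water, half -800 HU lung over 400 cm²: A_w = 200 + 40 = 240."""
        values = np.zeros((20, 20))
        values[:, 10:] = -800.0
        img = CTImage(values, (1.0, 1.0))  # 400 cm² total
        mask = BodyMask(np.ones((20, 20), dtype=bool))
        assert water_equivalent_area_pixels(img, mask) == pytest.approx(
            240.0, abs=1e-12
        )

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        img = CTImage(rng.uniform(-900, 300, (16, 16)), (0.25, 0.25))
        left = np.zeros((16, 16), dtype=bool)
        left[:, :8] = True
        whole = water_equivalent_area_pixels(img, BodyMask(np.ones((16, 16), bool)))
        parts = water_equivalent_area_pixels(
            img, BodyMask(left)
        ) + water_equivalent_area_pixels(img, BodyMask(~left))
        assert whole == pytest.approx(parts)

    def test_misaligned_shapes_rejected(self):
        img, _ = _uniform_roi(0.0, n=20)
        with pytest.raises(ValueError, match="match"):
            water_equivalent_area_pixels(img, BodyMask(np.ones((5, 5), bool)))

    def test_matches_roi_stats_route_exactly(self, chest_spec):
        img = render_phantom(chest_spec, 0.1)
        mask = segment_body(img)
        a_w = water_equivalent_area_pixels(img, mask)
        area = mask.area_cm2(img)
        mean_hu = float(img.values[mask.mask].mean())
        wed_stats = wed_from_roi_stats(mean_hu, area)
        assert wed_from_area(a_w) == pytest.approx(wed_stats, rel=1e-12)


class TestWedFromArea:
    def test_circle_of_radius_ten(self):
        assert wed_from_area(100.0 * math.pi) == pytest.approx(20.0)

    def test_hand_calculation(self):
        # mean HU -300 over 500 cm² -> A_w = 350 -> 2*sqrt(350/pi)
        assert wed_from_roi_stats(-300.0, 500.0) == pytest.approx(21.11, abs=0.005)

    def test_water_ellipse_wed_equals_ed(self):
        assert wed_from_roi_stats(0.0, 150.0 * math.pi) == pytest.approx(
            math.sqrt(600.0)
        )

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_area_rejected(self, bad):
        with pytest.raises(ValueError):
            wed_from_area(bad)
        with pytest.raises(ValueError):
            wed_from_roi_stats(0.0, bad)

    def test_pure_air_roi_rejected(self):
        with pytest.raises(ValueError, match="area"):
            wed_from_roi_stats(-1000.0, 300.0)


class TestSignProperty:
    @given(
        mean_hu=st.floats(min_value=-999.0, max_value=999.0).filter(
            lambda h: abs(h) > 0.5
        ),
        area=st.floats(min_value=10.0, max_value=2000.0),
    )
    def test_wed_sits_on_the_hu_sign_side_of_the_area_diameter(self, mean_hu, area):
        """Negative mean HU (chest-like) pulls WED below the equal-area
        diameter; positive (abdomen-like) pushes it above."""
        d_area = 2.0 * math.sqrt(area / math.pi)
        wed = wed_from_roi_stats(mean_hu, area)
        if mean_hu < 0:
            assert wed < d_area
        elif mean_hu > 0:
            assert wed > d_area

    def test_fitted_ellipse_roi_agrees_for_elliptical_bodies(self, chest_spec):
        img = render_phantom(chest_spec, 0.1)
        mask = segment_body(img)
        ell = fitted_ellipse_roi(mask)
        wed_mask = wed_from_area(water_equivalent_area_pixels(img, mask))
        wed_ell = wed_from_area(water_equivalent_area_pixels(img, ell))
        assert wed_ell == pytest.approx(wed_mask, rel=0.01)

    def test_resolution_stability(self, chest_spec):
        weds = []
        for spacing in (0.1, 0.05):
            img = render_phantom(chest_spec, spacing)
            mask = segment_body(img)
            weds.append(wed_from_area(water_equivalent_area_pixels(img, mask)))
        assert abs(weds[1] - weds[0]) / weds[0] < 0.005
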