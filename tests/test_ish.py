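"""RNAscope quantification: background, calibration, counting, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iriskit import ish
from iriskit import synthetic as syn


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestBackground:
    def test_constant_image(self):
        img = np.full((50, 50), 5.0)
        bg = ish.estimate_background(img, full_mask(img.shape))
        assert bg.avg_background_intensity == 5.0
        assert bg.sd == 0.0

    def test_pooled_regions_weight_by_area(self):
        """Regions of areas 100 and 300 with means 2 and 4 pool to 3.5."""
        img = np.zeros((40, 40))
        m1 = np.zeros_like(img, bool)
        m1[:10, :10] = True           # area 100
        img[m1] = 2.0
        m2 = np.zeros_like(img, bool)
        m2[20:35, 20:40] = True       # area 300
        img[m2] = 4.0
        bg = ish.estimate_background(img, [m1, m2])
        assert bg.avg_background_intensity == pytest.approx(3.5)
        assert bg.region_area == 400

    def test_zero_image(self):
        img = np.zeros((20, 20))
        bg = ish.estimate_background(img, full_mask(img.shape))
        assert bg.avg_background_intensity == 0.0

    def test_empty_mask_is_error(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="empty"):
            ish.estimate_background(img, np.zeros_like(img, bool))


@pytest.fixture(scope="module")
def calibration_field():
    """50 well-separated uniform dots (integrated intensity 500) on
    background 2, zero noise, plus a clean corner for background."""
    spec = syn.IshFieldSpec(n_dots=50, dot_intensity_mean=500.0,
                            background_level=2.0, image_size=512, seed=7)
    img, truth = syn.generate_ish_field(spec)
    bg_mask = np.zeros(img.shape, bool)
    bg_mask[:30, :30] = True
    assert not ((truth.centers[:, 0] < 40) & (truth.centers[:, 1] < 40)).any()
    bg = ish.estimate_background(img, bg_mask)
    return img, truth, bg


class TestDotSelection:
    def test_exactly_twenty_dots_all_selected(self):
        spec = syn.IshFieldSpec(n_dots=20, dot_intensity_mean=400.0,
                                background_level=1.0, image_size=300, seed=3)
        img, truth = syn.generate_ish_field(spec)
        bg = ish.BackgroundEstimate(1.0, 100, 100.0, sd=0.0)
        dots = ish.select_representative_dots(img, bg, n=20,
                                              dot_radius=spec.dot_radius)
        assert len(dots) == 20
        covered = np.zeros(img.shape, bool)
        for m in dots:
            covered |= m
        hit = [covered[int(r), int(c)] for r, c in truth.centers]
        assert all(hit)

    def test_selection_is_representative_of_intensity_spread(self):
        spec = syn.IshFieldSpec(n_dots=100, dot_intensity_mean=500.0,
                                dot_intensity_sd=100.0, background_level=2.0,
                                image_size=768, seed=11)
        img, truth = syn.generate_ish_field(spec)
        bg = ish.BackgroundEstimate(2.0, 100, 200.0, sd=0.0)
        dots = ish.select_representative_dots(img, bg, n=20,
                                              dot_radius=spec.dot_radius)
        selected = [img[m].sum() - 2.0 * m.sum() for m in dots]
        assert abs(np.median(selected) / np.median(truth.intensities) - 1) < 0.10

    def test_blank_image_is_insufficient(self):
        img = np.full((100, 100), 2.0)
        bg = ish.estimate_background(img, full_mask(img.shape))
        with pytest.raises(ValueError, match="insufficient"):
            ish.select_representative_dots(img, bg, n=20)


class TestCalibration:
    def test_printed_formula_hand_example(self):
        """bg 2/px, 20 dots totalling 1040 over 120 px -> (1040-240)/20 = 40."""
        img = np.zeros((30, 30))
        dots = []
        for i in range(20):
            mask = np.zeros_like(img, bool)
            r, c = divmod(i, 5)
            mask[r * 6:r * 6 + 2, c * 6:c * 6 + 3] = True  # 6 px per dot
            img[mask] = 1040.0 / (20 * 6)
            dots.append(mask)
        bg = ish.BackgroundEstimate(2.0, 100, 200.0)
        cal = ish.calibrate_dot_intensity(img, dots, bg)
        assert cal.total_dot_area == 120
        assert cal.total_dot_intensity == pytest.approx(1040.0)
        assert cal.avg_intensity_per_dot == pytest.approx(40.0)

    def test_zero_background_reduces_to_mean(self):
        img = np.zeros((20, 20))
        mask = np.zeros_like(img, bool)
        mask[5:8, 5:8] = True
        img[mask] = 10.0
        bg = ish.BackgroundEstimate(0.0, 50, 0.0)
        cal = ish.calibrate_dot_intensity(img, [mask], bg)
        assert cal.avg_intensity_per_dot == pytest.approx(90.0)

    def test_planted_intensity_recovered(self, calibration_field):
        img, _truth, bg = calibration_field
        dots = ish.select_representative_dots(img, bg, n=20, dot_radius=3)
        cal = ish.calibrate_dot_intensity(img, dots, bg)
        assert cal.avg_intensity_per_dot == pytest.approx(500.0, rel=0.01)


class TestRoiCount:
    def test_pure_background_counts_zero(self, calibration_field):
        img, _, bg = calibration_field
        dots = ish.select_representative_dots(img, bg, n=20, dot_radius=3)
        cal = ish.calibrate_dot_intensity(img, dots, bg)
        roi = np.zeros(img.shape, bool)
        roi[:30, :30] = True
        res = ish.count_dots_in_roi(img, roi, bg, cal)
        assert res.dot_count == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("background_level", [0.0, 2.0, 10.0])
    @pytest.mark.parametrize("n_dots", [0, 1, 50, 200])
    def test_exact_recovery_independent_of_background(
        self, calibration_field, background_level, n_dots
    ):
        """With uniform dots and zero noise the printed formulas recover
        the planted count exactly; the background term cancels."""
        img_cal, _, bg_cal = calibration_field
        dots = ish.select_representative_dots(img_cal, bg_cal, n=20, dot_radius=3)
        cal = ish.calibrate_dot_intensity(img_cal, dots, bg_cal)
        spec = syn.IshFieldSpec(n_dots=n_dots, dot_intensity_mean=500.0,
                                background_level=background_level,
                                image_size=768, seed=13)
        img, _ = syn.generate_ish_field(spec)
        bg = ish.BackgroundEstimate(background_level, 100,
                                    background_level * 100)
        res = ish.count_dots_in_roi(img, full_mask(img.shape), bg, cal)
        assert res.dot_count == pytest.approx(n_dots, abs=1e-6)

    def test_linearity_in_planted_count(self, calibration_field):
        """Estimated vs planted dot number: slope 1, intercept 0,
        R² >= 0.999 at zero noise."""
        img_cal, _, bg_cal = calibration_field
        dots = ish.select_representative_dots(img_cal, bg_cal, n=20, dot_radius=3)
        cal = ish.calibrate_dot_intensity(img_cal, dots, bg_cal)
        planted = np.array([0, 10, 25, 50, 100, 150, 200])
        estimated = []
        for n in planted:
            spec = syn.IshFieldSpec(n_dots=int(n), dot_intensity_mean=500.0,
                                    background_level=2.0, image_size=768,
                                    seed=100 + n)
            img, _ = syn.generate_ish_field(spec)
            bg = ish.BackgroundEstimate(2.0, 100, 200.0)
            estimated.append(
                ish.count_dots_in_roi(img, full_mask(img.shape), bg, cal).dot_count
            )
        slope, intercept = np.polyfit(planted, estimated, 1)
        resid = np.array(estimated) - (slope * planted + intercept)
        ss_tot = ((estimated - np.mean(estimated)) ** 2).sum()
        r2 = 1 - (resid ** 2).sum() / ss_tot
        assert slope == pytest.approx(1.0, abs=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-6)
        assert r2 >= 0.999

    def test_variable_dots_within_five_percent(self, calibration_field):
        img_cal, _, bg_cal = calibration_field
        dots = ish.select_representative_dots(img_cal, bg_cal, n=20, dot_radius=3)
        cal = ish.calibrate_dot_intensity(img_cal, dots, bg_cal)
        spec = syn.IshFieldSpec(n_dots=50, dot_intensity_mean=500.0,
                                dot_intensity_sd=50.0, background_level=2.0,
                                image_size=768, seed=21)
        img, _ = syn.generate_ish_field(spec)
        bg = ish.BackgroundEstimate(2.0, 100, 200.0)
        res = ish.count_dots_in_roi(img, full_mask(img.shape), bg, cal)
        assert res.dot_count == pytest.approx(50, rel=0.05)

    def test_negative_estimate_floored_and_flagged(self):
        img = np.zeros((50, 50))
        bg = ish.BackgroundEstimate(1.0, 100, 100.0)
        cal = ish.DotCalibration(20, 1000.0, 100, 50.0)
        res = ish.count_dots_in_roi(img, full_mask(img.shape), bg, cal)
        assert res.dot_count == 0.0
        assert res.floored

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_dots=st.integers(0, 300),
        intensity=st.floats(1.0, 1e4),
        bg_level=st.floats(0.0, 100.0),
        area=st.integers(100, 10_000),
    )
    def test_formula_algebra_is_exact(self, n_dots, intensity, bg_level, area):
        """For idealized totals the ROI formula returns the planted count to
        rounding error, whatever the background."""
        cal = ish.DotCalibration(20, 20 * intensity + bg_level * 20 * 9, 20 * 9,
                                 intensity)
        total = bg_level * area + n_dots * intensity
        count = (total - bg_level * area) / cal.avg_intensity_per_dot
        assert count == pytest.approx(n_dots, rel=1e-9, abs=1e-6)


class TestRelativeAbundance:
    def make(self, roi, transcript, count):
        return ish.RoiDotCount(roi_id=roi, roi_area=100, roi_total_intensity=0.0,
                               dot_count=count, transcript=transcript)

    def test_reference_against_itself_is_one(self):
        res = ish.relative_abundance([self.make("r1", "Adra1a", 40.0)], "Adra1a")
        assert res[0].ratio == 1.0

    def test_two_to_one_ratio(self):
        counts = [self.make("r1", "Nos1", 80.0), self.make("r1", "Adra1a", 40.0)]
        res = ish.relative_abundance(counts, "Adra1a")
        ratios = {r.transcript: r.ratio for r in res}
        assert ratios["Nos1"] == pytest.approx(2.0)

    def test_zero_reference_is_flagged(self):
        counts = [self.make("r1", "Nos1", 80.0), self.make("r1", "Adra1a", 0.0)]
        with pytest.warns(UserWarning, match="undefined"):
            res = ish.relative_abundance(counts, "Adra1a")
        assert res == []

    def test_invariant_to_global_gain(self):
        counts = [self.make("r1", "Nos1", 64.0), self.make("r1", "Adra1a", 16.0)]
        scaled = [self.make("r1", "Nos1", 640.0), self.make("r1", "Adra1a", 160.0)]
        r1 = ish.relative_abundance(counts, "Adra1a")
        r2 = ish.relative_abundance(scaled, "Adra1a")
        assert {x.transcript: x.ratio for x in r1} == {
            x.transcript: x.ratio for x in r2
        }
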