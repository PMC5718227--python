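"""Calibration: accepted-threshold sweeps, regression fitting, selection."""

import numpy as np
import pandas as pd
import pytest

from petthresh.calibration import (
    accepted_thresholds_area,
    accepted_thresholds_axis,
    composed_r_squared,
    fit_family,
    select_best,
    select_slice,
)
from petthresh.errors import DegenerateFitError, ModelDomainError
from petthresh.imaging import ImageSlice2D, LungContext, RegionMask, threshold_region
from petthresh.metrics import load_lesion_table
from petthresh.models import predefined_model
from petthresh.phantom import PhantomSpec, generate_phantom

from conftest import make_image, sweep_calibration


def _full_lung(image):
    return LungContext.from_image(image, RegionMask(np.ones(image.shape, bool)))


def _disc_image(radius_px=2, value=100.0, background=1.0, size=9):
    grid = np.full((size, size), background)
    rr, cc = np.ogrid[:size, :size]
    disc = (rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= radius_px**2
    grid[disc] = value
    return make_image(grid), int(disc.sum())


class TestAcceptedThresholdsArea:
    def test_binary_disc_exact_match(self):
        image, n_disc = _disc_image()
        sample = accepted_thresholds_area(
            image, (0, 9, 0, 9), _full_lung(image), area_ct=n_disc * 16.0
        )
        assert sample.ath_min == sample.ath_max == sample.threshold == 100.0
        assert sample.t_mean == 100.0 and sample.pct_tmean == pytest.approx(100.0)
        assert sample.area_pet_mm2 == n_disc * 16.0

    def test_concentric_three_level_matches_sweep_oracle(self):
        grid = np.full((11, 11), 5.0)
        rr, cc = np.ogrid[:11, :11]
        ring = (rr - 5) ** 2 + (cc - 5) ** 2 <= 16
        core = (rr - 5) ** 2 + (cc - 5) ** 2 <= 4
        grid[ring] = 60.0
        grid[core] = 100.0
        image = make_image(grid)
        target = float((ring.sum()) * 16.0)  # core+ring area
        sample = accepted_thresholds_area(image, (0, 11, 0, 11), _full_lung(image), target)
        ath, midpoint = sweep_calibration(
            image, (0, 11, 0, 11), lambda m: abs(m.n_pixels * 16.0 - target)
        )
        assert sample.ath_min == min(ath) and sample.ath_max == max(ath)
        assert sample.threshold == midpoint

    def test_equidistant_reference_accepts_both_brackets(self):
        # Intensity staircase: areas 16, 32, 48 ... at thresholds 90, 80, 70 ...
        grid = np.full((8, 8), 1.0)
        values = [90.0, 80.0, 70.0, 60.0]
        for k, v in enumerate(values):
            grid[3, 2 + k] = v  # one new pixel joins per step down
        image = make_image(grid)
        # target midway between the 2-pixel (32) and 3-pixel (48) areas
        sample = accepted_thresholds_area(image, (0, 8, 0, 8), _full_lung(image), 40.0)
        assert sample.ath_min == 70.0 and sample.ath_max == 80.0
        assert sample.threshold == 75.0

    def test_sample_invariant_threshold_reconstructs(self):
        image, n_disc = _disc_image()
        sample = accepted_thresholds_area(
            image, (0, 9, 0, 9), _full_lung(image), area_ct=n_disc * 16.0
        )
        assert sample.pct_tmean * sample.t_mean / 100.0 == pytest.approx(
            sample.threshold, abs=0.5
        )


class TestAcceptedThresholdsAxis:
    def test_single_hot_pixel_zero_axis(self):
        grid = np.full((7, 7), 2.0)
        grid[3, 3] = 100.0
        grid[2, 2] = 50.0
        image = make_image(grid)
        sample = accepted_thresholds_axis(image, (0, 7, 0, 7), _full_lung(image), 0.0)
        # accepted thresholds isolate exactly the hot pixel
        mask = threshold_region(image, (0, 7, 0, 7), sample.ath_min)
        assert mask.n_pixels == 1

    def test_bar_phantom_matches_sweep_oracle(self):
        grid = np.full((7, 9), 2.0)
        grid[3, 2:7] = 100.0  # 5-pixel bar: center span 16 mm
        grid[2, 2:7] = 60.0
        image = make_image(grid)
        from petthresh.imaging import major_axis

        sample = accepted_thresholds_axis(image, (0, 7, 0, 9), _full_lung(image), 16.0)
        ath, midpoint = sweep_calibration(
            image, (0, 7, 0, 9), lambda m: abs(major_axis(m, 4.0, 4.0) - 16.0)
        )
        assert sample.ath_min == min(ath) and sample.ath_max == max(ath)
        assert sample.threshold == midpoint

    def test_elliptical_phantom_matches_sweep_oracle(self):
        from petthresh.imaging import major_axis

        ph = generate_phantom(PhantomSpec(a_mm=16, b_mm=10, noise_sd=0.0, seed=5))
        lung = LungContext.from_image(ph.pet, ph.lung_mask)
        sample = accepted_thresholds_axis(ph.pet, ph.roi, lung, ph.truth_major_axis_mm)
        ath, midpoint = sweep_calibration(
            ph.pet,
            ph.roi,
            lambda m: abs(major_axis(m, 4.0, 4.0) - ph.truth_major_axis_mm),
        )
        assert sample.threshold == midpoint
        assert sample.reference_kind == "hist_axis"

    def test_axis_sample_records_mean_area(self):
        grid = np.full((7, 9), 2.0)
        grid[3, 2:7] = 100.0
        image = make_image(grid)
        sample = accepted_thresholds_axis(image, (0, 7, 0, 9), _full_lung(image), 16.0)
        assert sample.area_pet_mm2 > 0


class TestFitFamily:
    def test_power_recovers_published_law_exactly(self):
        x = np.linspace(2.0, 60.0, 10)
        y = 130.9 * x**-0.23
        model = fit_family(list(zip(x, y)), "power")
        assert model.coefficients[0] == pytest.approx(130.9, abs=1e-6)
        assert model.coefficients[1] == pytest.approx(-0.23, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_linear_recovers_tmax_law(self):
        x = np.linspace(2000.0, 20000.0, 12)
        y = 1.64 * x - 1634.8
        model = fit_family(list(zip(x, y)), "linear", predictor="tmean")
        assert model.coefficients == pytest.approx((1.64, -1634.8))
        assert model.r_squared == pytest.approx(1.0)

    def test_noisy_power_exponent_recovery(self):
        # 100 replicates of n=38 noisy power-law samples: the average
        # recovered exponent stays within 0.05 of the generating value.
        rng = np.random.default_rng(7)
        exponents = []
        for _ in range(100):
            x = rng.uniform(5.0, 60.0, 38)
            y = 130.9 * x**-0.23 + rng.normal(0.0, 2.0, 38)
            model = fit_family(list(zip(x, y)), "power")
            exponents.append(model.coefficients[1])
        assert np.mean(exponents) == pytest.approx(-0.23, abs=0.05)

    @pytest.mark.parametrize("family", ["logarithmic", "exponential", "polynomial2"])
    def test_noiseless_recovery_other_families(self, family):
        x = np.linspace(1.0, 20.0, 15)
        truth = {
            "logarithmic": (10.0, 5.0),
            "exponential": (50.0, -0.1),
            "polynomial2": (0.5, -2.0, 30.0),
        }[family]
        if family == "logarithmic":
            y = truth[0] * np.log(x) + truth[1]
        elif family == "exponential":
            y = truth[0] * np.exp(truth[1] * x)
        else:
            y = truth[0] * x**2 + truth[1] * x + truth[2]
        model = fit_family(list(zip(x, y)), family)
        assert model.coefficients == pytest.approx(truth)
        assert model.r_squared == pytest.approx(1.0)

    def test_domain_and_degeneracy_errors(self):
        with pytest.raises(DegenerateFitError):
            fit_family([(1.0, 2.0), (2.0, 3.0)], "linear")  # too few
        with pytest.raises(DegenerateFitError):
            fit_family([(1.0, 2.0)] * 5, "linear")  # singular design
        with pytest.raises(ModelDomainError):
            fit_family([(-1.0, 2.0), (2.0, 3.0), (3.0, 4.0)], "power")
        with pytest.raises(ModelDomainError):
            fit_family([(1.0, -2.0), (2.0, 3.0), (3.0, 4.0)], "exponential")


class TestSelectBest:
    def test_power_generated_data_selects_power(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(5.0, 60.0, 30)
        y = 130.9 * x**-0.23 + rng.normal(0.0, 0.5, 30)
        fit = select_best(list(zip(x, y)))
        assert fit.model.family == "power"
        assert len(fit.residuals) == 30

    def test_linear_data_beaten_only_by_nesting(self):
        x = np.linspace(1.0, 30.0, 20)
        y = 1.5 * x + 4.0 + np.sin(x) * 0.01
        fit = select_best(list(zip(x, y)))
        assert fit.model.family in ("linear", "polynomial2")
        assert fit.family_scores["polynomial2"] >= fit.family_scores["linear"]

    def test_exact_tie_prefers_declared_order(self):
        # Noiseless line: linear and polynomial2 both reach R^2 == 1
        x = np.linspace(1.0, 10.0, 8)
        y = 2.0 * x + 1.0
        fit = select_best(list(zip(x, y)), ("linear", "polynomial2"))
        assert fit.model.family == "linear"
        fit2 = select_best(list(zip(x, y)), ("polynomial2", "linear"))
        assert fit2.model.family == "polynomial2"


class TestComposedRSquared:
    def test_perfect_predictions(self):
        from petthresh.models import evaluate_pct

        m4 = predefined_model(4)
        samples = [
            (t, b, evaluate_pct(m4, t, b))
            for t, b in [(5000.0, 400.0), (10000.0, 300.0), (16000.0, 500.0)]
        ]
        assert composed_r_squared(m4, samples) == pytest.approx(1.0)

    def test_mean_only_predictions_give_zero(self):
        # A constant model predicting the observed mean everywhere scores 0.
        from petthresh.models import ThresholdFunctionModel

        obs = [(10.0, 1.0, 50.0), (20.0, 1.0, 60.0), (30.0, 1.0, 70.0)]
        const = ThresholdFunctionModel("linear", (0.0, 60.0), "tmean_over_bmin")
        assert composed_r_squared(const, obs) == pytest.approx(0.0)

    def test_published_model_on_printed_operating_points(self):
        df = pd.concat([load_lesion_table("table1"), load_lesion_table("table2")])
        samples = list(zip(df["tmean"], df["bmin"], df["pct_tmean"]))
        value = composed_r_squared(predefined_model(8), samples)
        assert 0.9 <= value <= 1.0

    def test_zero_variance_degenerate(self):
        m4 = predefined_model(4)
        with pytest.raises(DegenerateFitError):
            composed_r_squared(m4, [(5000.0, 400.0, 60.0)] * 4)


class TestSelectSlice:
    @staticmethod
    def _stack(widths, seed=3):
        slices, lungs = [], []
        roi = None
        for w in widths:
            ph = generate_phantom(
                PhantomSpec(a_mm=w, b_mm=w, noise_sd=5.0, seed=seed)
            )
            slices.append(ph.pet)
            lungs.append(LungContext.from_image(ph.pet, ph.lung_mask))
            roi = (8, 40, 8, 40)  # shared central roi covering all lesions
        return slices, lungs, roi

    def test_widest_slice_wins(self):
        slices, lungs, roi = self._stack([10.0, 14.0, 18.0, 14.0, 10.0])
        assert select_slice(slices, lungs, roi, predefined_model(4)) == 2

    def test_single_slice(self):
        slices, lungs, roi = self._stack([15.0])
        assert select_slice(slices, lungs, roi, predefined_model(4)) == 0

    def test_tie_goes_to_lowest_index(self):
        slices, lungs, roi = self._stack([15.0, 15.0])
        assert select_slice(slices, lungs, roi, predefined_model(4)) == 0


class TestAthContiguity:
    def test_accepted_set_is_contiguous_on_nested_phantom(self):
        ph = generate_phantom(PhantomSpec(a_mm=14, b_mm=14, noise_sd=0.0, seed=9))
        lung = LungContext.from_image(ph.pet, ph.lung_mask)
        sample = accepted_thresholds_area(ph.pet, ph.roi, lung, ph.truth_area_mm2)
        r0, r1, c0, c1 = ph.roi
        ladder = np.unique(ph.pet.values[r0:r1, c0:c1])
        target = ph.truth_area_mm2

        def diff(t):
            m = threshold_region(ph.pet, ph.roi, float(t))
            return abs(m.n_pixels * 16.0 - target)

        accepted = [t for t in ladder if diff(t) - min(diff(t2) for t2 in ladder) <= 1e-9]
        in_window = [t for t in ladder if sample.ath_min <= t <= sample.ath_max]
        assert accepted == in_window  # contiguous run over the sorted ladder
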