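import numpy as np
import pandas as pd
import pytest

from hzmhc.geo_clines import (
    center_shift,
    fit_geographic_cline,
    hedges_g_from_intervals,
    select_cline_model,
    sigmoid_cline,
)
from hzmhc.simulate import fixed_ends_cline, transect_positions


def cline_table(c=100.0, w=6.0, noise_rng=None, n=10, pmin=0.0, pmax=1.0):
    x = transect_positions()
    p = pmin + (pmax - pmin) * fixed_ends_cline(x, c, w)
    if noise_rng is not None:
        mean = noise_rng.binomial(2 * n, p) / (2 * n)
    else:
        mean = p
    return pd.DataFrame({"x": x, "mean": mean, "n": n, "sd": 0.0})


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_cline(100.0, 100.0, 6.0) == pytest.approx(0.5)

    def test_slope_at_center_is_range_over_width(self):
        eps = 1e-6
        slope = (sigmoid_cline(100 + eps, 100, 6.0) - sigmoid_cline(100 - eps, 100, 6.0)) / (2 * eps)
        assert slope == pytest.approx(1 / 6.0, rel=1e-6)

    def test_one_width_from_center(self):
        # x - c = w gives (1 + tanh 2)/2
        expected = (1 + np.tanh(2.0)) / 2
        assert sigmoid_cline(106.0, 100.0, 6.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.98201, abs=1e-5)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_cline(0.0, 0.0, 0.0)

    def test_monotone_and_bounded(self):
        x = np.linspace(0, 200, 300)
        p = sigmoid_cline(x, 100, 6, 0.1, 0.8)
        assert np.all(np.diff(p) >= 0)
        assert p.min() >= 0.1 - 1e-9 and p.max() <= 0.8 + 1e-9


class TestFit:
    def test_zero_noise_exact_recovery(self):
        fit = fit_geographic_cline(cline_table(), "none", compute_intervals=False)
        assert fit.center == pytest.approx(100.0, abs=1e-3)
        assert fit.width == pytest.approx(6.0, abs=1e-3)

    def test_zero_noise_free_model_recovery(self):
        tab = cline_table(pmin=0.1, pmax=0.9)
        fit = fit_geographic_cline(tab, "free", compute_intervals=False)
        assert fit.width == pytest.approx(6.0, abs=0.05)
        assert fit.pmin == pytest.approx(0.1, abs=1e-3)
        assert fit.pmax == pytest.approx(0.9, abs=1e-3)

    def test_width_interval_contains_ml_width(self):
        fit = fit_geographic_cline(cline_table(noise_rng=np.random.default_rng(0)), "none")
        lo, hi = fit.support_intervals["width"]
        assert lo <= fit.width <= hi

    def test_reversed_transect_mirrors_center_keeps_width(self):
        rng = np.random.default_rng(1)
        tab = cline_table(noise_rng=rng)
        rev = tab.assign(x=200.0 - tab.x)
        f1 = fit_geographic_cline(tab, "none", compute_intervals=False)
        f2 = fit_geographic_cline(rev, "none", compute_intervals=False)
        assert f2.center == pytest.approx(200.0 - f1.center, abs=1e-2)
        assert f2.width == pytest.approx(f1.width, abs=1e-2)

    def test_too_few_populations_rejected(self):
        tab = cline_table().iloc[:3]
        with pytest.raises(ValueError, match="populations"):
            fit_geographic_cline(tab, "none")


class TestModelSelection:
    def test_flat_data_selects_no_cline(self):
        rng = np.random.default_rng(2)
        x = transect_positions()
        tab = pd.DataFrame(
            {"x": x, "mean": np.clip(0.5 + rng.normal(0, 0.03, len(x)), 0, 1), "n": 10, "sd": 0.1}
        )
        fits = [
            fit_geographic_cline(tab, m, compute_intervals=False)
            for m in ("none", "fixed", "free", "no_cline")
        ]
        best = select_cline_model(fits)
        assert best.model == "no_cline" and best.excluded_no_cline

    def test_steep_cline_beats_null_decisively(self):
        rng = np.random.default_rng(3)
        fits = {
            m: fit_geographic_cline(cline_table(noise_rng=rng), m, compute_intervals=False)
            for m in ("none", "no_cline")
        }
        assert fits["no_cline"].aic - fits["none"].aic > 10

    def test_equal_likelihood_prefers_fewer_parameters(self):
        from hzmhc.geo_clines import GeographicClineFit

        f1 = GeographicClineFit("none", 100, 6, 0, 1, -10.0, 2 * 2 - 2 * -10.0)
        f2 = GeographicClineFit("free", 100, 6, 0, 1, -10.0, 2 * 4 - 2 * -10.0)
        assert select_cline_model([f1, f2]).model == "none"


class TestEffectSizes:
    def test_equal_estimates_give_zero(self):
        g, _ = hedges_g_from_intervals(5.0, (4.0, 6.0), 5.0, (4.0, 6.0))
        assert g == pytest.approx(0.0)

    def test_difference_of_one_pooled_sd_gives_one(self):
        # both CIs of half-width z_0.975 -> sd 1 -> pooled sd 1
        z = 1.959963984540054
        g, _ = hedges_g_from_intervals(6.0, (6 - z, 6 + z), 5.0, (5 - z, 5 + z))
        assert g == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetric_in_arguments(self):
        g1, _ = hedges_g_from_intervals(6.0, (5.0, 7.0), 4.0, (3.5, 4.5))
        g2, _ = hedges_g_from_intervals(4.0, (3.5, 4.5), 6.0, (5.0, 7.0))
        assert g1 == pytest.approx(-g2)

    def test_ci_contains_point_estimate(self):
        g, (lo, hi) = hedges_g_from_intervals(6.0, (5.0, 7.0), 4.0, (3.5, 4.5), seed=1)
        assert lo <= g <= hi

    def test_zero_pooled_sd_error(self):
        with pytest.raises(ValueError):
            hedges_g_from_intervals(5.0, (5.0, 5.0), 4.0, (4.0, 4.0))


class TestCenterShift:
    def fits(self, c_mhc, c_gw):
        fit = fit_geographic_cline(cline_table(c=c_mhc), "none", compute_intervals=False)
        gw = fit_geographic_cline(cline_table(c=c_gw), "none", compute_intervals=False)
        return fit, gw

    def test_identical_centers_zero(self):
        f, g = self.fits(100.0, 100.0)
        assert center_shift(f, g, "increasing_x") == pytest.approx(0.0, abs=1e-3)

    def test_shift_toward_less_diverse_is_positive(self):
        f, g = self.fits(102.0, 100.0)
        assert center_shift(f, g, "increasing_x") == pytest.approx(2.0, abs=0.01)

    def test_orientation_flip_flips_sign(self):
        f, g = self.fits(102.0, 100.0)
        assert center_shift(f, g, "decreasing_x") == pytest.approx(-2.0, abs=0.01)

    def test_invalid_orientation_rejected(self):
        f, g = self.fits(100.0, 100.0)
        with pytest.raises(ValueError):
            center_shift(f, g, "sideways")
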