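import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brunox.algorithms import (DEFAULT_H, FitBounds, SlopeSpectrum,
                               attenuation_slope, bf_fit, bounded_minimize,
                               bruno_fit, srs_fit, sto2, standard_bounds)
from brunox.chromophores import TissueParams, mu_a, mu_s_linear, mu_s_powerlaw
from brunox.forward import (MultidistanceSpectra, ProbeGeometry,
                            ebc_reflectance, simulate_multidistance,
                            zbc_slope_model)

TRUE_STO2 = 65.1  # % for the grey-matter concentration pair (55.0, 29.5)


def make_slope(table_on_grid, grid, params, mus=None):
    mua = mu_a(params, table_on_grid)
    if mus is None:
        mus = mu_s_powerlaw(params.a, params.b, grid)
    return SlopeSpectrum(grid, zbc_slope_model(mua, mus, 15, 30), 15, 30, 4)


class TestStO2:
    @pytest.mark.parametrize("c1,c2,expected", [
        (55.0, 29.5, 65.1), (67.0, 20.9, 76.2), (43.8, 15.7, 73.6)])
    def test_worked_saturation_values(self, c1, c2, expected):
        assert sto2(c1, c2) == pytest.approx(expected, abs=0.05)

    def test_extremes(self):
        assert sto2(0.0, 12.0) == 0.0
        assert sto2(12.0, 0.0) == 100.0

    def test_undefined_when_both_zero(self):
        assert np.isnan(sto2(0.0, 0.0))

    @given(c1=st.floats(0.1, 200), c2=st.floats(0.1, 200),
           k=st.floats(0.01, 100))
    def test_scale_invariance_and_monotonicity(self, c1, c2, k):
        assert sto2(k * c1, k * c2) == pytest.approx(sto2(c1, c2), abs=1e-9)
        assert sto2(c1 * 1.01, c2) > sto2(c1, c2)
        assert sto2(c1, c2 * 1.01) < sto2(c1, c2)


class TestAttenuationSlope:
    geometry = ProbeGeometry()

    def _meas(self, attenuation, grid):
        return MultidistanceSpectra(wavelength=grid, attenuation=attenuation,
                                    geometry=self.geometry)

    def test_exact_linear_attenuation(self, grid):
        att = 0.1 * self.geometry.as_array()[:, None] * np.ones(grid.size)
        slope = attenuation_slope(self._meas(att, grid))
        np.testing.assert_allclose(slope.slope, 0.1, rtol=1e-12)
        assert slope.d_s == 15 and slope.d_l == 30

    def test_distance_independent_attenuation_gives_zero(self, grid):
        att = np.ones((4, grid.size)) * 1.7
        slope = attenuation_slope(self._meas(att, grid))
        np.testing.assert_allclose(slope.slope, 0.0, atol=1e-14)

    def test_offset_invariance(self, grid):
        """A distance-independent coupling offset does not change the
        slope."""
        rng = np.random.default_rng(3)
        att = rng.uniform(1, 3, (4, grid.size))
        base = attenuation_slope(self._meas(att, grid)).slope
        shifted = attenuation_slope(self._meas(att + 0.8, grid)).slope
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_two_distances_reduce_to_difference_quotient(self, grid):
        g = ProbeGeometry((15.0, 30.0))
        att = np.vstack([np.full(grid.size, 1.0), np.full(grid.size, 2.2)])
        meas = MultidistanceSpectra(wavelength=grid, attenuation=att,
                                    geometry=g)
        np.testing.assert_allclose(attenuation_slope(meas).slope,
                                   1.2 / 15, rtol=1e-12)


class TestBoundedMinimize:
    def test_interior_quadratic(self):
        x, f, conv, _ = bounded_minimize(
            lambda x: np.sum((x - [0.3, -0.2])**2),
            [0.0, 0.0], [-1.0, -1.0], [1.0, 1.0])
        assert conv
        np.testing.assert_allclose(x, [0.3, -0.2], atol=1e-5)

    def test_minimum_outside_box_lands_on_boundary(self):
        x, *_ = bounded_minimize(lambda x: (x[0] - 5.0)**2, [0.5], [0.0], [1.0])
        assert x[0] == pytest.approx(1.0, abs=1e-6)

    def test_constant_objective_converges_at_start(self):
        x, f, conv, _ = bounded_minimize(lambda x: 2.0, [0.4], [0.0], [1.0])
        assert conv and f == 2.0 and x[0] == pytest.approx(0.4, abs=1e-6)

    def test_fixed_parameters_stay_fixed(self):
        x, *_ = bounded_minimize(lambda x: (x[0] - 1)**2 + (x[1] - 1)**2,
                                 [0.0, 0.2], [0.0, 0.0], [0.0, 1.0])
        assert x[0] == 0.0
        assert x[1] == pytest.approx(1.0, abs=1e-5)

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            bounded_minimize(lambda x: 0.0, [2.0], [0.0], [1.0])


class TestSRS:
    def test_exact_recovery_under_linear_scattering(self, table_on_grid,
                                                    grid, model1_params):
        """With model-consistent linear scattering the unknown amplitude k
        cancels and SRS is exact."""
        for k in (0.5, 1.0, 3.0):
            mus = mu_s_linear(k, DEFAULT_H, grid)
            slope = make_slope(table_on_grid, grid, model1_params, mus)
            res = srs_fit(slope, table_on_grid)
            assert res.sto2 == pytest.approx(TRUE_STO2, abs=0.05)

    def test_single_wavelength_inversion_arithmetic(self):
        """The scaled-absorption inversion reproduces the hand-computed
        value: slope 0.11536 OD/mm at 800 nm, 15/30 mm geometry."""
        lam, slope_val = 800.0, 0.115359
        geom_term = 2 * np.log(2.0) / 15.0
        k_mua = (np.log(10) * slope_val - geom_term)**2 / \
            (3 * (1 - DEFAULT_H * lam))
        # forward: mu_a = 0.01, mu_s' = 1.0 -> k = 1/(1-h*800)
        assert k_mua == pytest.approx(0.01 / (1 - DEFAULT_H * 800), rel=1e-3)

    def test_systematic_underestimate_with_powerlaw_scattering(
            self, table_on_grid, grid, model1_params):
        """Power-law scattering decays faster than the SRS linear
        approximation, down-weighting red wavelengths: StO2 is biased low."""
        slope = make_slope(table_on_grid, grid, model1_params)
        res = srs_fit(slope, table_on_grid)
        assert res.sto2 < TRUE_STO2 - 2.0
        assert res.sto2 > TRUE_STO2 - 12.0

    def test_negative_bracket_flagged(self, table_on_grid, grid):
        slope = SlopeSpectrum(grid, np.full(grid.size, 0.01), 15, 30, 4)
        res = srs_fit(slope, table_on_grid)
        assert any(f.startswith("negative_slope_bracket") for f in res.flags)


class TestBruno:
    def test_noiseless_round_trip(self, table_on_grid, grid, model1_params):
        slope = make_slope(table_on_grid, grid, model1_params)
        res = bruno_fit(slope, table_on_grid,
                        standard_bounds("simulation", water=False))
        assert res.converged
        assert res.sto2 == pytest.approx(TRUE_STO2, abs=0.1)

    def test_identifiable_quantities_with_water(self, table_on_grid, grid):
        """The slope model constrains mu_a * mu_s' only, so the absolute
        parameter scale has a flat direction (scale concentrations and WF
        by s, scattering amplitude by 1/s).  The identifiable quantities —
        StO2, the WF:c_THb ratio, and the mu_a*mu_s' product — must be
        recovered on noiseless self-generated data."""
        p = TissueParams(60.5, 32.5, 0.80, 0.5, 1.6)
        slope = make_slope(table_on_grid, grid, p)
        res = bruno_fit(slope, table_on_grid, standard_bounds("simulation"))
        assert res.sto2 == pytest.approx(TRUE_STO2, abs=0.5)
        q = res.params
        ratio_truth = 0.80 / (60.5 + 32.5)
        ratio_fit = q.wf / (q.c_hbo2 + q.c_hhb)
        assert ratio_fit == pytest.approx(ratio_truth, rel=0.05)
        prod_truth = (mu_a(p, table_on_grid)
                      * mu_s_powerlaw(p.a, p.b, grid))
        prod_fit = (mu_a(q, table_on_grid)
                    * mu_s_powerlaw(q.a, q.b, grid))
        np.testing.assert_allclose(prod_fit, prod_truth, rtol=0.03)

    def test_slope_amplitude_feeds_absolute_scale_not_saturation(
            self, table_on_grid, grid, model1_params):
        """Scaling the measured slope (a coupling error) scales the
        recovered mu_a*mu_s' product accordingly — the fit uses amplitude,
        not just shape — while StO2, a concentration ratio, stays put."""
        slope = make_slope(table_on_grid, grid, model1_params)
        bounds = standard_bounds("simulation", water=False)
        base = bruno_fit(slope, table_on_grid, bounds)
        scaled = SlopeSpectrum(grid, 1.3 * slope.slope, 15, 30, 4)
        res = bruno_fit(scaled, table_on_grid, bounds)
        assert res.sto2 == pytest.approx(base.sto2, abs=0.5)

        def product(p):
            return (mu_a(p, table_on_grid)
                    * mu_s_powerlaw(p.a, p.b, grid))
        ratio = np.median(product(res.params) / product(base.params))
        # derivative amplitude scales with sqrt(mu_a mu_s'): 1.3^2 = 1.69
        assert ratio == pytest.approx(1.69, rel=0.15)

    def test_grid_not_covering_fit_range_rejected(self, table_on_grid):
        sub = np.arange(750.0, 851.0)
        slope = SlopeSpectrum(sub, np.full(sub.size, 0.1), 15, 30, 4)
        with pytest.raises(ValueError, match="fit range"):
            bruno_fit(slope, table_on_grid)

    def test_quality_report_attached_and_clean(self, table_on_grid, grid,
                                               model1_params):
        slope = make_slope(table_on_grid, grid, model1_params)
        res = bruno_fit(slope, table_on_grid,
                        standard_bounds("simulation", water=False))
        assert res.quality is not None
        assert res.quality.passed and res.quality.score < 0.1


class TestBF:
    def test_noiseless_round_trip_with_unknown_coupling(
            self, table_on_grid, grid, model1_params):
        mua = mu_a(model1_params, table_on_grid)
        mus = mu_s_powerlaw(0.5, 1.7, grid)
        refl = 7.3 * ebc_reflectance(mua, mus, 30.0)  # arbitrary coupling
        res = bf_fit(refl, 30.0, grid, table_on_grid,
                     standard_bounds("simulation", water=False))
        assert res.sto2 == pytest.approx(TRUE_STO2, abs=0.5)
        assert res.params.a == pytest.approx(0.5, rel=0.05)

    def test_flattened_band_biases_recovery(
            self, table, table_on_grid, grid, model1_params):
        """Destroying spectral structure in part of the band (a detector
        artefact) pushes the fitted StO2 systematically away from the
        clean-input result."""
        bounds = standard_bounds("simulation", water=False)
        reps = simulate_multidistance(model1_params, table, grid,
                                      noise_fraction=0.01, n_replicates=8,
                                      seed=9, model="ebc")
        clean, broken = [], []
        flat = (grid >= 780) & (grid <= 830)
        for m in reps:
            refl = m.intensity[3]
            clean.append(bf_fit(refl, 30.0, grid, table_on_grid, bounds).sto2)
            damaged = refl.copy()
            damaged[flat] = damaged[flat].mean()
            broken.append(bf_fit(damaged, 30.0, grid, table_on_grid,
                                 bounds).sto2)
        assert abs(np.median(broken) - np.median(clean)) > 1.0

    def test_nonpositive_reflectance_rejected(self, table_on_grid, grid):
        refl = np.full(grid.size, 1e-6)
        refl[50] = -1e-7
        with pytest.raises(ValueError, match="positive"):
            bf_fit(refl, 30.0, grid, table_on_grid)


class TestBounds:
    def test_standard_bound_rows(self):
        nb = standard_bounds("simulation")
        assert nb.start == (70, 50, 50, 1.0, 1.0)
        assert nb.lower == (60, 0, 0, 0.3, 0.5)
        assert nb.upper == (95, 100, 100, 2.0, 3.0)
        ph = standard_bounds("phantom")
        assert ph.upper[1] == 40 and ph.lower[0] == 97

    def test_waterless_variant_pins_wf(self):
        b = standard_bounds("simulation", water=False)
        assert b.start[0] == b.lower[0] == b.upper[0] == 0.0

    def test_invalid_start_rejected(self):
        with pytest.raises(ValueError):
            FitBounds(start=(99, 0, 0, 1, 1), lower=(0, 0, 0, 0, 0),
                      upper=(95, 10, 10, 2, 2))
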