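import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytosds import (
    AllometricRule,
    InsufficientDataError,
    NormalizationError,
    SizeSpectrum,
    biomass_to_spectrum,
    community_equilibrium,
    fit_sds,
    make_proportional_bins,
    make_uniform_bins,
    normalize_to_reference,
    to_biomass_spectrum,
    wholesale_tilt,
)


def power_law_spectrum(binning, slope, amplitude=1e4):
    return SizeSpectrum(binning=binning, density=amplitude * binning.centers**slope)


class TestFitSDS:
    def test_exact_power_law_recovered(self, prop_bins):
        fit = fit_sds(power_law_spectrum(prop_bins, -4.0))
        assert abs(fit.slope + 4.0) < 1e-9
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_bins_used == prop_bins.n_bins

    @given(st.floats(1e-3, 1e8))
    def test_slope_invariant_to_scaling(self, scale):
        binning = make_proportional_bins(0.5, 100, 20)
        base = power_law_spectrum(binning, -3.7)
        scaled = SizeSpectrum(binning=binning, density=base.density * scale)
        assert fit_sds(scaled).slope == pytest.approx(fit_sds(base).slope, abs=1e-12)

    @pytest.mark.parametrize("n_bins", [6, 24, 77])
    def test_slope_invariant_to_bin_count(self, n_bins):
        binning = make_proportional_bins(0.5, 100, n_bins)
        assert fit_sds(power_law_spectrum(binning, -4.3)).slope == pytest.approx(-4.3, abs=1e-9)

    def test_zero_bins_dropped_with_warning(self, prop_bins, caplog):
        spec = power_law_spectrum(prop_bins, -4.0)
        spec.density[5] = 0.0
        with caplog.at_level("WARNING"):
            fit = fit_sds(spec)
        assert fit.n_bins_used == prop_bins.n_bins - 1
        assert fit.slope == pytest.approx(-4.0, abs=1e-9)
        assert "zero-density" in caplog.text

    def test_too_few_positive_bins(self, prop_bins):
        density = np.zeros(prop_bins.n_bins)
        density[:2] = 1.0
        with pytest.raises(InsufficientDataError):
            fit_sds(SizeSpectrum(binning=prop_bins, density=density))

    def test_noisy_slope_within_regression_ci(self):
        """Recovered slope falls within ±3·stderr of the truth at the
        rate classical OLS sampling theory predicts."""
        from scipy import stats

        binning = make_proportional_bins(0.5, 100, 20)
        covered = 0
        n_trials = 1000
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            density = 1e4 * binning.centers**-4.0 * 10 ** rng.normal(0, 0.1, 20)
            fit = fit_sds(SizeSpectrum(binning=binning, density=density))
            if abs(fit.slope + 4.0) <= 3 * fit.stderr:
                covered += 1
        # (slope − truth)/stderr is t-distributed with n−2 df, so the
        # coverage of ±3·stderr is P(|t_18| ≤ 3) ≈ 0.9923
        expected = 2 * stats.t.cdf(3.0, df=18) - 1
        tol = 3 * np.sqrt(n_trials * expected * (1 - expected))
        assert abs(covered - expected * n_trials) <= tol


class TestEquilibriumPipeline:
    def test_proportional_bins_give_fundamental_slope(self, prop_bins):
        P = community_equilibrium(prop_bins)
        fit = fit_sds(biomass_to_spectrum(P, prop_bins))
        assert fit.slope == pytest.approx(-4.0, abs=1e-6)

    def test_uniform_bins_give_minus_three(self, uniform_bins):
        P = community_equilibrium(uniform_bins)
        fit = fit_sds(biomass_to_spectrum(P, uniform_bins))
        assert fit.slope == pytest.approx(-3.0, abs=1e-6)

    def test_slope_additivity_with_power_law_allometries(self, prop_bins, rng):
        """P* ∝ mu·c3/c2, so power-law rules shift the slope by exactly
        e_mu + e_c3 − e_c2 from the −4 baseline."""
        for _ in range(10):
            e_mu, e_c2, e_c3 = rng.uniform(-0.3, 0.3, size=3)
            rules = {
                "mu": AllometricRule(base=1.0, exponent=e_mu),
                "c2": AllometricRule(base=0.2, exponent=e_c2),
                "c3": AllometricRule(base=1.0, exponent=e_c3),
            }
            P = community_equilibrium(prop_bins, allometries=rules)
            fit = fit_sds(biomass_to_spectrum(P, prop_bins))
            assert fit.slope == pytest.approx(-4.0 + e_mu + e_c3 - e_c2, abs=1e-9)

    def test_biomass_mismatch_rejected(self, prop_bins):
        with pytest.raises(ValueError):
            biomass_to_spectrum(np.ones(3), prop_bins)

    def test_zero_biomass_bin_maps_to_zero_density(self, prop_bins):
        P = np.ones(prop_bins.n_bins)
        P[7] = 0.0
        spec = biomass_to_spectrum(P, prop_bins)
        assert spec.density[7] == 0.0
        assert np.all(spec.density[np.arange(prop_bins.n_bins) != 7] > 0)


class TestNormalization:
    def test_reference_bin_anchored_exactly(self, prop_bins):
        spec = normalize_to_reference(power_law_spectrum(prop_bins, -4.0, amplitude=3.3))
        idx = prop_bins.bin_index(0.5)
        assert spec.density[idx] * prop_bins.widths[idx] == pytest.approx(1e4, rel=1e-12)

    def test_scale_factor_arithmetic(self, prop_bins):
        base = power_law_spectrum(prop_bins, -4.0)
        idx = prop_bins.bin_index(0.5)
        scale = 50.0 / (base.density[idx] * prop_bins.widths[idx])
        fifty = SizeSpectrum(binning=prop_bins, density=base.density * scale)
        normalized = normalize_to_reference(fifty)
        np.testing.assert_allclose(normalized.density, fifty.density * 200.0, rtol=1e-12)

    def test_slope_unchanged(self, prop_bins):
        spec = power_law_spectrum(prop_bins, -3.6, amplitude=7.7)
        before = fit_sds(spec).slope
        after = fit_sds(normalize_to_reference(spec)).slope
        assert abs(after - before) < 1e-12

    def test_reference_outside_grid_fails(self):
        binning = make_proportional_bins(1.0, 100, 10)
        with pytest.raises(NormalizationError):
            normalize_to_reference(power_law_spectrum(binning, -4.0), ref_diameter=0.5)

    def test_zero_reference_bin_fails(self, prop_bins):
        density = np.ones(prop_bins.n_bins)
        density[prop_bins.bin_index(0.5)] = 0.0
        with pytest.raises(NormalizationError):
            normalize_to_reference(SizeSpectrum(binning=prop_bins, density=density))


class TestWholesaleTilt:
    def test_endpoints(self):
        assert wholesale_tilt(-4.0, 0.0) == -4.0
        assert wholesale_tilt(-4.0, 1.0) == -3.0

    def test_midpoint(self):
        assert wholesale_tilt(-4.0, 0.5) == pytest.approx(-3.5)

    def test_monotone_in_fraction(self):
        f = np.linspace(0, 1, 21)
        tilted = [wholesale_tilt(-4.0, fi) for fi in f]
        assert np.all(np.diff(tilted) >= 0)

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_fraction_bounds(self, bad):
        with pytest.raises(ValueError):
            wholesale_tilt(-4.0, bad)


class TestBiomassSpectrum:
    def test_total_biomass_conserved(self, prop_bins, rng):
        for _ in range(10):
            spec = SizeSpectrum(binning=prop_bins, density=rng.uniform(0.1, 1e4, prop_bins.n_bins))
            bs = to_biomass_spectrum(spec, n_log_bins=rng.integers(2, 15))
            total_in = np.sum(
                spec.concentrations * (np.pi / 6) * prop_bins.centers**3
            )
            assert bs.total == pytest.approx(total_in, rel=1e-9)

    def test_bloom_spectrum_biomass_rises_with_volume(self, prop_bins):
        bs = to_biomass_spectrum(power_law_spectrum(prop_bins, -3.4), n_log_bins=8)
        assert np.all(np.diff(bs.biomass) > 0)

    def test_steep_spectrum_biomass_falls_with_volume(self, prop_bins):
        bs = to_biomass_spectrum(power_law_spectrum(prop_bins, -4.6), n_log_bins=8)
        assert np.all(np.diff(bs.biomass) < 0)

    def test_fundamental_slope_gives_flat_biomass(self, prop_bins):
        # at slope −4 each logarithmic volume bin holds equal biomass
        bs = to_biomass_spectrum(power_law_spectrum(prop_bins, -4.0), n_log_bins=8)
        np.testing.assert_allclose(bs.biomass, bs.biomass[0], rtol=1e-9)

    def test_empty_spectrum_rejected(self, prop_bins):
        spec = SizeSpectrum(binning=prop_bins, density=np.zeros(prop_bins.n_bins))
        with pytest.raises(InsufficientDataError):
            to_biomass_spectrum(spec)
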