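"""Peak fitting, Bragg strain conversion, and the P2 orientation parameter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saxstrain as sx
from saxstrain.peaks import _gaussian

from .conftest import flat_azimuthal_profile


def synthetic_profile(center=0.0094, sigma=4e-4, amp=100.0, bg=3.0,
                      q_lo=0.008, q_hi=0.011, n=200, noise_seed=None):
    q = np.linspace(q_lo, q_hi, n)
    y = _gaussian(q, center, sigma, amp, 0.0, bg)
    if noise_seed is not None:
        y = np.random.default_rng(noise_seed).poisson(y).astype(float)
    return sx.RadialProfile(q, y, np.full(n, 20), (-20.0, 20.0))


class TestFitPeak:
    def test_noiseless_center_to_five_significant_figures(self):
        prof = synthetic_profile(center=0.00940)
        fit = sx.fit_peak(prof, (0.0085, 0.0105))
        assert fit.converged
        assert fit.q_center == pytest.approx(0.00940, rel=1e-5)

    def test_flat_profile_flags_nonconvergence(self):
        prof = synthetic_profile(amp=0.0)
        fit = sx.fit_peak(prof, (0.0085, 0.0105))
        assert not fit.converged

    def test_window_outside_profile_is_an_error(self):
        prof = synthetic_profile()
        with pytest.raises(ValueError):
            sx.fit_peak(prof, (0.5, 0.6))

    def test_too_few_bins_is_an_error(self):
        prof = synthetic_profile(n=30)
        with pytest.raises(ValueError, match="bins"):
            sx.fit_peak(prof, (0.00938, 0.00942))

    def test_noisy_center_within_three_se(self):
        # calibration of the reported SE under Poisson counting noise
        hits = 0
        n_trials = 200
        for s in range(n_trials):
            prof = synthetic_profile(amp=1000.0, noise_seed=s)
            fit = sx.fit_peak(prof, (0.0085, 0.0105))
            if fit.converged and abs(fit.q_center - 0.0094) <= 3 * fit.q_center_se:
                hits += 1
        assert hits >= 0.95 * n_trials

    def test_lorentzian_model_supported(self):
        q = np.linspace(0.008, 0.011, 150)
        y = 50.0 / (1 + ((q - 0.0095) / 3e-4) ** 2) + 2.0
        prof = sx.RadialProfile(q, y, np.full(q.size, 15), (-20.0, 20.0))
        fit = sx.fit_peak(prof, (0.0085, 0.0105), model="lorentzian")
        assert fit.converged
        assert fit.q_center == pytest.approx(0.0095, rel=1e-4)


class TestDFromQ:
    @pytest.mark.parametrize(
        "q, d",
        [(2 * np.pi, 1.0), (0.1076, 58.39), (0.009378, 670.0)],
    )
    def test_bragg_relation(self, q, d):
        assert sx.d_from_q(q) == pytest.approx(d, rel=1e-3)

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError):
            sx.d_from_q(0.0)


class TestStrainSeries:
    @staticmethod
    def peaks_at(d_values):
        return [
            sx.PeakFit(2 * np.pi / d, 1e-6, 3e-4, 50.0, (0.0, 2.0), 0.99, True,
                       (0.008, 0.011))
            for d in d_values
        ]

    def test_constant_d_gives_zero_strain(self):
        peaks = self.peaks_at([670.0] * 6)
        series = sx.strain_series(peaks, np.arange(6.0), "collagen", n_reference=3)
        np.testing.assert_allclose(series.material_strain, 0.0, atol=1e-12)

    def test_half_percent_shift(self):
        peaks = self.peaks_at([670.0, 670.0, 670.0 * 1.005])
        series = sx.strain_series(peaks, [0.0, 1.0, 2.0], "collagen", n_reference=2)
        assert series.material_strain[-1] == pytest.approx(0.005, rel=1e-9)

    def test_unconverged_frames_carry_nan(self):
        peaks = self.peaks_at([670.0, 670.0, 671.0])
        peaks[2].converged = False
        series = sx.strain_series(peaks, [0.0, 1.0, 2.0], "collagen", n_reference=2)
        assert np.isnan(series.material_strain[2])

    def test_no_reference_frames_is_an_error(self):
        with pytest.raises(ValueError):
            sx.strain_series(self.peaks_at([670.0] * 3), [0, 1, 2], "collagen",
                             n_reference=0)

    def test_strain_invariant_under_intensity_rescaling(self):
        prof_a = synthetic_profile(center=0.0094, amp=100.0, bg=3.0)
        prof_b = sx.RadialProfile(prof_a.q, prof_a.intensity * 7.0,
                                  prof_a.n_pixels, prof_a.chi_range)
        fa = sx.fit_peak(prof_a, (0.0085, 0.0105))
        fb = sx.fit_peak(prof_b, (0.0085, 0.0105))
        assert fa.q_center == pytest.approx(fb.q_center, rel=1e-10)


class TestP2:
    def test_uniform_profile_gives_zero(self):
        assert sx.p2_orientation(flat_azimuthal_profile()) == pytest.approx(0.0, abs=1e-12)

    def test_axial_delta_approaches_one(self):
        prof = flat_azimuthal_profile(0.0, n=3600)
        idx = np.argmin(np.abs(prof.chi - 0.05))  # the bin containing chi=0
        prof.intensity[idx] = 1.0
        assert sx.p2_orientation(prof) == pytest.approx(1.0, abs=1e-5)

    def test_transverse_delta_approaches_minus_half(self):
        prof = flat_azimuthal_profile(0.0, n=3600)
        idx = np.argmin(np.abs(prof.chi - 90.0))
        prof.intensity[idx] = 1.0
        assert sx.p2_orientation(prof) == pytest.approx(-0.5, abs=1e-5)

    def test_all_zero_intensity_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            sx.p2_orientation(flat_azimuthal_profile(0.0))

    def test_insufficient_coverage_is_an_error(self):
        n = 100
        chi = -45.0 + (np.arange(n) + 0.5) * 0.9  # 90 degrees of coverage
        prof = sx.AzimuthalProfile(chi, np.ones(n), np.full(n, 5), (0.009, 0.010))
        with pytest.raises(ValueError, match="coverage"):
            sx.p2_orientation(prof)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=36, max_size=36))
    def test_bounds_hold_for_any_nonnegative_profile(self, intensities):
        intensities = np.asarray(intensities)
        if intensities.sum() <= 0:
            return
        width = 360.0 / 36
        chi = -180.0 + (np.arange(36) + 0.5) * width
        prof = sx.AzimuthalProfile(chi, intensities, np.full(36, 4), (0.009, 0.010))
        p2 = sx.p2_orientation(prof)
        assert -0.5 - 1e-9 <= p2 <= 1.0 + 1e-9

    def test_matches_generator_model(self):
        # analytic profile of the exp(kappa cos 2chi) model integrates back
        # to the P2 the concentration parameter was solved for
        from saxstrain.simulate import kappa_for_p2
        target = 0.35
        kappa = kappa_for_p2(target)
        n = 720
        chi = -180.0 + (np.arange(n) + 0.5) * (360.0 / n)
        intensity = np.exp(kappa * np.cos(2 * np.radians(chi)))
        prof = sx.AzimuthalProfile(chi, intensity, np.full(n, 10), (0.009, 0.010))
        assert sx.p2_orientation(prof) == pytest.approx(target, abs=2e-4)


class TestDeltaP2:
    def test_constant_p2_gives_zero_slope(self):
        series = sx.OrientationSeries(np.arange(10.0), np.full(10, 0.3))
        est = sx.delta_p2(series, np.linspace(0, 0.01, 10))
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_programmed_rate_recovered(self):
        rng = np.random.default_rng(4)
        eps = np.linspace(0, 0.01, 40)
        p2 = 0.25 + 5.0 * eps + rng.normal(0, 1e-3, eps.size)
        est = sx.delta_p2(sx.OrientationSeries(np.arange(40.0), p2), eps)
        assert abs(est.slope - 5.0) <= 2 * est.se

    def test_two_points_is_an_error(self):
        series = sx.OrientationSeries(np.array([0.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            sx.delta_p2(series, [0.0, 0.001])
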