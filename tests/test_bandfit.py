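"""Subpeak localization, constrained multi-peak fitting and band measures."""

import math

import numpy as np
import pytest

from osteospec.bandfit import (
    BandFitError,
    SubPeak,
    band_area,
    fit_band,
    intensity_at,
    peak_fwhm,
    pseudo_voigt,
    pv_area,
    second_derivative_minima,
)
from osteospec.spectra import Band, Spectrum


def spectrum_from_peaks(peaks, grid=(800.0, 1300.0, 1.0), noise_sd=0.0, seed=0,
                        baseline=0.0, modality="raman_fingerprint"):
    w = np.arange(grid[0], grid[1] + 0.5 * grid[2], grid[2])
    y = np.full_like(w, float(baseline))
    for c, a, f in peaks:
        y = y + pseudo_voigt(w, c, a, f, 0.0)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(w))
    return Spectrum(w, y, modality)


class TestPseudoVoigt:
    def test_gaussian_area_closed_form(self):
        # Gaussian: area = amp * sigma * sqrt(2 pi), sigma = fwhm/2.3548
        amp, fwhm = 1.7, 24.0
        sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
        assert pv_area(amp, fwhm, 0.0) == pytest.approx(amp * sigma * math.sqrt(2 * math.pi), rel=1e-9)

    def test_lorentzian_area_closed_form(self):
        amp, fwhm = 0.8, 30.0
        assert pv_area(amp, fwhm, 1.0) == pytest.approx(amp * math.pi * fwhm / 2, rel=1e-12)

    @pytest.mark.parametrize("eta", [0.0, 0.3, 1.0])
    def test_subpeak_area_matches_numeric_integral(self, eta):
        p = SubPeak(center=1000.0, amplitude=1.2, fwhm=18.0, eta=eta)
        w = np.arange(0.0, 2000.0, 0.05)
        numeric = np.trapezoid(p.profile(w), w)
        # Lorentzian tails converge slowly; generous domain, modest rtol
        assert p.area == pytest.approx(numeric, rel=2e-2 if eta else 1e-6)

    def test_subpeak_validation(self):
        with pytest.raises(BandFitError):
            SubPeak(960.0, -1.0, 20.0)
        with pytest.raises(BandFitError):
            SubPeak(960.0, 1.0, 20.0, eta=1.5)


class TestSecondDerivativeMinima:
    def test_single_gaussian_single_candidate(self):
        s = spectrum_from_peaks([(960, 1.0, 15)])
        got = second_derivative_minima(s, Band("b", 900, 1020))
        assert len(got) == 1
        assert got[0] == pytest.approx(960, abs=1.0)

    def test_resolved_doublet(self):
        s = spectrum_from_peaks([(1030, 1.0, 12), (1076, 1.0, 12)])
        got = second_derivative_minima(s, Band("b", 990, 1120))
        assert len(got) == 2
        assert got[0] == pytest.approx(1030, abs=2.0)
        assert got[1] == pytest.approx(1076, abs=2.0)

    def test_flat_spectrum_empty(self):
        s = spectrum_from_peaks([], baseline=1.0)
        assert second_derivative_minima(s, Band("b", 900, 1100)) == []


class TestFitBand:
    def test_single_gaussian_with_noise(self):
        s = spectrum_from_peaks([(960, 1.0, 20)], noise_sd=0.005, seed=7)
        fit = fit_band(s, Band("b", 880, 1040), seeds=[958.0], fwhm_init=15.0)
        assert fit.converged
        (p,) = fit.subpeaks
        assert p.center == pytest.approx(960, abs=0.5)
        assert p.fwhm == pytest.approx(20, rel=0.02)

    def test_noiseless_multipeak_areas_within_1pct(self):
        peaks = [(960, 2.0, 20), (1030, 1.0, 28), (1058, 0.5, 24),
                 (1076, 0.4, 24), (1127, 0.25, 26)]
        s = spectrum_from_peaks(peaks)
        fit = fit_band(s, Band("b", 900, 1200), seeds=[c for c, _, _ in peaks], fwhm_init=22.0)
        for (c, a, f), p in zip(peaks, fit.subpeaks):
            assert p.area == pytest.approx(pv_area(a, f, 0.0), rel=0.01)

    def test_exact_model_residual_tiny(self):
        s = spectrum_from_peaks([(960, 1.0, 20), (1030, 0.7, 25)])
        fit = fit_band(s, Band("b", 900, 1100), seeds=[960.0, 1030.0], fwhm_init=20.0)
        assert fit.residual_rms < 1e-6 * np.max(s.intensities)

    def test_seed_order_invariance(self):
        s = spectrum_from_peaks([(960, 1.0, 20), (1030, 0.7, 25), (1076, 0.4, 20)])
        b = Band("b", 900, 1150)
        f1 = fit_band(s, b, seeds=[960.0, 1030.0, 1076.0], fwhm_init=[20.0, 25.0, 20.0])
        f2 = fit_band(s, b, seeds=[1076.0, 960.0, 1030.0], fwhm_init=[20.0, 20.0, 25.0])
        for p1, p2 in zip(f1.subpeaks, f2.subpeaks):
            assert p1.center == pytest.approx(p2.center, abs=1e-6)
            assert p1.area == pytest.approx(p2.area, rel=1e-6)

    def test_model_reconstruction_matches_fitted(self):
        s = spectrum_from_peaks([(960, 1.0, 20)])
        fit = fit_band(s, Band("b", 900, 1020), seeds=[960.0])
        assert np.allclose(fit.model(), fit.fitted, atol=1e-8)

    def test_seeds_outside_band_rejected(self):
        s = spectrum_from_peaks([(960, 1.0, 20)])
        with pytest.raises(BandFitError):
            fit_band(s, Band("b", 900, 1000), seeds=[1200.0])

    def test_parameter_recovery_property(self):
        """Centers ±1 cm^-1, FWHM ±5%, areas ±5% on model-class bands with
        <=2% noise (seeded replicates)."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            c1 = rng.uniform(940, 980)
            c2 = c1 + rng.uniform(45, 80)
            peaks = [(c1, rng.uniform(0.5, 2.0), rng.uniform(12, 25)),
                     (c2, rng.uniform(0.5, 2.0), rng.uniform(12, 25))]
            s = spectrum_from_peaks(peaks, noise_sd=0.02 * max(a for _, a, _ in peaks),
                                    seed=int(rng.integers(1 << 31)))
            fit = fit_band(s, Band("b", 900, 1150), seeds=[c1, c2], fwhm_init=18.0)
            for (c, a, f), p in zip(peaks, fit.subpeaks):
                assert p.center == pytest.approx(c, abs=1.0)
                assert p.fwhm == pytest.approx(f, rel=0.05)
                assert p.area == pytest.approx(pv_area(a, f, 0.0), rel=0.05)


class TestPeakFwhm:
    def test_closed_form(self):
        s = spectrum_from_peaks([(960, 1.0, 20)])
        fit = fit_band(s, Band("b", 900, 1020), seeds=[960.0])
        sigma = peak_fwhm(fit, 960) / (2 * math.sqrt(2 * math.log(2)))
        assert peak_fwhm(fit, 960) == pytest.approx(2.3548 * sigma, rel=1e-4)
        assert 1.0 / peak_fwhm(fit, 960) == pytest.approx(0.05, rel=1e-3)

    def test_nearest_tie_toward_lower(self):
        s = spectrum_from_peaks([(955, 1.0, 14), (965, 1.0, 22)])
        fit = fit_band(s, Band("b", 900, 1020), seeds=[955.0, 965.0], center_tolerance=2.0)
        # 955 and 965 are equidistant from 960: the lower-wavenumber peak wins
        assert fit.nearest(960.0).center == pytest.approx(955, abs=0.5)

    def test_missing_peak_error(self):
        s = spectrum_from_peaks([(960, 1.0, 20)])
        fit = fit_band(s, Band("b", 900, 1020), seeds=[960.0])
        with pytest.raises(BandFitError, match="no subpeak"):
            peak_fwhm(fit, 1100)


class TestBandArea:
    def test_unit_rectangle(self):
        w = np.arange(800.0, 1001.0)
        y = np.where((w >= 900) & (w < 910), 1.0, 0.0)  # trapezoid area = width 10
        s = Spectrum(w, y, "raman_fingerprint")
        assert band_area(s, Band("r", 895, 915)) == pytest.approx(10.0, rel=0.01)

    def test_gaussian_trapezoid_vs_closed_form(self):
        s = spectrum_from_peaks([(1000, 1.3, 23.548)])  # sigma = 10
        got = band_area(s, Band("g", 900, 1100))
        assert got == pytest.approx(1.3 * 10 * math.sqrt(2 * math.pi), rel=0.005)

    def test_additive_over_disjoint_bands(self):
        s = spectrum_from_peaks([(950, 1.0, 15), (1100, 0.5, 15)])
        total = band_area(s, Band("t", 900, 1150))
        parts = band_area(s, Band("a", 900, 1025)) + band_area(s, Band("b", 1025, 1150))
        assert total == pytest.approx(parts, rel=0.01)

    def test_fit_mode_nonnegative_and_band_restricted(self):
        s = spectrum_from_peaks([(960, 1.0, 20), (1240, 0.5, 20)], grid=(800, 1300, 1.0))
        fit = fit_band(s, Band("wide", 900, 1290), seeds=[960.0, 1240.0])
        assert band_area(fit) >= 0
        inner = band_area(fit, Band("inner", 900, 1200))
        assert inner == pytest.approx(pv_area(1.0, 20.0, 0.0), rel=0.01)


class TestIntensityAt:
    def test_peak_at_center_and_offset(self):
        s = spectrum_from_peaks([(1003, 2.0, 10)])
        assert intensity_at(s, 1003) == pytest.approx(2.0, rel=1e-6)
        # peak at center+3 inside halfwidth 5: its height, not the on-grid value
        assert intensity_at(s, 1000, 5) == pytest.approx(2.0, rel=1e-6)

    def test_flat_value(self):
        s = spectrum_from_peaks([], baseline=0.7)
        assert intensity_at(s, 1000) == pytest.approx(0.7)

    def test_window_outside_grid(self):
        s = spectrum_from_peaks([])
        with pytest.raises(BandFitError):
            intensity_at(s, 1299, 5)
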