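import math

import numpy as np
import pytest
from scipy.integrate import quad

from modshift.mass_shift_detection import (
    DetectionConfig,
    GaussianFit,
    chi_square_goodness,
    detect_mass_shifts,
    fit_window_gaussian,
    quantify_and_shift,
    resolve_overlaps,
    scan_spectrum,
    shifts_to_dataframe,
)
from modshift.spectrum_io import CentroidPeakList
from modshift.synthetic_spectra import ModformSpec, NoiseModel, apply_noise, build_theoretical_spectrum


class TestChiSquare:
    def test_perfect_fit_gives_zero_and_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stat, p = chi_square_goodness(v, v)
        assert stat == 0.0
        assert p == 1.0

    def test_doubling_gives_sum_of_expected(self):
        e = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        stat, _ = chi_square_goodness(2 * e, e)
        assert stat == pytest.approx(e.sum())

    def test_five_percent_quantile_at_five_dof(self):
        # dof = 8 - 2 - 1 = 5; chi2(0.95, 5) = 11.07
        e = np.ones(8)
        o = e + np.sqrt(11.0705 / 8.0)
        stat, p = chi_square_goodness(o, e, n_fitted=2)
        assert stat == pytest.approx(11.0705, abs=1e-3)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_expected_points_excluded(self):
        o = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 9.9])
        e = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        stat, _ = chi_square_goodness(o, e)
        assert stat == 0.0  # the mismatching zero-expectation point is dropped

    def test_too_few_usable_points(self):
        with pytest.raises(ValueError, match=">= 5"):
            chi_square_goodness(np.ones(4), np.ones(4))


def _peaks_from_gaussian(mean, sigma, amp, span=6.0, noise_level=0.0):
    masses = np.arange(mean - span, mean + span + 0.5)
    intens = amp * np.exp(-((masses - mean) ** 2) / (2 * sigma**2))
    return CentroidPeakList(masses, intens, noise_level=noise_level)


class TestWindowFit:
    def test_noiseless_recovery(self):
        sigma = 3.0
        peaks = _peaks_from_gaussian(100.0, sigma, 0.8, span=4.0)
        cfg = DetectionConfig(window_size=9.0)
        fit = fit_window_gaussian(peaks, 95.5, sigma, cfg)
        assert fit is not None
        assert fit.mean == pytest.approx(100.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-6)
        assert fit.pvalue == pytest.approx(1.0)

    def test_fewer_than_five_signal_peaks_gives_none(self):
        peaks = CentroidPeakList(
            np.array([100.0, 101.0, 102.0, 103.0]), np.array([0.5, 1.0, 0.9, 0.4])
        )
        cfg = DetectionConfig(window_size=9.0)
        assert fit_window_gaussian(peaks, 98.0, 3.0, cfg) is None

    def test_peaks_below_noise_level_do_not_count(self):
        peaks = _peaks_from_gaussian(100.0, 3.0, 0.05, noise_level=0.2)
        cfg = DetectionConfig(window_size=9.0, noise_level=0.2)
        assert fit_window_gaussian(peaks, 95.5, 3.0, cfg) is None


def _fit(mean, pvalue, amplitude=1.0):
    return GaussianFit(mean=mean, amplitude=amplitude, sigma=3.0,
                       chi_square=0.0, pvalue=pvalue, window_start=mean - 4.5)


class TestResolveOverlaps:
    def test_close_pair_keeps_higher_pvalue(self):
        cfg = DetectionConfig(window_size=9.0, min_peak_distance=6.0)
        out = resolve_overlaps([_fit(100.0, 0.2), _fit(100.5, 0.9)], cfg)
        assert [f.mean for f in out] == [100.5]

    def test_distant_fits_both_survive(self):
        cfg = DetectionConfig(window_size=9.0, min_peak_distance=6.0)
        out = resolve_overlaps([_fit(100.0, 0.2), _fit(120.0, 0.9)], cfg)
        assert [f.mean for f in out] == [100.0, 120.0]

    def test_chain_resolved_best_first(self):
        # exhaustive reasoning: the 0.95 fit at 4 wins, excluding both others
        cfg = DetectionConfig(window_size=9.0, min_peak_distance=6.0)
        out = resolve_overlaps(
            [_fit(0.0, 0.9), _fit(4.0, 0.95), _fit(8.0, 0.9)], cfg
        )
        assert [f.mean for f in out] == [4.0]

    def test_result_independent_of_input_order(self, rng):
        cfg = DetectionConfig(window_size=9.0, min_peak_distance=6.0)
        fits = [_fit(float(m), float(p), float(a))
                for m, p, a in zip(rng.uniform(0, 60, 15),
                                   rng.uniform(0, 1, 15),
                                   rng.uniform(0.1, 1, 15))]
        ref_out = [f.mean for f in resolve_overlaps(fits, cfg)]
        for _ in range(5):
            rng.shuffle(fits)
            assert [f.mean for f in resolve_overlaps(list(fits), cfg)] == ref_out


class TestQuantify:
    class _Ref:
        reference_mass = 1000.0

    def test_area_matches_numerical_quadrature(self):
        # integral of 2*exp(-x^2/18) over the real line
        oracle, _ = quad(lambda x: 2.0 * math.exp(-(x**2) / 18.0), -np.inf, np.inf)
        [shift] = quantify_and_shift([_fit(1000.0, 1.0, amplitude=2.0)], self._Ref())
        assert shift.abundance == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(15.0398, abs=1e-3)

    def test_unit_gaussian_area_is_sqrt_two_pi(self):
        f = GaussianFit(mean=1000.0, amplitude=1.0, sigma=1.0,
                        chi_square=0.0, pvalue=1.0, window_start=0.0)
        [shift] = quantify_and_shift([f], self._Ref())
        assert shift.abundance == pytest.approx(math.sqrt(2 * math.pi), abs=1e-9)

    def test_single_fit_has_relative_abundance_one(self):
        [shift] = quantify_and_shift([_fit(1010.0, 0.5)], self._Ref())
        assert shift.relative_abundance == 1.0
        assert shift.shift == pytest.approx(10.0)

    def test_normalization_factor_rescales_area(self):
        [a] = quantify_and_shift([_fit(1000.0, 1.0)], self._Ref(), 1.0)
        [b] = quantify_and_shift([_fit(1000.0, 1.0)], self._Ref(), 250.0)
        assert b.abundance == pytest.approx(250.0 * a.abundance)
        assert b.relative_abundance == a.relative_abundance == 1.0

    def test_relative_abundances_sum_to_one(self, rng):
        fits = [_fit(100.0 * k, 0.5, float(a)) for k, a in enumerate(rng.uniform(0.1, 1, 6))]
        shifts = quantify_and_shift(fits, self._Ref(), 3.7)
        assert sum(s.relative_abundance for s in shifts) == pytest.approx(1.0, abs=1e-9)


class TestEndToEnd:
    def test_single_clean_species_gives_one_fit_within_20ppm(self, p53_ref):
        spec = ModformSpec.from_shifts(p53_ref, [(0.0, 1.0)])
        lo = p53_ref.reference_mass - 35
        hi = p53_ref.reference_mass + 35
        clean = build_theoretical_spectrum(spec, lo=lo, hi=hi)
        shifts = detect_mass_shifts(clean, p53_ref, lo, hi)
        assert len(shifts) == 1
        ppm = abs(shifts[0].mean - p53_ref.reference_mass) / p53_ref.reference_mass * 1e6
        assert ppm <= 20.0

    def test_pvalue_declines_with_vertical_noise(self, p53_ref):
        # statistical sanity: stronger peak-height scatter worsens the fit
        spec = ModformSpec.from_shifts(p53_ref, [(0.0, 1.0)])
        lo = p53_ref.reference_mass - 35
        hi = p53_ref.reference_mass + 35
        clean = build_theoretical_spectrum(spec, lo=lo, hi=hi)
        means = {}
        for vw in (0.02, 0.25):
            ps = []
            for seed in range(25):
                model = NoiseModel(basal_scale=0.0, horizontal_width=0.0,
                                   vertical_width=vw, seed=seed)
                noisy = apply_noise(clean, model)
                shifts = detect_mass_shifts(noisy, p53_ref, lo, hi)
                if shifts:
                    ps.append(max(s.pvalue for s in shifts))
            means[vw] = np.mean(ps)
        assert means[0.25] < means[0.02]

    def test_shift_table_columns(self, p53_ref):
        spec = ModformSpec.from_shifts(p53_ref, [(0.0, 0.6), (200.0, 0.4)])
        lo = p53_ref.reference_mass - 35
        hi = p53_ref.reference_mass + 235
        clean = build_theoretical_spectrum(spec, lo=lo, hi=hi, source_id="s1")
        df = shifts_to_dataframe(detect_mass_shifts(clean, p53_ref, lo, hi))
        assert list(df.columns) == [
            "sample_id", "mean_da", "shift_da", "pvalue", "abundance", "relative_abundance",
        ]
        assert len(df) == 2
        assert (df["sample_id"] == "s1").all()


def test_window_size_must_exceed_five_da():
    with pytest.raises(ValueError, match="bigger than 5"):
        DetectionConfig(window_size=4.0)
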