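import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from epibind import boltzmann, spectra, synth
from epibind.peptides import PROTON_MASS, mz
from epibind.spectra import (EductCourse, PeakCollisionWarning, Spectrum,
                             combine_scans, deconvolute_mass, fit_envelope,
                             normalized_educt, read_height,
                             read_species_heights, smooth)


def flat_spectrum(lo=1000.0, hi=2000.0, step=0.5, level=0.0):
    g = np.arange(lo, hi, step)
    return Spectrum(g, np.full(len(g), level))


class TestCombineScans:
    def test_idempotent_on_identical_scans(self):
        s = flat_spectrum(level=5.0)
        out = combine_scans([s, s])
        assert np.array_equal(out.intensity, s.intensity)

    def test_pointwise_mean(self):
        g = np.arange(100.0, 110.0, 1.0)
        out = combine_scans([Spectrum(g, np.zeros(10)), Spectrum(g, np.full(10, 2.0))])
        assert np.allclose(out.intensity, 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_scans([])

    def test_mismatched_grids_preserve_total_ion_current(self):
        """Resampling then averaging keeps the trapezoid integral within 1%."""
        g1 = np.linspace(500, 600, 2001)
        g2 = np.linspace(500, 600, 1601)
        peak = lambda g: 100 * np.exp(-0.5 * ((g - 550) / 3.0) ** 2) + 1.0
        s1, s2 = Spectrum(g1, peak(g1)), Spectrum(g2, peak(g2))
        out = combine_scans([s1, s2])
        tic = np.trapezoid(out.intensity, out.mz)
        expected = (np.trapezoid(s1.intensity, s1.mz)
                    + np.trapezoid(s2.intensity, s2.mz)) / 2
        assert tic == pytest.approx(expected, rel=0.01)


class TestSmooth:
    def test_low_degree_polynomial_unchanged_in_interior(self):
        g = np.arange(0.0, 100.0, 0.5)
        y = 3.0 + 0.2 * g + 0.01 * g ** 2
        out = smooth(Spectrum(g, y), window=10, passes=20, polyorder=2)
        assert np.allclose(out.intensity[30:-30], y[30:-30], atol=1e-9)

    def test_zero_passes_is_identity(self):
        g = np.arange(0.0, 50.0, 0.5)
        y = np.random.default_rng(0).random(len(g))
        out = smooth(Spectrum(g, y), passes=0)
        assert np.array_equal(out.intensity, y)

    def test_spike_response_equals_iterated_kernel(self):
        """Interior spike response equals explicit repeated convolution with
        the Savitzky-Golay kernel (independent oracle)."""
        g = np.arange(0.0, 200.0, 1.0)
        y = np.zeros(len(g))
        y[100] = 7.0
        passes = 5
        out = smooth(Spectrum(g, y), window=10, passes=passes, polyorder=2)
        kernel = savgol_coeffs(11, 2)
        ref = y.copy()
        for _ in range(passes):
            ref = np.convolve(ref, kernel, mode="same")
        assert np.allclose(out.intensity[50:150], ref[50:150], atol=1e-12)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            smooth(Spectrum(np.arange(5.0), np.zeros(5)))


class TestReadHeight:
    def test_reads_synthetic_apex(self, clean_recipe, clean_series):
        spec = clean_series.steps[0][1]
        h = read_height(spec, clean_recipe.antibody_mass + clean_recipe.peptide_mass,
                        25, 5.0)
        assert h > 0

    def test_flat_background_returns_background_level(self):
        s = flat_spectrum(level=10.0)
        assert read_height(s, 1500.0 * 2 - 2 * PROTON_MASS, 2, 1.0) == 10.0

    def test_window_outside_range_flagged_missing(self):
        s = flat_spectrum(1000, 2000)
        assert read_height(s, 500000.0, 2, 1.0) is None

    def test_collision_warning_for_overlapping_species(self):
        s = flat_spectrum(1000, 2000)
        masses = {"a": 2998.0, "b": 2998.5}  # 0.25 Th apart at 2+
        with pytest.warns(PeakCollisionWarning):
            read_species_heights(s, masses, 2, 1.0)


class TestFitEnvelope:
    def test_symmetric_envelope(self):
        pts = {23: 10.0, 24: 40.0, 25: 100.0, 26: 40.0, 27: 10.0}
        env = fit_envelope(pts, background=1.0)
        assert env.center_charge == pytest.approx(25.0, abs=0.01)
        assert env.apex_height == pytest.approx(100.0, rel=0.05)
        assert not env.imputed

    def test_imputation_to_five_points(self):
        env = fit_envelope({24: 30.0, 25: 90.0, 26: 35.0}, background=2.0)
        assert len(env.imputed) == 2
        assert len(env.points) == 5
        assert env.detected

    def test_all_background_is_non_detect(self):
        env = fit_envelope({24: 1.0, 25: 1.0, 26: 1.0}, background=1.0)
        assert env.center_charge is None
        assert env.apex_height == 1.0

    def test_matches_grid_search_oracle_on_asymmetric_envelope(self):
        """Least-squares center equals a brute-force grid search over
        (height, center, width) within 0.05 charge units."""
        true = (80.0, 24.7, 1.1)
        zs = np.arange(22, 29)
        ys = true[0] * np.exp(-0.5 * ((zs - true[1]) / true[2]) ** 2)
        pts = {int(z): float(y) for z, y in zip(zs, ys)}
        env = fit_envelope(pts, background=0.0)

        hh = np.linspace(60, 100, 81)
        cc = np.linspace(23.5, 26.0, 251)
        ww = np.linspace(0.6, 2.0, 141)
        best = (np.inf, None)
        for h in hh:
            for w in ww:
                pred = h * np.exp(-0.5 * ((zs[None, :] - cc[:, None]) / w) ** 2)
                sse = ((pred - ys[None, :]) ** 2).sum(axis=1)
                i = int(np.argmin(sse))
                if sse[i] < best[0]:
                    best = (sse[i], cc[i])
        assert env.center_charge == pytest.approx(best[1], abs=0.05)
        assert env.apex_height == pytest.approx(true[0], rel=0.01)

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            fit_envelope({}, background=0.0)


class TestNormalizedEduct:
    def test_basic_arithmetic(self):
        h = {"antibody": 10, "complex1": 30, "complex2": 10, "peptide": 0}
        assert normalized_educt(h) == pytest.approx(80.0)

    def test_fully_dissociated(self):
        h = {"antibody": 50, "complex1": 0, "complex2": 0, "peptide": 50}
        assert normalized_educt(h) == pytest.approx(0.0)

    def test_invariant_under_uniform_scaling(self):
        h = {"antibody": 12.0, "complex1": 7.0, "complex2": 3.0, "peptide": 5.0}
        scaled = {k: 13.7 * v for k, v in h.items()}
        assert normalized_educt(scaled) == pytest.approx(normalized_educt(h))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            normalized_educt({"antibody": 0, "complex1": 0, "complex2": 0})

    def test_missing_species_rejected(self):
        with pytest.raises(ValueError):
            normalized_educt({"antibody": 1, "complex1": 1})


class TestDeconvoluteMass:
    def test_two_adjacent_peaks_forward_inverse(self):
        peaks = [(mz(100000.0, 20), None), (mz(100000.0, 21), None)]
        mass, sd = deconvolute_mass(peaks)
        assert mass == pytest.approx(100000.0, abs=0.1)

    def test_single_peak_with_known_charge(self):
        m = 25 * (5001.00728 - PROTON_MASS)
        mass, sd = deconvolute_mass([(5001.00728, 25)])
        assert mass == pytest.approx(m, abs=1e-6)
        assert sd == 0.0

    def test_interleaved_masses_rejected(self):
        peaks = [(mz(100000.0, 20), None), (mz(120000.0, 21), None),
                 (mz(100000.0, 21), None)]
        with pytest.raises(ValueError):
            deconvolute_mass(peaks)

    @pytest.mark.parametrize("mass_da", [50000.0, 120000.0, 200000.0])
    def test_round_trip_within_one_ppm(self, mass_da):
        zs = range(22, 26)
        peaks = [(mz(mass_da, z), None) for z in zs]
        got, _ = deconvolute_mass(peaks)
        assert got == pytest.approx(mass_da, rel=1e-6)


class TestClosedLoop:
    def test_noise_free_series_recovers_generating_curve(self, clean_recipe,
                                                         clean_processed):
        truth = synth.ground_truth_course(clean_recipe)
        assert np.max(np.abs(clean_processed.educt - truth)) < 1e-6

    def test_noisy_series_recovers_within_noise(self):
        r = synth.SimulationRecipe(noise_sd=0.02, seed=11)
        res = spectra.process_series(synth.simulate_series(r),
                                     r.antibody_mass, r.peptide_mass)
        truth = synth.ground_truth_course(r)
        resid = np.abs(res.educt - truth)
        # 95% of steps within 3 sigma of the course-level noise scale
        assert np.mean(resid < 3 * 2.0) >= 0.95

    def test_noisy_fit_recovers_midpoint(self):
        r = synth.SimulationRecipe(noise_sd=0.02, seed=42)
        res = spectra.process_series(synth.simulate_series(r),
                                     r.antibody_mass, r.peptide_mass)
        fit = boltzmann.fit(res.dcv, res.educt)
        assert fit.x0 == pytest.approx(30.0, abs=0.5)

    def test_per_charge_courses_match_truth_noise_free(self, clean_recipe,
                                                       clean_processed):
        """Per-charge courses normalize over the heavy species only (the
        released peptide carries unrelated charges), so the expected fraction
        is educt/(educt + antibody) from the generator's height bookkeeping."""
        expected = np.array([
            100.0 * (h["complex1"] + h["complex2"])
            / (h["antibody"] + h["complex1"] + h["complex2"])
            for h in synth.species_heights(clean_recipe)
        ])
        for z, course in clean_processed.per_charge.items():
            assert np.max(np.abs(course - expected)) < 1e-6


class TestCourseContainer:
    def test_course_bounds_enforced(self):
        with pytest.raises(ValueError):
            EductCourse([2, 4], [50.0, 120.0], [0, 0], [1, 1])

    def test_aggregate_replicates(self, clean_recipe):
        a = spectra.process_series(synth.simulate_series(clean_recipe),
                                   clean_recipe.antibody_mass,
                                   clean_recipe.peptide_mass)
        course = spectra.aggregate_courses([a, a])
        assert np.allclose(course.sd, 0.0)
        assert np.all(course.n == 2)
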