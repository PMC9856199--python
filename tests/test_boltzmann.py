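import numpy as np
import pytest

from epibind import boltzmann
from epibind.boltzmann import (BoltzmannFit, NoTransitionError, boltzmann_value,
                               fit, tangent_line, tangent_slope)
from epibind.reference import COURSE_PARAMS


class TestSigmoidValue:
    def test_midpoint_is_mean_of_plateaus(self):
        assert boltzmann_value(30.0, 77.36, 36.24, 30.0, 15.2) == pytest.approx(
            (77.36 + 36.24) / 2)

    def test_asymptotes(self):
        assert boltzmann_value(-1e6, 77.36, 36.24, 30.0, 15.2) == pytest.approx(77.36)
        assert boltzmann_value(1e6, 77.36, 36.24, 30.0, 15.2) == pytest.approx(36.24)

    def test_closed_form_value(self):
        # direct evaluation: A2 + (A1-A2)/(1+exp((2-30)/15.2))
        expected = 36.24 + (77.36 - 36.24) / (1 + np.exp((2 - 30.0) / 15.2))
        v = boltzmann_value(2.0, 77.36, 36.24, 30.0, 15.2)
        assert v == pytest.approx(expected, abs=1e-12)
        assert round(v, 2) == 71.73

    def test_zero_dx_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_value(1.0, 77.0, 36.0, 30.0, 0.0)


class TestTangent:
    @pytest.mark.parametrize("num", [n for n in COURSE_PARAMS
                                     if COURSE_PARAMS[n][2] is not None])
    def test_slope_identity_reproduces_published_values(self, num):
        """-(A1-A2)/(4 dx) on the published initial/final/dx reproduces the
        published tangent slope for every orthodox course (within 0.02)."""
        a1, a2, _, dx, slope, _ = COURSE_PARAMS[num]
        assert tangent_slope(a1, a2, dx) == pytest.approx(slope, abs=0.02)

    def test_flat_curve_has_zero_slope(self):
        assert tangent_slope(40.0, 40.0, 10.0) == 0.0

    def test_tangent_line_passes_through_midpoint(self):
        f = BoltzmannFit(a1=77.36, a2=36.24, x0=30.0, dx=15.2, r2=1.0,
                         data_initial=77.0, data_final=36.0)
        s, b = tangent_line(f)
        assert s + 0 == f.slope
        assert s * f.x0 + b == pytest.approx((f.a1 + f.a2) / 2)


class TestFit:
    def test_exact_data_recovery(self, cv_steps):
        y = boltzmann_value(cv_steps, 77.36, 36.24, 30.0, 15.2)
        f = fit(cv_steps, y)
        for got, want in zip((f.a1, f.a2, f.x0, f.dx), (77.36, 36.24, 30.0, 15.2)):
            assert got == pytest.approx(want, abs=1e-6)
        assert f.r2 == pytest.approx(1.0, abs=1e-12)
        assert f.slope == pytest.approx(-(f.a1 - f.a2) / (4 * f.dx), abs=1e-12)

    def test_noisy_recovery_median_midpoint(self, cv_steps):
        """With 2-percentage-point course noise a single fit scatters by a few
        volts, but the median midpoint over seeded replicates stays on
        target."""
        true = boltzmann_value(cv_steps, 77.36, 36.24, 30.0, 15.2)
        xs = []
        for child in np.random.SeedSequence(7).spawn(300):
            rng = np.random.default_rng(child)
            xs.append(fit(cv_steps, true + rng.normal(0, 2.0, len(cv_steps))).x0)
        assert np.median(xs) == pytest.approx(30.0, abs=1.0)

    def test_recovery_error_and_interval_coverage_at_low_noise(self, cv_steps):
        """At half-point course noise the median absolute midpoint error and
        the 95% confidence-interval coverage stay in their measured bands
        (frozen from a 200-replicate calibration run)."""
        true = boltzmann_value(cv_steps, 77.36, 36.24, 30.0, 15.2)
        errs, cover = [], 0
        for i in range(200):
            rng = np.random.default_rng(i)
            f = fit(cv_steps, true + rng.normal(0, 0.5, len(cv_steps)))
            errs.append(abs(f.x0 - 30.0))
            se = np.sqrt(f.covariance[2, 2])
            cover += abs(f.x0 - 30.0) <= 1.96 * se
        assert np.median(errs) < 1.2
        assert 0.85 <= cover / 200 <= 0.99

    def test_flat_course_refused(self, cv_steps):
        """A weak-binder course spanning under 10 percentage points carries no
        transition and the fit is refused."""
        y = np.linspace(15.37, 5.90, len(cv_steps))
        with pytest.raises(NoTransitionError):
            fit(cv_steps, y)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit([2, 4, 6, 8], [70, 60, 50, 40])

    def test_excluded_points_recorded(self, cv_steps):
        y = boltzmann_value(cv_steps, 77.36, 36.24, 30.0, 15.2)
        f = fit(cv_steps, y, exclude=(3,))
        assert f.excluded_points == (3,)

    def test_data_initial_final_are_endpoint_values(self, cv_steps):
        y = boltzmann_value(cv_steps, 77.36, 36.24, 30.0, 15.2)
        f = fit(cv_steps, y)
        assert f.data_initial == pytest.approx(y[0])
        assert f.data_final == pytest.approx(y[-1])

    def test_matches_grid_search_oracle(self):
        """On a small noise-free instance the least-squares optimum matches a
        brute-force grid search over all four parameters."""
        x = np.array([0, 10, 20, 30, 40, 50, 60], dtype=float)
        true = (90.0, 20.0, 25.0, 8.0)
        y = boltzmann_value(x, *true)
        best = (np.inf, None)
        for a1 in np.linspace(85, 95, 11):
            for a2 in np.linspace(15, 25, 11):
                for x0 in np.linspace(20, 30, 21):
                    for dx in np.linspace(5, 11, 13):
                        sse = float(np.sum((boltzmann_value(x, a1, a2, x0, dx) - y) ** 2))
                        if sse < best[0]:
                            best = (sse, (a1, a2, x0, dx))
        f = fit(x, y)
        # the grid contains the truth, so the oracle lands exactly there
        assert best[1] == pytest.approx(true)
        assert f.x0 == pytest.approx(best[1][2], abs=0.05)
        assert f.a1 == pytest.approx(best[1][0], abs=0.1)
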