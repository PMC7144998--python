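"""Deterministic survival-model core: hazard, links, likelihood, predictions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.special import expit
from scipy.stats import binom, norm, poisson

from gobysurv import survival as sv


class TestCumulativeMortality:
    def test_zero_time_gives_zero_hazard(self):
        assert sv.cumulative_mortality(0.7, 3.1, 0.0) == 0.0

    def test_asymptote_is_m0_times_tau(self):
        assert sv.cumulative_mortality(1.0, 1.0, 1e9) == pytest.approx(1.0)
        # fleet-median hazard: M_inf = 0.298 * 2.57, survival fraction ~0.465
        m_inf = sv.cumulative_mortality(0.298, 2.57, 1e9)
        assert m_inf == pytest.approx(0.76586, abs=1e-4)
        assert math.exp(-m_inf) == pytest.approx(0.465, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sv.cumulative_mortality(0.3, -1.0, 2.0)
        with pytest.raises(ValueError):
            sv.cumulative_mortality(0.3, 1.0, -0.5)

    @given(
        m0=st.floats(0.01, 2.0),
        tau=st.floats(0.1, 10.0),
        t=st.floats(0.0, 50.0),
        dt=st.floats(0.01, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_nondecreasing_bounded(self, m0, tau, t, dt):
        a = sv.cumulative_mortality(m0, tau, t)
        b = sv.cumulative_mortality(m0, tau, t + dt)
        assert 0.0 <= a <= b <= m0 * tau + 1e-12

    @given(m0=st.floats(0.01, 2.0), tau=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_early_hazard_is_linear(self, m0, tau):
        t = 0.01 * tau
        assert sv.cumulative_mortality(m0, tau, t) == pytest.approx(m0 * t, rel=0.01)


class TestExpectedSurvivors:
    def test_zero_hazard_keeps_everyone(self):
        assert sv.expected_survivors(1.0, 100, 0.0, 1.0, 5.0) == pytest.approx(100.0)

    def test_time_zero_is_immediate_survivors(self):
        assert sv.expected_survivors(0.5, 100, 0.9, 2.0, 0.0) == pytest.approx(50.0)

    def test_fleet_median_haul_after_ten_hours(self):
        # frozen from direct evaluation, cross-checked by the ODE below
        val = sv.expected_survivors(1.0, 100, 0.298, 2.57, 10.0)
        assert val == pytest.approx(47.23, abs=0.05)

    def test_matches_ode_integration(self):
        """dN/dt = -m(t) N with m(t) = m0 exp(-t/tau), 20-point grid."""
        m0, tau, n0 = 0.298, 2.57, 100.0
        grid = np.linspace(0.0, 12.0, 20)
        sol = solve_ivp(
            lambda t, y: -m0 * np.exp(-t / tau) * y,
            (0.0, 12.0),
            [n0],
            t_eval=grid,
            rtol=1e-10,
            atol=1e-12,
        )
        ours = sv.expected_survivors(1.0, n0, m0, tau, grid)
        np.testing.assert_allclose(ours, sol.y[0], atol=1e-6)

    def test_invalid_s0_rejected(self):
        with pytest.raises(ValueError):
            sv.expected_survivors(1.2, 10, 0.1, 1.0, 1.0)


class TestLinearPredictors:
    def test_centering_identity(self, reference_params, reference_centering):
        m0, s0 = sv.linear_predictors(
            reference_params, 25.7, 15.7, 15.7, centering=reference_centering
        )
        assert m0 == pytest.approx(reference_params.alpha0)
        assert s0 == pytest.approx(expit(5.520), abs=1e-6)
        assert s0 == pytest.approx(0.996, abs=1e-3)

    def test_depth_slope_on_m0(self, reference_params, reference_centering):
        m0, _ = sv.linear_predictors(
            reference_params, 35.7, 15.7, 15.7, centering=reference_centering
        )
        assert m0 == pytest.approx(0.298 + 0.0084 * 10, abs=1e-9)

    def test_trip_effects_applied_and_unknown_trip_is_zero(self, small_params):
        cent = sv.Centering(25.0, 15.0, 17.0)
        m0_a, _ = sv.linear_predictors(small_params, 25.0, 15.0, 17.0, "tA", cent)
        m0_new, _ = sv.linear_predictors(small_params, 25.0, 15.0, 17.0, "tZ", cent)
        assert m0_a == pytest.approx(small_params.alpha0 + 0.05)
        assert m0_new == pytest.approx(small_params.alpha0)

    def test_m0_clipped_at_zero(self, small_params):
        cent = sv.Centering(25.0, 15.0, 17.0)
        m0, _ = sv.linear_predictors(small_params, 25.0, 15.0, -50.0, None, cent)
        assert m0 == 0.0


class TestAsymptoticSurvival:
    def test_limits(self):
        assert sv.asymptotic_survival(1.0, 0.0, 3.0) == 1.0
        assert sv.asymptotic_survival(0.5, 1e9, 1.0) == pytest.approx(0.0)

    def test_fleet_median_value(self):
        assert sv.asymptotic_survival(0.996, 0.298, 2.57) == pytest.approx(0.463, abs=1e-3)


class TestRelativeSurvival:
    def test_reference_point_is_one(self, reference_params):
        assert sv.relative_survival(reference_params, 25.7, 15.7) == pytest.approx(1.0)

    def test_ten_meters_deeper_costs_about_twenty_percent(self, reference_params):
        ratio = sv.relative_survival(reference_params, 35.7, 15.7)
        assert ratio == pytest.approx(0.81, abs=0.02)

    def test_temperature_for_doubled_mortality(self, reference_params):
        dT = sv.mortality_doubling_temperature(reference_params)
        assert dT == pytest.approx(math.log(2) / (0.094 * 2.57), abs=1e-6)
        assert dT == pytest.approx(2.87, abs=0.01)

    def test_handling_mortality_cancels(self, reference_params):
        """Additive handling hazard (a constant shift of m0 everywhere)
        leaves the survival ratio unchanged."""
        import dataclasses

        base = sv.relative_survival(reference_params, 30.0, 16.0)
        for c in (0.1, 0.5, 2.0):
            shifted = dataclasses.replace(
                reference_params, alpha0=reference_params.alpha0 + c
            )
            assert sv.relative_survival(shifted, 30.0, 16.0) == pytest.approx(
                base, rel=1e-12
            )


class TestRelativeSurvivalGrid:
    def test_monotone_in_temperature_and_reference_contour(self, reference_params):
        depths, temps, values = sv.relative_survival_grid(reference_params, n_grid=41)
        # alpha2 > 0 (and beta2 < 0): survival falls with temperature at fixed depth
        assert (np.diff(values, axis=1) < 0).all()
        contours = sv.iso_contours(depths, temps, values, [1.0])
        pts = np.vstack(contours[1.0])
        d_at_ref_temp = np.interp(15.7, pts[::-1, 1], pts[::-1, 0])
        dist = np.min(np.hypot(pts[:, 0] - 25.7, (pts[:, 1] - 15.7) * 10))
        assert dist < 1.0  # contour passes near (25.7 m, 15.7 C)

    def test_half_survival_isoline_position(self, reference_params):
        """The 0.5 iso-ratio at the reference depth sits where the model's
        own root lies, ~2.7-2.9 C above the reference temperature."""
        from scipy.optimize import brentq

        dT_star = brentq(
            lambda dT: sv.relative_survival(reference_params, 25.7, 15.7 + dT) - 0.5,
            0.1,
            10.0,
        )
        assert dT_star == pytest.approx(2.87, abs=0.2)
        depths, temps, values = sv.relative_survival_grid(
            reference_params, temp_range=(14.5, 19.5), n_grid=81
        )
        contours = sv.iso_contours(depths, temps, values, [0.5])
        pts = np.vstack(contours[0.5])
        t_at_ref_depth = pts[np.argmin(np.abs(pts[:, 0] - 25.7)), 1]
        assert t_at_ref_depth - 15.7 == pytest.approx(dT_star, abs=0.1)

    def test_empty_range_rejected(self, reference_params):
        with pytest.raises(ValueError):
            sv.relative_survival_grid(reference_params, depth_range=(30.0, 20.0))


class TestLogLikelihood:
    def test_degenerate_haul(self):
        h = sv.HaulObservation("t0", "h0", 100, 100, 60, 4.0, 25.0, 15.0, 15.0)
        h2 = sv.HaulObservation("t1", "h1", 100, 100, 70, 4.0, 25.0, 15.0, 15.0)
        params = sv.SurvivalParams(
            alpha0=0.0, alpha1=0.0, alpha2=0.0,
            beta0=50.0, beta1=0.0, beta2=0.0, tau=1.0,
        )
        cent = sv.Centering(25.0, 15.0, 15.0)
        # s0 ~ 1 and m0 = 0: binomial term ~ 0, Poisson mean = n0
        ll = sv.log_likelihood([h, h2], params, cent, hierarchical=False)
        expected = poisson.logpmf(60, 100) + poisson.logpmf(70, 100)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_matches_textbook_pmf_sum(self, three_hauls, small_params):
        """Brute-force oracle: scipy binomial + Poisson + normal densities."""
        cent = sv.Centering(25.0, 15.5, 17.5)
        expected = 0.0
        for h in three_hauls:
            dd = h.depth_m - cent.depth_ref
            m0 = (small_params.alpha0 + small_params.alpha1 * dd
                  + small_params.alpha2 * (h.tempf_C - cent.tempf_ref)
                  + small_params.rnd1[h.trip_id])
            m0 = max(m0, 0.0)
            s0 = expit(small_params.beta0 + small_params.beta1 * dd
                       + small_params.beta2 * (h.temp0_C - cent.temp0_ref)
                       + small_params.rnd2[h.trip_id])
            M = m0 * small_params.tau * (1 - math.exp(-h.t_hours / small_params.tau))
            expected += binom.logpmf(h.n0_alive, h.n_total, s0)
            expected += poisson.logpmf(h.nf_alive, h.n0_alive * math.exp(-M))
        for d in (small_params.rnd1, small_params.rnd2):
            sigma = small_params.sigma1 if d is small_params.rnd1 else small_params.sigma2
            for v in d.values():
                expected += norm.logpdf(v, 0.0, sigma)
        ours = sv.log_likelihood(three_hauls, small_params, cent)
        assert ours == pytest.approx(expected, abs=1e-9)

    def test_zero_mean_with_positive_count_is_minus_inf(self):
        h = sv.HaulObservation("t0", "h0", 50, 40, 10, 4.0, 25.0, 15.0, 15.0)
        params = sv.SurvivalParams(
            alpha0=1e9, alpha1=0.0, alpha2=0.0,
            beta0=0.0, beta1=0.0, beta2=0.0, tau=1.0,
        )
        cent = sv.Centering(25.0, 15.0, 15.0)
        assert sv.log_likelihood([h], params, cent, hierarchical=False) == -np.inf

    def test_sigma_to_zero_approaches_fixed_effects(self, three_hauls):
        import dataclasses

        cent = sv.Centering(25.0, 15.5, 17.5)
        base = sv.SurvivalParams(
            alpha0=0.3, alpha1=0.0, alpha2=0.0,
            beta0=3.0, beta1=0.0, beta2=0.0, tau=2.0,
            sigma1=1e-3, sigma2=1e-3,
            rnd1={"tA": 0.0, "tB": 0.0}, rnd2={"tA": 0.0, "tB": 0.0},
        )
        fixed = sv.log_likelihood(
            three_hauls,
            dataclasses.replace(base, sigma1=0.0, sigma2=0.0, rnd1={}, rnd2={}),
            cent,
        )
        # hierarchical density at rnd=0 differs only by the normal normalising
        # constants, which -> a point mass as sigma -> 0
        hier = sv.log_likelihood(three_hauls, base, cent)
        assert hier - fixed == pytest.approx(
            2 * 2 * (-0.5 * math.log(2 * math.pi) - math.log(1e-3)), abs=1e-9
        )


class TestFilterHauls:
    def test_threshold_minus_inf_retains_all(self, three_hauls):
        kept, report = sv.filter_hauls(three_hauls, -np.inf)
        assert len(kept) == 3 and report == []

    def test_two_of_five_below_threshold(self, three_hauls):
        extra = [
            sv.HaulObservation("tC", "tC-h0", 100, 90, 40, 4.0, 20.0, 15.0, 16.0, 1.0),
            sv.HaulObservation("tC", "tC-h1", 100, 90, 40, 4.0, 20.0, 15.0, 16.0, 2.0),
        ]
        kept, report = sv.filter_hauls(three_hauls + extra, 3.0)
        assert len(kept) == 3 and len(report) == 2
        assert {r["haul_id"] for r in report} == {"tC-h0", "tC-h1"}

    def test_missing_reading_passes_with_warning(self):
        h = sv.HaulObservation("t0", "h0", 10, 9, 5, 2.0, 20.0, 15.0, 16.0, None)
        with pytest.warns(UserWarning, match="no oxygen"):
            kept, report = sv.filter_hauls([h], 3.0)
        assert kept == [h] and report == []

    def test_study_scale_exclusion_flow(self, rng):
        """47 hauls, 6 constructed below threshold -> 41 analysed."""
        hauls = []
        for i in range(47):
            hauls.append(
                sv.HaulObservation(
                    f"t{i // 3}", f"h{i}", 100, 95, 50, 4.0, 25.0, 15.5, 17.0,
                    oxygen=(2.0 if i < 6 else 6.0),
                )
            )
        kept, report = sv.filter_hauls(hauls, 4.0)
        assert len(kept) == 41 and len(report) == 6


class TestHaulObservationValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nf_alive": 95, "n0_alive": 90},   # nf > n0
            {"n0_alive": 150},                   # n0 > n_total
            {"t_hours": 0.0},
            {"depth_m": -3.0},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        base = dict(
            trip_id="t", haul_id="h", n_total=100, n0_alive=90, nf_alive=50,
            t_hours=4.0, depth_m=25.0, temp0_C=15.0, tempf_C=16.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            sv.HaulObservation(**base)
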