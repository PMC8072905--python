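"""Structural and numerical checks of the EHR compartmental models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ehrpk
from ehrpk import (DispositionParams, DoseSchedule, ModelParams,
                   ModelStructureError, Route, SolverConfig, ehr_fraction,
                   gbr, reference_params, rhs, simulate_amounts,
                   simulate_profile)
from ehrpk.model import state_labels


class TestGbr:
    @pytest.mark.parametrize("tau, expected", [
        (1.0, 1.0),
        (1.46, 1 / 1.46),
        (31.5, 1 / 31.5),
    ])
    def test_reciprocal(self, tau, expected):
        assert gbr(tau) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("tau", [0.0, -1.0])
    def test_nonpositive_rejected(self, tau):
        with pytest.raises(ValueError):
            gbr(tau)


class TestRhs:
    def test_no_flux_when_all_rates_zero(self, mean_params, schedules):
        p = mean_params[Route.IV].with_values(cl=0, cl2=0, k_cb=0, k_gc=0)
        state = np.array([1000.0, 500.0, 0.0, 0.0])
        dy = rhs(0.0, state, p, schedules[Route.IV])
        assert np.allclose(dy, 0.0)

    def test_ehr_off_reduces_to_two_compartment(self, mean_params, schedules):
        p = mean_params[Route.IV].with_values(k_cb=0)
        c = simulate_amounts(p, schedules[Route.IV], [0.5, 2, 10, 48])
        labels = state_labels(p)
        assert np.allclose(c[:, labels.index("bile")], 0.0)
        assert np.allclose(c[:, labels.index("gut")], 0.0)

    def test_oral_initial_derivatives(self, mean_params, schedules):
        p = mean_params[Route.ORAL]
        labels = state_labels(p)
        state = np.zeros(len(labels))
        D = 5.0e5
        state[labels.index("depot")] = D
        dy = rhs(0.0, state, p, schedules[Route.ORAL])
        assert dy[labels.index("central")] == pytest.approx(
            p.absorp.ka1 * D, rel=1e-12)
        assert dy[labels.index("transit1")] == pytest.approx(
            p.absorp.ka2 * D, rel=1e-12)
        assert dy[labels.index("depot")] == pytest.approx(
            -(p.absorp.ka1 + p.absorp.ka2) * D, rel=1e-12)

    def test_dimension_mismatch_rejected(self, mean_params, schedules):
        with pytest.raises(ModelStructureError):
            rhs(0.0, np.zeros(3), mean_params[Route.IV], schedules[Route.IV])


class TestSimulate:
    def test_iv_bolus_initial_concentration(self, mean_params, schedules):
        c = simulate_profile(mean_params[Route.IV], schedules[Route.IV],
                             [0.0])
        assert c[0] == pytest.approx(5.0e5 / 110.0, rel=1e-12)

    @pytest.mark.parametrize("route", list(Route))
    def test_mass_conservation_without_elimination(self, route, mean_params,
                                                   schedules, sample_times):
        p = mean_params[route].with_values(cl=0)
        amounts = simulate_amounts(p, schedules[route], sample_times[route])
        released = 5.0e5 * p.absorp.released_fraction
        totals = amounts.sum(axis=1)
        if route is Route.SUPRALINGUAL:
            # dose still entering during the release window
            t = sample_times[route]
            frac_in = np.clip((t - p.absorp.t_lag)
                              / (p.absorp.patch_duration - p.absorp.t_lag),
                              0, 1)
            expected = released * frac_in
        else:
            expected = np.full_like(totals, released)
        assert np.allclose(totals, expected, rtol=1e-6)

    @pytest.mark.parametrize("route", list(Route))
    def test_total_mass_never_exceeds_released_dose(self, route, mean_params,
                                                    schedules, sample_times):
        amounts = simulate_amounts(mean_params[route], schedules[route],
                                   sample_times[route])
        released = 5.0e5 * mean_params[route].absorp.released_fraction
        assert np.all(amounts >= 0)
        assert np.all(amounts.sum(axis=1) <= released * (1 + 1e-9))

    @pytest.mark.parametrize("method", ["expm", "lsoda"])
    def test_two_compartment_closed_form(self, method, mean_params,
                                         schedules, sample_times):
        """IV with the biliary path off must match the independent
        biexponential solution of the two-compartment model."""
        p = mean_params[Route.IV].with_values(k_cb=0)
        d = p.disp
        k10, k12, k21 = d.cl / d.v, d.cl2 / d.v, d.cl2 / d.v2
        s = k10 + k12 + k21
        disc = np.sqrt(s * s - 4 * k10 * k21)
        alpha, beta = (s + disc) / 2, (s - disc) / 2
        t = sample_times[Route.IV]
        c0 = 5.0e5 / d.v
        closed = c0 * ((alpha - k21) / (alpha - beta) * np.exp(-alpha * t)
                       + (k21 - beta) / (alpha - beta) * np.exp(-beta * t))
        sim = simulate_profile(p, schedules[Route.IV], t,
                               SolverConfig(method=method))
        assert np.max(np.abs(sim - closed) / closed) < 1e-5

    def test_expm_and_lsoda_agree(self, mean_params, schedules,
                                  sample_times):
        for route in Route:
            a = simulate_profile(mean_params[route], schedules[route],
                                 sample_times[route],
                                 SolverConfig(method="expm"))
            b = simulate_profile(mean_params[route], schedules[route],
                                 sample_times[route],
                                 SolverConfig(method="lsoda"))
            assert np.allclose(a, b, rtol=1e-6, atol=1e-8)

    def test_supralingual_silent_before_lag(self, mean_params, schedules):
        c = simulate_profile(mean_params[Route.SUPRALINGUAL],
                             schedules[Route.SUPRALINGUAL],
                             [0.1, 0.25, 0.49, 0.75, 1.0])
        assert np.allclose(c[:3], 0.0)
        assert np.all(c[3:] > 0)

    def test_doubling_clearance_reduces_auc(self, mean_params, schedules):
        from ehrpk.nca import auc_trapz
        t = np.linspace(0.01, 48, 200)
        for route in Route:
            p = mean_params[route]
            auc1 = auc_trapz(t, simulate_profile(p, schedules[route], t))
            p2 = p.with_values(cl=2 * p.disp.cl)
            auc2 = auc_trapz(t, simulate_profile(p2, schedules[route], t))
            assert auc2 < auc1

    def test_one_compartment_limit_peak_approaches_release_end(
            self, mean_params, schedules):
        """With instantaneous absorption and no recycling, the supralingual
        model tends to lagged zero-order-input one-compartment kinetics:
        the peak time converges monotonically to the end of release."""
        p0 = mean_params[Route.SUPRALINGUAL].with_values(k_cb=0)
        t = np.linspace(0.5, 8.0, 751)
        release_end = p0.absorp.patch_duration
        tmaxes = []
        for scale in (1.0, 10.0, 100.0):
            p = p0.with_values(ka1=21.6 * scale, ka2=37.3 * scale,
                               k_tr=50.0 * scale)
            c = simulate_profile(p, schedules[Route.SUPRALINGUAL], t)
            tmaxes.append(t[np.argmax(c)])
        gaps = [abs(tm - release_end) for tm in tmaxes]
        assert gaps[0] >= gaps[1] >= gaps[2]
        assert gaps[2] < 0.05

    def test_windowed_bile_mode_conserves_mass(self, mean_params, schedules):
        p = mean_params[Route.IV].with_values(cl=0)
        cfg = SolverConfig(method="lsoda", bile_mode="windowed",
                           bile_window_start=1.0)
        amounts = simulate_amounts(p, schedules[Route.IV],
                                   [0.5, 1.5, 3.0, 10.0, 48.0], cfg)
        assert np.allclose(amounts.sum(axis=1), 5.0e5, rtol=1e-5)
        assert np.all(amounts >= 0)


class TestEhrFraction:
    def test_supralingual_value(self, mean_params):
        assert ehr_fraction(mean_params[Route.SUPRALINGUAL]) == \
            pytest.approx(100 * 2.28 / (2.28 + 250 / 3090), rel=1e-12)

    def test_oral_value(self, mean_params):
        assert ehr_fraction(mean_params[Route.ORAL]) == pytest.approx(
            69.14, abs=0.01)

    def test_no_biliary_route_gives_zero(self, mean_params):
        assert ehr_fraction(mean_params[Route.IV].with_values(k_cb=0)) == 0.0

    def test_missing_peripheral_rejected(self):
        disp = DispositionParams(cl=100, v=100, k_cb=1, k_gc=1, tau=1)
        p = ModelParams(route=Route.SUPRALINGUAL, disp=disp,
                        absorp=reference_params(Route.SUPRALINGUAL).absorp)
        with pytest.raises(ModelStructureError):
            ModelParams(route=Route.IV, disp=disp)
        assert 0 < ehr_fraction(p) < 100

    @given(cl=st.floats(1, 1e4), v=st.floats(1, 1e4),
           cl2=st.floats(1, 1e4), v2=st.floats(1, 1e4),
           k_cb=st.floats(1e-3, 1e3), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_scale_invariant(self, cl, v, cl2, v2, k_cb, scale):
        p = reference_params(Route.IV).with_values(
            cl=cl, v=v, cl2=cl2, v2=v2, k_cb=k_cb)
        e1 = ehr_fraction(p)
        assert 0 < e1 < 100
        p2 = p.with_values(cl=cl * scale, v=v * scale,
                           cl2=cl2 * scale, v2=v2 * scale)
        assert ehr_fraction(p2) == pytest.approx(e1, rel=1e-9)


class TestParameterCounts:
    @pytest.mark.parametrize("route, expected", [
        (Route.IV, 8), (Route.ORAL, 11), (Route.SUPRALINGUAL, 9)])
    def test_counts_include_sigma(self, route, expected, mean_params):
        assert mean_params[route].n_parameters == expected
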