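import math

import numpy as np
import pytest

from translokin import model as md, stimulus as st
from translokin.errors import InvalidArgumentError
from conftest import rk4_oracle


class TestStepResponse:
    def test_starts_at_rest(self, model):
        assert md.step_response(model, 25.0, 0.0) == 0.0

    def test_asymptote_is_gain_times_concentration(self, model):
        assert md.step_response(model, 25.0, 1e6) == pytest.approx(model.k * 25.0)

    def test_sixty_minutes_against_integrator(self, model, cs_profile):
        analytic = md.step_response(model, 25.0, 60.0)
        assert analytic == pytest.approx(1.0 - math.exp(-60.0 / 16.6), rel=1e-12)
        oracle = rk4_oracle(model, cs_profile, [60.0])
        assert analytic == pytest.approx(oracle[0], rel=1e-6)

    def test_negative_time_rejected(self, model):
        with pytest.raises(InvalidArgumentError):
            md.step_response(model, 25.0, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidArgumentError):
            md.TranslocationModel(tau=-1.0, k=0.04)
        with pytest.raises(InvalidArgumentError):
            md.TranslocationModel(tau=16.6, k=0.0)


class TestSimulate:
    def test_continuous_profile_equals_step_response(self, model, cs_profile):
        ts = np.arange(0.0, 61.0, 5.0)
        trace = md.simulate(model, cs_profile, ts)
        np.testing.assert_allclose(trace.y, md.step_response(model, 25.0, ts))

    def test_zero_profile_stays_at_rest(self, model):
        trace = md.simulate(model, st.make_continuous(0.0, 60.0), [0.0, 30.0, 60.0])
        assert np.all(trace.y == 0.0)

    def test_empty_sample_times_gives_empty_trace(self, model, cs_profile):
        assert len(md.simulate(model, cs_profile, [])) == 0

    def test_unsorted_sample_times_rejected(self, model, cs_profile):
        with pytest.raises(InvalidArgumentError):
            md.simulate(model, cs_profile, [10.0, 5.0])

    @pytest.mark.parametrize("period", [2.0, 10.0, 40.0])
    def test_square_wave_matches_fine_step_integrator(self, model, period):
        profile = st.make_periodic(25.0, period, 0.5, 60.0)
        ts = np.arange(0.0, 61.0, 1.0)
        exact = md.simulate(model, profile, ts).y
        oracle = rk4_oracle(model, profile, ts, h=0.005)
        np.testing.assert_allclose(exact, oracle, rtol=1e-6, atol=1e-9)

    def test_fast_periodic_near_duty_weighted_mean(self, model):
        # period << tau: response converges to the half-amplitude step
        profile = st.make_periodic(25.0, 2.0, 0.5, 60.0)
        y60 = md.simulate(model, profile, [60.0]).y[0]
        mean_resp = 0.5 * md.step_response(model, 25.0, 60.0)
        ripple = md.steady_state_ripple(model, 25.0, 2.0, 0.5)
        assert abs(y60 - mean_resp) <= ripple

    def test_linearity_in_amplitude(self, model):
        profile = st.make_periodic(25.0, 10.0, 0.5, 60.0)
        ts = np.arange(0.0, 61.0, 5.0)
        y1 = md.simulate(model, profile, ts).y
        y3 = md.simulate(model, profile.scaled(3.0), ts).y
        np.testing.assert_allclose(y3, 3.0 * y1, rtol=1e-12)

    def test_superposition_of_shifted_steps(self, model):
        # one ON-OFF pulse = step up at 0 minus step up at t_off
        profile = st.StimulusProfile((0.0, 20.0, 60.0), (25.0, 0.0))
        ts = np.array([0.0, 10.0, 20.0, 30.0, 45.0, 60.0])
        pulse = md.simulate(model, profile, ts).y
        up = md.step_response(model, 25.0, ts)
        down = np.where(
            ts > 20.0, md.step_response(model, 25.0, np.maximum(ts - 20.0, 0.0)), 0.0
        )
        np.testing.assert_allclose(pulse, up - down, rtol=1e-12, atol=1e-15)

    def test_bounded_by_steady_state(self, model):
        profile = st.make_periodic(25.0, 40.0, 0.5, 120.0)
        y = md.simulate(model, profile, np.linspace(0, 120, 500)).y
        assert np.all(y >= 0.0) and np.all(y <= model.k * 25.0)

    def test_asymmetric_export_slows_decay(self):
        slow = md.TranslocationModel(tau=16.6, k=0.04, tau_export=240.0)
        sym = md.TranslocationModel(tau=16.6, k=0.04)
        profile = st.StimulusProfile((0.0, 20.0, 120.0), (25.0, 0.0))
        ts = [20.0, 60.0, 120.0]
        y_slow = md.simulate(slow, profile, ts).y
        y_sym = md.simulate(sym, profile, ts).y
        assert y_slow[0] == pytest.approx(y_sym[0])  # rise unchanged
        assert np.all(y_slow[1:] > y_sym[1:])  # decay retarded


class TestFrequencyDomain:
    def test_dc_gain_is_k(self, model):
        assert md.transfer_magnitude(model, 0.0) == pytest.approx(model.k)

    def test_strictly_decreasing_low_pass(self, model):
        f = np.logspace(-3, 1, 100)
        mags = md.transfer_magnitude(model, f)
        assert np.all(np.diff(mags) < 0)
        assert mags[-1] < 1e-2 * model.k

    def test_minus_three_db_at_standard_corner(self, model):
        fc = 1.0 / (2.0 * math.pi * model.tau)
        assert md.transfer_magnitude(model, fc) == pytest.approx(
            model.k / math.sqrt(2.0)
        )
        # same identity in the alternative labelling convention at f = 1/tau
        assert md.transfer_magnitude(model, 1.0 / model.tau, convention="natural") == (
            pytest.approx(model.k / math.sqrt(2.0))
        )

    def test_corner_frequency_conventions(self, model):
        assert md.corner_frequency(model, "natural") == pytest.approx(1.0 / 16.6)
        assert md.corner_frequency(
            md.TranslocationModel(tau=1.0, k=1.0), "standard"
        ) == pytest.approx(1.0 / (2.0 * math.pi))
        with pytest.raises(InvalidArgumentError):
            md.corner_frequency(model, "bogus")

    def test_negative_frequency_rejected(self, model):
        with pytest.raises(InvalidArgumentError):
            md.transfer_magnitude(model, -0.1)

    def test_frequency_response_table(self, model):
        fr = md.frequency_response(model, np.logspace(-3, 0, 10))
        assert fr.corner_frequency == pytest.approx(1.0 / 16.6)
        assert fr.to_frame().shape == (10, 2)


class TestHalfTime:
    def test_unit_tau(self):
        assert md.half_time(md.TranslocationModel(tau=1.0, k=1.0)) == pytest.approx(
            math.log(2.0)
        )

    def test_reference_tau(self, model):
        assert md.half_time(model) == pytest.approx(16.6 * math.log(2.0), rel=1e-12)
        assert md.half_time(model) == pytest.approx(11.5, abs=0.1)

    def test_step_response_at_half_time_is_half_steady_state(self, model):
        t_half = md.half_time(model)
        assert md.step_response(model, 25.0, t_half) == pytest.approx(
            0.5 * model.k * 25.0
        )


class TestRipple:
    @pytest.mark.parametrize("period", [2.0, 10.0, 40.0])
    def test_limit_cycle_amplitude_matches_simulation(self, model, period):
        # simulate far past the transient and measure peak-to-trough of y
        duty = 0.5
        n_per = int(np.ceil(30 * 16.6 / period))  # settle ~30 tau first
        profile = st.make_periodic(25.0, period, duty, (n_per + 1) * period)
        ts = np.linspace(n_per * period, (n_per + 1) * period, 2001)
        y = md.simulate(model, profile, ts).y
        measured = y.max() - y.min()
        assert measured == pytest.approx(
            md.steady_state_ripple(model, 25.0, period, duty), rel=1e-4
        )

    def test_monotone_increasing_in_period(self, model):
        periods = [1.0, 2.0, 5.0, 10.0, 20.0, 40.0]
        ripples = [md.steady_state_ripple(model, 25.0, p, 0.5) for p in periods]
        assert np.all(np.diff(ripples) > 0)


def test_response_trace_serialization_round_trip(tmp_path, model, cs_profile):
    trace = md.simulate(model, cs_profile, np.arange(0.0, 61.0, 10.0))
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = md.ResponseTrace.from_csv(path)
    np.testing.assert_allclose(back.times, trace.times)
    np.testing.assert_allclose(back.y, trace.y)
    np.testing.assert_allclose(back.r_norm, trace.y + 1.0)
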