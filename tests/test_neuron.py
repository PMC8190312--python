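"""Unit and property tests for the LIFL neuron primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liflsim.neuron import (
    DecayKind, LiflDomainError, Mode, NeuronParams, NeuronState,
    apply_pulse, fire, leakage_term, rise_term, state_from_time_to_fire,
    time_to_fire,
)


class TestFiringEquation:
    def test_direct_substitution(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.01)
        assert time_to_fire(2.0, p) == 1.0

    def test_max_latency_at_threshold(self):
        p = NeuronParams(a=2.0, b=0.5, c=0.1)
        assert time_to_fire(p.S_th, p) == pytest.approx(p.a / p.c - p.b)
        assert p.t_f_max == pytest.approx(2.0 / 0.1 - 0.5)

    def test_zero_latency_at_ceiling(self):
        p = NeuronParams(a=1.0, b=0.5, c=0.1)
        S_max = 1.0 + p.a / p.b
        assert time_to_fire(S_max - 1e-12, p) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(LiflDomainError):
            time_to_fire(S_max, p)

    def test_domain_errors(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.05)
        with pytest.raises(LiflDomainError):
            time_to_fire(1.0, p)  # below threshold
        with pytest.raises(LiflDomainError):
            state_from_time_to_fire(p.t_f_max + 1.0, p)

    @given(st.floats(0.02, 10.0), st.floats(0.02, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing_and_invertible(self, s1, s2):
        p = NeuronParams(a=1.3, b=0.2, c=0.01)
        lo, hi = p.S_th, p.S_max - 1e-6
        S1 = lo + (hi - lo) * s1 / 10.0
        S2 = lo + (hi - lo) * s2 / 10.0
        t1, t2 = time_to_fire(S1, p), time_to_fire(S2, p)
        if S1 < S2:
            assert t1 > t2
        assert state_from_time_to_fire(t1, p) == pytest.approx(S1, rel=1e-9)
        assert 0.0 < t1 <= p.t_f_max + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(a=1.0, b=1.0, c=2.0)  # violates c < a/b
        with pytest.raises(ValueError):
            NeuronParams(c=0.0)
        with pytest.raises(ValueError):
            NeuronParams(A=0.0)


class TestLeakage:
    def test_no_time_no_decay(self):
        assert leakage_term(0.5, 0.0, 20.0, DecayKind.EXPONENTIAL) == 0.0
        assert leakage_term(0.5, 0.0, 20.0, DecayKind.LINEAR) == 0.0

    def test_exponential_closed_form(self):
        # decay over one time constant loses a 1 - 1/e fraction
        T_l = leakage_term(0.5, 20.0, 20.0, DecayKind.EXPONENTIAL)
        assert T_l == pytest.approx(0.5 * (1.0 - math.exp(-1.0)), rel=1e-12)

    def test_asymptotic_full_decay(self):
        assert leakage_term(0.5, 1e9, 20.0, DecayKind.EXPONENTIAL) == pytest.approx(0.5)
        assert leakage_term(0.5, 1e9, 20.0, DecayKind.LINEAR) == 0.5

    def test_exponential_matches_dense_integration(self):
        # independent oracle: many small exponential-decay steps
        S, D, dt = 0.5, 20.0, 20.0
        steps = 200_000
        S_dense = S
        for _ in range(steps):
            S_dense -= S_dense * (dt / steps) / D  # forward Euler
        T_l = leakage_term(S, dt, D, DecayKind.EXPONENTIAL)
        assert S - T_l == pytest.approx(S_dense, abs=1e-5)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 100.0), st.floats(0.1, 100.0),
           st.sampled_from(list(DecayKind)))
    @settings(max_examples=200, derandomize=True)
    def test_contract(self, S_p, dt, D, kind):
        T_l = leakage_term(S_p, dt, D, kind)
        assert 0.0 <= T_l <= S_p + 1e-15
        # nondecreasing in dt
        assert leakage_term(S_p, dt * 2, D, kind) >= T_l - 1e-15


class TestRise:
    def test_zero_dt(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.05)
        assert rise_term(1.5, 0.0, p) == 0.0

    def test_direct_substitution(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.05)
        assert rise_term(2.0, 0.5, p) == pytest.approx(1.0)

    def test_past_emission_is_domain_error(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.05)
        with pytest.raises(LiflDomainError):
            rise_term(2.0, 1.5, p)  # t_f(2.0) = 1 < 1.5

    @given(st.floats(0.001, 0.999), st.floats(0.0, 0.999))
    @settings(max_examples=300, derandomize=True)
    def test_consistency_with_firing_equation(self, u, frac):
        """Advancing the state by T_r shortens the latency by exactly dt."""
        p = NeuronParams(a=1.3, b=0.4, c=0.02)
        S = p.S_th + (p.S_max - 1e-6 - p.S_th) * u
        t_f = time_to_fire(S, p)
        dt = t_f * frac
        S_adv = S + rise_term(S, dt, p)
        assert time_to_fire(S_adv, p) == pytest.approx(t_f - dt, abs=1e-9)


class TestApplyPulse:
    def test_subthreshold_stays_passive(self, default_params):
        st_ = NeuronState(S=0.5, t_last=0.0)
        out = apply_pulse(st_, 0.0, 0.2, default_params)
        assert st_.S == pytest.approx(0.7)
        assert st_.mode is Mode.PASSIVE and out.schedule is None

    def test_threshold_crossing_schedules_fire(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.05, D_exc=20.0)
        st_ = NeuronState(S=0.9, t_last=1.0)
        out = apply_pulse(st_, 1.0, 0.2, p)  # dt=0: no decay
        assert st_.S == pytest.approx(1.1)
        assert st_.mode is Mode.ACTIVE
        assert out.schedule == pytest.approx(1.0 + 1.0 / 0.1)

    def test_post_trigger_anticipation_and_postponement(self, default_params):
        st_ = NeuronState(S=1.5, t_last=0.0, mode=Mode.ACTIVE, t_fire_scheduled=2.0)
        out = apply_pulse(st_, 0.5, 0.3, default_params)
        assert out.schedule is not None and out.schedule < 2.0  # anticipation
        st2 = NeuronState(S=1.5, t_last=0.0, mode=Mode.ACTIVE, t_fire_scheduled=2.0)
        out2 = apply_pulse(st2, 0.5, -0.2, default_params)
        assert out2.schedule is not None and out2.schedule > 2.0  # postponement

    def test_post_trigger_inhibition_cancels(self, default_params):
        st_ = NeuronState(S=1.2, t_last=0.0, mode=Mode.ACTIVE, t_fire_scheduled=5.0)
        out = apply_pulse(st_, 1.0, -0.5, default_params)
        assert out.cancel and st_.mode is Mode.PASSIVE
        assert st_.t_fire_scheduled is None

    def test_immediate_fire_past_ceiling(self):
        p = NeuronParams(a=1.0, b=0.5, c=0.1)  # S_max = 3
        st_ = NeuronState(S=0.5, t_last=0.0)
        out = apply_pulse(st_, 0.0, 3.0, p)
        assert out.fire_now

    def test_clamp_at_rest(self, default_params):
        st_ = NeuronState(S=0.3, t_last=0.0)
        apply_pulse(st_, 0.0, -1.0, default_params)
        assert st_.S == 0.0

    def test_refractory_discard_and_boundary(self, default_params):
        st_ = NeuronState(S=0.0, t_last=10.0, mode=Mode.REFRACTORY, refractory_until=15.0)
        out = apply_pulse(st_, 14.9, 0.5, default_params)
        assert out.absorbed and st_.mode is Mode.REFRACTORY
        # arrival exactly at the boundary is accepted, from rest
        out2 = apply_pulse(st_, 15.0, 0.5, default_params)
        assert not out2.absorbed and st_.S == pytest.approx(0.5)

    def test_ordering_violation(self, default_params):
        st_ = NeuronState(S=0.1, t_last=5.0)
        with pytest.raises(LiflDomainError):
            apply_pulse(st_, 4.0, 0.1, default_params)

    def test_decay_selects_constant_by_synapse_type(self):
        p = NeuronParams(a=1, b=0, c=0.05, D_exc=10.0, D_inh=40.0)
        s_exc = NeuronState(S=0.8, t_last=0.0)
        apply_pulse(s_exc, 10.0, 0.01, p)
        s_inh = NeuronState(S=0.8, t_last=0.0)
        apply_pulse(s_inh, 10.0, -0.01, p)
        exp_exc = 0.8 * math.exp(-1.0) + 0.01
        exp_inh = 0.8 * math.exp(-0.25) - 0.01
        assert s_exc.S == pytest.approx(exp_exc, rel=1e-12)
        assert s_inh.S == pytest.approx(exp_inh, rel=1e-12)


class TestFire:
    def test_tonic_single_emission(self, default_params):
        st_ = NeuronState(S=1.2, t_last=0.0, mode=Mode.ACTIVE, t_fire_scheduled=3.0)
        res = fire(st_, 3.0, default_params)
        assert res.emission_times == (3.0,)
        assert st_.S == 0.0 and st_.mode is Mode.REFRACTORY
        assert st_.refractory_until == 3.0 + default_params.t_arp

    def test_burst_train(self):
        p = NeuronParams(a=1, b=0, c=0.05, N_b=3, IBI=2.0, t_arp=5.0)
        st_ = NeuronState(S=1.2, t_last=0.0, mode=Mode.ACTIVE, t_fire_scheduled=1.0)
        res = fire(st_, 1.0, p)
        assert res.emission_times == (1.0, 3.0, 5.0)
        # refractoriness starts after the last burst emission
        assert st_.refractory_until == 5.0 + 5.0

    def test_fire_on_passive_neuron_is_contract_violation(self, default_params):
        with pytest.raises(LiflDomainError):
            fire(NeuronState(), 0.0, default_params)


class TestSingleNeuronOracle:
    def test_event_driven_matches_dense_clock(self):
        """State at pulse times agrees with a dt=1e-4 clock integrator."""
        p = NeuronParams(a=1.0, b=0.0, c=0.05, D_exc=20.0, t_arp=5.0)
        rng = np.random.default_rng(7)
        pulse_t = np.sort(rng.uniform(0, 80, 25))
        pulse_w = rng.uniform(-0.2, 0.25, 25)

        st_ = NeuronState()
        event_states = []
        for t, w in zip(pulse_t, pulse_w):
            if st_.mode is Mode.ACTIVE and st_.t_fire_scheduled <= t:
                fire(st_, st_.t_fire_scheduled, p)
            apply_pulse(st_, t, w, p)
            event_states.append((t, st_.S if st_.mode is not Mode.REFRACTORY else 0.0))

        dt = 1e-4
        S, mode, tf_rem, refr = 0.0, 0, 0.0, 0.0
        dense_states = {}
        k, t = 0, 0.0
        n_steps = int(80.1 / dt)
        pulses = list(zip(pulse_t, pulse_w))
        for step in range(n_steps):
            t = step * dt
            if mode == 0:
                S *= math.exp(-dt / p.D_exc) if step else 1.0
            elif mode == 1:
                tf_rem -= dt
                if tf_rem <= 0:
                    S, mode, refr = 0.0, 2, t + p.t_arp
            if mode == 2 and refr <= t:
                mode, S = 0, 0.0
            while k < len(pulses) and pulses[k][0] <= t:
                tp, w = pulses[k]
                if mode == 2:
                    k += 1
                    continue
                if mode == 1:
                    S = 1.0 + p.a / (tf_rem + p.b)
                S = max(0.0, S + w)
                if S >= p.S_th:
                    mode, tf_rem = 1, p.a / (S - 1.0) - p.b
                else:
                    mode = 0
                dense_states[tp] = S
                k += 1

        for t, s_event in event_states:
            if t in dense_states:
                assert s_event == pytest.approx(dense_states[t], abs=1e-3)
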