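"""LSM drive and leak dynamics, Izhikevich reference, conductance model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsmnet.neurons import (
    HHParams,
    IZParams,
    IZState,
    LSMParams,
    LSMState,
    hh_analytic,
    hh_step_implicit,
    iz_parameter_grid,
    iz_run,
    iz_step,
    lsm_drive,
    lsm_filter,
    lsm_step,
)


class TestLsmDrive:
    def test_zero_inputs_give_zero(self):
        p = LSMParams(n_synapses=4, use_dynamic_leak=False)
        assert lsm_drive(np.zeros(4), p) == 0.0

    def test_single_unit_input_hand_value(self):
        # one synapse, w*a = 1, k_static = 1: 1 / (1 + 1) = 0.5
        p = LSMParams(k_static=1.0, n_synapses=1)
        assert lsm_drive(np.array([1.0]), p) == pytest.approx(0.5)

    def test_net_inhibition_thresholded_to_zero(self):
        p = LSMParams(n_synapses=3)
        assert lsm_drive(np.array([0.2, -0.5, -0.1]), p) == 0.0

    def test_input_count_checked(self):
        with pytest.raises(ValueError, match="expected"):
            lsm_drive(np.ones(3), LSMParams(n_synapses=2))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        wa=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=30),
        k=st.floats(0.01, 10.0),
    )
    def test_output_bounded_in_unit_interval(self, wa, k):
        """The denominator strictly dominates the numerator: output in [0, 1)."""
        p = LSMParams(k_static=k, n_synapses=len(wa))
        out = lsm_drive(np.array(wa), p)
        assert 0.0 <= out < 1.0


class TestLsmStep:
    def test_converges_to_constant_drive(self):
        p = LSMParams(tau_dyn=10.0, n_synapses=1)
        s = LSMState()
        for _ in range(2000):
            s = lsm_step(s, 0.42, 1.0, p)
        assert s.a_dyn == pytest.approx(0.42, abs=1e-9)

    def test_single_tau_step_decay(self):
        # drive 0 from A_dyn = 1, one step of dt = tau: exp(-1)
        p = LSMParams(tau_dyn=10.0, n_synapses=1)
        s = lsm_step(LSMState(a_dyn=1.0), 0.0, 10.0, p)
        assert s.a_dyn == pytest.approx(np.exp(-1), rel=1e-12)

    def test_no_dynamic_leak_is_identity_on_drive(self):
        p = LSMParams(n_synapses=1, use_dynamic_leak=False)
        s = lsm_step(LSMState(a_dyn=0.9), 0.3, 1.0, p)
        assert s.a_dyn == 0.3

    def test_filter_matches_stepwise_update(self):
        rng = np.random.default_rng(0)
        drive = rng.random(500)
        p = LSMParams(tau_dyn=10.0, n_synapses=1)
        y = lsm_filter(drive, 1.0, p)
        s = LSMState()
        for n, d in enumerate(drive):
            s = lsm_step(s, d, 1.0, p)
            assert y[n] == pytest.approx(s.a_dyn, rel=1e-10)

    @pytest.mark.parametrize("f_hz", [1.0, 10.0, 50.0, 200.0, 500.0])
    def test_first_order_lowpass_frequency_response(self, f_hz):
        """Steady-state amplitude ratio matches 1/sqrt(1+(2*pi*f*tau)^2)."""
        tau, dt = 10.0, 0.1  # ms
        p = LSMParams(tau_dyn=tau, n_synapses=1)
        t = np.arange(0, 2000.0, dt)  # 2 s
        drive = 0.5 + 0.25 * np.sin(2 * np.pi * f_hz * t / 1000.0)
        y = lsm_filter(drive, dt, p)
        n_settle = int(10 * tau / dt)
        seg_t = t[n_settle:] / 1000.0
        seg = y[n_settle:] - np.mean(y[n_settle:])
        # quadrature demodulation at f
        c = 2 * np.mean(seg * np.cos(2 * np.pi * f_hz * seg_t))
        s = 2 * np.mean(seg * np.sin(2 * np.pi * f_hz * seg_t))
        amp = np.hypot(c, s)
        expected = 0.25 / np.sqrt(1 + (2 * np.pi * f_hz * tau / 1000.0) ** 2)
        assert amp == pytest.approx(expected, rel=0.05)


class TestIzhikevich:
    def test_resting_fixed_point(self):
        # v = -70, u = b*v solves 0.04 v^2 + 5 v + 140 - u = 0 (quadratic roots
        # -70 and -50 with b = 0.2)
        p = IZParams()
        s = iz_step(IZState(v=-70.0, u=-14.0), 0.0, 1.0, p)
        assert s.v == pytest.approx(-70.0, abs=1e-9)
        assert s.u == pytest.approx(-14.0, abs=1e-9)

    def test_reset_after_threshold(self):
        p = IZParams()
        s = iz_step(IZState(v=29.0, u=0.0), 1.0, 1.0, p)
        assert s.v == p.c
        assert len(s.spikes) == 1

    def test_spikes_under_constant_suprathreshold_drive(self):
        p = IZParams()
        spikes, _ = iz_run(np.full(1000, 0.05), dt=1.0, params=p)
        assert len(spikes) > 0

    def test_regular_spiking_low_isi_cv(self):
        """Table-defaults produce regular (non-bursting) spiking: ISI CV < 1."""
        p = IZParams()
        spikes, _ = iz_run(np.full(2000, 0.05), dt=1.0, params=p)
        isi = np.diff(spikes[1:])  # discard initial transient interval
        assert isi.size > 3
        assert isi.std() / isi.mean() < 1.0

    def test_divergence_detected(self):
        p = IZParams()
        with pytest.raises(FloatingPointError):
            iz_run(np.full(200, 1e5), dt=1.0, params=p)

    def test_parameter_grid_size_and_fixed_coefficients(self):
        grid = iz_parameter_grid()
        assert len(grid) == 405
        assert len(set(grid)) == 405
        assert all(g.A == 0.04 and g.B == 5.0 and g.C == 140.0 for g in grid)


class TestConductanceModel:
    def test_pure_leak_decays_without_crossing_zero(self):
        p = HHParams(g_leak=1.0, dt=0.5)
        v = 1.0
        prev = v
        for _ in range(200):
            v = hh_step_implicit(v, 0.0, 0.0, p)
            assert 0.0 < v < prev
            prev = v

    def test_steady_state_matches_lsm_drive(self):
        """Fixed point equals the LSM drive with g_leak = k_static*i."""
        rng = np.random.default_rng(3)
        wa = rng.uniform(-1, 1, size=8)
        k = 0.7
        p_lsm = LSMParams(k_static=k, n_synapses=8)
        g_exc = np.clip(wa, 0, None).sum()
        g_inh = np.clip(-wa, 0, None).sum()
        p_hh = HHParams(g_leak=k * 8, dt=1.0)
        v = 0.0
        for _ in range(5000):
            v = hh_step_implicit(v, g_exc, g_inh, p_hh)
        expected = wa.sum() / (k * 8 + np.abs(wa).sum())  # pre-threshold drive
        assert v == pytest.approx(expected, abs=1e-9)
        if expected >= 0:
            assert lsm_drive(wa, p_lsm) == pytest.approx(v, abs=1e-9)

    def test_bounded_for_random_conductance_sequences(self):
        rng = np.random.default_rng(11)
        p = HHParams(g_leak=0.5, dt=2.0)
        for _ in range(20):
            v = rng.uniform(-1, 1)
            for ge, gi in rng.uniform(0, 50, size=(200, 2)):
                v = hh_step_implicit(v, ge, gi, p)
                assert -1.0 < v < 1.0

    def test_analytic_limits(self):
        p = HHParams(g_leak=1.0, dt=1.0)
        assert hh_analytic(0.3, 2.0, 1.0, 0.0, p) == pytest.approx(0.3)
        v_inf = hh_analytic(0.3, 2.0, 1.0, 1e6, p)
        assert v_inf == pytest.approx((2.0 - 1.0) / (1.0 + 2.0 + 1.0))

    def test_implicit_euler_first_order_convergence(self):
        """Halving dt halves the endpoint error against the analytic solution."""
        ge, gi, v0, t_end = 1.5, 0.5, -0.2, 2.0
        exact = hh_analytic(v0, ge, gi, t_end, HHParams(g_leak=1.0, dt=1.0))

        def endpoint_error(dt):
            p = HHParams(g_leak=1.0, dt=dt)
            v = v0
            for _ in range(int(round(t_end / dt))):
                v = hh_step_implicit(v, ge, gi, p)
            return abs(v - exact)

        e1, e2 = endpoint_error(0.02), endpoint_error(0.01)
        assert e1 / e2 == pytest.approx(2.0, abs=0.2)


def test_static_leak_cv_increases_then_saturates(small_block):
    """CV of output activity grows with k_static and levels off (0.1 to 10)."""
    from lsmnet.experiments import isolated_lsm_response
    from lsmnet.analysis import coefficient_of_variation

    _, _, signals = small_block
    rng = np.random.default_rng(5)
    w = rng.normal(0.4, 0.08, size=6).clip(min=0.01)
    grid = [0.1, 0.3, 1.0, 3.0, 10.0]
    cvs = []
    for k in grid:
        p = LSMParams(k_static=k, n_synapses=6, use_dynamic_leak=True)
        cvs.append(coefficient_of_variation(isolated_lsm_response(signals, w, p)))
    assert all(b >= a for a, b in zip(cvs, cvs[1:]))  # monotone on the grid
    # saturation: last increment much smaller than the first
    assert (cvs[-1] - cvs[-2]) < 0.5 * (cvs[1] - cvs[0])
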