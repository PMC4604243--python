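"""Receptor kinetics, short-term plasticity and PSP calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from columnet.neurons import default_neuron_params
from columnet.synapses import (CONNECTION_TABLE, CalibrationError, Receptor,
                               STPMode, STPSpec, STPState, SynapseSpec,
                               SynapseState, calibrate_peak_conductance,
                               gating_step, mg_block, stp_on_spike,
                               synaptic_current, unitary_psp_peak)

FRESH = 1e12  # "first spike" interval


def integrate_fine(spec: SynapseSpec, dt, n_steps, spikes, release=None):
    """Independent dense-ODE reference for the (x, s) kinetics.

    Forward-Euler at dt/100 with delta increments of x at spike steps.
    """
    sub = dt / 100.0
    x = s = 0.0
    out = np.empty(n_steps)
    spikes = dict(spikes)
    for i in range(n_steps):
        if i in spikes:
            x += spec.alpha_x * spikes[i]
        for _ in range(100):
            dx = -x / spec.tau_x
            ds = spec.alpha_s * x * (1 - s) - s / spec.tau_s
            x += sub * dx
            s += sub * ds
        out[i] = s
    return out


class TestGating:
    def test_pure_decay_solution(self):
        spec = SynapseSpec.for_receptor("AMPA", 1.0, 0.0)
        st_ = SynapseState(x=0.0, s=0.5)
        dt = 0.5
        for k in range(1, 11):
            st_ = gating_step(spec, st_, dt)
        assert st_.s == pytest.approx(0.5 * math.exp(-5.0 / spec.tau_s),
                                      rel=1e-9)

    @pytest.mark.parametrize("receptor", ["AMPA", "NMDA", "GABA_A"])
    def test_single_spike_matches_fine_ode(self, receptor):
        spec = SynapseSpec.for_receptor(receptor, 1.0, 0.0)
        dt = 0.05
        n = 400
        st_ = SynapseState()
        trace = np.empty(n)
        for i in range(n):
            st_ = gating_step(spec, st_, dt, spike_arrivals=1 if i == 10 else 0)
            trace[i] = st_.s
        ref = integrate_fine(spec, dt, n, {10: 1.0})
        peak = ref.max()
        assert peak > 0
        assert np.max(np.abs(trace - ref)) / peak < 0.01
        assert trace.max() <= 1.0 and trace.min() >= 0.0

    def test_periodic_input_reaches_periodic_steady_state(self):
        spec = SynapseSpec.for_receptor("AMPA", 1.0, 0.0)
        dt = 0.05
        period = 200  # 10 ms -> 100 Hz
        st_ = SynapseState()
        peaks = []
        cur_peak = 0.0
        for i in range(40 * period):
            st_ = gating_step(spec, st_, dt,
                              spike_arrivals=1 if i % period == 0 else 0)
            cur_peak = max(cur_peak, st_.s)
            if i % period == period - 1:
                peaks.append(cur_peak)
                cur_peak = 0.0
        assert abs(peaks[-1] - peaks[-2]) < 1e-6

    def test_invalid_dt(self):
        spec = SynapseSpec.for_receptor("AMPA", 1.0, 0.0)
        with pytest.raises(ValueError):
            gating_step(spec, SynapseState(), 0.0)


class TestCurrents:
    def test_closed_channels_pass_no_current(self):
        for receptor, E in [("AMPA", 0.0), ("NMDA", 0.0), ("GABA_A", -75.0)]:
            spec = SynapseSpec.for_receptor(receptor, 0.5, E)
            assert synaptic_current(spec, SynapseState(s=0.0), -65.0) == 0.0

    def test_mg_block_at_zero_mv(self):
        assert float(mg_block(0.0, 1.0)) == pytest.approx(
            1.0 / (1.0 + 1.0 / 3.57), abs=1e-4)

    def test_mg_block_at_minus_seventy(self):
        expect = 1.0 / (1.0 + math.exp(0.062 * 70.0) / 3.57)
        assert float(mg_block(-70.0, 1.0)) == pytest.approx(expect, rel=1e-6)
        assert float(mg_block(-70.0, 1.0)) == pytest.approx(0.0446, abs=5e-4)


class TestSTP:
    def test_depressing_first_spike(self):
        spec = STPSpec(mode=STPMode.DEPRESSING, U=0.4, tau_rec=600.0)
        new, release = stp_on_spike(spec, STPState(), FRESH)
        assert release == pytest.approx(0.4)
        assert new.R == pytest.approx(0.6)

    def test_depressing_recovery_closed_form(self):
        spec = STPSpec(mode=STPMode.DEPRESSING, U=0.4, tau_rec=600.0)
        state, _ = stp_on_spike(spec, STPState(), FRESH)
        # R recovered just before a second spike 600 ms later
        R_before = 1.0 - (1.0 - state.R) * math.exp(-1.0)
        assert R_before == pytest.approx(1.0 - 0.4 * math.exp(-1.0), rel=1e-12)
        state2, release2 = stp_on_spike(spec, state, 600.0)
        assert release2 == pytest.approx(0.4 * R_before, rel=1e-12)

    def test_facilitating_closed_form_recursion(self):
        spec = STPSpec(mode=STPMode.FACILITATING, U1=0.05, tau_rec=1e9,
                       tau_facil=1000.0)
        s1, r1 = stp_on_spike(spec, STPState(), FRESH)
        assert s1.U_dyn == pytest.approx(0.05)
        u_before = 0.05 * math.exp(-20.0 / 1000.0)
        assert u_before == pytest.approx(0.04901, abs=1e-5)
        s2, r2 = stp_on_spike(spec, s1, 20.0)
        assert s2.U_dyn == pytest.approx(u_before + 0.05 * (1 - u_before),
                                         rel=1e-9)
        assert s2.U_dyn == pytest.approx(0.09656, abs=1e-5)

    def test_negative_interval_rejected(self):
        spec = STPSpec(mode=STPMode.DEPRESSING, U=0.4, tau_rec=600.0)
        with pytest.raises(ValueError):
            stp_on_spike(spec, STPState(), -1.0)

    def test_depressing_release_non_increasing_on_regular_train(self):
        spec = STPSpec(mode=STPMode.DEPRESSING, U=0.5, tau_rec=600.0)
        state = STPState()
        prev = 1.1
        interval = FRESH
        for _ in range(20):
            state, release = stp_on_spike(spec, state, interval)
            assert release <= prev + 1e-12
            prev = release
            interval = 25.0

    def test_facilitating_paired_pulse_ratio_above_one(self):
        spec = STPSpec(mode=STPMode.FACILITATING, U1=0.05, tau_rec=20.0,
                       tau_facil=1000.0)
        s1, r1 = stp_on_spike(spec, STPState(), FRESH)
        s2, r2 = stp_on_spike(spec, s1, 20.0)
        assert r2 / r1 > 1.0

    @given(st.lists(st.floats(min_value=0.1, max_value=500.0),
                    min_size=1, max_size=60),
           st.sampled_from(["dep", "fac"]))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_states_bounded_for_arbitrary_trains(self, intervals, mode):
        if mode == "dep":
            spec = STPSpec(mode=STPMode.DEPRESSING, U=0.37, tau_rec=210.0)
        else:
            spec = STPSpec(mode=STPMode.FACILITATING, U1=0.11, tau_rec=35.0,
                           tau_facil=730.0)
        state = STPState()
        iv = FRESH
        for nxt in intervals:
            state, release = stp_on_spike(spec, state, iv)
            assert 0.0 <= state.R <= 1.0
            assert 0.0 <= state.U_dyn <= 1.0
            assert 0.0 <= release <= 1.0
            iv = nxt

    def _steady_release(self, spec, rate_hz, n=400):
        state = STPState()
        iv = FRESH
        release = 0.0
        for _ in range(n):
            state, release = stp_on_spike(spec, state, iv)
            iv = 1000.0 / rate_hz
        return release

    def test_depression_monotone_in_U_tau_rec(self):
        vals = []
        for U, tau in [(0.2, 200.0), (0.4, 400.0), (0.6, 800.0)]:
            spec = STPSpec(mode=STPMode.DEPRESSING, U=U, tau_rec=tau)
            vals.append(self._steady_release(spec, 20.0))
        assert vals[0] > vals[1] > vals[2]

    def test_facilitation_monotone_in_tau_facil(self):
        vals = []
        for tf in (100.0, 500.0, 2000.0):
            spec = STPSpec(mode=STPMode.FACILITATING, U1=0.05, tau_rec=20.0,
                           tau_facil=tf)
            vals.append(self._steady_release(spec, 20.0))
        assert vals[0] < vals[1] < vals[2]


class TestEventOracle:
    """Event-based R/U recursion vs dense integration of the printed ODEs."""

    def _ode_reference(self, spec, spike_times, t_end, sub=0.005):
        R, U = 1.0, 0.0
        t = 0.0
        releases = []
        idx = 0
        n = int(t_end / sub)
        for i in range(n):
            t = i * sub
            if idx < len(spike_times) and abs(t - spike_times[idx]) < sub / 2:
                if spec.mode == STPMode.FACILITATING:
                    U = U + spec.U1 * (1.0 - U)
                    rel = U * R
                else:
                    rel = spec.U * R
                releases.append(rel)
                R -= rel
                idx += 1
            R += sub * (1.0 - R) / spec.tau_rec
            if spec.mode == STPMode.FACILITATING:
                U += sub * (-U / spec.tau_facil)
        return np.array(releases)

    @pytest.mark.parametrize("mode", ["dep", "fac"])
    def test_recursion_matches_fine_ode(self, mode, rng):
        if mode == "dep":
            spec = STPSpec(mode=STPMode.DEPRESSING, U=0.4, tau_rec=600.0)
        else:
            spec = STPSpec(mode=STPMode.FACILITATING, U1=0.05, tau_rec=20.0,
                           tau_facil=1000.0)
        times = np.sort(rng.uniform(1.0, 900.0, 25))
        times = np.round(times / 0.005) * 0.005  # align to reference grid
        ref = self._ode_reference(spec, times, 950.0)
        state = STPState()
        ev = []
        prev = None
        for t in times:
            iv = FRESH if prev is None else t - prev
            state, release = stp_on_spike(spec, state, iv)
            ev.append(release)
            prev = t
        ev = np.array(ev)
        assert np.max(np.abs(ev - ref) / np.abs(ref)) < 1e-3


class TestCalibration:
    def test_pc_pc_ampa_unitary(self):
        cls = CONNECTION_TABLE["PC-PC_LO"]
        params = default_neuron_params(cls.post)
        G = calibrate_peak_conductance("AMPA", 1.2, params, 0.0,
                                       cls.stp.first_spike_release)
        peak = unitary_psp_peak(Receptor.AMPA, G, params, 0.0,
                                cls.stp.first_spike_release)
        assert peak == pytest.approx(1.2, abs=0.01)

    def test_bc_pc_gaba_unitary(self):
        cls = CONNECTION_TABLE["BC-PC"]
        params = default_neuron_params(cls.post)
        G = calibrate_peak_conductance("GABA_A", -1.4, params, -75.0,
                                       cls.stp.first_spike_release)
        peak = unitary_psp_peak(Receptor.GABA_A, G, params, -75.0,
                                cls.stp.first_spike_release)
        assert peak == pytest.approx(-1.4, abs=0.01)

    def test_zero_target_rejected(self):
        params = default_neuron_params("PC")
        with pytest.raises(CalibrationError):
            calibrate_peak_conductance("AMPA", 0.0, params, 0.0, 0.4)

    def test_unreachable_hyperpolarization_rejected(self):
        # reversal only ~4.5 mV below rest: -10 mV cannot be reached
        params = default_neuron_params("PC")
        with pytest.raises(CalibrationError):
            calibrate_peak_conductance("GABA_A", -10.0, params, -75.0, 0.25)
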