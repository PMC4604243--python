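"""Numba-compiled integration kernels.

Two kernels live here: a single-neuron kernel used for unitary-PSP
measurement/calibration, and the full network kernel with delayed spike
delivery, event-based short-term plasticity and point-conductance drives.

Numerics: exponential-Euler updates for the membrane potential (against the
instantaneous total conductance) and for the channel gates; the synaptic
drive variable x decays exactly and the open fraction s is advanced against
the within-step average of x so that the sub-step decay of the very fast x
(tau_x = 0.05 ms) is not lost at dt comparable to tau_x.  The network kernel
reads gate steady states and relaxation factors from per-cell-type lookup
tables sampled every 0.05 mV with linear interpolation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# status codes returned by the network kernel
OK = 0
ERR_SPIKE_OVERFLOW = 1
ERR_RING_OVERFLOW = 2
ERR_NAN = 3

# dormancy thresholds for synapse bookkeeping
_X_EPS = 1e-10
_S_EPS = 1e-7


@njit(cache=True, fastmath=True)
def _exprel(z):
    # z / (exp(z) - 1), continuous at 0
    if abs(z) < 1e-8:
        return 1.0 - 0.5 * z
    return z / (math.exp(z) - 1.0)


@njit(cache=True, fastmath=True)
def _gate_rates(V, VT):
    u_m = V - VT - 13.0
    u_b = V - VT - 40.0
    u_n = V - VT - 15.0
    am = 1.28 * _exprel(-u_m / 4.0)
    bm = 1.4 * _exprel(u_b / 5.0)
    ah = 0.128 * math.exp(-(V - VT - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-u_b / 5.0))
    an = 0.16 * _exprel(-u_n / 5.0)
    bn = 0.5 * math.exp(-(V - VT - 10.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, fastmath=True)
def _p_steady(V, tau_max):
    p_inf = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * math.exp((V + 35.0) / 20.0)
                       + math.exp(-(V + 35.0) / 20.0))
    return p_inf, tau_p


@njit(cache=True, fastmath=True)
def psp_response(C, gL, gNa, gKd, gM, EL, ENa, EK, VT, tau_max,
                 V0, m0, h0, n0, p0,
                 G, Esyn, tau_x, tau_s, is_nmda, mg,
                 x_incr, alpha_s, dt, t_max):
    """Integrate one neuron with one synapse hit by one spike at t = 5 ms.

    Returns (signed peak deflection from V0, spiked flag).
    """
    n_steps = int(t_max / dt)
    spike_step = int(5.0 / dt)
    V, m, h, n, p = V0, m0, h0, n0, p0
    x = 0.0
    s = 0.0
    dec_x = math.exp(-dt / tau_x)
    vmax = V0
    vmin = V0
    spiked = False
    for step in range(n_steps):
        if step == spike_step:
            x += x_incr
        # synapse
        if x > 1e-14 or s > 1e-14:
            xbar = x * (1.0 - dec_x) * (tau_x / dt)
            a = alpha_s * xbar + 1.0 / tau_s
            s_inf = alpha_s * xbar / a
            s = s_inf + (s - s_inf) * math.exp(-a * dt)
            x *= dec_x
        g_syn = G * s
        if is_nmda == 1 and mg > 0.0:
            g_syn /= (1.0 + mg * math.exp(-0.062 * V) / 3.57)
        # gates at current V
        am, bm, ah, bh, an, bn = _gate_rates(V, VT)
        p_inf, tau_p = _p_steady(V, tau_max)
        m += (am / (am + bm) - m) * (1.0 - math.exp(-dt * (am + bm)))
        h += (ah / (ah + bh) - h) * (1.0 - math.exp(-dt * (ah + bh)))
        n += (an / (an + bn) - n) * (1.0 - math.exp(-dt * (an + bn)))
        p += (p_inf - p) * (1.0 - math.exp(-dt / tau_p))
        # membrane, exponential Euler on total conductance
        g_na = gNa * m * m * m * h
        g_kd = gKd * n * n * n * n
        g_m = gM * p
        g_tot = gL + g_na + g_kd + g_m + g_syn
        num = (gL * EL + g_na * ENa + g_kd * EK + g_m * EK + g_syn * Esyn)
        v_inf = num / g_tot
        V = v_inf + (V - v_inf) * math.exp(-dt * g_tot / C)
        if V > 0.0:
            spiked = True
            break
        if V > vmax:
            vmax = V
        if V < vmin:
            vmin = V
    up = vmax - V0
    down = vmin - V0
    peak = up if abs(up) >= abs(down) else down
    return peak, spiked


@njit(cache=True, fastmath=True)
def single_cell_trace(C, gL, gNa, gKd, gM, EL, ENa, EK, VT, tau_max,
                      V0, m0, h0, n0, p0, I_ext, dt, n_steps):
    """Current-clamp integration of one neuron; returns V trace and spikes.

    Spikes are upward crossings of 0 mV with a 2 ms lockout.
    """
    V, m, h, n, p = V0, m0, h0, n0, p0
    out = np.empty(n_steps)
    spikes = np.empty(n_steps, np.float64)
    n_spk = 0
    armed = V < 0.0
    lockout = int(2.0 / dt)
    last_spk = -10 ** 9
    for step in range(n_steps):
        am, bm, ah, bh, an, bn = _gate_rates(V, VT)
        p_inf, tau_p = _p_steady(V, tau_max)
        m += (am / (am + bm) - m) * (1.0 - math.exp(-dt * (am + bm)))
        h += (ah / (ah + bh) - h) * (1.0 - math.exp(-dt * (ah + bh)))
        n += (an / (an + bn) - n) * (1.0 - math.exp(-dt * (an + bn)))
        p += (p_inf - p) * (1.0 - math.exp(-dt / tau_p))
        g_na = gNa * m * m * m * h
        g_kd = gKd * n * n * n * n
        g_m = gM * p
        g_tot = gL + g_na + g_kd + g_m
        num = gL * EL + g_na * ENa + g_kd * EK + g_m * EK + I_ext
        v_inf = num / g_tot
        V = v_inf + (V - v_inf) * math.exp(-dt * g_tot / C)
        out[step] = V
        if V < 0.0:
            armed = True
        elif armed and step - last_spk >= lockout:
            spikes[n_spk] = step * dt
            n_spk += 1
            last_spk = step
            armed = False
    return out, spikes[:n_spk]


@njit(cache=True, fastmath=True)
def simulate(dt, n_steps,
             # cells
             cell_tt, C, gL, gNa, gKd, gM, EL, ENa, EK,
             V, m, h, n, p,
             # per-type gate tables: tabs[type, 8, nv] =
             # (minf, mfac, hinf, hfac, ninf, nfac, pinf, pfac)
             tabs, v_min, v_step_inv,
             # synapse entries
             syn_post, syn_G, syn_E, syn_nmda, syn_tau_x, syn_tau_s,
             stp_facil, stp_U, stp_U1, stp_tau_rec, stp_tau_facil,
             x, s, R, Udyn, last_t,
             # outgoing connectivity (CSR over synapse entries)
             indptr, out_syn, out_delay,
             n_slots, slot_cap,
             # drives
             noise_mean, noise_sd, noise_tau,
             stim_mean, stim_sd, stim_tau, stim_on, stim_off,
             I_ext,
             mg, alpha_s, seed, lockout_steps,
             # outputs
             rec_cell, rec_t,
             vrec_idx, vrec_every, vout):
    np.random.seed(seed)
    N = V.shape[0]
    M = x.shape[0]
    nv = tabs.shape[2]

    dec_x = np.empty(M)
    dec_s = np.empty(M)
    xbar_f = np.empty(M)
    for j in range(M):
        dec_x[j] = math.exp(-dt / syn_tau_x[j])
        dec_s[j] = math.exp(-dt / syn_tau_s[j])
        xbar_f[j] = (1.0 - dec_x[j]) * (syn_tau_x[j] / dt)

    has_nmda = False
    for j in range(M):
        if syn_nmda[j] == 1:
            has_nmda = True
            break

    ring = np.full((n_slots, slot_cap), -1, np.int64)
    ring_cnt = np.zeros(n_slots, np.int64)

    active = np.zeros(M, np.uint8)
    act_list = np.empty(M, np.int64)
    n_act = 0

    gsum = np.zeros(N)
    gEsum = np.zeros(N)
    bv = np.ones(N)

    g_noise = np.full(N, noise_mean)
    g_stim = np.zeros(N)
    a_noise = math.exp(-dt / noise_tau)
    sq_noise = math.sqrt(max(0.0, 1.0 - a_noise * a_noise))
    b_noise = np.empty(N)
    any_noise_sd = False
    for i in range(N):
        b_noise[i] = noise_sd[i] * sq_noise
        if noise_sd[i] > 0.0:
            any_noise_sd = True
    a_stim = math.exp(-dt / stim_tau)
    b_stim = stim_sd * math.sqrt(max(0.0, 1.0 - a_stim * a_stim))

    last_spk = np.full(N, -10 ** 9, np.int64)
    armed = np.empty(N, np.uint8)
    for i in range(N):
        armed[i] = 1 if V[i] < 0.0 else 0

    n_spikes = 0
    delivered = 0
    cap_spikes = rec_cell.shape[0]
    n_vrec = vrec_idx.shape[0]

    status = OK
    bad_cell = -1
    bad_step = -1

    for step in range(n_steps):
        tnow = step * dt
        # --- deliver queued spike events: STP recursion, then x increment
        slot = step % n_slots
        cnt = ring_cnt[slot]
        for q in range(cnt):
            j = ring[slot, q]
            dtp = tnow - last_t[j]
            last_t[j] = tnow
            Rj = 1.0 - (1.0 - R[j]) * math.exp(-dtp / stp_tau_rec[j])
            if stp_facil[j] == 1:
                U = Udyn[j] * math.exp(-dtp / stp_tau_facil[j])
                U = U + stp_U1[j] * (1.0 - U)
                Udyn[j] = U
                rel = U * Rj
            else:
                rel = stp_U[j] * Rj
            R[j] = Rj - rel
            x[j] += rel  # alpha_x = 1
            if active[j] == 0:
                active[j] = 1
                act_list[n_act] = j
                n_act += 1
        ring_cnt[slot] = 0
        delivered += cnt

        # --- NMDA Mg unblock factor at the current potentials
        if has_nmda:
            for i in range(N):
                bv[i] = 1.0 / (1.0 + mg * math.exp(-0.062 * V[i]) / 3.57)

        # --- synapse update + conductance accumulation (active set only)
        for i in range(N):
            gsum[i] = 0.0
            gEsum[i] = 0.0
        w = 0
        for q in range(n_act):
            j = act_list[q]
            xj = x[j]
            sj = s[j]
            if xj > _X_EPS:
                xbar = xj * xbar_f[j]
                a = alpha_s * xbar + 1.0 / syn_tau_s[j]
                s_inf = alpha_s * xbar / a
                sj = s_inf + (sj - s_inf) * math.exp(-a * dt)
                x[j] = xj * dec_x[j]
            elif sj > _S_EPS:
                x[j] = 0.0
                sj = sj * dec_s[j]
            else:
                # dormant: drop from the active set
                x[j] = 0.0
                s[j] = 0.0
                active[j] = 0
                continue
            s[j] = sj
            act_list[w] = j
            w += 1
            pj = syn_post[j]
            g = syn_G[j] * sj
            if syn_nmda[j] == 1:
                g *= bv[pj]
            gsum[pj] += g
            gEsum[pj] += g * syn_E[j]
        n_act = w

        # --- point-conductance drives (Ornstein-Uhlenbeck, clipped at 0)
        if any_noise_sd or noise_mean > 0.0:
            for i in range(N):
                gn = noise_mean + (g_noise[i] - noise_mean) * a_noise \
                    + b_noise[i] * np.random.standard_normal()
                g_noise[i] = gn if gn > 0.0 else 0.0
        in_window = (step >= stim_on) and (step < stim_off)
        for i in range(N):
            if stim_mean[i] > 0.0:
                if in_window:
                    gs = stim_mean[i] + (g_stim[i] - stim_mean[i]) * a_stim \
                        + b_stim * np.random.standard_normal()
                    g_stim[i] = gs if gs > 0.0 else 0.0
                elif g_stim[i] > 0.0:
                    g_stim[i] *= a_stim

        # --- membrane + gates
        for i in range(N):
            Vi = V[i]
            tt = cell_tt[i]
            pos = (Vi - v_min) * v_step_inv
            if pos < 0.0:
                pos = 0.0
            elif pos > nv - 1.001:
                pos = nv - 1.001
            i0 = int(pos)
            fr = pos - i0
            minf = tabs[tt, 0, i0] + fr * (tabs[tt, 0, i0 + 1] - tabs[tt, 0, i0])
            mfac = tabs[tt, 1, i0] + fr * (tabs[tt, 1, i0 + 1] - tabs[tt, 1, i0])
            hinf = tabs[tt, 2, i0] + fr * (tabs[tt, 2, i0 + 1] - tabs[tt, 2, i0])
            hfac = tabs[tt, 3, i0] + fr * (tabs[tt, 3, i0 + 1] - tabs[tt, 3, i0])
            ninf = tabs[tt, 4, i0] + fr * (tabs[tt, 4, i0 + 1] - tabs[tt, 4, i0])
            nfac = tabs[tt, 5, i0] + fr * (tabs[tt, 5, i0 + 1] - tabs[tt, 5, i0])
            pinf = tabs[tt, 6, i0] + fr * (tabs[tt, 6, i0 + 1] - tabs[tt, 6, i0])
            pfac = tabs[tt, 7, i0] + fr * (tabs[tt, 7, i0 + 1] - tabs[tt, 7, i0])
            mi = m[i] + (minf - m[i]) * mfac
            hi = h[i] + (hinf - h[i]) * hfac
            ni = n[i] + (ninf - n[i]) * nfac
            pi = p[i] + (pinf - p[i]) * pfac
            m[i] = mi
            h[i] = hi
            n[i] = ni
            p[i] = pi
            g_na = gNa[i] * mi * mi * mi * hi
            g_kd = gKd[i] * ni * ni * ni * ni
            g_m = gM[i] * pi
            g_dr = g_noise[i] + g_stim[i]
            g_tot = gL[i] + g_na + g_kd + g_m + g_dr + gsum[i]
            num = (gL[i] * EL[i] + g_na * ENa[i] + (g_kd + g_m) * EK[i]
                   + gEsum[i] + I_ext[i])  # drive reversal is 0 mV
            v_inf = num / g_tot
            Vi = v_inf + (Vi - v_inf) * math.exp(-dt * g_tot / C[i])
            V[i] = Vi

            # --- spike detection and event push
            if Vi < 0.0:
                armed[i] = 1
            elif armed[i] == 1 and step - last_spk[i] >= lockout_steps:
                armed[i] = 0
                last_spk[i] = step
                if n_spikes >= cap_spikes:
                    status = ERR_SPIKE_OVERFLOW
                    bad_cell = i
                    bad_step = step
                    return n_spikes, delivered, status, bad_cell, bad_step
                rec_cell[n_spikes] = i
                rec_t[n_spikes] = tnow
                n_spikes += 1
                for k in range(indptr[i], indptr[i + 1]):
                    slot2 = (step + out_delay[k]) % n_slots
                    c2 = ring_cnt[slot2]
                    if c2 >= slot_cap:
                        status = ERR_RING_OVERFLOW
                        bad_cell = i
                        bad_step = step
                        return n_spikes, delivered, status, bad_cell, bad_step
                    ring[slot2, c2] = out_syn[k]
                    ring_cnt[slot2] = c2 + 1

        # --- voltage recording
        if vrec_every > 0 and step % vrec_every == 0:
            row = step // vrec_every
            for q in range(n_vrec):
                vout[row, q] = V[vrec_idx[q]]

        # --- sanity check
        if step % 400 == 0:
            for i in range(N):
                if not math.isfinite(V[i]):
                    return n_spikes, delivered, ERR_NAN, i, step

    return n_spikes, delivered, status, bad_cell, bad_step
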