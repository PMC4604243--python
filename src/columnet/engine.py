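"""Time-stepped network integration with delayed spike delivery.

The engine lowers a built :class:`~columnet.network.Network` into flat
arrays (one entry per synaptic receptor contact), calibrates peak
conductances to the unitary PSP table, and hands everything to the numba
kernel.  Spikes are delivered through a circular event buffer indexed by the
integer delay of each connection (delays are rounded up to the dt grid);
short-term plasticity is updated event-wise at spike arrival.  Runs are
bit-reproducible given (network, drives, config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import _kernel
from .drive import NoiseSpec, StimulusField, apply_stimulus
from .network import CODE_TYPES, Network, TYPE_CODES
from .neurons import (CellType, NeuronParams, absolute_params,
                      default_neuron_params, m_current_steady, rate_functions,
                      resting_state)
from .synapses import (ALPHA_S, DEFAULT_MG_MM, CONNECTION_TABLE, Receptor,
                       STPMode, calibrate_peak_conductance)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025            # ms; <= 0.05 for HH stability
    t_total: float = 1000.0      # ms
    seed: int = 0
    record_voltages: tuple[int, ...] = ()
    voltage_every: float = 1.0   # ms between recorded voltage samples
    lockout: float = 2.0         # ms spike-detection lockout

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.05:
            raise ValueError("dt must be in (0, 0.05] ms")
        if self.t_total <= 0:
            raise ValueError("t_total must be > 0")


@dataclass
class SpikeRecord:
    """Time-sorted (cell_id, spike_time) pairs for one run."""

    cells: np.ndarray
    times: np.ndarray
    t_total: float
    n_cells: int

    def __len__(self) -> int:
        return len(self.cells)

    def of_population(self, ids) -> "SpikeRecord":
        ids = np.asarray(ids)
        mask = np.isin(self.cells, ids)
        return SpikeRecord(self.cells[mask], self.times[mask],
                           self.t_total, self.n_cells)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(dict(cell_id=self.cells, t_ms=self.times))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path, voltages: dict | None = None) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes/cell_id", data=self.cells)
            f.create_dataset("spikes/t_ms", data=self.times)
            f.attrs["t_total_ms"] = self.t_total
            if voltages:
                for cid, tr in voltages.items():
                    f.create_dataset(f"voltage/{cid}", data=tr)


@dataclass
class SimResult:
    spikes: SpikeRecord
    voltages: dict[int, np.ndarray]
    voltage_times: np.ndarray
    delivered_events: int
    config: SimConfig


# ---------------------------------------------------------------------------
# calibration of per-class conductances (cached across networks)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _calibrated_G(receptor: str, amplitude: float, post_type: str,
                  E_syn: float, first_release: float, dt: float,
                  clamp_mg_block: bool = True) -> float:
    params = default_neuron_params(CellType(post_type))
    return calibrate_peak_conductance(receptor, amplitude, params, E_syn,
                                      first_release, dt=dt,
                                      clamp_mg_block=clamp_mg_block)


def _effective_stp(net: Network, cls: str):
    src = net.stp_overrides.get(cls, cls)
    stp = CONNECTION_TABLE[src].stp
    if (net.tau_facil_override is not None
            and cls in ("PC-MC_LO", "PC-MC_LR")
            and stp.mode == STPMode.FACILITATING):
        stp = replace(stp, tau_facil=float(net.tau_facil_override))
    return stp


# ---------------------------------------------------------------------------
# lowering to kernel arrays
# ---------------------------------------------------------------------------

def _gate_tables(params_by_type: dict[int, NeuronParams], dt: float):
    v_min, v_max, v_step = -120.0, 60.0, 0.05
    V = np.arange(v_min, v_max + v_step / 2, v_step)
    nv = len(V)
    n_types = max(params_by_type) + 1
    tabs = np.zeros((n_types, 8, nv))
    for code, prm in params_by_type.items():
        r = rate_functions(V, prm.V_T)
        am, bm = r["alpha_m"], r["beta_m"]
        ah, bh = r["alpha_h"], r["beta_h"]
        an, bn = r["alpha_n"], r["beta_n"]
        p_inf, tau_p = m_current_steady(V, prm.tau_max)
        tabs[code, 0] = am / (am + bm)
        tabs[code, 1] = -np.expm1(-dt * (am + bm))
        tabs[code, 2] = ah / (ah + bh)
        tabs[code, 3] = -np.expm1(-dt * (ah + bh))
        tabs[code, 4] = an / (an + bn)
        tabs[code, 5] = -np.expm1(-dt * (an + bn))
        tabs[code, 6] = p_inf
        tabs[code, 7] = -np.expm1(-dt / tau_p)
    return tabs, v_min, 1.0 / v_step


class _Compiled:
    """Flat-array form of a network for one dt."""

    def __init__(self, net: Network, dt: float,
                 neuron_params: dict | None = None):
        self.dt = dt
        spec = net.spec
        if neuron_params is None:
            neuron_params = {t: default_neuron_params(t) for t in CellType}
        self.params_by_code = {TYPE_CODES[t]: p
                               for t, p in neuron_params.items()}
        tp = net.cells["type"].values.astype(np.int64)
        N = len(tp)
        self.cell_tt = tp
        arrs = {k: np.empty(N) for k in
                ("C", "gL", "gNa", "gKd", "gM", "EL", "ENa", "EK")}
        self.V0 = np.empty(N)
        self.m0 = np.empty(N)
        self.h0 = np.empty(N)
        self.n0 = np.empty(N)
        self.p0 = np.empty(N)
        for code, prm in self.params_by_code.items():
            sel = tp == code
            ap = absolute_params(prm)
            arrs["C"][sel] = ap["C"]
            arrs["gL"][sel] = ap["g_leak"]
            arrs["gNa"][sel] = ap["g_Na"]
            arrs["gKd"][sel] = ap["g_Kd"]
            arrs["gM"][sel] = ap["g_M"]
            arrs["EL"][sel] = prm.E_leak
            arrs["ENa"][sel] = prm.E_Na
            arrs["EK"][sel] = prm.E_K
            rest = resting_state(prm)
            self.V0[sel] = rest.V
            self.m0[sel] = rest.m
            self.h0[sel] = rest.h
            self.n0[sel] = rest.n
            self.p0[sel] = rest.p
        self.cell_arrays = arrs
        self.tabs, self.v_min, self.v_step_inv = _gate_tables(
            self.params_by_code, dt)

        # --- synapse entries (one per receptor contact) -------------------
        conn = net.connections
        n_conn = len(conn)
        pre_list, post_list = [], []
        G_list, E_list, nmda_list = [], [], []
        tx_list, ts_list = [], []
        fac_list, U_list, U1_list, trec_list, tfac_list = [], [], [], [], []
        delay_list = []
        from .synapses import _KINETICS  # kinetics per receptor
        cls_vals = conn["cls"].astype(str).values
        pre_vals = conn["pre"].values
        post_vals = conn["post"].values
        w_vals = conn["weight_scale"].values if "weight_scale" in conn else \
            np.ones(n_conn)
        d_vals = conn["delay_ms"].values
        for cls in np.unique(cls_vals):
            cdef = CONNECTION_TABLE[cls]
            stp = _effective_stp(net, cls)
            sel = cls_vals == cls
            idx = np.nonzero(sel)[0]
            for receptor, amp in cdef.amplitudes:
                G = _calibrated_G(receptor.value, amp, cdef.post.value,
                                  cdef.E_rev, stp.first_spike_release, 0.025)
                tau_x, tau_s = _KINETICS[receptor.value]
                k = len(idx)
                pre_list.append(pre_vals[idx])
                post_list.append(post_vals[idx])
                G_list.append(G * w_vals[idx])
                E_list.append(np.full(k, cdef.E_rev))
                nmda_list.append(np.full(
                    k, 1 if receptor == Receptor.NMDA else 0, np.uint8))
                tx_list.append(np.full(k, tau_x))
                ts_list.append(np.full(k, tau_s))
                fac_list.append(np.full(
                    k, 1 if stp.mode == STPMode.FACILITATING else 0,
                    np.uint8))
                U_list.append(np.full(k, stp.U))
                U1_list.append(np.full(k, stp.U1))
                trec_list.append(np.full(k, stp.tau_rec))
                tfac_list.append(np.full(k, max(stp.tau_facil, 1.0)))
                delay_list.append(d_vals[idx])

        def cat(lst, dtype=None):
            if not lst:
                return np.empty(0, dtype or np.float64)
            out = np.concatenate(lst)
            return out.astype(dtype) if dtype else out

        self.syn_pre = cat(pre_list, np.int64)
        self.syn_post = cat(post_list, np.int64)
        self.syn_G = cat(G_list)
        self.syn_E = cat(E_list)
        self.syn_nmda = cat(nmda_list, np.uint8)
        self.syn_tau_x = cat(tx_list)
        self.syn_tau_s = cat(ts_list)
        self.stp_facil = cat(fac_list, np.uint8)
        self.stp_U = cat(U_list)
        self.stp_U1 = cat(U1_list)
        self.stp_tau_rec = cat(trec_list)
        self.stp_tau_facil = cat(tfac_list)
        delay_ms = cat(delay_list)
        self.delay_steps = np.maximum(
            np.ceil(delay_ms / dt).astype(np.int64), 1)

        # outgoing CSR over synapse entries
        order = np.argsort(self.syn_pre, kind="stable")
        self.out_syn = order.astype(np.int64)
        self.out_delay = self.delay_steps[order]
        counts = np.bincount(self.syn_pre, minlength=N)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.max_delay = int(self.delay_steps.max()) if len(
            self.delay_steps) else 1

    @property
    def n_entries(self) -> int:
        return len(self.syn_post)


def compile_network(net: Network, dt: float,
                    neuron_params: dict | None = None) -> _Compiled:
    key = (dt, id(neuron_params))
    cache = getattr(net, "_compiled_cache", None)
    if cache is None:
        cache = {}
        net._compiled_cache = cache
    if key not in cache:
        cache[key] = _Compiled(net, dt, neuron_params)
    return cache[key]


def run(net: Network, config: SimConfig,
        noise: NoiseSpec | None = None,
        stimulus: StimulusField | None = None,
        I_ext: np.ndarray | dict | None = None,
        neuron_params: dict | None = None) -> SimResult:
    """Integrate the network and return spikes (plus optional voltages)."""
    comp = compile_network(net, config.dt, neuron_params)
    N = net.n_cells
    dt = config.dt
    n_steps = int(round(config.t_total / dt))
    if noise is None:
        noise = NoiseSpec()

    if stimulus is not None:
        stim_mean = apply_stimulus(stimulus, net)
        stim_on = int(round(stimulus.onset / dt))
        stim_off = int(round((stimulus.onset + stimulus.duration) / dt))
        stim_sd, stim_tau = stimulus.g_sd, stimulus.tau
    else:
        stim_mean = np.zeros(N)
        stim_on, stim_off = 0, 0
        stim_sd, stim_tau = 0.0, 1.0

    noise_sd_arr = np.full(N, noise.g_sd)
    if noise.equalize_fluctuations and noise.g_sd > 0:
        ref = comp.params_by_code[TYPE_CODES[CellType.PC]]
        for code, prm in comp.params_by_code.items():
            noise_sd_arr[comp.cell_tt == code] = \
                noise.g_sd * noise.sd_scale(prm, ref)

    ext = np.zeros(N)
    if I_ext is not None:
        if isinstance(I_ext, dict):
            for cid, val in I_ext.items():
                ext[cid] = val
        else:
            ext[:] = np.asarray(I_ext)

    vrec_idx = np.asarray(config.record_voltages, np.int64)
    vrec_every = max(int(round(config.voltage_every / dt)), 1) \
        if len(vrec_idx) else 0
    n_rows = (n_steps + vrec_every - 1) // vrec_every if vrec_every else 0
    lockout_steps = max(int(round(config.lockout / dt)), 1)
    kseed = int(config.seed) % (2 ** 31 - 1)

    cap_spikes = int(N * (config.t_total / 1000.0) * 250) + 10000
    slot_cap = 1024
    for _attempt in range(4):
        x = np.zeros(comp.n_entries)
        s = np.zeros(comp.n_entries)
        R = np.ones(comp.n_entries)
        Udyn = np.zeros(comp.n_entries)
        last_t = np.full(comp.n_entries, -1e30)
        V = comp.V0.copy()
        m = comp.m0.copy()
        h = comp.h0.copy()
        nn = comp.n0.copy()
        p = comp.p0.copy()
        rec_cell = np.empty(cap_spikes, np.int32)
        rec_t = np.empty(cap_spikes)
        vout = np.zeros((n_rows, len(vrec_idx)))
        ca = comp.cell_arrays
        n_spk, delivered, status, bad_cell, bad_step = _kernel.simulate(
            dt, n_steps,
            comp.cell_tt, ca["C"], ca["gL"], ca["gNa"], ca["gKd"], ca["gM"],
            ca["EL"], ca["ENa"], ca["EK"],
            V, m, h, nn, p,
            comp.tabs, comp.v_min, comp.v_step_inv,
            comp.syn_post, comp.syn_G, comp.syn_E, comp.syn_nmda,
            comp.syn_tau_x, comp.syn_tau_s,
            comp.stp_facil, comp.stp_U, comp.stp_U1, comp.stp_tau_rec,
            comp.stp_tau_facil,
            x, s, R, Udyn, last_t,
            comp.indptr, comp.out_syn, comp.out_delay,
            comp.max_delay + 2, slot_cap,
            noise.g_mean, noise_sd_arr, noise.tau_noise,
            stim_mean, stim_sd, stim_tau, stim_on, stim_off,
            ext,
            DEFAULT_MG_MM, ALPHA_S, kseed, lockout_steps,
            rec_cell, rec_t, vrec_idx, vrec_every, vout)
        if status == _kernel.OK:
            break
        if status == _kernel.ERR_SPIKE_OVERFLOW:
            cap_spikes *= 4
        elif status == _kernel.ERR_RING_OVERFLOW:
            slot_cap *= 4
        else:
            raise SimulationError(
                f"non-finite membrane potential at cell {bad_cell}, "
                f"t = {bad_step * dt:.3f} ms")
    else:
        raise SimulationError("event buffers kept overflowing")

    spikes = SpikeRecord(rec_cell[:n_spk].copy(), rec_t[:n_spk].copy(),
                         config.t_total, N)
    voltages = {int(cid): vout[:, q] for q, cid in enumerate(vrec_idx)}
    vt = np.arange(n_rows) * vrec_every * dt if n_rows else np.empty(0)
    return SimResult(spikes=spikes, voltages=voltages, voltage_times=vt,
                     delivered_events=int(delivered), config=config)


def halve_step_check(net: Network, config: SimConfig,
                     noise: NoiseSpec | None = None,
                     stimulus: StimulusField | None = None,
                     I_ext=None, bin_ms: float = 100.0,
                     tolerance: float = 0.05) -> dict:
    """Numerical-accuracy control: compare dt with dt/2.

    Population rate traces (bin_ms bins, per cell type) are compared by
    relative RMS difference, and total spike counts per type by relative
    difference.  Exceeding ``tolerance`` flags the report; it is not fatal.
    """
    res1 = run(net, config, noise, stimulus, I_ext)
    cfg2 = replace(config, dt=config.dt / 2)
    res2 = run(net, cfg2, noise, stimulus, I_ext)
    edges = np.arange(0.0, config.t_total + bin_ms / 2, bin_ms)
    report = {"dt": config.dt, "bins_ms": bin_ms, "populations": {}}
    ok = True
    tp = net.cells["type"].values
    for code, ct in CODE_TYPES.items():
        ids = np.nonzero(tp == code)[0]
        a = np.histogram(res1.spikes.of_population(ids).times, edges)[0]
        b = np.histogram(res2.spikes.of_population(ids).times, edges)[0]
        denom = max(np.sqrt(np.mean((0.5 * (a + b)) ** 2)), 1e-12)
        rms = float(np.sqrt(np.mean((a - b) ** 2)) / denom)
        ca, cb = int(a.sum()), int(b.sum())
        cdiff = abs(ca - cb) / max(ca, cb, 1)
        within = (rms < tolerance or max(ca, cb) == 0) and cdiff < tolerance
        ok &= within
        report["populations"][ct.value] = dict(
            rate_rms_rel=rms, count_dt=ca, count_dt_half=cb,
            count_rel_diff=float(cdiff), within_tolerance=bool(within))
    report["within_tolerance"] = bool(ok)
    return report
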