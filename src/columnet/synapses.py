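"""Kinetic receptor models, short-term plasticity and PSP calibration.

Receptors (AMPA/kainate, NMDA, GABA_A) follow first-order gating: an
auxiliary drive ``x`` is incremented by ``alpha_x`` at each presynaptic spike
and decays with ``tau_x``; the open-channel fraction ``s`` relaxes via
``ds/dt = alpha_s x (1 - s) - s / tau_s``.  The synaptic current is
``G s (E_syn - V)``; NMDA is additionally gated by the voltage-dependent
magnesium block ``B(V) = 1 / (1 + [Mg] exp(-0.062 V) / 3.57)``.

Short-term plasticity is the standard resource model: a fraction ``U`` of the
available vesicle pool ``R`` is released per spike and recovers with
``tau_rec``.  At facilitating synapses ``U`` is itself dynamic, incremented by
``U1 (1 - U)`` per spike and decaying with ``tau_facil``.  The release scale
``U_eff * R`` multiplies the per-spike increment of ``x``.

Peak conductances are not free parameters: they are calibrated so that a
single presynaptic spike onto a resting postsynaptic cell produces the
tabulated unitary PSP amplitude for its connection class.  Because the
release scale of the very first spike from a fresh state is ``U`` (depressing)
or ``U1`` (facilitating), that factor is absorbed into the calibrated ``G``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache

import numpy as np

from .neurons import CellType, NeuronParams, default_neuron_params

DEFAULT_MG_MM = 1.0  # Mg2+ concentration (mM) for the NMDA block

ALPHA_X = 1.0   # dimensionless increment of x per spike
ALPHA_S = 1.0   # 1/ms

# Receptor kinetics: (tau_x ms, tau_s ms).
_KINETICS = {
    "AMPA": (0.05, 6.0),
    "GABA_A": (0.05, 6.0),
    "NMDA": (5.0, 150.0),
}


class Receptor(str, Enum):
    AMPA = "AMPA"
    NMDA = "NMDA"
    GABA_A = "GABA_A"


@dataclass(frozen=True)
class SynapseSpec:
    receptor: Receptor
    G_syn: float               # peak conductance scale (uS)
    E_syn: float               # reversal potential (mV)
    alpha_x: float = ALPHA_X
    alpha_s: float = ALPHA_S
    tau_x: float = 0.05        # ms
    tau_s: float = 6.0         # ms
    mg_conc: float = DEFAULT_MG_MM

    def __post_init__(self):
        if self.G_syn < 0:
            raise ValueError("G_syn must be >= 0")
        if self.tau_x <= 0 or self.tau_s <= 0:
            raise ValueError("tau_x and tau_s must be > 0")

    @classmethod
    def for_receptor(cls, receptor: Receptor | str, G_syn: float,
                     E_syn: float, **kw) -> "SynapseSpec":
        receptor = Receptor(receptor)
        tau_x, tau_s = _KINETICS[receptor.value]
        return cls(receptor=receptor, G_syn=G_syn, E_syn=E_syn,
                   tau_x=tau_x, tau_s=tau_s, **kw)


@dataclass
class SynapseState:
    x: float = 0.0
    s: float = 0.0


class STPMode(str, Enum):
    DEPRESSING = "depressing"
    FACILITATING = "facilitating"


@dataclass(frozen=True)
class STPSpec:
    mode: STPMode
    U: float = 0.0          # baseline utilization (depressing mode)
    U1: float = 0.0         # per-spike facilitation increment
    tau_rec: float = 1.0    # ms
    tau_facil: float = 0.0  # ms; 0 means no facilitation variable

    def __post_init__(self):
        if not (0.0 <= self.U <= 1.0 and 0.0 <= self.U1 <= 1.0):
            raise ValueError("U and U1 must be in [0, 1]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be > 0")
        if self.tau_facil < 0:
            raise ValueError("tau_facil must be >= 0")
        if self.mode == STPMode.FACILITATING and self.tau_facil <= 0:
            raise ValueError("facilitating mode requires tau_facil > 0")

    @property
    def first_spike_release(self) -> float:
        """Release scale of the first spike from a fresh state (R = 1)."""
        if self.mode == STPMode.DEPRESSING:
            return self.U
        return self.U1


@dataclass
class STPState:
    R: float = 1.0
    U_dyn: float = 0.0


def mg_block(V, mg_conc: float = DEFAULT_MG_MM):
    """NMDA magnesium unblock factor B(V)."""
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + mg_conc * np.exp(-0.062 * V) / 3.57)


def synaptic_current(spec: SynapseSpec, state: SynapseState, V: float) -> float:
    """Postsynaptic current in nA (positive = inward/depolarizing)."""
    I = spec.G_syn * state.s * (spec.E_syn - V)
    if spec.receptor == Receptor.NMDA:
        I *= float(mg_block(V, spec.mg_conc))
    return float(I)


def gating_step(spec: SynapseSpec, state: SynapseState, dt: float,
                spike_arrivals: int = 0,
                release_scale: float = 1.0) -> SynapseState:
    """Advance (x, s) by one time step of length dt.

    Arriving spikes increment x by ``alpha_x * release_scale`` at the start of
    the step.  x then decays exactly; s is advanced by exponential Euler
    against the within-step average of x, which keeps the update accurate even
    when ``dt`` is comparable to ``tau_x``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = state.x + spike_arrivals * spec.alpha_x * release_scale
    decay = math.exp(-dt / spec.tau_x)
    xbar = x * (1.0 - decay) * (spec.tau_x / dt)
    a = spec.alpha_s * xbar + 1.0 / spec.tau_s
    s_inf = spec.alpha_s * xbar / a
    s = s_inf + (state.s - s_inf) * math.exp(-a * dt)
    return SynapseState(x=x * decay, s=min(max(s, 0.0), 1.0))


def stp_on_spike(spec: STPSpec, state: STPState,
                 interval_since_last: float) -> tuple[STPState, float]:
    """Event-based update of (R, U) at a presynaptic spike.

    ``interval_since_last`` is the time since the previous spike (use a very
    large value, e.g. 1e12, for the first spike of a fresh synapse).  Returns
    the post-spike state and the release scale ``U_eff * R`` that multiplies
    the gating increment for this spike.
    """
    if interval_since_last < 0:
        raise ValueError("interval must be >= 0")
    R = 1.0 - (1.0 - state.R) * math.exp(-interval_since_last / spec.tau_rec)
    if spec.mode == STPMode.FACILITATING:
        U = state.U_dyn
        if spec.tau_facil > 0:
            U *= math.exp(-interval_since_last / spec.tau_facil)
        U = U + spec.U1 * (1.0 - U)
        U_eff = U
        new_U = U
    else:
        U_eff = spec.U
        new_U = state.U_dyn
    release = U_eff * R
    R = R - release
    return STPState(R=R, U_dyn=new_U), release


# ---------------------------------------------------------------------------
# Connection classes (the pre/post pathway parameter table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectionClass:
    """One pre->post pathway: receptors with unitary amplitudes plus STP.

    ``amplitudes`` maps receptor -> unitary PSP amplitude in mV measured at
    the postsynaptic resting potential (negative for IPSPs).  ``probability``
    is the Bernoulli connection probability within ``scope`` ("minicolumn",
    "hypercolumn" or "longrange").
    """

    name: str
    pre: CellType
    post: CellType
    amplitudes: tuple[tuple[Receptor, float], ...]
    probability: float | None
    scope: str
    stp: STPSpec
    E_rev: float

    def synapse_spec(self, receptor: Receptor, G_syn: float) -> SynapseSpec:
        return SynapseSpec.for_receptor(receptor, G_syn, self.E_rev)


_DEP = STPMode.DEPRESSING
_FAC = STPMode.FACILITATING

_STP_PC_MC = STPSpec(mode=_FAC, U1=0.05, tau_rec=20.0, tau_facil=1000.0)
_STP_PC_BC = STPSpec(mode=_DEP, U=0.5, tau_rec=600.0)
_STP_GABA = STPSpec(mode=_DEP, U=0.25, tau_rec=500.0)
_STP_PC_PC = STPSpec(mode=_DEP, U=0.4, tau_rec=600.0)


def connection_table() -> dict[str, ConnectionClass]:
    """Default pathway table (amplitudes mV, probabilities, STP constants)."""
    A, N, G = Receptor.AMPA, Receptor.NMDA, Receptor.GABA_A
    PC, BC, MC, VIP = CellType.PC, CellType.BC, CellType.MC, CellType.VIP
    rows = [
        ConnectionClass("PC-PC_LO", PC, PC, ((A, 1.2), (N, 0.6)), 0.25,
                        "minicolumn", _STP_PC_PC, 0.0),
        ConnectionClass("PC-PC_LR", PC, PC, ((A, 0.3), (N, 0.15)), None,
                        "longrange", _STP_PC_PC, 0.0),
        ConnectionClass("PC-BC", PC, BC, ((A, 1.7),), 0.70,
                        "hypercolumn", _STP_PC_BC, 0.0),
        ConnectionClass("PC-MC_LO", PC, MC, ((A, 0.1),), 0.30,
                        "minicolumn", _STP_PC_MC, 0.0),
        ConnectionClass("PC-MC_LR", PC, MC, ((A, 0.1),), None,
                        "longrange", _STP_PC_MC, 0.0),
        ConnectionClass("BC-PC", BC, PC, ((G, -1.4),), 0.70,
                        "hypercolumn", _STP_GABA, -75.0),
        ConnectionClass("MC-PC", MC, PC, ((G, -0.6),), 0.80,
                        "minicolumn", _STP_GABA, -75.0),
        ConnectionClass("VIP-MC", VIP, MC, ((G, -0.2),), 0.60,
                        "minicolumn", _STP_GABA, -75.0),
        # Variant pathway: long-range terminal redirected onto basket cells.
        # Uses the PC-BC unitary amplitude; dynamics set per network variant.
        ConnectionClass("PC-BC_LR", PC, BC, ((A, 1.7),), None,
                        "longrange", _STP_PC_BC, 0.0),
    ]
    return {r.name: r for r in rows}


CONNECTION_TABLE = connection_table()


# ---------------------------------------------------------------------------
# Unitary-PSP calibration
# ---------------------------------------------------------------------------

def unitary_psp_peak(receptor: Receptor, G_syn: float,
                     post_params: NeuronParams, E_syn: float,
                     release_scale: float, *, mg_conc: float = DEFAULT_MG_MM,
                     clamp_mg_block: bool = False, dt: float = 0.025,
                     t_max: float | None = None) -> float:
    """Peak somatic deflection (mV, signed) from one presynaptic spike.

    Integrates a single postsynaptic neuron from its resting fixed point with
    one synapse receiving a single spike.  Raises if the cell spikes.
    """
    from ._kernel import psp_response  # deferred: numba compilation
    from .neurons import absolute_params, resting_state

    tau_x, tau_s = _KINETICS[Receptor(receptor).value]
    if t_max is None:
        t_max = 120.0 if tau_s < 50 else 400.0
    rest = resting_state(post_params)
    ap = absolute_params(post_params)
    is_nmda = 1 if Receptor(receptor) == Receptor.NMDA else 0
    mg = 0.0 if (clamp_mg_block and is_nmda) else mg_conc
    peak, spiked = psp_response(
        ap["C"], ap["g_leak"], ap["g_Na"], ap["g_Kd"], ap["g_M"],
        post_params.E_leak, post_params.E_Na, post_params.E_K,
        post_params.V_T, post_params.tau_max,
        rest.V, rest.m, rest.h, rest.n, rest.p,
        G_syn, E_syn, tau_x, tau_s, is_nmda, mg,
        release_scale * ALPHA_X, ALPHA_S, dt, t_max)
    if spiked:
        raise CalibrationError(
            "postsynaptic cell spiked during unitary PSP measurement")
    return float(peak)


class CalibrationError(RuntimeError):
    pass


def calibrate_peak_conductance(receptor: Receptor | str,
                               target_amplitude: float,
                               post_params: NeuronParams,
                               E_syn: float,
                               first_spike_release: float,
                               *, tol: float = 2e-3,
                               mg_conc: float = DEFAULT_MG_MM,
                               clamp_mg_block: bool = False,
                               dt: float = 0.025) -> float:
    """Find G_syn such that the unitary PSP equals ``target_amplitude``.

    The unitary peak is monotone in G_syn in the subthreshold regime, so a
    bracketing secant/bisection converges; ``tol`` is the permitted deviation
    of the measured peak (mV).
    """
    receptor = Receptor(receptor)
    if target_amplitude == 0:
        raise CalibrationError("target amplitude must be nonzero")
    rest_V = None
    if target_amplitude < 0:
        # hyperpolarizing targets beyond the driving force are unreachable
        from .neurons import resting_potential
        rest_V = resting_potential(post_params)
        if target_amplitude <= E_syn - rest_V:
            raise CalibrationError(
                f"target {target_amplitude} mV unreachable: reversal is only "
                f"{E_syn - rest_V:.2f} mV below rest")
    if first_spike_release <= 0:
        raise CalibrationError("first-spike release scale must be > 0")

    def peak(G):
        try:
            return unitary_psp_peak(receptor, G, post_params, E_syn,
                                    first_spike_release, mg_conc=mg_conc,
                                    clamp_mg_block=clamp_mg_block, dt=dt)
        except CalibrationError:
            # postsynaptic spike: the probe conductance is far too large
            return math.copysign(1e6, target_amplitude)

    # bracket the target: |peak| is monotone increasing in G subthreshold
    g_lo, g_hi = 0.0, 1e-4
    f_hi = peak(g_hi)
    for _ in range(80):
        if abs(f_hi) >= abs(target_amplitude):
            break
        g_hi *= 2.0
        f_hi = peak(g_hi)
    else:
        raise CalibrationError("could not bracket target amplitude")
    if abs(f_hi - target_amplitude) < tol:
        return g_hi
    # bisection on the bracket
    for _ in range(200):
        g_mid = 0.5 * (g_lo + g_hi)
        f_mid = peak(g_mid)
        if abs(f_mid - target_amplitude) < tol:
            return g_mid
        if abs(f_mid) < abs(target_amplitude):
            g_lo = g_mid
        else:
            g_hi = g_mid
    raise CalibrationError("calibration did not converge")


@lru_cache(maxsize=8)
def calibrated_conductances(dt: float = 0.025,
                            mg_conc: float = DEFAULT_MG_MM,
                            clamp_mg_block: bool = True
                            ) -> dict[tuple[str, str], float]:
    """Calibrated G_syn (uS) for every (connection class, receptor) pair."""
    out: dict[tuple[str, str], float] = {}
    for name, cls in connection_table().items():
        post_params = default_neuron_params(cls.post)
        for receptor, amp in cls.amplitudes:
            out[(name, receptor.value)] = calibrate_peak_conductance(
                receptor, amp, post_params, cls.E_rev,
                cls.stp.first_spike_release, mg_conc=mg_conc,
                clamp_mg_block=clamp_mg_block, dt=dt)
    return out
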