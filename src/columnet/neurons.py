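"""Single-compartment Hodgkin-Huxley neurons for the four cortical cell types.

The network distinguishes layer 2/3 pyramidal cells (PC), parvalbumin basket
cells (BC), somatostatin Martinotti cells (MC) and VIP interneurons.  Each is
a single cylindrical compartment carrying a transient Na current, a delayed
rectifier K current and a slow non-inactivating M-type K current that produces
spike-frequency adaptation.  The kinetics follow the Traub-Miles-style
formalism with a threshold-shift parameter ``V_T``; channel densities,
reversal potentials and soma diameters are per-cell-type constants.

Units used throughout the package: mV, ms, uS (microsiemens), nA, nF.
Channel densities are stored as specific conductances in S/cm^2 and converted
with the membrane area of the soma cylinder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq


class CellType(str, Enum):
    PC = "PC"
    BC = "BC"
    MC = "MC"
    VIP = "VIP"


#: default soma length as a fraction of the diameter.  The length of the
#: soma cylinder is a free geometric parameter; it fixes the absolute
#: membrane area and therefore how strong the fixed drive conductances
#: (background noise, stimulus levels) are relative to each cell.  L = d/8
#: gives input resistances of a few hundred megaohms (physiological for
#: layer 2/3 cells) and makes the default stimulus level a suprathreshold
#: mean drive, consistent with the stated drive constants; set
#: ``soma_length = soma_diameter`` for an iso-dimensional cylinder.
DEFAULT_LENGTH_RATIO = 0.30


@dataclass(frozen=True)
class NeuronParams:
    """Per-cell-type membrane parameters.

    ``E_*`` are reversal potentials (mV), ``g_*`` specific conductances
    (S/cm^2), ``soma_diameter`` in um, ``c_m`` in uF/cm^2.  ``V_T`` shifts
    the Na/K activation kinetics and sets the spike threshold region;
    ``tau_max`` scales the M-current time constant (ms).
    """

    cell_type: CellType
    E_leak: float = -70.0
    E_Na: float = 50.0
    E_K: float = -100.0
    g_leak: float = 1e-4
    g_Na: float = 0.05
    g_Kd: float = 0.005
    g_M: float = 7e-5
    soma_diameter: float = 96.0
    soma_length: float | None = None   # um; None -> DEFAULT_LENGTH_RATIO * d
    c_m: float = 1.0
    tau_max: float = 1000.0
    V_T: float = -55.0

    def __post_init__(self) -> None:
        for name in ("g_leak", "g_Na", "g_Kd", "g_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.soma_diameter <= 0:
            raise ValueError("soma_diameter must be > 0")
        if self.soma_length is not None and self.soma_length <= 0:
            raise ValueError("soma_length must be > 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if self.tau_max <= 0:
            raise ValueError("tau_max must be > 0")

    @classmethod
    def default(cls, cell_type: CellType | str) -> "NeuronParams":
        return default_neuron_params(CellType(cell_type))


# Default parameter table.  MC and VIP share one column: both are adapting
# interneurons of the same soma size as BC, and no separate VIP measurements
# are available, so VIP inherits the MC values.
_DEFAULTS: dict[CellType, dict] = {
    CellType.PC: dict(g_leak=1e-4, g_Na=0.05, g_Kd=0.005, g_M=7e-5,
                      soma_diameter=96.0),
    CellType.BC: dict(g_leak=1.5e-4, g_Na=0.05, g_Kd=0.01, g_M=9.8e-5,
                      soma_diameter=67.0, V_T=-58.0),
    CellType.MC: dict(g_leak=1.5e-4, g_Na=0.05, g_Kd=0.01, g_M=1e-4,
                      soma_diameter=67.0, V_T=-60.0),
}
_DEFAULTS[CellType.VIP] = dict(_DEFAULTS[CellType.MC])


def default_neuron_params(cell_type: CellType, *, adapting_bc: bool = True,
                          **overrides) -> NeuronParams:
    """Default parameter set for a cell type.

    ``adapting_bc=False`` zeroes the BC M-current: BC are described as
    non-adapting fast spikers, yet the parameter table assigns them a small
    g_M; the table value is the default and the switch restores strict
    non-adaptation.
    """
    kw = dict(_DEFAULTS[CellType(cell_type)])
    if cell_type == CellType.BC and not adapting_bc:
        kw["g_M"] = 0.0
    kw.update(overrides)
    return NeuronParams(cell_type=CellType(cell_type), **kw)


@dataclass
class GatingState:
    """Instantaneous channel state: membrane potential plus the four gates."""

    V: float
    m: float
    h: float
    n: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n, self.p])


def membrane_area(params: NeuronParams) -> float:
    """Lateral area (cm^2) of the soma cylinder: pi * d * L.

    With ``soma_length`` unset, L defaults to ``DEFAULT_LENGTH_RATIO * d``
    (see that constant for the rationale).  The area converts the specific
    channel densities into absolute conductances and sets the cell's input
    resistance, hence the potency of the absolute drive conductances.
    """
    if params.soma_diameter <= 0:
        raise ValueError("soma_diameter must be > 0")
    d_cm = params.soma_diameter * 1e-4
    L = params.soma_length if params.soma_length is not None \
        else DEFAULT_LENGTH_RATIO * params.soma_diameter
    return math.pi * d_cm * (L * 1e-4)


def absolute_params(params: NeuronParams) -> dict[str, float]:
    """Convert specific conductances/capacitance to absolute uS / nF."""
    area = membrane_area(params)
    s_to_us = 1e6
    return dict(
        C=params.c_m * area * 1e3,            # uF/cm^2 * cm^2 -> uF -> nF
        g_leak=params.g_leak * area * s_to_us,
        g_Na=params.g_Na * area * s_to_us,
        g_Kd=params.g_Kd * area * s_to_us,
        g_M=params.g_M * area * s_to_us,
    )


def _exprel(z):
    """z / (exp(z) - 1), continuous at z = 0."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-8
    den = np.where(small, 1.0, np.expm1(np.where(small, 1.0, z)))
    out = np.where(small, 1.0 - z / 2.0, np.where(small, 1.0, z) / den)
    return out


def rate_functions(V, V_T: float):
    """Voltage-dependent transition rates (1/ms) of the Na and Kd gates.

    Returns a dict with alpha/beta for m, h and n.  The removable
    singularities of alpha_m (at V - V_T = 13), beta_m (at V - V_T = 40) and
    alpha_n (at V - V_T = 15) are evaluated by their analytic limits.
    """
    V = np.asarray(V, dtype=float)
    u_m = V - V_T - 13.0
    u_b = V - V_T - 40.0
    u_n = V - V_T - 15.0
    # alpha_m = -0.32 u / (exp(-u/4) - 1) = 0.32 * 4 * exprel(-u/4) ... note
    # x/(exp(-x/a)-1) = -a * (x/a)/(exp(-x/a)-1) -> rewrite via exprel.
    alpha_m = 1.28 * _exprel(-u_m / 4.0)
    beta_m = 1.4 * _exprel(u_b / 5.0)
    alpha_h = 0.128 * np.exp(-(V - V_T - 17.0) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp(-u_b / 5.0))
    alpha_n = 0.16 * _exprel(-u_n / 5.0)
    beta_n = 0.5 * np.exp(-(V - V_T - 10.0) / 40.0)
    return dict(alpha_m=alpha_m, beta_m=beta_m, alpha_h=alpha_h,
                beta_h=beta_h, alpha_n=alpha_n, beta_n=beta_n)


def m_current_steady(V, tau_max: float):
    """Steady state and time constant of the M-current gate p."""
    if tau_max <= 0:
        raise ValueError("tau_max must be > 0")
    V = np.asarray(V, dtype=float)
    p_inf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * np.exp((V + 35.0) / 20.0)
                       + np.exp(-(V + 35.0) / 20.0))
    return p_inf, tau_p


def steady_gates(V: float, params: NeuronParams) -> GatingState:
    """Gate values at their voltage-dependent steady state."""
    r = rate_functions(V, params.V_T)
    m = float(r["alpha_m"] / (r["alpha_m"] + r["beta_m"]))
    h = float(r["alpha_h"] / (r["alpha_h"] + r["beta_h"]))
    n = float(r["alpha_n"] / (r["alpha_n"] + r["beta_n"]))
    p_inf, _ = m_current_steady(V, params.tau_max)
    return GatingState(V=float(V), m=m, h=h, n=n, p=float(p_inf))


def membrane_derivative(state: GatingState, params: NeuronParams,
                        I_syn_total: float = 0.0) -> np.ndarray:
    """Time derivative of (V, m, h, n, p); synaptic current in nA."""
    vals = state.as_array()
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite state in membrane_derivative")
    V, m, h, n, p = state.V, state.m, state.h, state.n, state.p
    ap = absolute_params(params)
    I_Na = ap["g_Na"] * m ** 3 * h * (V - params.E_Na)
    I_Kd = ap["g_Kd"] * n ** 4 * (V - params.E_K)
    I_M = ap["g_M"] * p * (V - params.E_K)
    I_leak = ap["g_leak"] * (V - params.E_leak)
    dV = (-I_leak - I_Na - I_Kd - I_M + I_syn_total) / ap["C"]
    r = rate_functions(V, params.V_T)
    dm = float(r["alpha_m"] * (1 - m) - r["beta_m"] * m)
    dh = float(r["alpha_h"] * (1 - h) - r["beta_h"] * h)
    dn = float(r["alpha_n"] * (1 - n) - r["beta_n"] * n)
    p_inf, tau_p = m_current_steady(V, params.tau_max)
    dp = float((p_inf - p) / tau_p)
    return np.array([float(dV), dm, dh, dn, dp])


def _steady_current(V: float, params: NeuronParams, g_extra: float,
                    E_extra: float) -> float:
    """Total membrane current (nA) with all gates at steady state."""
    st = steady_gates(V, params)
    ap = absolute_params(params)
    I = (-ap["g_leak"] * (V - params.E_leak)
         - ap["g_Na"] * st.m ** 3 * st.h * (V - params.E_Na)
         - ap["g_Kd"] * st.n ** 4 * (V - params.E_K)
         - ap["g_M"] * st.p * (V - params.E_K)
         + g_extra * (E_extra - V))
    return I


def resting_potential(params: NeuronParams, g_extra: float = 0.0,
                      E_extra: float = 0.0) -> float:
    """Resting fixed point of the membrane equation (root near E_leak).

    Scans upward from well below E_leak and takes the first zero crossing of
    the steady-state current, which is the stable rest state.
    """
    grid = np.arange(-95.0, -35.0, 0.25)
    vals = [_steady_current(v, params, g_extra, E_extra) for v in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0:
            return float(lo)
        if flo * fhi < 0:
            return float(brentq(_steady_current, lo, hi,
                                args=(params, g_extra, E_extra), xtol=1e-10))
    raise RuntimeError("no resting fixed point found in [-95, -35] mV")


def resting_state(params: NeuronParams, g_extra: float = 0.0,
                  E_extra: float = 0.0) -> GatingState:
    """GatingState at the noise-free resting fixed point."""
    V0 = resting_potential(params, g_extra, E_extra)
    return steady_gates(V0, params)
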