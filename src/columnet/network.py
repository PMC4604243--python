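"""Hypercolumn/minicolumn network construction.

The model patch is a square grid of hypercolumns (default 6 x 6, 500 um
apart), each containing a fixed number of minicolumns (default 6).  A
minicolumn holds 30 pyramidal cells (PC), 3 Martinotti cells (MC) and 3 VIP
cells; each hypercolumn additionally holds 8 basket cells (BC) that provide
unspecific lateral inhibition across its minicolumns.  Minicolumns with the
same index in different hypercolumns encode the same feature ("pattern") and
are linked by long-range connections: every PC innervates 4 PC and 1
interneuron terminal in one randomly chosen same-pattern minicolumn of
another hypercolumn.

Six wiring variants control who receives the long-range interneuron
terminal and how specific that inhibition is; weight compensation keeps the
product (interneurons per pool x incoming projections x weight) constant
across variants so that total inhibition is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .neurons import CellType

# integer codes used in the cell table
TYPE_CODES = {CellType.PC: 0, CellType.BC: 1, CellType.MC: 2, CellType.VIP: 3}
CODE_TYPES = {v: k for k, v in TYPE_CODES.items()}


class Variant(str, Enum):
    TYPE1 = "Type1"
    TYPE2 = "Type2"
    TYPE3 = "Type3"
    TYPE4 = "Type4"
    TYPE5 = "Type5"
    TYPE6 = "Type6"


# (lr_target, lr_dynamics, interneuron_orientation) presets.  Types 2 and 3
# are both BC-mediated, orientation-unspecific variants; they are exposed as
# the depressing and facilitating flavor of the long-range synapse onto BC.
# Type 6 ("orientation-specific BC") keeps the minicolumn-specific relay
# wiring of Type 1 but gives the PC->relay synapses depressing BC-type
# dynamics.
VARIANT_PRESETS: dict[Variant, tuple[str, str | None, str]] = {
    Variant.TYPE1: ("MC", "facilitating", "specific"),
    Variant.TYPE2: ("BC", "depressing", "unspecific"),
    Variant.TYPE3: ("BC", "facilitating", "unspecific"),
    Variant.TYPE4: ("MC", "facilitating", "unspecific"),
    Variant.TYPE5: ("none", None, "specific"),
    Variant.TYPE6: ("BC", "depressing", "specific"),
}


class BuildError(RuntimeError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    grid: tuple[int, int] = (6, 6)
    minicolumns_per_hc: int = 6
    pc_per_mc: int = 30
    mc_per_mc: int = 3
    vip_per_mc: int = 3
    bc_per_hc: int = 8
    hc_diameter: float = 500.0          # um
    conduction_speed_mean: float = 0.3  # m/s
    conduction_speed_sd: float = 0.06   # m/s (0.2 x mean)
    variant: Variant = Variant.TYPE1
    tau_facil_override: float | None = None  # ms, PC-MC_LO and PC-MC_LR
    seed: int = 0
    z_jitter: float = 50.0              # um

    def __post_init__(self):
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise BuildError("grid must be at least 1x1")
        if self.pc_per_mc < 5:
            raise BuildError("need at least 5 PC per minicolumn "
                             "(4 long-range targets + source)")
        if self.mc_per_mc < 1 or self.bc_per_hc < 1:
            raise BuildError("need at least one MC per minicolumn and BC "
                             "per hypercolumn")

    @property
    def n_hc(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def lr_target(self) -> str:
        return VARIANT_PRESETS[self.variant][0]

    @property
    def lr_dynamics(self) -> str | None:
        return VARIANT_PRESETS[self.variant][1]

    @property
    def interneuron_orientation(self) -> str:
        return VARIANT_PRESETS[self.variant][2]

    @property
    def cells_per_mc(self) -> int:
        return self.pc_per_mc + self.mc_per_mc + self.vip_per_mc

    @property
    def cells_per_hc(self) -> int:
        return self.minicolumns_per_hc * self.cells_per_mc + self.bc_per_hc

    @property
    def n_cells(self) -> int:
        return self.n_hc * self.cells_per_hc


@dataclass
class Network:
    spec: NetworkSpec
    cells: pd.DataFrame          # id, type, hc, mc, x, y, z
    connections: pd.DataFrame    # pre, post, cls, delay_ms, weight_scale
    stp_overrides: dict[str, str] = field(default_factory=dict)
    tau_facil_override: float | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def pattern_of(self, minicolumn: int) -> int:
        """Same-index minicolumns across hypercolumns share a pattern."""
        return int(minicolumn)

    def cell_ids(self, cell_type: CellType | str | None = None,
                 hc: int | None = None, mc: int | None = None) -> np.ndarray:
        sel = np.ones(len(self.cells), bool)
        if cell_type is not None:
            sel &= self.cells["type"].values == TYPE_CODES[CellType(cell_type)]
        if hc is not None:
            sel &= self.cells["hc"].values == hc
        if mc is not None:
            sel &= self.cells["mc"].values == mc
        return self.cells.index.values[sel]

    def class_edges(self, cls: str) -> pd.DataFrame:
        return self.connections[self.connections["cls"] == cls]

    def to_csv(self, directory) -> None:
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cells = self.cells.copy()
        cells["type"] = [CODE_TYPES[c].value for c in cells["type"]]
        cells.to_csv(d / "cells.csv", index_label="id")
        self.connections.to_csv(d / "connections.csv", index=False)


def _bernoulli_edges(rng, pre_ids, post_ids, p, forbid_self=True):
    """All ordered (pre, post) pairs retained with probability p."""
    mask = rng.random((len(pre_ids), len(post_ids))) < p
    if forbid_self:
        same = pre_ids[:, None] == post_ids[None, :]
        mask &= ~same
    ii, jj = np.nonzero(mask)
    return pre_ids[ii], post_ids[jj]


def build_network(spec: NetworkSpec) -> Network:
    """Realize cells, local wiring, long-range wiring, weights and delays.

    Fully deterministic given the spec (one seeded generator, fixed
    iteration order).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    n_mc = spec.minicolumns_per_hc

    # --- cells and coordinates -------------------------------------------
    ids, types, hcs, mcs = [], [], [], []
    for hc in range(spec.n_hc):
        for mc in range(n_mc):
            for t, cnt in ((CellType.PC, spec.pc_per_mc),
                           (CellType.MC, spec.mc_per_mc),
                           (CellType.VIP, spec.vip_per_mc)):
                types.extend([TYPE_CODES[t]] * cnt)
                hcs.extend([hc] * cnt)
                mcs.extend([mc] * cnt)
        types.extend([TYPE_CODES[CellType.BC]] * spec.bc_per_hc)
        hcs.extend([hc] * spec.bc_per_hc)
        mcs.extend([-1] * spec.bc_per_hc)
    n_cells = len(types)
    hc_arr = np.asarray(hcs)
    cx = (hc_arr % cols + 0.5) * spec.hc_diameter
    cy = (hc_arr // cols + 0.5) * spec.hc_diameter
    rr = 0.5 * spec.hc_diameter * np.sqrt(rng.random(n_cells))
    th = 2 * math.pi * rng.random(n_cells)
    x = cx + rr * np.cos(th)
    y = cy + rr * np.sin(th)
    z = rng.uniform(-spec.z_jitter, spec.z_jitter, n_cells)
    cells = pd.DataFrame(dict(type=np.asarray(types), hc=hc_arr,
                              mc=np.asarray(mcs), x=x, y=y, z=z))
    net = Network(spec=spec, cells=cells,
                  connections=pd.DataFrame(),
                  tau_facil_override=spec.tau_facil_override)

    pre_l, post_l, cls_l = [], [], []

    def add(cls, pre, post):
        pre_l.append(np.asarray(pre, np.int64))
        post_l.append(np.asarray(post, np.int64))
        cls_l.extend([cls] * len(pre))

    type_arr = cells["type"].values
    mc_arr = cells["mc"].values
    pc_mask = type_arr == TYPE_CODES[CellType.PC]

    mc_pool_hcwide = (spec.lr_target == "MC"
                      and spec.interneuron_orientation == "unspecific")

    # --- local wiring -----------------------------------------------------
    for hc in range(spec.n_hc):
        in_hc = hc_arr == hc
        pc_hc = np.nonzero(in_hc & pc_mask)[0]
        bc_hc = np.nonzero(in_hc & (type_arr == TYPE_CODES[CellType.BC]))[0]
        mc_hc = np.nonzero(in_hc & (type_arr == TYPE_CODES[CellType.MC]))[0]
        for mc in range(n_mc):
            in_mc = in_hc & (mc_arr == mc)
            pc_ids = np.nonzero(in_mc & pc_mask)[0]
            mc_ids = np.nonzero(in_mc & (type_arr == TYPE_CODES[CellType.MC]))[0]
            vip_ids = np.nonzero(in_mc & (type_arr == TYPE_CODES[CellType.VIP]))[0]
            add("PC-PC_LO", *_bernoulli_edges(rng, pc_ids, pc_ids, 0.25))
            if not mc_pool_hcwide:
                add("PC-MC_LO", *_bernoulli_edges(rng, pc_ids, mc_ids, 0.30))
                add("MC-PC", *_bernoulli_edges(rng, mc_ids, pc_ids, 0.80))
            add("VIP-MC", *_bernoulli_edges(rng, vip_ids, mc_ids, 0.60))
        if mc_pool_hcwide:
            # merged MC pool: minicolumn-blind excitation and inhibition
            add("PC-MC_LO", *_bernoulli_edges(rng, pc_hc, mc_hc, 0.30))
            add("MC-PC", *_bernoulli_edges(rng, mc_hc, pc_hc, 0.80))
        add("PC-BC", *_bernoulli_edges(rng, pc_hc, bc_hc, 0.70))
        add("BC-PC", *_bernoulli_edges(rng, bc_hc, pc_hc, 0.70))

    # --- long-range wiring ------------------------------------------------
    lr = long_range_wiring(net, spec, None, mc_arr, hc_arr, type_arr)
    for cls, pre, post in lr:
        add(cls, pre, post)

    conn = pd.DataFrame(dict(
        pre=np.concatenate(pre_l) if pre_l else np.empty(0, np.int64),
        post=np.concatenate(post_l) if post_l else np.empty(0, np.int64),
        cls=pd.Categorical(cls_l)))
    net.connections = conn

    # Type 6: minicolumn-specific relays with depressing BC-type input
    # dynamics (see module docstring).
    if (spec.lr_target == "BC"
            and spec.interneuron_orientation == "specific"):
        net.stp_overrides = {"PC-MC_LO": "PC-BC", "PC-MC_LR": "PC-BC"}
    elif spec.lr_target == "BC" and spec.lr_dynamics == "facilitating":
        net.stp_overrides = {"PC-BC_LR": "PC-MC_LO"}

    compensate_weights(net, spec)
    assign_delays(net, spec, None)  # dedicated stream: delays of shared
    return net                      # edges match across variants


def long_range_wiring(net, spec, rng, mc_arr, hc_arr, type_arr):
    """One terminal field per PC: 4 PC plus 1 interneuron terminal in a
    uniformly chosen same-pattern minicolumn of another hypercolumn.

    The PC targets and the interneuron terminal are drawn from separate
    seeded streams so that variants differing only in the terminal routing
    share an identical PC-PC_LR edge list.
    """
    out = {"PC-PC_LR": ([], []), "PC-MC_LR": ([], []), "PC-BC_LR": ([], [])}
    if spec.n_hc < 2:
        return [(k, np.array(v[0], np.int64), np.array(v[1], np.int64))
                for k, (v) in out.items()]
    pc_code = TYPE_CODES[CellType.PC]
    mc_code = TYPE_CODES[CellType.MC]
    bc_code = TYPE_CODES[CellType.BC]
    # index cells by (hc, mc)
    pc_by = {}
    mc_by = {}
    bc_by = {}
    for hc in range(spec.n_hc):
        sel_hc = hc_arr == hc
        bc_by[hc] = np.nonzero(sel_hc & (type_arr == bc_code))[0]
        for mc in range(spec.minicolumns_per_hc):
            sel = sel_hc & (mc_arr == mc)
            pc_by[(hc, mc)] = np.nonzero(sel & (type_arr == pc_code))[0]
            mc_by[(hc, mc)] = np.nonzero(sel & (type_arr == mc_code))[0]
    rng_pc = np.random.default_rng(spec.seed + 101)
    rng_term = np.random.default_rng(spec.seed + 102)
    pc_all = np.nonzero(type_arr == pc_code)[0]
    for gid in pc_all:
        hc, mc = int(hc_arr[gid]), int(mc_arr[gid])
        others = [h for h in range(spec.n_hc) if h != hc]
        tgt_hc = int(rng_pc.choice(others))
        tgt = (tgt_hc, mc)
        pcs = pc_by[tgt]
        if len(pcs) < 4:
            raise BuildError("fewer than 4 PC in target minicolumn")
        chosen = rng_pc.choice(pcs, size=4, replace=False)
        out["PC-PC_LR"][0].extend([gid] * 4)
        out["PC-PC_LR"][1].extend(chosen.tolist())
        if spec.lr_target == "MC" or (spec.lr_target == "BC"
                                      and spec.interneuron_orientation
                                      == "specific"):
            tgt_mc_cells = mc_by[tgt]
            term = int(rng_term.choice(tgt_mc_cells))
            out["PC-MC_LR"][0].append(gid)
            out["PC-MC_LR"][1].append(term)
        elif spec.lr_target == "BC":
            term = int(rng_term.choice(bc_by[tgt_hc]))
            out["PC-BC_LR"][0].append(gid)
            out["PC-BC_LR"][1].append(term)
    return [(k, np.array(v[0], np.int64), np.array(v[1], np.int64))
            for k, v in out.items()]


def _expected_in_degrees(spec: NetworkSpec) -> dict[str, float]:
    """Expected per-cell in-degrees of the Type 1 reference wiring."""
    has_lr = spec.n_hc > 1
    lr_per_relay_mc = (spec.pc_per_mc / spec.mc_per_mc) if has_lr else 0.0
    return {
        "PC-MC_LO": 0.30 * spec.pc_per_mc,
        "PC-MC_LR": lr_per_relay_mc,
        "MC-PC": 0.80 * spec.mc_per_mc,
        "PC-BC": 0.70 * spec.pc_per_mc * spec.minicolumns_per_hc,
        "PC-BC_LR": 0.0,
        "BC-PC": 0.70 * spec.bc_per_hc,
    }


def compensate_weights(net: Network, spec: NetworkSpec) -> Network:
    """Rescale per-connection weights so total inhibition is conserved.

    Two conservation rules relative to the Type 1 reference:
    * inhibitory output classes (MC-PC, BC-PC): per-PC in-degree x weight
      constant;
    * excitation onto an interneuron pool (PC-MC_LO + PC-MC_LR, and
      PC-BC + PC-BC_LR): summed in-degree x weight constant, applied as one
      factor to all classes of the group.
    """
    ref = _expected_in_degrees(spec)
    has_lr = spec.n_hc > 1
    n_mc = spec.minicolumns_per_hc
    scale: dict[str, float] = {}

    pool_wide = (spec.lr_target == "MC"
                 and spec.interneuron_orientation == "unspecific")
    # --- excitation onto MC relays
    mc_group_ref = ref["PC-MC_LO"] + ref["PC-MC_LR"]
    lo_new = ref["PC-MC_LO"] * (n_mc if pool_wide else 1.0)
    relay_is_mc = (spec.lr_target == "MC"
                   or (spec.lr_target == "BC"
                       and spec.interneuron_orientation == "specific"))
    if relay_is_mc:
        # terminals per hypercolumn are invariant; pooled MC split them
        lr_new = ref["PC-MC_LR"]
    else:
        lr_new = 0.0
    mc_group_new = lo_new + lr_new
    if mc_group_new <= 0:
        raise BuildError("weight compensation undefined: no excitatory "
                         "projections onto the MC pool")
    scale["PC-MC_LO"] = mc_group_ref / mc_group_new
    scale["PC-MC_LR"] = mc_group_ref / mc_group_new
    # --- MC inhibitory output
    mcpc_new = ref["MC-PC"] * (n_mc if pool_wide else 1.0)
    scale["MC-PC"] = ref["MC-PC"] / mcpc_new
    # --- BC side
    if spec.lr_target == "BC" and spec.interneuron_orientation == "unspecific":
        lr_per_bc = (spec.pc_per_mc * n_mc / spec.bc_per_hc) if has_lr else 0.0
        bc_group_ref = ref["PC-BC"]
        bc_group_new = ref["PC-BC"] + lr_per_bc
        scale["PC-BC"] = bc_group_ref / bc_group_new
        scale["PC-BC_LR"] = bc_group_ref / bc_group_new
    else:
        scale["PC-BC"] = 1.0
        scale["PC-BC_LR"] = 1.0
    scale["BC-PC"] = 1.0

    conn = net.connections
    ws = np.ones(len(conn))
    cls_vals = conn["cls"].astype(str).values
    for cls, f in scale.items():
        ws[cls_vals == cls] = f
    conn["weight_scale"] = ws
    return net


def assign_delays(net: Network, spec: NetworkSpec, rng=None) -> Network:
    """Distance / speed delays; speed is Gaussian truncated at 5% of mean."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    conn = net.connections
    if len(conn) == 0:
        conn["delay_ms"] = np.empty(0)
        return net
    xyz = net.cells[["x", "y", "z"]].values
    d = np.linalg.norm(xyz[conn["pre"].values] - xyz[conn["post"].values],
                       axis=1)  # um
    v = rng.normal(spec.conduction_speed_mean, spec.conduction_speed_sd,
                   len(conn))
    lo = 0.05 * spec.conduction_speed_mean
    bad = v <= lo
    while bad.any():
        v[bad] = rng.normal(spec.conduction_speed_mean,
                            spec.conduction_speed_sd, int(bad.sum()))
        bad = v <= lo
    delay = d / (v * 1000.0)  # um / (um/ms)
    conn["delay_ms"] = np.maximum(delay, 1e-3)
    return net


def reduced_spec(grid=(3, 3), variant: Variant = Variant.TYPE1,
                 seed: int = 0, **kw) -> NetworkSpec:
    """Desk-scale preset: a smaller hypercolumn grid, same microcircuit."""
    return NetworkSpec(grid=grid, variant=variant, seed=seed, **kw)


def spec_to_file(spec: NetworkSpec, path) -> None:
    """Serialize a network spec as YAML."""
    import dataclasses

    import yaml
    d = dataclasses.asdict(spec)
    d["grid"] = list(spec.grid)
    d["variant"] = spec.variant.value
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def spec_from_file(path) -> NetworkSpec:
    """Load a network spec from a YAML (or JSON) file."""
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "grid" in d:
        d["grid"] = tuple(d["grid"])
    if "variant" in d:
        d["variant"] = Variant(d["variant"])
    return NetworkSpec(**d)
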