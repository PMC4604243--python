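"""Pre-registered experiment runners.

Each runner builds the networks it needs, applies the stimulus protocol,
runs seeded trials and reduces the spikes to the summary statistics of the
corresponding experiment:

* ``run_surround_suppression`` — small vs large stimulus of one pattern,
  with and without the long-range PC->MC pathway;
* ``run_contextual_contrast`` — full-field stimulation with the recorded
  minicolumn either part of a homogeneous background or of a contrasting
  center;
* ``run_center_surround`` — center/surround pattern layout, delta statistic
  across wiring variants Type 1..6 and facilitation time constants;
* ``run_disinhibition`` — size series with and without VIP drive.

Every report embeds the fully resolved configuration and all seeds used, so
a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import (DEFAULT_BIN_MS, DeltaTrace, RateTrace, binned_rate,
                       delta, size_tuning, spearman_increasing)
from .drive import (G_DEFAULT_LEVEL, G_VIP_DRIVE, NoiseSpec, StimulusField)
from .engine import SimConfig, run
from .network import Network, NetworkSpec, Variant, build_network
from .neurons import CellType

# default reduced-scale timing (ms)
PRE_MS = 200.0
STIM_MS = 1000.0
POST_MS = 100.0


@dataclass(frozen=True)
class ExperimentSpec:
    """Resolved settings shared by the experiment runners."""

    grid: tuple[int, int] = (3, 3)
    n_trials: int = 3
    level: str = G_DEFAULT_LEVEL
    dt: float = 0.05
    seed: int = 0
    pre_ms: float = PRE_MS
    stim_ms: float = STIM_MS
    post_ms: float = POST_MS
    bin_ms: float = DEFAULT_BIN_MS

    @property
    def t_total(self) -> float:
        return self.pre_ms + self.stim_ms + self.post_ms

    @property
    def window(self) -> tuple[float, float]:
        return self.pre_ms, self.pre_ms + self.stim_ms


def _trial_seed(base: int, condition: int, trial: int) -> int:
    return (base * 7919 + condition * 1009 + trial * 13 + 1) % (2 ** 31 - 1)


def _run_trials(net: Network, ex: ExperimentSpec, stim: StimulusField,
                condition: int, noise: NoiseSpec | None = None):
    out = []
    for trial in range(ex.n_trials):
        cfg = SimConfig(dt=ex.dt, t_total=ex.t_total,
                        seed=_trial_seed(ex.seed, condition, trial))
        out.append(run(net, cfg, noise=noise, stimulus=stim).spikes)
    return out


def _pc_rate(records, net: Network, hc: int, mc: int,
             ex: ExperimentSpec) -> RateTrace:
    ids = net.cell_ids(CellType.PC, hc=hc, mc=mc)
    return binned_rate(records, ids, ex.bin_ms, label=f"PC hc{hc} mc{mc}")


def _hc_centers(grid):
    rows, cols = grid
    return [(r, c) for r in range(rows) for c in range(cols)]


def _corner_hcs(grid) -> list[int]:
    """Three mutually distant hypercolumns (corners of the patch)."""
    rows, cols = grid
    return [0, cols - 1, (rows - 1) * cols]


def _resolved(ex: ExperimentSpec, **extra) -> dict:
    d = dataclasses.asdict(ex)
    d.update(extra)
    return d


def run_surround_suppression(ex: ExperimentSpec = ExperimentSpec(),
                             pattern: int = 0) -> dict:
    """Small vs large stimulus of one pattern, with/without PC-MC_LR.

    The small stimulus drives the pattern minicolumn in three mutually
    distant hypercolumns; the large one drives it in every hypercolumn.  The
    recorded minicolumn is drawn (seeded) from the small driven set, so it is
    driven under both stimuli.  Reports PC/BC/MC rate traces and the
    suppression indicator sign(rate_large - rate_small) per population.
    """
    small_hcs = _corner_hcs(ex.grid)
    n_hc = ex.grid[0] * ex.grid[1]
    rng = np.random.default_rng(ex.seed + 17)
    rec_hc = int(rng.choice(small_hcs))
    stim_small = StimulusField(tuple((h, pattern) for h in small_hcs),
                               level=ex.level, onset=ex.pre_ms,
                               duration=ex.stim_ms)
    stim_large = StimulusField(tuple((h, pattern) for h in range(n_hc)),
                               level=ex.level, onset=ex.pre_ms,
                               duration=ex.stim_ms)
    report = {"config": _resolved(ex, pattern=pattern, recorded_hc=rec_hc,
                                  small_hcs=small_hcs),
              "wirings": {}}
    w0, w1 = ex.window
    for cond, (label, variant) in enumerate(
            [("with_lr_mc", Variant.TYPE1), ("without_lr_mc", Variant.TYPE5)]):
        net = build_network(NetworkSpec(grid=ex.grid, variant=variant,
                                        seed=ex.seed))
        entry = {"variant": variant.value, "stimuli": {}}
        for k, (sname, stim) in enumerate(
                [("small", stim_small), ("large", stim_large)]):
            recs = _run_trials(net, ex, stim, condition=10 * cond + k)
            pops = {
                "PC": net.cell_ids(CellType.PC, hc=rec_hc, mc=pattern),
                "BC": net.cell_ids(CellType.BC, hc=rec_hc),
                "MC": net.cell_ids(CellType.MC, hc=rec_hc, mc=pattern),
            }
            traces = {pname: binned_rate(recs, ids, ex.bin_ms, label=pname)
                      for pname, ids in pops.items()}
            entry["stimuli"][sname] = {
                "traces": traces,
                "window_rate": {pname: tr.window_mean(w0, w1)
                                for pname, tr in traces.items()},
            }
        entry["suppression"] = {
            pname: entry["stimuli"]["large"]["window_rate"][pname]
            - entry["stimuli"]["small"]["window_rate"][pname]
            for pname in ("PC", "BC", "MC")}
        report["wirings"][label] = entry
    return report


def run_contextual_contrast(ex: ExperimentSpec = ExperimentSpec(),
                            center_pattern: int = 0,
                            background_pattern: int = 1) -> dict:
    """Full-field stimulation; the recorded hypercolumn is driven either as
    part of a homogeneous background or as a contrasting center.

    Saliency indicator: rate(contrast) - rate(homogeneous) of the recorded
    minicolumn's PC; it flips sign when the long-range PC->MC pathway is
    present.
    """
    rows, cols = ex.grid
    n_hc = rows * cols
    rec_hc = (rows // 2) * cols + cols // 2
    homog = tuple((h, background_pattern) for h in range(n_hc))
    contrast = tuple((h, center_pattern) if h == rec_hc
                     else (h, background_pattern) for h in range(n_hc))
    report = {"config": _resolved(ex, recorded_hc=rec_hc,
                                  center_pattern=center_pattern,
                                  background_pattern=background_pattern),
              "wirings": {}}
    w0, w1 = ex.window
    for cond, (label, variant) in enumerate(
            [("with_lr_mc", Variant.TYPE1), ("without_lr_mc", Variant.TYPE5)]):
        net = build_network(NetworkSpec(grid=ex.grid, variant=variant,
                                        seed=ex.seed))
        entry = {"variant": variant.value, "layouts": {}}
        for k, (lname, driven, rec_mc) in enumerate(
                [("homogeneous", homog, background_pattern),
                 ("contrast", contrast, center_pattern)]):
            stim = StimulusField(driven, level=ex.level, onset=ex.pre_ms,
                                 duration=ex.stim_ms)
            recs = _run_trials(net, ex, stim, condition=20 + 10 * cond + k)
            tr = _pc_rate(recs, net, rec_hc, rec_mc, ex)
            entry["layouts"][lname] = {"trace": tr,
                                       "window_rate": tr.window_mean(w0, w1)}
        entry["saliency"] = (entry["layouts"]["contrast"]["window_rate"]
                             - entry["layouts"]["homogeneous"]["window_rate"])
        report["wirings"][label] = entry
    return report


def _center_surround_layout(grid, center_pattern=0, surround_pattern=1):
    """2x2 center block of hypercolumns vs the remaining surround."""
    rows, cols = grid
    if rows < 2 or cols < 2 or rows * cols < 5:
        raise ValueError("center-surround layout needs at least a 2x2 "
                         "center plus surround")
    center = [r * cols + c for r in range(2) for c in range(2)]
    surround = [h for h in range(rows * cols) if h not in center]
    # site 1: center hypercolumn; site 2: surround hypercolumn farthest
    # from the center block centroid
    crs = np.array([(h // cols, h % cols) for h in center], float)
    centroid = crs.mean(axis=0)
    far = max(surround, key=lambda h: (h // cols - centroid[0]) ** 2
              + (h % cols - centroid[1]) ** 2)
    driven = tuple((h, center_pattern) if h in center
                   else (h, surround_pattern) for h in range(rows * cols))
    site1 = (center[0], center_pattern)
    site2 = (far, surround_pattern)
    return driven, site1, site2


def run_center_surround(ex: ExperimentSpec = ExperimentSpec(),
                        variants: Sequence[Variant] = tuple(Variant),
                        levels: Sequence[str] | None = None,
                        tau_facil_values: Sequence[float] = (),
                        ) -> dict:
    """delta(t) = PC rate at the center site minus the surround site.

    Runs the center-surround stimulus against the requested wiring variants
    (and optionally against Type 1 networks with modified PC->MC
    facilitation time constants) and summarizes sign and positive duration
    of delta during the stimulus.
    """
    if levels is None:
        levels = (ex.level,)
    driven, site1, site2 = _center_surround_layout(ex.grid)
    report = {"config": _resolved(ex, site1=site1, site2=site2,
                                  levels=list(levels),
                                  variants=[v.value for v in variants],
                                  tau_facil_values=list(tau_facil_values)),
              "variants": {}, "tau_facil": {}}
    w0, w1 = ex.window

    def one(net, condition, level):
        stim = StimulusField(driven, level=level, onset=ex.pre_ms,
                             duration=ex.stim_ms)
        recs = _run_trials(net, ex, stim, condition=condition)
        r1 = _pc_rate(recs, net, site1[0], site1[1], ex)
        r2 = _pc_rate(recs, net, site2[0], site2[1], ex)
        dl = delta(r1, r2)
        half = (w0 + w1) / 2
        return {
            "delta": dl,
            "window_mean": dl.window_mean(w0, w1),
            "early_mean": dl.window_mean(w0, half),
            "late_mean": dl.window_mean(half, w1),
            "positive_duration_ms": dl.positive_duration(w0, w1),
        }

    cond = 100
    for variant in variants:
        net = build_network(NetworkSpec(grid=ex.grid, variant=variant,
                                        seed=ex.seed))
        per_level = {}
        for level in levels:
            per_level[level] = one(net, cond, level)
            cond += 1
        report["variants"][variant.value] = per_level
    for tf in tau_facil_values:
        net = build_network(NetworkSpec(grid=ex.grid, variant=Variant.TYPE1,
                                        seed=ex.seed,
                                        tau_facil_override=float(tf)))
        per_level = {}
        for level in levels:
            per_level[level] = one(net, cond, level)
            cond += 1
        report["tau_facil"][float(tf)] = per_level
    return report


def _size_series(grid, pattern, rec_hc) -> list[int]:
    """Hypercolumns ordered by distance from the recorded one."""
    rows, cols = grid
    rr, rc = rec_hc // cols, rec_hc % cols
    return sorted(range(rows * cols),
                  key=lambda h: ((h // cols - rr) ** 2 + (h % cols - rc) ** 2,
                                 h))


def run_disinhibition(ex: ExperimentSpec = ExperimentSpec(),
                      sizes: Sequence[int] = (1, 3, 6, 9),
                      pattern: int = 0) -> dict:
    """Size tuning of the recorded minicolumn with and without VIP drive.

    The stimulus drives the pattern minicolumn in the ``size`` hypercolumns
    nearest the recorded one (a growing patch).  With VIP drive the VIP
    cells of the driven minicolumns are also driven, inhibiting MC and
    releasing PC from long-range disynaptic inhibition.
    """
    if len(sizes) < 2:
        raise ValueError("need at least 2 stimulus sizes")
    rows, cols = ex.grid
    n_hc = rows * cols
    if max(sizes) > n_hc:
        raise ValueError("stimulus size exceeds the number of hypercolumns")
    rec_hc = (rows // 2) * cols + cols // 2
    order = _size_series(ex.grid, pattern, rec_hc)
    report = {"config": _resolved(ex, sizes=list(sizes), pattern=pattern,
                                  recorded_hc=rec_hc, hc_order=order),
              "curves": {}}
    net = build_network(NetworkSpec(grid=ex.grid, variant=Variant.TYPE1,
                                    seed=ex.seed))
    w0, w1 = ex.window
    cond = 300
    for vip_on in (False, True):
        label = "vip_on" if vip_on else "control"
        responses = {}
        traces = {}
        for size in sizes:
            driven = tuple((h, pattern) for h in order[:size])
            stim = StimulusField(driven, level=ex.level, onset=ex.pre_ms,
                                 duration=ex.stim_ms,
                                 vip_drive=G_VIP_DRIVE if vip_on else None)
            recs = _run_trials(net, ex, stim, condition=cond)
            cond += 1
            tr = _pc_rate(recs, net, rec_hc, pattern, ex)
            traces[size] = tr
            responses[size] = tr.window_mean(w0, w1)
        report["curves"][label] = {"responses": responses, "traces": traces,
                                   "tuning": size_tuning(responses)}
    ctl = report["curves"]["control"]["responses"]
    von = report["curves"]["vip_on"]["responses"]
    diff = {s: von[s] - ctl[s] for s in sizes}
    report["difference"] = diff
    report["difference_spearman"] = spearman_increasing(
        list(sizes), [diff[s] for s in sizes])
    return report
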