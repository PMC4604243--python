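"""Population rate extraction and the summary statistics of the model.

Rates are trial-averaged per-cell firing rates in fixed bins (default
100 ms).  The center-saliency statistic ``delta`` is the binned PC rate at a
center-site minicolumn minus the rate at a surround-site minicolumn:
positive delta means the center is salient.  ``size_tuning`` summarizes the
mean response of a recorded minicolumn against stimulus size (number of
driven minicolumns), the readout used for surround suppression and its
VIP-mediated release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import SpikeRecord

DEFAULT_BIN_MS = 100.0


@dataclass
class RateTrace:
    bin_edges: np.ndarray       # ms, len nbins + 1
    rate: np.ndarray            # Hz per bin, trial-averaged
    population: str = ""
    n_cells: int = 0
    n_trials: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def window_mean(self, t0: float, t1: float) -> float:
        """Mean rate over bins fully inside [t0, t1]."""
        sel = (self.bin_edges[:-1] >= t0 - 1e-9) & \
              (self.bin_edges[1:] <= t1 + 1e-9)
        if not sel.any():
            raise ValueError("no bins fully inside the window")
        return float(self.rate[sel].mean())


@dataclass
class DeltaTrace:
    bin_edges: np.ndarray
    delta: np.ndarray           # Hz, rate(site 1) - rate(site 2)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def window_mean(self, t0: float, t1: float) -> float:
        sel = (self.bin_edges[:-1] >= t0 - 1e-9) & \
              (self.bin_edges[1:] <= t1 + 1e-9)
        if not sel.any():
            raise ValueError("no bins fully inside the window")
        return float(self.delta[sel].mean())

    def positive_duration(self, t0: float, t1: float,
                          eps: float = 0.0) -> float:
        """Total time (ms) of bins with delta > eps inside [t0, t1]."""
        widths = np.diff(self.bin_edges)
        sel = (self.bin_edges[:-1] >= t0 - 1e-9) & \
              (self.bin_edges[1:] <= t1 + 1e-9)
        return float(widths[sel][self.delta[sel] > eps].sum())


def binned_rate(records: SpikeRecord | Sequence[SpikeRecord],
                population: np.ndarray,
                bin_ms: float = DEFAULT_BIN_MS,
                label: str = "") -> RateTrace:
    """Trial-averaged population firing rate.

    rate(bin) = spike count / (n_cells * bin_width * n_trials).
    """
    if isinstance(records, SpikeRecord):
        records = [records]
    population = np.asarray(population)
    if len(population) == 0:
        raise ValueError("empty population")
    t_total = records[0].t_total
    edges = np.arange(0.0, t_total + bin_ms * 0.5, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for rec in records:
        if abs(rec.t_total - t_total) > 1e-9:
            raise ValueError("records have mismatched durations")
        sub = rec.of_population(population)
        counts += np.histogram(sub.times, edges)[0]
    rate = counts / (len(population) * (bin_ms * 1e-3) * len(records))
    return RateTrace(bin_edges=edges, rate=rate, population=label,
                     n_cells=len(population), n_trials=len(records))


def delta(rate1: RateTrace, rate2: RateTrace) -> DeltaTrace:
    """Center-minus-surround rate difference, bin-wise."""
    if rate1.bin_edges.shape != rate2.bin_edges.shape or \
            not np.allclose(rate1.bin_edges, rate2.bin_edges):
        raise ValueError("mismatched binning")
    return DeltaTrace(bin_edges=rate1.bin_edges.copy(),
                      delta=rate1.rate - rate2.rate)


def size_tuning(responses: Mapping[int, float],
                normalize: bool = False) -> pd.DataFrame:
    """Response-vs-size curve from per-size window-mean responses.

    ``responses`` maps n_driven_minicolumns -> mean PC rate of the recorded
    minicolumn over the stimulus window.  With ``normalize`` the curve is
    scaled to its peak.
    """
    if len(responses) < 2:
        raise ValueError("need at least 2 stimulus sizes")
    sizes = sorted(responses)
    resp = np.array([responses[s] for s in sizes], float)
    out = pd.DataFrame(dict(size=sizes, response=resp))
    if normalize:
        peak = resp.max()
        out["response"] = resp / peak if peak > 0 else resp
    return out


def spearman_increasing(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (scipy), for 'grows with size' checks."""
    from scipy.stats import spearmanr
    rho = spearmanr(x, y).statistic
    return float(rho)
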