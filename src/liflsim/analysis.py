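"""Post-hoc spike-train metrics: PSTH, firing rates, rate degradation.

The peristimulus time histogram (PSTH) bins population spikes (internal
neurons only) into fixed windows — 1 ms by default.  Two summary indices
characterize population synchrony: ``max_psth``, the highest bin count, and
``c_hi_psth``, the number of bins whose count strictly exceeds a threshold
(100 spikes by default).  ``frd`` quantifies the percentage loss of mean
firing rate between two logs of the same experiment (e.g. a grid-based rerun
at a coarser time step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["PsthResult", "RateSummary", "psth", "mean_firing_rate", "frd",
           "plot_raster", "plot_psth"]


@dataclass(frozen=True)
class PsthResult:
    bin_width: float
    counts: np.ndarray
    max_psth: int
    c_hi_psth: int
    c_th: int

    def __repr__(self) -> str:  # compact: counts can be long
        return (f"PsthResult(bin_width={self.bin_width}, n_bins={len(self.counts)}, "
                f"max_psth={self.max_psth}, c_hi_psth={self.c_hi_psth}, c_th={self.c_th})")


@dataclass(frozen=True)
class RateSummary:
    mean_rate_hz: float
    per_neuron: pd.DataFrame
    window_ms: Tuple[float, float]
    frd: Optional[float] = None


def _spike_times(firing) -> np.ndarray:
    """Internal spike times from an EventLog, firing DataFrame or array."""
    if hasattr(firing, "firing"):  # EventLog / SimulationResult
        firing = firing.firing
    if isinstance(firing, pd.DataFrame):
        if "external" in firing.columns:
            firing = firing[firing["external"] == 0]
        return firing["t"].to_numpy(dtype=np.float64)
    return np.asarray(firing, dtype=np.float64)


def psth(firing, t_stop: float, bin_width: float = 1.0, c_th: int = 100) -> PsthResult:
    """Population PSTH over ``[0, t_stop)`` with its synchrony indices."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = _spike_times(firing)
    t = t[(t >= 0) & (t < t_stop)]
    n_bins = int(np.ceil(t_stop / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(t, bins=edges)
    return PsthResult(
        bin_width=bin_width,
        counts=counts.astype(np.int64),
        max_psth=int(counts.max()) if n_bins else 0,
        c_hi_psth=int((counts > c_th).sum()),
        c_th=c_th,
    )


def mean_firing_rate(firing, n_neurons: int,
                     window_ms: Tuple[float, float] = (0.0, 1000.0)) -> RateSummary:
    """Mean per-neuron rate: internal spikes / (n_neurons * window seconds)."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if hasattr(firing, "firing"):
        firing = firing.firing
    seconds = (t1 - t0) / 1000.0
    if isinstance(firing, pd.DataFrame):
        df = firing[firing["external"] == 0] if "external" in firing.columns else firing
        df = df[(df["t"] >= t0) & (df["t"] < t1)]
        total = len(df)
        if {"node", "neuron"}.issubset(df.columns):
            per = (df.groupby(["node", "neuron"], observed=True).size() / seconds)
            per = per.rename("rate_hz").reset_index()
        else:
            per = pd.DataFrame(columns=["node", "neuron", "rate_hz"])
    else:
        t = np.asarray(firing, dtype=np.float64)
        total = int(((t >= t0) & (t < t1)).sum())
        per = pd.DataFrame(columns=["node", "neuron", "rate_hz"])
    return RateSummary(
        mean_rate_hz=total / n_neurons / seconds,
        per_neuron=per,
        window_ms=(t0, t1),
    )


def frd(log_fine, log_coarse) -> float:
    """Firing-rate decrease, percent: ``100 (r_fine - r_coarse) / r_fine``.

    Both logs must cover the same network and window, so spike counts stand
    in for rates.  Positive values mean the coarser run lost spikes.
    """
    c_fine = len(_spike_times(log_fine))
    c_coarse = len(_spike_times(log_coarse))
    if c_fine == 0:
        raise ValueError("reference log has no spikes; FRd undefined")
    return 100.0 * (c_fine - c_coarse) / c_fine


# ---------------------------------------------------------------------------
# small plotting helpers (matplotlib optional)


def plot_raster(firing, ax=None, **scatter_kw):
    """Spike raster (time vs global spike index order); returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if hasattr(firing, "firing"):
        firing = firing.firing
    df = firing[firing["external"] == 0] if "external" in firing.columns else firing
    ax.scatter(df["t"], df["neuron"], s=scatter_kw.pop("s", 1), **scatter_kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    return ax


def plot_psth(result: PsthResult, ax=None, **bar_kw):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = np.arange(len(result.counts)) * result.bin_width
    ax.bar(edges, result.counts, width=result.bin_width, align="edge", **bar_kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"spikes / {result.bin_width:g} ms")
    return ax
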