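"""Pair-based spike-timing-dependent plasticity (STDP).

Additive all-pairs exponential rule with hard clamping.  For a plastic
synapse, every (pre-arrival, post-fire) pair with timing difference
``dt = t_post - t_pre_arrival`` inside the timeout window ``|dt| <= TO``
updates the post-synaptic weight:

    dt > 0 (pre before post, LTP):  w <- min(W_max, w + eta_plus  * exp(-dt/tau_plus))
    dt < 0 (post before pre, LTD):  w <- max(0,     w - eta_minus * exp( dt/tau_minus))

Pre-synaptic timing is measured at pulse *arrival* (i.e. after the conduction
delay), which keeps the rule causal for delayed inter-node synapses.  STDP is
parameterized per node and acts on the synapses terminating in that node;
synapses with inhibitory senders are excluded unless ``include_inhibitory``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Deque, Dict, List

__all__ = ["StdpParams", "on_pre_post_pair", "PairTracker"]


@dataclass(frozen=True)
class StdpParams:
    """Per-node plasticity constants (all strictly positive, ``TO`` finite)."""

    tau_plus: float = 20.0   # LTP time constant, ms
    tau_minus: float = 20.0  # LTD time constant, ms
    eta_plus: float = 0.01   # LTP learning constant (weight units)
    eta_minus: float = 0.01  # LTD learning constant
    TO: float = 100.0        # timeout: largest |dt| considered, ms
    enabled: bool = True
    include_inhibitory: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_plus", "tau_minus", "eta_plus", "eta_minus", "TO"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"STDP parameter {name} must be positive and finite, got {v}")


def on_pre_post_pair(w: float, dt_pair: float, params: StdpParams,
                     W_max: float = math.inf) -> float:
    """Apply one pair update to a weight; returns the clamped new weight.

    ``dt_pair = t_post_spike - t_pre_arrival``.  Outside the timeout window,
    or at exact coincidence (``dt_pair = 0``), the weight is unchanged.
    """
    if abs(dt_pair) > params.TO or dt_pair == 0.0:
        return w
    if dt_pair > 0.0:
        return min(W_max, w + params.eta_plus * math.exp(-dt_pair / params.tau_plus))
    return max(0.0, w - params.eta_minus * math.exp(dt_pair / params.tau_minus))


class PairTracker:
    """Online all-pairs bookkeeping for the event engine.

    Keeps, per plastic synapse, the recent pre-arrival times, and per neuron
    the recent post-fire times, both pruned beyond the timeout window.  The
    engine reports every plastic pulse arrival and every firing; the tracker
    answers with the weight increments to apply.
    """

    def __init__(self) -> None:
        self._pre_hist: Dict[int, Deque[float]] = {}      # synapse -> arrival times
        self._post_hist: Dict[int, Deque[float]] = {}     # neuron -> fire times
        self._incoming: Dict[int, List[int]] = {}         # neuron -> plastic synapse ids

    def register_synapse(self, syn_id: int, post_neuron: int) -> None:
        self._incoming.setdefault(post_neuron, []).append(syn_id)
        self._pre_hist.setdefault(syn_id, deque())

    def on_pre_arrival(self, syn_id: int, post_neuron: int, t: float, w: float,
                       params: StdpParams, W_max: float) -> float:
        """Pulse arrived at a plastic synapse: pair it with past post fires (LTD)."""
        hist = self._pre_hist[syn_id]
        hist.append(t)
        self._prune(hist, t, params.TO)
        new_w = w
        post = self._post_hist.get(post_neuron)
        if post:
            self._prune(post, t, params.TO)
            for t_post in post:
                new_w = on_pre_post_pair(new_w, t_post - t, params, W_max)
        return new_w

    def on_post_fire(self, post_neuron: int, t: float, weights, params: StdpParams,
                     W_max: float) -> None:
        """Neuron fired: pair with past pre arrivals on its plastic synapses (LTP).

        ``weights`` is the mutable synapse weight array, updated in place.
        """
        hist = self._post_hist.setdefault(post_neuron, deque())
        hist.append(t)
        self._prune(hist, t, params.TO)
        for syn_id in self._incoming.get(post_neuron, ()):
            pres = self._pre_hist[syn_id]
            self._prune(pres, t, params.TO)
            w = weights[syn_id]
            for t_pre in pres:
                w = on_pre_post_pair(w, t - t_pre, params, W_max)
            weights[syn_id] = w

    @staticmethod
    def _prune(hist: Deque[float], t_now: float, TO: float) -> None:
        while hist and t_now - hist[0] > TO:
            hist.popleft()
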