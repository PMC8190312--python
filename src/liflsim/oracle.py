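"""Clock-driven reference integrator used as a validation oracle in tests.

Integrates the same LIFL rules on a fixed grid of step ``dt``: passive decay
is applied every step, pulses are applied at the first grid instant at or
after their exact arrival time, active neurons count down their residual
latency.  Emission times are reconstructed at sub-grid precision from the
residual-latency overshoot (the *precise spiking* device used by
grid-driven reference neuron models), so the dominant error is the O(dt)
pulse-arrival rounding.  Intended for small motifs only (the cost is
O(n * t_stop / dt)).
"""

from __future__ import annotations

import heapq
import math
from typing import Optional, Sequence, Tuple

import numpy as np

from .network import Network
from .stimuli import StimulusBatch

__all__ = ["clock_driven_oracle"]


def clock_driven_oracle(
    network: Network,
    stimuli: Sequence[StimulusBatch],
    dt: float,
    t_stop: float,
    init_S: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Grid-based realization; returns (spike_times, spike_neurons).

    Restrictions: tonic neurons only (``N_b = 1``) and strictly positive
    synaptic delays (a zero-delay pulse cannot act within the emission's own
    grid step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if (network.N_b > 1).any():
        raise ValueError("oracle supports tonic neurons only")
    syn = network.synapses
    if len(syn) and (syn.delay <= 0).any():
        raise ValueError("oracle requires strictly positive synaptic delays")

    n = network.n_neurons
    a, b, c = network.a, network.b, network.c
    D_exc, D_inh = network.D_exc, network.D_inh
    t_arp = network.t_arp
    exp_dec = network.exp_decay
    latency = network.latency
    amp_syn = network.A[syn.pre] * syn.weight

    S = np.zeros(n) if init_S is None else np.asarray(init_S, dtype=float).copy()
    # modes: 0 passive, 1 active, 2 refractory
    mode = np.zeros(n, dtype=np.int8)
    tf_rem = np.zeros(n)
    refr_until = np.zeros(n)

    # pending deliveries: (exact_time, order, target, amplitude)
    pending: list = []
    order = 0
    for batch in stimuli:
        for t, j, w in zip(batch.delivery_time, batch.delivery_target, batch.delivery_amp):
            heapq.heappush(pending, (float(t), order, int(j), float(w)))
            order += 1

    def s_th(j):
        return 1.0 + c[j]

    def s_max(j):
        return 1.0 + a[j] / b[j] if b[j] > 0 else math.inf

    def activate(j):
        mode[j] = 1
        tf_rem[j] = (a[j] / (S[j] - 1.0) - b[j]) if latency[j] else 0.0

    for j in range(n):
        if S[j] >= s_th(j):
            activate(j)

    spikes_t, spikes_n = [], []
    n_steps = int(round(t_stop / dt))
    for step in range(n_steps + 1):
        t = step * dt
        if t >= t_stop:
            break
        if step > 0:
            # passive decay over the elapsed step
            passive = mode == 0
            if passive.any():
                Se = S[passive]
                De = D_exc[passive]
                dec = np.where(exp_dec[passive], Se * np.exp(-dt / De),
                               np.maximum(0.0, Se - dt / De))
                S[passive] = dec
            # active latency countdown
            tf_rem[mode == 1] -= dt

        def emit(j, t_spike):
            """Emission with sub-grid timing; fan out and enter refractoriness."""
            nonlocal order
            spikes_t.append(t_spike)
            spikes_n.append(j)
            for s_id in range(network.indptr[j], network.indptr[j + 1]):
                heapq.heappush(
                    pending,
                    (t_spike + float(syn.delay[s_id]), order,
                     int(syn.post[s_id]), float(amp_syn[s_id])))
                order += 1
            S[j] = 0.0
            mode[j] = 2
            refr_until[j] = t_spike + t_arp[j]

        # emissions whose latency elapsed inside this step (reconstruct the
        # exact sub-grid moment: tf_rem has overshot by its negative part)
        due = np.flatnonzero((mode == 1) & (tf_rem <= 1e-12))
        for j in due:
            emit(int(j), t + float(tf_rem[j]))

        # end refractoriness whose boundary fell at or before this instant
        done = (mode == 2) & (refr_until <= t)
        if done.any():
            mode[done] = 0
            S[done] = 0.0
        # apply pulses due by this instant
        while pending and pending[0][0] <= t:
            tau, _, j, w = heapq.heappop(pending)
            if mode[j] == 2:
                if tau < refr_until[j]:
                    continue  # discarded by refractoriness (exact boundary)
                mode[j] = 0
                S[j] = 0.0
            if mode[j] == 1:
                # convert residual latency back to state, add pulse
                S[j] = 1.0 + a[j] / (tf_rem[j] + b[j]) if latency[j] else S[j]
                S[j] += w
                if S[j] < s_th(j):
                    mode[j] = 0
                elif S[j] >= s_max(j) or not latency[j]:
                    emit(j, t)
                else:
                    tf_rem[j] = a[j] / (S[j] - 1.0) - b[j]
            else:
                S[j] = max(0.0, S[j] + w)
                if S[j] >= s_th(j):
                    activate(j)
                    if tf_rem[j] <= 0.0:
                        emit(j, t)

    return np.asarray(spikes_t), np.asarray(spikes_n, dtype=np.int64)
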