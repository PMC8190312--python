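"""Event-driven simulation core.

A single global priority queue orders three kinds of events in time:

* ``firing`` — a neuron's scheduled spike emission (committed burst emissions
  included);
* ``burning`` — delivery of a synaptic pulse batch to the out-synapses of an
  emission, after the per-synapse conduction delay;
* ``input`` — delivery of an external stimulus pulse.

Ties at identical timestamps are broken by kind (firing < burning < input: a
neuron whose latency elapses exactly when a pulse arrives fires first) and
then by insertion sequence, which makes runs bit-reproducible.  A neuron has
at most one *valid* pending firing event at any time; rescheduling and
post-trigger cancellation are implemented by lazy invalidation (a version
counter per neuron).  Time is a continuous float throughout — there is no
grid anywhere.

Two interchangeable backends execute the same semantics: this module's pure
Python loop (the reference; supports STDP and bursting) and a compiled kernel
(:mod:`liflsim._kernel`) used automatically for large plasticity-free
networks.  An equivalence test keeps them aligned.

When CSV sinks are attached and in-memory recording is switched off, records
are flushed to disk every ``S_b`` events, so the engine's memory stays
bounded by O(S_b + pending events + network size) independent of ``t_stop``.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .neuron import Mode, NeuronState, fire as neuron_fire, apply_pulse, time_to_fire
from .network import Network
from .stdp import PairTracker
from .stimuli import StimulusBatch, realize_stimuli

__all__ = ["GlobalConfig", "Event", "SimulationResult", "run", "SimulationError", "ConfigError"]

EVENT_FIRE, EVENT_BURN, EVENT_INPUT = 0, 1, 2


class SimulationError(RuntimeError):
    """Internal ordering fault or contract violation during a run."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GlobalConfig:
    """Global simulation parameters.

    ``t_stop`` (ms) is the simulated biological time; ``v`` the global
    conduction speed (mm/ms) turning tract lengths into delays; ``W_max`` the
    weight ceiling; ``S_b`` the serialization buffer (events per flush of the
    CSV sinks); ``N_m`` the neuron-model switch ('LIFL' keeps spike latency,
    'LIF' fires immediately at threshold); ``master_seed`` feeds every source
    of randomness.
    """

    t_stop: float
    v: float = 5.5
    W_max: float = math.inf
    S_b: int = 100_000
    N_m: str = "LIFL"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.t_stop <= 0:
            raise ConfigError("t_stop must be positive")
        if self.v <= 0 or self.W_max <= 0 or self.S_b < 1:
            raise ConfigError("v, W_max must be positive and S_b >= 1")
        if self.N_m not in ("LIFL", "LIF"):
            raise ConfigError(f"N_m must be 'LIFL' or 'LIF', got {self.N_m!r}")


@dataclass(frozen=True)
class Event:
    """One timestamped occurrence, as exposed in logs and debugging hooks."""

    time: float
    kind: str                       # 'firing' | 'burning' | 'input'
    pre: Optional[Tuple[str, int]] = None
    post: Optional[Tuple[str, int]] = None
    weight: float = 0.0
    sequence: int = 0


@dataclass
class SimulationResult:
    """Outcome of one run: event logs, counters and final synaptic weights.

    ``counts`` reports processed events by kind: internal spike emissions
    ('firing'), synaptic pulse arrivals from internal neurons ('burning'),
    external pulse arrivals ('input'), and arrivals discarded by
    refractoriness ('discarded', a subset of the former two).
    """

    firing: pd.DataFrame
    burning: Optional[pd.DataFrame]
    counts: Dict[str, int]
    final_weights: np.ndarray
    t_stop: float
    n_neurons: int
    weight_snapshots: Optional[pd.DataFrame] = None

    def internal_firing(self) -> pd.DataFrame:
        return self.firing[self.firing["external"] == 0]

    def mean_rate_hz(self) -> float:
        return len(self.internal_firing()) / self.n_neurons / (self.t_stop / 1000.0)


# ---------------------------------------------------------------------------
# helpers


def _delay_runs(net: Network):
    """Group each neuron's delay-sorted out-synapses into equal-delay runs."""
    syn = net.synapses
    n_syn = len(syn)
    if n_syn == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), np.zeros(0), z.copy(), np.zeros(net.n_neurons + 1, dtype=np.int64)
    new_run = np.ones(n_syn, dtype=bool)
    new_run[1:] = (np.diff(syn.pre) != 0) | (np.diff(syn.delay) != 0)
    run_start = np.flatnonzero(new_run).astype(np.int64)
    run_end = np.append(run_start[1:], n_syn).astype(np.int64)
    run_delay = syn.delay[run_start]
    run_neuron = syn.pre[run_start]
    rptr = np.searchsorted(run_neuron, np.arange(net.n_neurons + 1)).astype(np.int64)
    return run_start, run_end, run_delay, run_neuron, rptr


def _merge_inputs(batches: Sequence[StimulusBatch]):
    if not batches:
        z = np.zeros(0)
        return z, np.zeros(0, dtype=np.int64), z.copy(), np.zeros(0, dtype=np.int64)
    t = np.concatenate([b.delivery_time for b in batches])
    tgt = np.concatenate([b.delivery_target for b in batches])
    amp = np.concatenate([b.delivery_amp for b in batches])
    src = np.concatenate([b.delivery_source for b in batches])
    order = np.argsort(t, kind="stable")
    return t[order], tgt[order], amp[order], src[order]


def _check_zero_delay_loops(net: Network) -> None:
    """Zero-delay cycles among neurons without refractoriness would let a
    single instant cascade forever; reject them at validation time."""
    syn = net.synapses
    risky = net.t_arp == 0.0
    mask = (syn.delay == 0.0) & risky[syn.pre] & risky[syn.post]
    if not mask.any():
        return
    pre, post = syn.pre[mask], syn.post[mask]
    nodes, inv = np.unique(np.concatenate([pre, post]), return_inverse=True)
    m = len(nodes)
    pre_l, post_l = inv[: len(pre)], inv[len(pre):]
    indeg = np.bincount(post_l, minlength=m)
    order = np.argsort(pre_l, kind="stable")
    pre_s, post_s = pre_l[order], post_l[order]
    ptr = np.searchsorted(pre_s, np.arange(m + 1))
    stack = list(np.flatnonzero(indeg == 0))
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for j in range(ptr[u], ptr[u + 1]):
            v = post_s[j]
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    if seen < m:
        raise ConfigError(
            "zero-delay connection cycle among neurons with t_arp = 0; "
            "set a positive refractory period to bound same-instant cascades"
        )


def _init_states(net: Network, init_S: Optional[np.ndarray]) -> np.ndarray:
    if init_S is None:
        return np.zeros(net.n_neurons)
    init_S = np.asarray(init_S, dtype=np.float64)
    if init_S.shape != (net.n_neurons,):
        raise ConfigError(f"init_S must have shape ({net.n_neurons},)")
    if (init_S < 0).any():
        raise ConfigError("initial states must be non-negative")
    return init_S.copy()


def _format_firing(net: Network, t: np.ndarray, n: np.ndarray,
                   noi_idx: Optional[set]) -> pd.DataFrame:
    node_idx = net.node_of[n] if len(n) else np.zeros(0, dtype=np.int64)
    df = pd.DataFrame({
        "t": t,
        "node": [net.node_ids[i] for i in node_idx],
        "neuron": (n - net.offsets[node_idx]).astype(np.int64) if len(n) else n,
        "external": np.zeros(len(t), dtype=np.int8),
    })
    if noi_idx is not None:
        df = df[np.isin(node_idx, list(noi_idx))].reset_index(drop=True)
    return df


def _format_burning(net: Network, rows: List[Tuple[float, int, int, float, float]],
                    noi_idx: Optional[set]) -> pd.DataFrame:
    bt = np.asarray([r[0] for r in rows])
    bpost = np.asarray([r[1] for r in rows], dtype=np.int64)
    bpre = np.asarray([r[2] for r in rows], dtype=np.int64)
    btf = np.asarray([r[3] for r in rows])
    bwt = np.asarray([r[4] for r in rows])
    post_node = net.node_of[bpost] if len(bpost) else np.zeros(0, dtype=np.int64)
    node_fire: List[str] = []
    neuron_fire = np.empty(len(bpre), dtype=np.int64)
    for k in range(len(bpre)):
        if bpre[k] < 0:
            node_fire.append("ext")
            neuron_fire[k] = -1 - bpre[k]
        else:
            ni = net.node_of[bpre[k]]
            node_fire.append(net.node_ids[ni])
            neuron_fire[k] = bpre[k] - net.offsets[ni]
    df = pd.DataFrame({
        "t_burn": bt,
        "node_burn": [net.node_ids[i] for i in post_node],
        "neuron_burn": (bpost - net.offsets[post_node]).astype(np.int64)
                       if len(bpost) else bpost,
        "node_fire": node_fire,
        "neuron_fire": neuron_fire,
        "t_fire": btf,
        "weight": bwt,
    })
    if noi_idx is not None:
        df = df[np.isin(post_node, list(noi_idx))].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# public entry point


def run(
    network: Network,
    stimuli: Sequence = (),
    config: Optional[GlobalConfig] = None,
    *,
    t_stop: Optional[float] = None,
    init_S: Optional[np.ndarray] = None,
    noi: Optional[Sequence[str]] = None,
    firing_sink=None,
    burning_sink=None,
    record_burning: bool = False,
    record_firing: bool = True,
    weight_snapshot_interval: Optional[float] = None,
    backend: str = "auto",
) -> SimulationResult:
    """Simulate the network until ``t_stop``.

    ``stimuli`` may be realized :class:`StimulusBatch` objects or stimulus
    specs (realized here from ``config.master_seed``).  ``noi`` restricts the
    logs to the named nodes of interest (empty/None = all nodes).  Sinks, if
    given, receive the same records with a flush every ``S_b`` events; when
    the corresponding ``record_*`` flag is False, records are streamed to the
    sink and never accumulated in memory.  ``weight_snapshot_interval`` (ms;
    python backend) samples all plastic synaptic weights every interval,
    exposed as ``result.weight_snapshots`` (columns t, pre, post, weight).
    ``backend`` is ``'auto'``
    (compiled kernel when the network has no active plasticity or bursting
    and is large), ``'python'`` or ``'kernel'``.
    """
    if config is None:
        if t_stop is None:
            raise ConfigError("either config or t_stop is required")
        config = GlobalConfig(t_stop=t_stop)
    elif t_stop is not None:
        config = dc_replace(config, t_stop=t_stop)

    if stimuli and not isinstance(stimuli[0], StimulusBatch):
        stimuli = realize_stimuli(
            stimuli, network, np.random.SeedSequence([config.master_seed, 0x5717]))

    noi_idx: Optional[set] = None
    if noi:
        noi_idx = {network.node_index(x) for x in noi}

    _check_zero_delay_loops(network)

    has_stdp = bool(network.synapses.plastic.any()) and any(
        s.stdp_params is not None and s.stdp_params.enabled for s in network.node_specs
    )
    has_burst = bool((network.N_b > 1).any())
    lif_mode = config.N_m == "LIF"

    if backend == "auto":
        backend = "python" if (has_stdp or has_burst or network.n_neurons < 200) else "kernel"
    if backend == "kernel" and (has_stdp or has_burst):
        raise ConfigError("compiled kernel does not support STDP or bursting")

    # streaming (bounded-memory) mode is a python-backend feature; the kernel
    # returns complete arrays and the sink still flushes them in S_b chunks
    stream_fire = backend != "kernel" and firing_sink is not None and not record_firing
    stream_burn = backend != "kernel" and burning_sink is not None and not record_burning
    want_burn = record_burning or burning_sink is not None

    flush_fire = None
    flush_burn = None
    if stream_fire:
        def flush_fire(t_arr, n_arr):
            firing_sink.write_frame(_format_firing(network, t_arr, n_arr, noi_idx))
    if stream_burn:
        def flush_burn(rows):
            burning_sink.write_frame(_format_burning(network, rows, noi_idx))

    if backend == "kernel":
        if weight_snapshot_interval is not None:
            raise ConfigError("weight snapshots require the python backend")
        raw = _run_kernel_backend(network, stimuli, config, init_S, want_burn, lif_mode)
    else:
        raw = _run_python_backend(network, stimuli, config, init_S, want_burn, lif_mode,
                                  flush_fire, flush_burn, weight_snapshot_interval)

    return _assemble_result(network, stimuli, config, raw, noi_idx,
                            firing_sink, burning_sink,
                            record_firing, record_burning, stream_fire, stream_burn)


# ---------------------------------------------------------------------------
# pure-python backend (reference implementation)


def _run_python_backend(net: Network, batches, config: GlobalConfig,
                        init_S, want_burn: bool, lif_mode: bool,
                        flush_fire=None, flush_burn=None,
                        snapshot_interval=None):
    n = net.n_neurons
    syn = net.synapses
    weights = syn.weight.copy()
    plastic = syn.plastic
    A_pre = net.A
    post = syn.post
    pre = syn.pre
    run_start, run_end, run_delay, run_neuron, rptr = _delay_runs(net)
    in_time, in_target, in_amp, in_src = _merge_inputs(batches)
    n_in = len(in_time)
    t_stop = config.t_stop
    chunk = config.S_b

    params = [net.params_of(i) for i in range(n)]
    if lif_mode:
        params = [dc_replace(p, latency=False) for p in params]
    states = [NeuronState() for _ in range(n)]
    fire_ver = np.zeros(n, dtype=np.int64)

    stdp_of_node = [
        s.stdp_params if (s.stdp_params is not None and s.stdp_params.enabled) else None
        for s in net.node_specs
    ]
    tracker = PairTracker()
    if plastic.any():
        for s_id in np.flatnonzero(plastic):
            tracker.register_synapse(int(s_id), int(post[s_id]))

    heap: List[Tuple[float, int, int, int, int]] = []
    seq = 0
    counts = {"firing": 0, "burning": 0, "input": 0, "discarded": 0}
    fire_t: List[float] = []
    fire_n: List[int] = []
    burn_rows: List[Tuple[float, int, int, float, float]] = []

    S0 = _init_states(net, init_S)
    for i in range(n):
        if S0[i] <= 0.0:
            continue
        st = states[i]
        st.S = S0[i]
        if S0[i] >= params[i].S_th:
            st.mode = Mode.ACTIVE
            if S0[i] >= params[i].S_max or not params[i].latency:
                sched = 0.0
            else:
                sched = time_to_fire(S0[i], params[i])
            st.t_fire_scheduled = sched
            fire_ver[i] += 1
            heapq.heappush(heap, (sched, EVENT_FIRE, seq, i, int(fire_ver[i])))
            seq += 1

    def _emit(t: float, i: int) -> None:
        nonlocal seq
        counts["firing"] += 1
        fire_t.append(t)
        fire_n.append(i)
        if flush_fire is not None and len(fire_t) >= chunk:
            flush_fire(np.asarray(fire_t), np.asarray(fire_n, dtype=np.int64))
            fire_t.clear()
            fire_n.clear()
        sp = stdp_of_node[net.node_of[i]]
        if sp is not None:
            tracker.on_post_fire(i, t, weights, sp, config.W_max)
        for r in range(rptr[i], rptr[i + 1]):
            heapq.heappush(heap, (t + run_delay[r], EVENT_BURN, seq, int(r), 0))
            seq += 1

    def _do_fire(t: float, i: int) -> None:
        nonlocal seq
        res = neuron_fire(states[i], t, params[i])
        fire_ver[i] += 1
        _emit(t, i)
        for te in res.emission_times[1:]:
            heapq.heappush(heap, (te, EVENT_FIRE, seq, i, -1))
            seq += 1

    def _record_burn(row) -> None:
        burn_rows.append(row)
        if flush_burn is not None and len(burn_rows) >= chunk:
            flush_burn(burn_rows)
            burn_rows.clear()

    def _deliver(t: float, j: int, amp: float, syn_id: int = -1) -> None:
        nonlocal seq
        out = apply_pulse(states[j], t, amp, params[j])
        if out.absorbed:
            counts["discarded"] += 1
            return
        if syn_id >= 0 and plastic[syn_id]:
            sp = stdp_of_node[net.node_of[j]]
            if sp is not None:
                weights[syn_id] = tracker.on_pre_arrival(
                    int(syn_id), j, t, weights[syn_id], sp, config.W_max)
        if out.fire_now:
            _do_fire(t, j)
        elif out.schedule is not None:
            fire_ver[j] += 1
            heapq.heappush(heap, (out.schedule, EVENT_FIRE, seq, j, int(fire_ver[j])))
            seq += 1
        elif out.cancel:
            fire_ver[j] += 1

    snap_rows: List[Tuple[float, int, int, float]] = []
    plastic_ids = np.flatnonzero(plastic)
    next_snap = snapshot_interval if snapshot_interval else math.inf

    in_ptr = 0
    current = 0.0
    while True:
        take_heap = bool(heap) and (in_ptr >= n_in or heap[0][0] <= in_time[in_ptr])
        if take_heap:
            t, kind, _s, a_f, b_f = heapq.heappop(heap)
        elif in_ptr < n_in:
            t, kind, a_f, b_f = in_time[in_ptr], EVENT_INPUT, 0, 0
        else:
            break
        if t >= t_stop:
            break
        if t < current:
            raise SimulationError(
                f"event at t={t} popped after t={current}: ordering fault")
        current = t
        while t >= next_snap:
            for s_id in plastic_ids:
                snap_rows.append((next_snap, int(pre[s_id]), int(post[s_id]),
                                  float(weights[s_id])))
            next_snap += snapshot_interval

        if kind == EVENT_FIRE:
            if b_f == -1:  # committed burst emission
                _emit(t, a_f)
            elif states[a_f].mode is Mode.ACTIVE and b_f == fire_ver[a_f]:
                _do_fire(t, a_f)
        elif kind == EVENT_BURN:
            r = a_f
            i_pre = int(run_neuron[r])
            t_emit = t - run_delay[r]
            for s_id in range(run_start[r], run_end[r]):
                amp = A_pre[pre[s_id]] * weights[s_id]
                counts["burning"] += 1
                if want_burn:
                    _record_burn((t, int(post[s_id]), i_pre, t_emit, amp))
                _deliver(t, int(post[s_id]), amp, int(s_id))
        else:  # INPUT
            j = int(in_target[in_ptr])
            amp = float(in_amp[in_ptr])
            counts["input"] += 1
            if want_burn:
                _record_burn((t, j, -1 - int(in_src[in_ptr]), t, amp))
            in_ptr += 1
            _deliver(t, j, amp)

    if snapshot_interval:
        while next_snap <= t_stop:
            for s_id in plastic_ids:
                snap_rows.append((next_snap, int(pre[s_id]), int(post[s_id]),
                                  float(weights[s_id])))
            next_snap += snapshot_interval

    if flush_fire is not None and fire_t:
        flush_fire(np.asarray(fire_t), np.asarray(fire_n, dtype=np.int64))
        fire_t, fire_n = [], []
    if flush_burn is not None and burn_rows:
        flush_burn(burn_rows)
        burn_rows = []

    return {
        "fire_t": np.asarray(fire_t),
        "fire_n": np.asarray(fire_n, dtype=np.int64),
        "burn": burn_rows,
        "counts": counts,
        "weights": weights,
        "snapshots": snap_rows,
    }


# ---------------------------------------------------------------------------
# compiled backend


def _run_kernel_backend(net: Network, batches, config: GlobalConfig,
                        init_S, want_burn: bool, lif_mode: bool):
    from . import _kernel

    syn = net.synapses
    amp_syn = net.A[syn.pre] * syn.weight
    run_start, run_end, run_delay, run_neuron, rptr = _delay_runs(net)
    in_time, in_target, in_amp, in_src = _merge_inputs(batches)
    latency = net.latency & (not lif_mode)
    S0 = _init_states(net, init_S)

    out = _kernel.run_kernel(
        syn.post.astype(np.int64), amp_syn,
        run_start, run_end, run_delay, run_neuron, rptr,
        net.a, net.b, net.c, net.D_exc, net.D_inh, net.t_arp,
        net.exp_decay.astype(np.uint8), latency.astype(np.uint8),
        S0, float(config.t_stop),
        in_time, in_target.astype(np.int64), in_amp,
        np.uint8(1 if want_burn else 0),
    )
    (fire_t, fire_n, bt, bpost, bpre, btf, bw, kcounts) = out
    if kcounts[4] != 0:
        raise SimulationError("event popped out of time order: internal fault")
    burn_rows: List[Tuple[float, int, int, float, float]] = []
    if want_burn:
        k = 0
        for row in zip(bt.tolist(), bpost.tolist(), bpre.tolist(),
                       btf.tolist(), bw.tolist()):
            if row[2] == -1:  # input delivery: re-attribute its source id
                burn_rows.append((row[0], row[1], -1 - int(in_src[k]), row[3], row[4]))
                k += 1
            else:
                burn_rows.append(row)
    counts = {"firing": int(kcounts[0]), "burning": int(kcounts[1]),
              "input": int(kcounts[2]), "discarded": int(kcounts[3])}
    return {
        "fire_t": fire_t, "fire_n": fire_n, "burn": burn_rows,
        "counts": counts, "weights": syn.weight.copy(),
    }


# ---------------------------------------------------------------------------
# result assembly


def _assemble_result(net: Network, batches, config: GlobalConfig, raw,
                     noi_idx, firing_sink, burning_sink,
                     record_firing: bool, record_burning: bool,
                     stream_fire: bool, stream_burn: bool) -> SimulationResult:
    t_stop = config.t_stop
    fire_t, fire_n = raw["fire_t"], raw["fire_n"]
    node_idx = net.node_of[fire_n] if len(fire_n) else np.zeros(0, dtype=np.int64)
    local = fire_n - net.offsets[node_idx] if len(fire_n) else fire_n

    ext_t_l, ext_node_l, ext_src_l = [], [], []
    for b in batches:
        m = b.emission_time < t_stop
        ext_t_l.append(b.emission_time[m])
        ext_node_l.append(np.full(int(m.sum()), net.node_index(b.target_node), dtype=np.int64))
        ext_src_l.append(b.emission_source[m])
    ext_t = np.concatenate(ext_t_l) if ext_t_l else np.zeros(0)
    ext_node = np.concatenate(ext_node_l) if ext_node_l else np.zeros(0, dtype=np.int64)
    ext_src = np.concatenate(ext_src_l) if ext_src_l else np.zeros(0, dtype=np.int64)

    all_t = np.concatenate([fire_t, ext_t])
    all_node = np.concatenate([node_idx, ext_node])
    all_neuron = np.concatenate([local, ext_src])
    all_ext = np.concatenate([
        np.zeros(len(fire_t), dtype=np.int8), np.ones(len(ext_t), dtype=np.int8)])
    order = np.lexsort((np.arange(len(all_t)), all_ext, all_t))
    firing = pd.DataFrame({
        "t": all_t[order],
        "node": [net.node_ids[i] for i in all_node[order]],
        "neuron": all_neuron[order].astype(np.int64),
        "external": all_ext[order],
    })
    if noi_idx is not None:
        firing = firing[np.isin(all_node[order], list(noi_idx))].reset_index(drop=True)

    burning = _format_burning(net, raw["burn"], noi_idx) if record_burning else None

    if firing_sink is not None:
        if stream_fire:
            # internal records were streamed during the run; append externals
            ext_only = firing[firing["external"] == 1]
            if len(ext_only):
                firing_sink.write_frame(ext_only)
        else:
            firing_sink.write_frame(firing)
        firing_sink.flush()
    if burning_sink is not None:
        if not stream_burn and burning is not None:
            burning_sink.write_frame(burning)
        burning_sink.flush()

    snapshots = None
    if raw.get("snapshots"):
        snapshots = pd.DataFrame(raw["snapshots"],
                                 columns=["t", "pre", "post", "weight"])

    return SimulationResult(
        firing=firing if record_firing else firing.iloc[0:0],
        burning=burning,
        counts=raw["counts"],
        final_weights=raw["weights"],
        t_stop=t_stop,
        n_neurons=net.n_neurons,
        weight_snapshots=snapshots,
    )
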