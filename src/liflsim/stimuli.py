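"""Input stimuli: Poisson spike trains, constant (DC-like) trains, spike streams.

Stimuli are delivered by fictive *external neurons*: excitatory-only sources,
each permanently wired to one or more neurons of its target node.  A stimulus
is realized up front as a :class:`StimulusBatch` — the sorted emission times
of the external sources plus the individual pulse deliveries (one per
emission x wired target), which the event engine merges into its queue.
Delivered amplitude is the bare input amplitude (``A_P``/``A_c``/``A_ss``);
input pulses bypass the synaptic weight tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "PoissonInputSpec",
    "ConstantInputSpec",
    "StreamInputSpec",
    "StimulusBatch",
    "gen_poisson_events",
    "gen_constant_events",
    "load_stream",
    "realize_stimuli",
]


@dataclass(frozen=True)
class PoissonInputSpec:
    """Poisson-like trains on a grid of candidate instants.

    Each of ``n_ext`` sources may emit at the instants ``t_start + k*delta_t``
    (ms) in ``[t_start, t_end)``, independently with probability
    ``r_hz * delta_t / 1000`` (Table-3 names: n_extP, t_startP, t_endP, r_P,
    delta_t_P, A_P).  As ``delta_t -> 0`` this converges to a Poisson process
    of rate ``r_hz``.
    """

    target_node: str
    n_ext: int
    r_hz: float
    t_start: float = 0.0
    t_end: float = 1000.0
    delta_t: float = 0.1
    amplitude: float = 1.0
    targets_per_source: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ext < 1 or self.targets_per_source < 1:
            raise ValueError("n_ext and targets_per_source must be >= 1")
        if self.r_hz <= 0 or self.delta_t <= 0:
            raise ValueError("r_hz and delta_t must be positive")
        if self.amplitude <= 0:
            raise ValueError("external sources are excitatory: amplitude must be > 0")
        if self.r_hz * self.delta_t / 1000.0 > 1.0:
            raise ValueError(
                f"per-instant probability r*delta_t/1000 = "
                f"{self.r_hz * self.delta_t / 1000.0:.3f} exceeds 1"
            )


@dataclass(frozen=True)
class ConstantInputSpec:
    """Deterministic train emulating DC input, sampled every ``interval`` ms."""

    target_node: str
    n_ext: int
    interval: float            # Table-3 int_c
    t_start: float = 0.0
    t_end: float = 1000.0
    amplitude: float = 1.0
    targets_per_source: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ext < 1 or self.targets_per_source < 1:
            raise ValueError("n_ext and targets_per_source must be >= 1")
        if self.interval <= 0:
            raise ValueError("interspike interval must be positive")
        if self.amplitude <= 0:
            raise ValueError("external sources are excitatory: amplitude must be > 0")


@dataclass(frozen=True)
class StreamInputSpec:
    """Arbitrary spike stream: explicit (source id, time ms) events."""

    target_node: str
    amplitude: float
    events: Tuple[Tuple[int, float], ...] = ()
    targets_per_source: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("external sources are excitatory: amplitude must be > 0")
        events = tuple((int(s), float(t)) for s, t in self.events)
        for s, t in events:
            if t < 0 or not np.isfinite(t):
                raise ValueError(f"stream event time must be finite and >= 0, got {t}")
            if s < 0:
                raise ValueError(f"stream source id must be >= 0, got {s}")
        object.__setattr__(self, "events", events)


@dataclass
class StimulusBatch:
    """Realized stimulus: source emissions and the pulses they deliver.

    ``emission_*`` list every external-source spike (for the firing log);
    ``delivery_*`` list one entry per (emission, wired target), time-sorted,
    ready for the event queue.
    """

    target_node: str
    emission_time: np.ndarray
    emission_source: np.ndarray
    delivery_time: np.ndarray
    delivery_target: np.ndarray   # global neuron index
    delivery_source: np.ndarray
    delivery_amp: np.ndarray

    @property
    def n_emissions(self) -> int:
        return len(self.emission_time)

    @property
    def n_deliveries(self) -> int:
        return len(self.delivery_time)


def _wire_sources(rng: np.random.Generator, n_sources: int, node_neurons: np.ndarray,
                  targets_per_source: int) -> np.ndarray:
    """Fixed source->target map: each source picks targets without replacement."""
    if targets_per_source > len(node_neurons):
        raise ValueError("targets_per_source exceeds node size")
    out = np.empty((n_sources, targets_per_source), dtype=np.int64)
    for s in range(n_sources):
        out[s] = rng.choice(node_neurons, size=targets_per_source, replace=False)
    return out


def _expand(target_node: str, times: np.ndarray, sources: np.ndarray,
            wiring: np.ndarray, amplitude: float) -> StimulusBatch:
    order = np.lexsort((sources, times))
    times, sources = times[order], sources[order]
    tps = wiring.shape[1]
    return StimulusBatch(
        target_node=target_node,
        emission_time=times,
        emission_source=sources,
        delivery_time=np.repeat(times, tps),
        delivery_target=wiring[sources].reshape(-1),
        delivery_source=np.repeat(sources, tps),
        delivery_amp=np.full(len(times) * tps, amplitude),
    )


def gen_poisson_events(spec: PoissonInputSpec, node_neurons: np.ndarray,
                       rng: Optional[np.random.Generator] = None) -> StimulusBatch:
    """Realize a Poisson stimulus (Bernoulli thinning on the ``delta_t`` grid)."""
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    wiring = _wire_sources(rng, spec.n_ext, np.asarray(node_neurons), spec.targets_per_source)
    n_instants = max(0, int(np.ceil((spec.t_end - spec.t_start) / spec.delta_t - 1e-12)))
    p = spec.r_hz * spec.delta_t / 1000.0
    src_list, t_list = [], []
    chunk = max(1, min(n_instants, 4_000_000 // max(spec.n_ext, 1)))
    for k0 in range(0, n_instants, chunk):
        k1 = min(k0 + chunk, n_instants)
        hits = rng.random((spec.n_ext, k1 - k0)) < p
        s, k = np.nonzero(hits)
        src_list.append(s)
        t_list.append(spec.t_start + (k0 + k) * spec.delta_t)
    sources = np.concatenate(src_list) if src_list else np.empty(0, dtype=np.int64)
    times = np.concatenate(t_list) if t_list else np.empty(0)
    return _expand(spec.target_node, times, sources.astype(np.int64), wiring, spec.amplitude)


def gen_constant_events(spec: ConstantInputSpec, node_neurons: np.ndarray,
                        rng: Optional[np.random.Generator] = None) -> StimulusBatch:
    """Realize a constant train: every source emits at ``t_start + k*interval``."""
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    wiring = _wire_sources(rng, spec.n_ext, np.asarray(node_neurons), spec.targets_per_source)
    n_pulses = max(0, int(np.ceil((spec.t_end - spec.t_start) / spec.interval - 1e-12)))
    base = spec.t_start + np.arange(n_pulses) * spec.interval
    times = np.tile(base, spec.n_ext)
    sources = np.repeat(np.arange(spec.n_ext, dtype=np.int64), n_pulses)
    return _expand(spec.target_node, times, sources, wiring, spec.amplitude)


def gen_stream_events(spec: StreamInputSpec, node_neurons: np.ndarray,
                      rng: Optional[np.random.Generator] = None) -> StimulusBatch:
    """Realize an arbitrary spike stream (duplicates delivered as-is)."""
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    if spec.events:
        sources = np.asarray([s for s, _ in spec.events], dtype=np.int64)
        times = np.asarray([t for _, t in spec.events])
    else:
        sources = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    n_sources = int(sources.max()) + 1 if len(sources) else 1
    wiring = _wire_sources(rng, n_sources, np.asarray(node_neurons), spec.targets_per_source)
    return _expand(spec.target_node, times, sources, wiring, spec.amplitude)


def load_stream(path, target_node: str, amplitude: float,
                targets_per_source: int = 1, rng_seed: int = 0) -> StreamInputSpec:
    """Parse a stream file with lines ``source_id<sep>time_ms`` (comma/tab/space)."""
    events: List[Tuple[int, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").replace("\t", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'source_id, time_ms', got {raw!r}")
        try:
            events.append((int(parts[0]), float(parts[1])))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numbers in {raw!r}") from None
    return StreamInputSpec(target_node=target_node, amplitude=amplitude,
                           events=tuple(events), targets_per_source=targets_per_source,
                           rng_seed=rng_seed)


def realize_stimuli(specs: Sequence[Union[PoissonInputSpec, ConstantInputSpec, StreamInputSpec]],
                    network, master_seed: Union[int, np.random.SeedSequence] = 0,
                    ) -> List[StimulusBatch]:
    """Realize all stimuli against a built network, one RNG stream each."""
    ss = (master_seed if isinstance(master_seed, np.random.SeedSequence)
          else np.random.SeedSequence(master_seed))
    streams = ss.spawn(len(specs))
    batches = []
    for spec, child in zip(specs, streams):
        rng = np.random.default_rng(child)
        neurons = network.neurons_of(spec.target_node)
        if isinstance(spec, PoissonInputSpec):
            batches.append(gen_poisson_events(spec, neurons, rng))
        elif isinstance(spec, ConstantInputSpec):
            batches.append(gen_constant_events(spec, neurons, rng))
        elif isinstance(spec, StreamInputSpec):
            batches.append(gen_stream_events(spec, neurons, rng))
        else:
            raise TypeError(f"unknown stimulus spec {type(spec)!r}")
    return batches
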