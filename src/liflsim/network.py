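"""Network synthesis: small-world nodes, delayed inter-node edges, connectomes.

A *node* is a population of LIFL neurons standing for a brain region, wired
internally by a directed adaptation of the Watts-Strogatz procedure (exact
out-degree ``k`` per neuron, ``n*k`` connections, rewiring probability ``p``
interpolating between ring lattice and random graph).  An *edge* is a bundle
of ``N_e`` long-range axons between two nodes; each axon gets a Gaussian
post-synaptic weight and a gamma-distributed length, converted to a
conduction delay through the global propagation speed ``v`` (``tau = lambda/v``).
Intra-node connections are instantaneous (delay 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .neuron import DecayKind, NeuronParams
from .stdp import StdpParams

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "SynapseTable",
    "Network",
    "build_node",
    "build_edge",
    "build_network",
    "import_connectome",
    "read_matrix",
]

_SENDER_POOLS = ("exc", "inh", "mixed")


@dataclass(frozen=True)
class NodeSpec:
    """Generative description of one neuron population.

    ``n`` neurons on a ring, each with out-degree ``k`` (even, ``k <= n-1``;
    the special value ``k = n-1`` builds a fully connected population and may
    be odd), rewired with probability ``p``.  ``round(R*n)`` neurons are
    excitatory senders (amplitude ``A_exc``), the rest inhibitory (``A_inh``),
    interleaved deterministically along the ring.  Intra-node post-synaptic
    weights are Gaussian per sender type, clamped to ``[0, W_max]``.
    """

    node_id: str
    n: int
    k: int
    p: float
    R: float = 0.8
    mu_w_exc: float = 1.0
    sigma_w_exc: float = 0.0
    mu_w_inh: float = 1.0
    sigma_w_inh: float = 0.0
    A_exc: float = 1.0
    A_inh: float = -1.0
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    stdp_params: Optional[StdpParams] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"node {self.node_id}: n must be >= 1")
        if self.k < 0 or self.k > self.n - 1:
            raise ValueError(f"node {self.node_id}: need 0 <= k <= n-1, got k={self.k}")
        if self.k % 2 != 0 and self.k != self.n - 1:
            # k = n-1 (full connectivity, rewiring moot) is the only odd case;
            # k = 0 builds an unconnected pool, useful for explicit motifs
            raise ValueError(
                f"node {self.node_id}: k must be even (or n-1 for full connectivity), got {self.k}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"node {self.node_id}: p must be in [0,1]")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"node {self.node_id}: R must be in [0,1]")
        if self.A_exc <= 0 or self.A_inh >= 0:
            raise ValueError(f"node {self.node_id}: need A_exc > 0 and A_inh < 0")
        if 0 < self.k < self.n - 1 and self.k < math.log(self.n):
            warnings.warn(
                f"node {self.node_id}: small-world regime expects n >> k >> ln(n)",
                stacklevel=2,
            )

    @property
    def n_excitatory(self) -> int:
        return int(round(self.R * self.n))


@dataclass(frozen=True)
class EdgeSpec:
    """Generative description of one fibre tract (directed node-to-node bundle)."""

    source_node: str
    target_node: str
    N_e: int
    mu_omega: float
    sigma_omega: float = 0.0
    mu_lambda: float = 10.0   # mean axonal length, mm
    alpha_lambda: float = 10.0  # gamma shape; scale = mu_lambda/alpha_lambda
    t_E: Tuple[str, str] = ("exc", "exc")

    def __post_init__(self) -> None:
        if self.N_e < 1:
            raise ValueError("edge cardinality N_e must be >= 1")
        if self.mu_lambda <= 0 or self.alpha_lambda <= 0:
            raise ValueError("gamma length parameters must be positive")
        t_E = tuple(self.t_E)
        if len(t_E) != 2 or any(t not in _SENDER_POOLS for t in t_E):
            raise ValueError(f"t_E must be a pair over {_SENDER_POOLS}, got {self.t_E}")
        object.__setattr__(self, "t_E", t_E)


class SynapseTable:
    """Realized directed connections: (pre, post, weight, delay, plastic).

    Neuron indices are global (node offsets applied); weights live in
    ``[0, W_max]``; intra-node delays are exactly 0.
    """

    __slots__ = ("pre", "post", "weight", "delay", "plastic")

    def __init__(self, pre, post, weight, delay, plastic=None):
        self.pre = np.asarray(pre, dtype=np.int64)
        self.post = np.asarray(post, dtype=np.int64)
        self.weight = np.asarray(weight, dtype=np.float64)
        self.delay = np.asarray(delay, dtype=np.float64)
        if plastic is None:
            plastic = np.zeros(len(self.pre), dtype=bool)
        self.plastic = np.asarray(plastic, dtype=bool)
        n = len(self.pre)
        if not (len(self.post) == len(self.weight) == len(self.delay) == len(self.plastic) == n):
            raise ValueError("synapse table columns must have equal length")

    def __len__(self) -> int:
        return len(self.pre)

    @classmethod
    def empty(cls) -> "SynapseTable":
        return cls([], [], [], [])

    @classmethod
    def concat(cls, tables: Sequence["SynapseTable"]) -> "SynapseTable":
        if not tables:
            return cls.empty()
        return cls(
            np.concatenate([t.pre for t in tables]),
            np.concatenate([t.post for t in tables]),
            np.concatenate([t.weight for t in tables]),
            np.concatenate([t.delay for t in tables]),
            np.concatenate([t.plastic for t in tables]),
        )

    def shifted(self, pre_offset: int, post_offset: int) -> "SynapseTable":
        return SynapseTable(self.pre + pre_offset, self.post + post_offset,
                            self.weight, self.delay, self.plastic)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre": self.pre, "post": self.post,
            "weight": self.weight, "delay": self.delay, "plastic": self.plastic,
        })


# ---------------------------------------------------------------------------
# node generation


def _inhibitory_positions(n: int, n_inh: int) -> np.ndarray:
    """Deterministic interleaving of inhibitory neurons along the ring."""
    if n_inh == 0:
        return np.empty(0, dtype=np.int64)
    pos = np.floor((np.arange(n_inh) + 0.5) * n / n_inh).astype(np.int64)
    # guard against rounding collisions for extreme ratios
    pos = np.unique(pos)
    j = 0
    out = list(pos)
    while len(out) < n_inh:
        if j not in out:
            out.append(j)
        j += 1
    return np.sort(np.asarray(out[:n_inh], dtype=np.int64))


def _ring_lattice_targets(n: int, k: int) -> np.ndarray:
    """Lattice out-targets, shape (n, k); row i lists i+1, i-1, i+2, i-2, ..."""
    if k == n - 1:
        d = np.arange(1, n)
        return (np.arange(n)[:, None] + d[None, :]) % n
    half = k // 2
    offs = np.empty(k, dtype=np.int64)
    offs[0::2] = np.arange(1, half + 1)
    offs[1::2] = -np.arange(1, half + 1)
    return (np.arange(n)[:, None] + offs[None, :]) % n


def build_node(
    spec: NodeSpec,
    rng_seed: Union[int, np.random.Generator],
    W_max: float = math.inf,
) -> Tuple[SynapseTable, np.ndarray]:
    """Realize one node: directed small-world wiring plus neuron type labels.

    Returns a :class:`SynapseTable` in local neuron indices (exactly ``n*k``
    records, every neuron with out-degree ``k``) and a boolean array marking
    excitatory senders.  Deterministic given ``(spec, rng_seed)``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n, k, p = spec.n, spec.k, spec.p

    is_exc = np.ones(n, dtype=bool)
    is_exc[_inhibitory_positions(n, n - spec.n_excitatory)] = False

    targets = _ring_lattice_targets(n, k)
    if p > 0.0 and k < n - 1:
        rewire_mask = rng.random((n, k)) < p
        for i in range(n):
            row = targets[i]
            hits = np.flatnonzero(rewire_mask[i])
            if hits.size == 0:
                continue
            current = set(row.tolist())
            for j in hits:
                old = row[j]
                current.discard(int(old))
                while True:
                    m = int(rng.integers(0, n))
                    if m != i and m not in current:
                        break
                current.add(m)
                row[j] = m

    pre = np.repeat(np.arange(n, dtype=np.int64), k)
    post = targets.reshape(-1)
    w = np.where(
        is_exc[pre],
        rng.normal(spec.mu_w_exc, spec.sigma_w_exc, size=n * k),
        rng.normal(spec.mu_w_inh, spec.sigma_w_inh, size=n * k),
    )
    np.clip(w, 0.0, W_max, out=w)
    table = SynapseTable(pre, post, w, np.zeros(n * k))
    return table, is_exc


# ---------------------------------------------------------------------------
# edge realization


class _NodeView:
    """What build_edge needs to know about an already-built node."""

    __slots__ = ("offset", "is_excitatory")

    def __init__(self, offset: int, is_excitatory: np.ndarray):
        self.offset = offset
        self.is_excitatory = is_excitatory

    def pool(self, kind: str) -> np.ndarray:
        if kind == "exc":
            local = np.flatnonzero(self.is_excitatory)
        elif kind == "inh":
            local = np.flatnonzero(~self.is_excitatory)
        else:
            local = np.arange(len(self.is_excitatory))
        return local + self.offset


def build_edge(
    spec: EdgeSpec,
    nodes: Dict[str, _NodeView],
    v: float,
    rng_seed: Union[int, np.random.Generator],
    W_max: float = math.inf,
) -> SynapseTable:
    """Realize one fibre tract as ``N_e`` delayed synapses (global indices).

    Pre/post neurons are sampled with replacement from the pools selected by
    ``t_E`` (multiple parallel axons between the same pair are allowed);
    weights are Gaussian clamped to ``[0, W_max]``; delays are gamma lengths
    divided by the conduction speed ``v`` (mm / (mm/ms) -> ms).
    """
    if v <= 0:
        raise ValueError("conduction speed v must be positive")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    for name in (spec.source_node, spec.target_node):
        if name not in nodes:
            raise ValueError(f"edge references unknown node {name!r}")
    senders = nodes[spec.source_node].pool(spec.t_E[0])
    receivers = nodes[spec.target_node].pool(spec.t_E[1])
    if senders.size == 0 or receivers.size == 0:
        raise ValueError(
            f"edge {spec.source_node}->{spec.target_node}: empty {spec.t_E} pool"
        )
    pre = rng.choice(senders, size=spec.N_e, replace=True)
    post = rng.choice(receivers, size=spec.N_e, replace=True)
    w = np.clip(rng.normal(spec.mu_omega, spec.sigma_omega, size=spec.N_e), 0.0, W_max)
    lengths = rng.gamma(spec.alpha_lambda, spec.mu_lambda / spec.alpha_lambda, size=spec.N_e)
    return SynapseTable(pre, post, w, lengths / v)


# ---------------------------------------------------------------------------
# whole-network assembly


class Network:
    """A fully realized network: neuron labels, parameters and synapses.

    Synapses are stored sorted by ``(pre, delay, insertion order)`` with a CSR
    index so the event engine can fan out a firing without a search.
    """

    def __init__(
        self,
        node_specs: Sequence[NodeSpec],
        synapses: SynapseTable,
        is_excitatory: np.ndarray,
        offsets: np.ndarray,
    ):
        self.node_specs = list(node_specs)
        self.node_ids = [s.node_id for s in node_specs]
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.n_neurons = int(self.offsets[-1])
        self.is_excitatory = np.asarray(is_excitatory, dtype=bool)
        self.node_of = np.repeat(
            np.arange(len(node_specs)), [s.n for s in node_specs]
        ).astype(np.int64)

        order = np.lexsort((np.arange(len(synapses)), synapses.delay, synapses.pre))
        self.synapses = SynapseTable(
            synapses.pre[order], synapses.post[order], synapses.weight[order],
            synapses.delay[order], synapses.plastic[order],
        )
        self.indptr = np.searchsorted(
            self.synapses.pre, np.arange(self.n_neurons + 1), side="left"
        ).astype(np.int64)

        # per-neuron parameter vectors used by both engines
        self.A = np.empty(self.n_neurons)
        for arr_name in ("a", "b", "c", "D_exc", "D_inh", "t_arp", "IBI"):
            setattr(self, arr_name, np.empty(self.n_neurons))
        self.N_b = np.empty(self.n_neurons, dtype=np.int64)
        self.exp_decay = np.empty(self.n_neurons, dtype=bool)
        self.latency = np.empty(self.n_neurons, dtype=bool)
        for idx, s in enumerate(node_specs):
            sl = slice(self.offsets[idx], self.offsets[idx + 1])
            P = s.neuron_params
            self.a[sl], self.b[sl], self.c[sl] = P.a, P.b, P.c
            self.D_exc[sl] = P.D_exc
            self.D_inh[sl] = P.D_inh if P.D_inh is not None else P.D_exc
            self.t_arp[sl], self.N_b[sl], self.IBI[sl] = P.t_arp, P.N_b, P.IBI
            self.exp_decay[sl] = P.U_t is DecayKind.EXPONENTIAL
            self.latency[sl] = P.latency
            loc = self.is_excitatory[sl]
            self.A[sl] = np.where(loc, s.A_exc, s.A_inh)

    # -- lookups ------------------------------------------------------------

    def node_index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def neurons_of(self, node_id: str) -> np.ndarray:
        i = self.node_index(node_id)
        return np.arange(self.offsets[i], self.offsets[i + 1])

    def local_id(self, neuron: int) -> int:
        return int(neuron - self.offsets[self.node_of[neuron]])

    def params_of(self, neuron: int) -> NeuronParams:
        spec = self.node_specs[self.node_of[neuron]]
        A = spec.A_exc if self.is_excitatory[neuron] else spec.A_inh
        return replace(spec.neuron_params, A=A)

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    # -- export -------------------------------------------------------------

    def to_edge_list(self) -> pd.DataFrame:
        syn = self.synapses
        pre_node = self.node_of[syn.pre]
        post_node = self.node_of[syn.post]
        return pd.DataFrame({
            "pre_node": [self.node_ids[i] for i in pre_node],
            "pre_neuron": syn.pre - self.offsets[pre_node],
            "post_node": [self.node_ids[i] for i in post_node],
            "post_neuron": syn.post - self.offsets[post_node],
            "weight": syn.weight,
            "delay_ms": syn.delay,
        })

    def export_edge_list(self, path) -> None:
        self.to_edge_list().to_csv(path, index=False)


def build_network(
    node_specs: Sequence[NodeSpec],
    edge_specs: Sequence[EdgeSpec] = (),
    v: float = 5.5,
    W_max: float = math.inf,
    master_seed: Union[int, np.random.SeedSequence] = 0,
) -> Network:
    """Build all nodes then all edges, each from its own spawned RNG stream.

    Deterministic given specs and ``master_seed``.  Synapses whose
    post-synaptic neuron belongs to a node with STDP enabled are flagged
    plastic (intra-node and incoming inter-node alike); by default only
    synapses with an excitatory sender (see :mod:`liflsim.stdp`).
    """
    ids = [s.node_id for s in node_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids")
    ss = (master_seed if isinstance(master_seed, np.random.SeedSequence)
          else np.random.SeedSequence(master_seed))
    streams = ss.spawn(len(node_specs) + len(edge_specs))

    tables: List[SynapseTable] = []
    labels: List[np.ndarray] = []
    offsets = np.zeros(len(node_specs) + 1, dtype=np.int64)
    views: Dict[str, _NodeView] = {}
    for i, spec in enumerate(node_specs):
        frag, is_exc = build_node(spec, np.random.default_rng(streams[i]), W_max=W_max)
        offsets[i + 1] = offsets[i] + spec.n
        tables.append(frag.shifted(offsets[i], offsets[i]))
        labels.append(is_exc)
        views[spec.node_id] = _NodeView(int(offsets[i]), is_exc)

    for j, espec in enumerate(edge_specs):
        rng = np.random.default_rng(streams[len(node_specs) + j])
        tables.append(build_edge(espec, views, v=v, rng_seed=rng, W_max=W_max))

    synapses = SynapseTable.concat(tables)
    net = Network(node_specs, synapses, np.concatenate(labels), offsets)

    plastic_nodes = {
        i for i, s in enumerate(node_specs)
        if s.stdp_params is not None and s.stdp_params.enabled
    }
    if plastic_nodes:
        syn = net.synapses
        mask = np.isin(net.node_of[syn.post], list(plastic_nodes))
        for i in plastic_nodes:
            sp = node_specs[i].stdp_params
            if not sp.include_inhibitory:
                here = net.node_of[syn.post] == i
                mask &= ~here | net.is_excitatory[syn.pre]
        syn.plastic[:] = mask
    return net


# ---------------------------------------------------------------------------
# connectome import


def read_matrix(path) -> Tuple[List[str], np.ndarray]:
    """Read a delimited square matrix with a one-line header of node ids."""
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise ValueError(f"{path}: empty file")
    delim = "\t" if "\t" in text[0] else ","
    header = [h.strip() for h in text[0].split(delim)]
    rows = [line.split(delim) for line in text[1:] if line.strip()]
    if len(rows) != len(header):
        raise ValueError(f"{path}: expected {len(header)} rows, found {len(rows)}")
    try:
        mat = np.asarray([[float(x) for x in r] for r in rows])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric entry ({e})") from None
    if mat.shape != (len(header), len(header)):
        raise ValueError(f"{path}: matrix is not square: {mat.shape}")
    if (mat < 0).any():
        raise ValueError(f"{path}: negative entries not allowed")
    return header, mat


def import_connectome(
    counts_file,
    weights_file,
    lengths_file,
    sigma_omega_frac: float = 0.0,
    alpha_lambda: float = 10.0,
    t_E: Tuple[str, str] = ("exc", "exc"),
) -> Tuple[List[str], List[EdgeSpec]]:
    """Turn connectome matrices into edge specs, one per nonzero count cell.

    The three files hold per-node-pair connection counts, mean weights and
    mean tract lengths (mm); row = source, column = target, zero diagonal and
    zero counts mean "no edge".  ``sigma_omega_frac`` sets the weight spread
    as a fraction of the cell mean; ``alpha_lambda`` the gamma length shape.
    """
    ids, counts = read_matrix(counts_file)
    ids_w, weights = read_matrix(weights_file)
    ids_l, lengths = read_matrix(lengths_file)
    if ids_w != ids or ids_l != ids:
        raise ValueError("connectome matrices disagree on node ids/order")
    edges: List[EdgeSpec] = []
    for i, src in enumerate(ids):
        for j, dst in enumerate(ids):
            if i == j or counts[i, j] == 0:
                continue
            if lengths[i, j] <= 0:
                raise ValueError(f"edge {src}->{dst}: nonzero count but length {lengths[i, j]}")
            edges.append(EdgeSpec(
                source_node=src, target_node=dst,
                N_e=int(round(counts[i, j])),
                mu_omega=float(weights[i, j]),
                sigma_omega=sigma_omega_frac * float(weights[i, j]),
                mu_lambda=float(lengths[i, j]),
                alpha_lambda=alpha_lambda,
                t_E=t_E,
            ))
    return ids, edges
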