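"""Structured configuration: YAML/dict -> simulation setup.

One document defines a whole experiment: global parameters, per-node
topology/neuron/plasticity parameters (neuron keys follow the standard
parameter names: a, b, c, D_exc, D_inh, t_arp, N_b, IBI, U_t), per-edge
connectivity, stimuli, optional connectome matrices and the list of nodes of
interest (NOIs).  See ``examples/`` for complete documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import yaml

from .engine import ConfigError, GlobalConfig, run
from .io import BURNING_HEADER, FIRING_HEADER, CsvSink
from .network import EdgeSpec, NodeSpec, build_network, import_connectome
from .neuron import NeuronParams
from .stdp import StdpParams
from .stimuli import ConstantInputSpec, PoissonInputSpec, StreamInputSpec, load_stream

__all__ = ["SimulationSetup", "load_config", "parse_config", "run_setup"]


@dataclass
class SimulationSetup:
    """Parsed and validated configuration, ready to build and run."""

    global_config: GlobalConfig
    nodes: List[NodeSpec]
    edges: List[EdgeSpec]
    stimuli: List
    noi: Optional[List[str]] = None

    def build(self):
        return build_network(self.nodes, self.edges, v=self.global_config.v,
                             W_max=self.global_config.W_max,
                             master_seed=self.global_config.master_seed)


def _neuron_params(d: Optional[dict]) -> NeuronParams:
    d = dict(d or {})
    known = {"a", "b", "c", "D_exc", "D_inh", "t_arp", "N_b", "IBI", "U_t", "latency"}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown neuron parameter(s): {sorted(unknown)}")
    return NeuronParams(**d)


def _stdp_params(d: Optional[dict]) -> Optional[StdpParams]:
    if d is None:
        return None
    return StdpParams(**d)


def _node_spec(d: dict) -> NodeSpec:
    w_exc = d.get("w_exc", {})
    w_inh = d.get("w_inh", {})
    return NodeSpec(
        node_id=str(d["id"]),
        n=int(d["n"]),
        k=int(d["k"]),
        p=float(d.get("p", 0.0)),
        R=float(d.get("R", 0.8)),
        mu_w_exc=float(w_exc.get("mu", 1.0)),
        sigma_w_exc=float(w_exc.get("sigma", 0.0)),
        mu_w_inh=float(w_inh.get("mu", 1.0)),
        sigma_w_inh=float(w_inh.get("sigma", 0.0)),
        A_exc=float(d.get("A_exc", 1.0)),
        A_inh=float(d.get("A_inh", -1.0)),
        neuron_params=_neuron_params(d.get("neuron")),
        stdp_params=_stdp_params(d.get("stdp")),
    )


def _edge_spec(d: dict) -> EdgeSpec:
    omega = d.get("omega", {})
    length = d.get("length", {})
    t_E = d.get("t_E", "exc->exc")
    if isinstance(t_E, str):
        parts = t_E.split("->")
        if len(parts) != 2:
            raise ConfigError(f"t_E must look like 'exc->inh', got {t_E!r}")
        t_E = (parts[0].strip(), parts[1].strip())
    return EdgeSpec(
        source_node=str(d["source"]),
        target_node=str(d["target"]),
        N_e=int(d["N_e"]),
        mu_omega=float(omega.get("mu", 1.0)),
        sigma_omega=float(omega.get("sigma", 0.0)),
        mu_lambda=float(length.get("mu", 10.0)),
        alpha_lambda=float(length.get("alpha", 10.0)),
        t_E=tuple(t_E),
    )


def _stimulus_spec(d: dict, base_dir: Path, index: int):
    kind = d.get("kind", "poisson")
    node = str(d["node"])
    if kind == "poisson":
        return PoissonInputSpec(
            target_node=node,
            n_ext=int(d["n_ext"]),
            r_hz=float(d["r"]),
            t_start=float(d.get("t_start", 0.0)),
            t_end=float(d.get("t_end", 1000.0)),
            delta_t=float(d.get("delta_t", 0.1)),
            amplitude=float(d["A"]),
            targets_per_source=int(d.get("targets_per_source", 1)),
        )
    if kind == "constant":
        return ConstantInputSpec(
            target_node=node,
            n_ext=int(d.get("n_ext", 1)),
            interval=float(d["int"]),
            t_start=float(d.get("t_start", 0.0)),
            t_end=float(d.get("t_end", 1000.0)),
            amplitude=float(d["A"]),
            targets_per_source=int(d.get("targets_per_source", 1)),
        )
    if kind == "stream":
        if "file" in d:
            return load_stream(base_dir / d["file"], target_node=node,
                               amplitude=float(d["A"]),
                               targets_per_source=int(d.get("targets_per_source", 1)))
        events = tuple((int(s), float(t)) for s, t in d.get("events", ()))
        return StreamInputSpec(target_node=node, amplitude=float(d["A"]),
                               events=events,
                               targets_per_source=int(d.get("targets_per_source", 1)))
    raise ConfigError(f"stimulus #{index}: unknown kind {kind!r}")


def parse_config(doc: dict, base_dir: Path = Path(".")) -> SimulationSetup:
    """Validate a configuration dict and resolve referenced files."""
    g = dict(doc.get("global", {}))
    if "t_stop" not in g:
        raise ConfigError("global.t_stop is required")
    gc = GlobalConfig(
        t_stop=float(g["t_stop"]),
        v=float(g.get("v", 5.5)),
        W_max=float(g.get("W_max", float("inf"))),
        S_b=int(g.get("S_b", 100_000)),
        N_m=str(g.get("N_m", "LIFL")),
        master_seed=int(g.get("seed", 0)),
    )
    nodes = [_node_spec(d) for d in doc.get("nodes", [])]
    edges = [_edge_spec(d) for d in doc.get("edges", [])]

    conn = doc.get("connectome")
    if conn is not None:
        ids, conn_edges = import_connectome(
            base_dir / conn["counts"], base_dir / conn["weights"],
            base_dir / conn["lengths"],
            sigma_omega_frac=float(conn.get("sigma_omega_frac", 0.0)),
            alpha_lambda=float(conn.get("alpha_lambda", 10.0)),
        )
        defined = {s.node_id for s in nodes}
        template_id = conn.get("node_template")
        if template_id is not None:
            template = next((s for s in nodes if s.node_id == template_id), None)
            if template is None:
                raise ConfigError(f"connectome.node_template {template_id!r} not defined")
            from dataclasses import replace as dc_replace
            for nid in ids:
                if nid not in defined:
                    nodes.append(dc_replace(template, node_id=nid))
                    defined.add(nid)
        missing = [nid for nid in ids if nid not in defined]
        if missing:
            raise ConfigError(f"connectome references undefined nodes: {missing}")
        edges.extend(conn_edges)

    if not nodes:
        raise ConfigError("at least one node is required")

    stimuli = [_stimulus_spec(d, base_dir, i) for i, d in enumerate(doc.get("stimuli", []))]
    noi = doc.get("noi")
    if noi is not None:
        noi = [str(x) for x in noi]
        declared = {s.node_id for s in nodes}
        unknown = set(noi) - declared
        if unknown:
            raise ConfigError(f"NOI(s) not declared as nodes: {sorted(unknown)}")
    return SimulationSetup(global_config=gc, nodes=nodes, edges=edges,
                           stimuli=stimuli, noi=noi)


def load_config(path) -> SimulationSetup:
    """Load and parse a YAML configuration file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(doc, base_dir=path.parent)


def run_setup(setup: SimulationSetup, out_dir, seed: Optional[int] = None,
              duration: Optional[float] = None, write_burning: bool = True):
    """Build, simulate and write event files; returns the SimulationResult."""
    gc = setup.global_config
    if seed is not None:
        from dataclasses import replace as dc_replace
        gc = dc_replace(gc, master_seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup = SimulationSetup(gc, setup.nodes, setup.edges, setup.stimuli, setup.noi)
    net = setup.build()
    with CsvSink(out / "firing.csv", FIRING_HEADER, gc.S_b) as fsink:
        if write_burning:
            with CsvSink(out / "burning.csv", BURNING_HEADER, gc.S_b) as bsink:
                result = run(net, setup.stimuli, gc, t_stop=duration,
                             noi=setup.noi, firing_sink=fsink, burning_sink=bsink,
                             record_firing=False, record_burning=False)
        else:
            result = run(net, setup.stimuli, gc, t_stop=duration,
                         noi=setup.noi, firing_sink=fsink,
                         record_firing=False, record_burning=False)
    return result
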