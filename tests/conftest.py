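"""Shared fixtures: hand-assembled motifs and small random networks."""

from __future__ import annotations

import numpy as np
import pytest

from liflsim.network import Network, NodeSpec, SynapseTable, build_network
from liflsim.neuron import NeuronParams
from liflsim.stimuli import StimulusBatch


def make_motif(node_sizes, synapses, neuron_params=None, is_excitatory=None,
               A_exc=1.0, A_inh=-1.0, stdp=None):
    """Build a Network with explicit synapses.

    ``node_sizes``: dict node_id -> n.  ``synapses``: iterable of
    (pre, post, weight, delay) in *global* neuron indices.  ``stdp``: dict
    node_id -> StdpParams for plastic nodes.
    """
    params = neuron_params or NeuronParams(a=1.0, b=0.0, c=0.01, D_exc=20.0, t_arp=2.0)
    specs = []
    for nid, n in node_sizes.items():
        specs.append(NodeSpec(
            node_id=nid, n=n, k=0, p=0.0, R=1.0,
            A_exc=A_exc, A_inh=A_inh, neuron_params=params,
            stdp_params=(stdp or {}).get(nid),
        ))
    base = build_network(specs, master_seed=0)
    if synapses:
        pre, post, w, d = map(np.asarray, zip(*synapses))
    else:
        pre = post = np.zeros(0, dtype=np.int64)
        w = d = np.zeros(0)
    table = SynapseTable(pre, post, w, d)
    net = Network(base.node_specs, table, base.is_excitatory.copy(), base.offsets)
    if is_excitatory is not None:
        net.is_excitatory[:] = is_excitatory
        for idx, s in enumerate(base.node_specs):
            sl = slice(net.offsets[idx], net.offsets[idx + 1])
            net.A[sl] = np.where(net.is_excitatory[sl], s.A_exc, s.A_inh)
    # plastic flags: synapses terminating in an STDP node, excitatory senders
    if stdp:
        plastic_nodes = {i for i, s in enumerate(net.node_specs)
                         if s.stdp_params is not None and s.stdp_params.enabled}
        mask = np.isin(net.node_of[net.synapses.post], list(plastic_nodes))
        for i in plastic_nodes:
            sp = net.node_specs[i].stdp_params
            if not sp.include_inhibitory:
                here = net.node_of[net.synapses.post] == i
                mask &= ~here | net.is_excitatory[net.synapses.pre]
        net.synapses.plastic[:] = mask
    return net


def stream_batch(net, node_id, events, amplitude=None):
    """StimulusBatch delivering explicit (time, global_neuron[, amp]) pulses."""
    times = np.asarray([e[0] for e in events], dtype=float)
    targets = np.asarray([e[1] for e in events], dtype=np.int64)
    amps = np.asarray([e[2] if len(e) > 2 else amplitude for e in events], dtype=float)
    order = np.argsort(times, kind="stable")
    return StimulusBatch(
        target_node=node_id,
        emission_time=times[order],
        emission_source=np.arange(len(times))[order],
        delivery_time=times[order],
        delivery_target=targets[order],
        delivery_source=np.arange(len(times))[order],
        delivery_amp=amps[order],
    )


@pytest.fixture
def default_params():
    return NeuronParams(a=1.0, b=0.0, c=0.05, D_exc=20.0, t_arp=5.0)


@pytest.fixture
def small_random_net():
    """Two heterogeneous nodes with delayed inter-node edges (seeded)."""
    from liflsim.network import EdgeSpec

    specs = [
        NodeSpec("A", n=60, k=6, p=0.3, R=0.8, mu_w_exc=0.12, sigma_w_exc=0.02,
                 mu_w_inh=0.4, sigma_w_inh=0.05,
                 neuron_params=NeuronParams(a=1, b=0, c=0.01, D_exc=20, t_arp=3)),
        NodeSpec("B", n=50, k=4, p=0.6, R=0.75, mu_w_exc=0.12, mu_w_inh=0.3,
                 neuron_params=NeuronParams(a=1, b=0.5, c=0.02, D_exc=15, D_inh=25,
                                            t_arp=2, U_t="linear")),
    ]
    edges = [
        EdgeSpec("A", "B", N_e=120, mu_omega=0.12, sigma_omega=0.03,
                 mu_lambda=40, alpha_lambda=5),
        EdgeSpec("B", "A", N_e=80, mu_omega=0.10, sigma_omega=0.02,
                 mu_lambda=60, alpha_lambda=2),
    ]
    return build_network(specs, edges, v=5.5, W_max=1.0, master_seed=42)
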