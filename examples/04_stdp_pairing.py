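"""Spike-timing-dependent plasticity on a delayed two-neuron motif.

Repeated pre->post pairings at a fixed lag potentiate the synapse by
eta_plus * exp(-dt/tau_plus) per pair; post->pre ordering depresses it.
Pre timing is measured at pulse arrival (after the conduction delay).
"""

import numpy as np

from liflsim import NodeSpec, NeuronParams, StdpParams, build_network, run
from liflsim.stimuli import StreamInputSpec, realize_stimuli

params = NeuronParams(a=1.0, b=0.0, c=0.01, D_exc=20.0, t_arp=2.0)
sp = StdpParams(tau_plus=20.0, tau_minus=20.0, eta_plus=0.02, eta_minus=0.02,
                TO=100.0)
nodes = [
    NodeSpec("pre", n=1, k=0, p=0.0, R=1.0, neuron_params=params),
    NodeSpec("post", n=1, k=0, p=0.0, R=1.0, neuron_params=params,
             stdp_params=sp),
]
from liflsim import EdgeSpec
edges = [EdgeSpec("pre", "post", N_e=1, mu_omega=0.3, sigma_omega=0.0,
                  mu_lambda=11.0, alpha_lambda=1e6)]  # delay ~ 2 ms at v=5.5

net = build_network(nodes, edges, v=5.5, W_max=1.0, master_seed=0)
print(f"synapse delay: {net.synapses.delay[0]:.3f} ms, "
      f"initial weight {net.synapses.weight[0]:.3f}")

# 10 pairing cycles: drive pre at t0, post 8 ms later (pre arrival leads post)
events_pre, events_post = [], []
for k in range(10):
    t0 = 200.0 * k
    events_pre.append((0, t0))
    events_post.append((0, t0 + 8.0))
stimuli = [
    StreamInputSpec("pre", amplitude=2.0, events=tuple(events_pre)),
    StreamInputSpec("post", amplitude=2.0, events=tuple(events_post)),
]
batches = realize_stimuli(stimuli, net, master_seed=1)
res = run(net, batches, t_stop=2000.0, backend="python")

print(f"final weight after 10 pairings: {res.final_weights[0]:.4f}")
dw = res.final_weights[0] - 0.3
print(f"total potentiation {dw:+.4f} "
      f"(~10 x 0.02 x exp(-dt_pair/20) for the realized pair lags)")
# Reversing the order (post before pre) would drive the weight down instead;
# weights are always clamped to [0, W_max].
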