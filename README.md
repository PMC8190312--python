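# liflsim

Event-driven simulation of spiking neural networks built from **leaky
integrate-and-fire neurons with spike latency (LIFL)** — for exploring how
single-neuron dynamics and long-range conduction delays shape the activity
of interacting neuron populations (brain regions), even over long biological
times on modest hardware.

## Who this is for

Computational neuroscientists who want spiking-level network models of one
or more brain regions — custom motifs, small-world populations, or
multi-region networks constrained by structural connectivity matrices —
with delayed inter-region connections, synaptic plasticity, configurable
stimuli, and exhaustive event logs for reconstructing electrophysiology-like
signals.

## The model

Each neuron carries a dimensionless inner state `S` (0 = rest). Below the
threshold `S_th = 1 + c` the state decays between pulses (exponential or
linear law, decay parameter `D`). At or above threshold the neuron is
committed to fire, but only after the state-dependent **spike latency**

```
t_f = a / (S − 1) − b        (maximal a/c − b at threshold)
```

so pulses arriving inside the latency window *anticipate*, *postpone* or
*cancel* the emission — a neurocomputational feature of most cortical
neurons that plain integrate-and-fire models lack. Because the state between
events has a closed form, the network is simulated **event-driven**: a
global queue of firing events (emissions), burning events (deliveries, after
the conduction delay `τ = λ/v` of each axon) and stimulus pulses, processed
in continuous time with no integration grid. Refractoriness, tonic bursting,
pair-based STDP (exponential windows, hard bounds `[0, W_max]`), Poisson /
constant / arbitrary-stream stimuli, and Watts–Strogatz-based population
generation are all included; a compiled kernel handles large
plasticity-free networks at millions of events per second.

## A worked example

```python
from liflsim import run
from liflsim.analysis import psth
from liflsim.benchmarks import make_regime, instantiate

for regime in ("HA", "RD"):
    cfg = make_regime(regime)                     # packaged 4000-neuron node
    net, stimuli, S0 = instantiate(cfg, seed=1)   # wiring, inputs, initial S
    res = run(net, stimuli, cfg.global_config, init_S=S0)
    p = psth(res, t_stop=1000.0)
    print(f"{regime}: rate {res.mean_rate_hz():6.2f} Hz   "
          f"max_PSTH {p.max_psth:5d}   c_hi-PSTH {p.c_hi_psth:4d}")
```

prints

```
HA: rate  10.31 Hz   max_PSTH    68   c_hi-PSTH    0
RD: rate  49.22 Hz   max_PSTH  3858   c_hi-PSTH   90
```

`HA` is the homogeneous-activity regime: a 4000-neuron population (80/20
excitatory/inhibitory, 2% connectivity, delta synapses) driven by 4000
Poisson sources at 5 Hz fires asynchronously at ~10 Hz; the largest 1-ms
population histogram bin holds 68 spikes and no bin exceeds the 100-spike
synchrony threshold. `RD` (doubled connectivity, equal-and-opposite synaptic
weights, stronger drive) instead produces ~50 Hz carried by about fifty
near-full-population synchronous discharges per second — each packing
~3900 spikes into a millisecond, and each crossing the 100-spike threshold
for a bin or two (`c_hi-PSTH` 90).

More narrative scripts live in `examples/`: single-neuron latency effects,
small-world node generation, delayed two-region interaction, STDP pairing,
benchmark regimes, and connectome-matrix import. A thin CLI wraps the same
library: `liflsim run --config cfg.yaml --out dir`, `liflsim analyze
psth|rate --firing firing.csv`, `liflsim fixtures make A1|HA|SD|RD|B`.

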