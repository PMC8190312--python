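# Methods

## The neuron model

Each neuron carries a dimensionless inner state `S ≥ 0` (0 = resting
potential, a surrogate of the membrane potential). Pulses are Dirac deltas:
a pulse of amplitude `A_i · W_ij` (pre-synaptic amplitude × post-synaptic
weight) shifts the state instantaneously. Two regimes:

* **Passive** (`S < S_th = 1 + c`): between pulses the state decays. Two
  laws are available per node, selected by `U_t` and parameterized by a
  decay parameter chosen by the type of the arriving synapse (`D_exc` or
  `D_inh`, defaulting to `D_exc`):
  - exponential: `T_l = S_p (1 − e^{−Δt/D})`, `D` a time constant in ms;
  - linear: `T_l = min(S_p, Δt/D)`, `1/D` a slope in 1/ms.
  A pulse update is `S ← max(0, S_p − T_l + A·W)` (decay first, then pulse,
  then clamp at rest).
* **Active** (`S ≥ S_th`): the spike is emitted only after the
  state-dependent latency (*time to fire*)

      t_f = a/(S − 1) − b ,

  maximal at threshold (`t_f,max = a/c − b`) and zero at the ceiling
  `S_max = 1 + a/b` (infinite when `b = 0`). Between pulses the state grows
  along the same hyperbola; a pulse arriving after `Δt` sees
  `S ← S_p + T_r + A·W` with the rise term
  `T_r = (S_p−1)² Δt / (a − (S_p−1) Δt)`, which satisfies the exact identity
  `t_f(S_p + T_r) = t_f(S_p) − Δt` (no-input invariance; property-tested to
  machine precision). Excitatory pulses during the latency window anticipate
  the spike, inhibitory ones postpone it, and inhibition strong enough to
  pull `S` under threshold cancels it. Input driving `S` past `S_max` fires
  the neuron immediately.

On emission the state resets to 0 and the neuron is insensitive to input for
the absolute refractory period `t_arp`; a pulse arriving exactly at the end
of the window is accepted (boundary inclusive). With burst cardinality
`N_b > 1` an emission commits a train of `N_b` spikes spaced `IBI` ms apart;
burst emissions are unconditional and refractoriness starts after the last
one (the model source gives no rule for input during a burst; we discard it,
which keeps burst trains intact). The `N_m = 'LIF'` switch disables the
latency feature entirely: the neuron fires the instant it reaches threshold.
The exact under-threshold decay forms and the pair-based plasticity rule are
conventional choices (standard leaky-integrator and exponential-window
forms) satisfying the documented contracts.

## Event-driven core

Simulation is asynchronous: a neuron is touched only when a pulse reaches it
or when it emits. A single priority queue orders *firing* events (scheduled
emissions), *burning* events (pulse deliveries) and external *input*
deliveries by `(time, kind, insertion sequence)`, with firing < burning <
input at equal times — a neuron whose latency elapses exactly when a pulse
arrives fires first. Time is a continuous float; there is no grid anywhere.

Each neuron has at most one valid pending firing event; rescheduling after
every state change uses lazy invalidation (a per-neuron version counter, so
stale queue entries are skipped on pop). Deliveries are queued as per-
emission batches grouped by equal delay, which preserves per-event ordering
(same-time deliveries of one emission are contiguous in sequence) while
keeping the queue small. Zero-delay cascades resolve within one timestamp in
insertion order; configurations containing a zero-delay cycle among neurons
with `t_arp = 0` are rejected at validation time, since such a cycle could
recur unboundedly within a single instant.

Two backends execute identical semantics:

* the **pure-Python reference loop** — feature-complete (STDP, bursting,
  bounded-memory streaming to sinks) and the normative implementation;
* a **compiled kernel** (numba) for static-weight, non-bursting networks,
  selected automatically for large runs. An equivalence test asserts
  identical event counts, orderings and spike times (≤1e-9 ms) between the
  two on heterogeneous two-population networks with mixed delays.

The kernel replaces a worker-thread scheme as the performance path; the
engine itself is single-threaded and deterministic: identical
(network, stimuli, seed) triples give byte-identical logs.

## Networks

A **node** (one brain region, or a sub-population of one) is generated by a
directed adaptation of the Watts–Strogatz procedure: a ring lattice of `n`
neurons with out-degree `k` (connections to the `k/2` nearest neighbours per
side), after which every out-edge is independently rewired with probability
`p` to a uniformly drawn target avoiding self-loops and duplicates (redraw
on collision; rewiring exchanges targets, so the count `n·k` and every
out-degree are invariant). `p` interpolates ring lattice → small world →
random graph. We treat each directed out-edge as owned by its source and
rewire each exactly once; restricting rewiring to half the edges would leave
a `p = 1` graph half-lattice rather than random. `round(R·n)` neurons are
excitatory (positive pre-synaptic amplitude `A_exc`), the rest inhibitory
(`A_inh < 0`), interleaved deterministically along the ring to avoid
spatially clustered inhibition at low `p`. Intra-node weights are Gaussian
per sender type, clamped to `[0, W_max]` (clamping, not redrawing, keeps the
draw monotone in the underlying normal variate). Special cases: `k = n − 1`
(odd allowed) builds a fully connected pool; `k = 0` an unconnected pool for
explicit motifs; `n = 1` single-neuron nodes are legal.

An **edge** (fibre tract) realizes `N_e` directed axons between two nodes:
pre/post neurons sampled with replacement from the pools selected by the
sender→receiver type pair `t_E` (multiple parallel axons between one pair
are allowed), Gaussian weights clamped to `[0, W_max]`, and gamma lengths
(mean `μ_λ` mm, shape `α_λ`, scale `μ_λ/α_λ`) converted to conduction delays
by the global speed: `τ = λ/v` ms. Intra-node connections are instantaneous
(`τ = 0`). Connectome matrices (counts / mean weights / mean lengths;
delimited text with a node-id header row) import as one edge spec per
nonzero count cell.

## Stimuli

External sources are fictive excitatory neurons, each permanently wired to
`targets_per_source` distinct neurons of its target node; delivered
amplitude is the bare input amplitude (inputs bypass the weight tables).
Poisson trains are realized by Bernoulli thinning on a grid of candidate
instants (`p = r·δt/1000` per instant, at most one spike per instant per
source); a distribution test confirms convergence to exponential intervals
as `δt → 0`. Constant trains emit every `int_c` ms — an event-driven stand-in
for DC input. Arbitrary streams are explicit (source, time) lists, parsed
from delimited text; the engine sorts, so file order is irrelevant.

## Plasticity

Pair-based additive STDP with exponential windows and hard clamping to
`[0, W_max]`:

    Δw = +η₊ e^{−Δt/τ₊}  for Δt = t_post − t_pre_arrival ∈ (0, TO]
    Δw = −η₋ e^{+Δt/τ₋}  for Δt ∈ [−TO, 0)

All pre/post pairs within the timeout `TO` contribute (all-to-all pairing);
pre timing is measured at pulse arrival, i.e. after the conduction delay,
which keeps the rule causal on delayed edges. Parameters are per node; a
synapse is plastic iff its post-synaptic node has STDP enabled, and synapses
with inhibitory senders are excluded unless `include_inhibitory` is set
(whether inhibitory synapses should be plastic is left open by the model
source; excluding them is the conservative default). Nodes without STDP
parameters are provably untouched, and a disabled-STDP run is event-for-event
identical to a plasticity-free run.

## Output

`firing.csv` (one row per emission: `t,node,neuron,external`) and
`burning.csv` (one row per delivery:
`t_burn,node_burn,neuron_burn,node_fire,neuron_fire,t_fire,weight`, with
`t_burn = t_fire + τ` exactly) for the selected nodes of interest (NOIs;
empty = all). External emissions appear in `firing.csv` flagged
`external=1` for auditability. Floats are written with the shortest
round-tripping representation, so write→read→write is byte-stable. Sinks
flush every `S_b` records (the serialization buffer); with in-memory
recording off, engine memory is bounded by O(S_b + pending events + network
size) independent of the simulated time — the property behind long-duration
runs on small machines. Files are time-sorted within flush blocks; a global
sort utility is provided.

## Analysis metrics

PSTH over `[0, t_stop)` in fixed bins (1 ms default) of internal spikes
only; `max_PSTH` is the highest bin, `c_hi_PSTH` counts bins *strictly*
above `c_th` (default 100 spikes; the threshold boundary is excluded).
`mean_firing_rate` = internal spikes / (neurons × seconds). `FRd` is the
percentage rate loss between two logs of the same experiment, used to
quantify spike loss when a grid-based realization coarsens its step; the
event-driven engine has no step, so it only ever appears on oracle runs.

## Validation oracle

A clock-driven integrator realizes the same neuron rules on a fixed grid:
per-step passive decay, pulses applied at the first grid instant at or after
their exact arrival, latency countdown for active neurons. Emission times
are reconstructed at sub-grid precision from the countdown overshoot (the
precise-spiking device used by grid-based reference models), so its
dominant error is the O(dt) arrival rounding, shrinking linearly with `dt`.
On ≤10-neuron motifs with positive delays and unambiguous (suprathreshold)
triggers, the event engine matches the oracle's spike counts exactly and its
spike times within `2·dt` at `dt = 1e-4` ms. The oracle shares no code with
the engine's queue machinery and is used only in tests.

## Packaged benchmarks

**Benchmark A** re-creates a classic voltage-jump (delta-synapse) random
network: `n` = 4000/8000/16000 neurons, 80/20 E/I, out-degree 80 (2%
connection probability at the 4k base; larger scales keep the mean degree so
total counts scale with `n` — matching the published connection-count
table), driven by `n` Poisson sources at 5 Hz, 10 targets each, amplitude
calibrated to a ~10 Hz network rate. The underlying integrate-and-fire
parameterization (threshold −50 mV, reset −60 mV, τ = 20 ms, t_arp = 5 ms,
jumps +0.25/−2.25 mV) maps onto the LIFL state by the affine transform
`S = (V − V_reset)/(V_th − V_reset)`: jumps ±0.025/0.225, exponential decay
`D = 20` ms, initial states uniform on [0, 1). The latency curve stays at
the model defaults `a = 1, b = 0, c = 0.01` (max latency 100 ms); with the
calibrated drive this reproduces the published homogeneous-activity
statistics, the long near-threshold latencies supplying the asynchrony.

Working regimes derived from the 4k node:

* **HA** — identical to A1; asynchronous irregular firing at ~10 Hz.
* **SD** — fully connected (`k = 3999`), input reduced toward ~1 Hz;
  sparse activity with occasional synchronous discharges.
* **RD** — doubled connection probability (`k = 160`) and excitatory and
  inhibitory weights set to equal and opposite values, input adjusted toward
  ~50 Hz. The magnitude of the equal-and-opposite weights is not fixed by
  the regime's description; we use the benchmark's inhibitory magnitude
  (0.225), under which the regime shows the described frequent, regular,
  near-full-population discharges (~50 per second). With the excitatory
  magnitude (0.025) instead, spike latency smears recruitment over many
  milliseconds and the discharges fragment into partial waves — an
  instructive illustration of the latency feature's desynchronizing action,
  but not the described regime.

Input amplitudes per regime (HA 0.636, SD 0.482, RD 0.420) were fixed once
by the packaged calibration utility — bisection of a 1 s seeded run's mean
rate against the regime target (10/1/50 Hz) — and are frozen constants, so
benchmark runs never re-tune themselves. **Benchmark B** interconnects 14
nodes of the A1 type through a *synthetic* 14-region connectome
(lognormally spread counts summing to ~1e5, gamma tract lengths of tens of
mm, excitatory-to-excitatory): constructed surrogate numbers standing in for
tractography-derived data, useful for exercising multi-region mechanics,
not for anatomical inference.

## Problem sizes and what the tests show

The test suite exercises full-size A1/HA trials (4000 neurons, 1 s) and RD
trials (≈3×10⁷ deliveries per second of biological time) through the
compiled kernel; oracle comparisons run on ≤10-neuron motifs at
`dt = 1e-4` ms over ≤100 ms; plasticity checks use explicit motifs and
~100-neuron noisy networks. Passing tests demonstrate the engine's exactness
(event ordering, latency algebra, conservation, determinism) and the
benchmark statistics under the packaged synthetic conditions; they do not
certify behavior on tractography-derived anatomies, conductance-based
synapses, or regimes outside those calibrated here.

## Known limitations

* The RD regime reproduces the described discharge structure qualitatively,
  but its peak amplitudes run ~25% above and its discharge count ~80% above
  the published reference values; the weight magnitude and latency-curve
  adaptation underlying those values are not recoverable from the available
  description (see the calibration discussion above).
* STDP and bursting run only on the reference Python backend; large plastic
  networks are correspondingly slower.
* The multi-threaded partitioning scheme of the original tool is not
  implemented; the compiled kernel serves the same goal (throughput) with a
  simpler correctness story.
* External input amplitudes bypass synaptic weight tables by design; inputs
  cannot be made plastic.
* The clock-driven oracle supports tonic neurons and positive delays only.
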