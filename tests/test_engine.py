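"""Tests for the event-driven core: propagation, rescheduling, determinism,
backend equivalence, the clock-driven oracle, and bounded-memory flushing."""

import numpy as np
import pytest

from liflsim import run
from liflsim.engine import ConfigError, GlobalConfig
from liflsim.io import CsvSink, FIRING_HEADER
from liflsim.neuron import NeuronParams
from liflsim.oracle import clock_driven_oracle
from liflsim.stimuli import ConstantInputSpec, PoissonInputSpec, realize_stimuli

from conftest import make_motif, stream_batch

MOTIF_PARAMS = NeuronParams(a=1.0, b=0.0, c=0.01, D_exc=20.0, t_arp=2.0)


class TestPropagation:
    def test_single_path_latency(self):
        """A's spike reaches B exactly one latency after the input pulse."""
        net = make_motif({"A": 1, "B": 1}, [(0, 1, 0.5, 0.0)],
                         neuron_params=MOTIF_PARAMS)
        # S = 2 => t_f = 1 ms
        res = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0)])],
                  t_stop=10.0, backend="python", record_burning=True)
        assert res.internal_firing()["t"].tolist() == [2.0]
        internal = res.burning[res.burning["node_fire"] != "ext"]
        assert internal["t_burn"].tolist() == [2.0]

    def test_delay_additivity(self):
        net = make_motif({"A": 1, "B": 1}, [(0, 1, 0.5, 25.0)],
                         neuron_params=MOTIF_PARAMS)
        res = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0)])],
                  t_stop=40.0, backend="python", record_burning=True)
        internal = res.burning[res.burning["node_fire"] != "ext"]
        assert internal["t_burn"].tolist() == [2.0 + 25.0]
        assert internal["t_fire"].tolist() == [2.0]

    def test_burning_count_conservation(self, small_random_net):
        """Burning events = sum of out-degrees over emissions; inputs counted."""
        net = small_random_net
        stim = [PoissonInputSpec(target_node="A", n_ext=40, r_hz=60.0,
                                 t_end=300.0, amplitude=0.9, targets_per_source=4)]
        batches = realize_stimuli(stim, net, 13)
        res = run(net, batches, t_stop=300.0, backend="python")
        outdeg = net.out_degree()
        fired = res.internal_firing()
        # map (node, local) back to global index
        globals_ = np.array([
            net.offsets[net.node_index(r.node)] + r.neuron
            for r in fired.itertuples()
        ])
        # only deliveries scheduled before t_stop count
        assert res.counts["burning"] <= int(outdeg[globals_].sum())
        # zero-delay part is exact
        zero_delay = (net.synapses.delay == 0)
        zd_out = np.bincount(net.synapses.pre[zero_delay],
                             minlength=net.n_neurons)
        assert res.counts["burning"] >= int(zd_out[globals_].sum())
        n_inputs = int((batches[0].delivery_time < 300.0).sum())
        assert res.counts["input"] == n_inputs
        assert res.counts["firing"] == len(fired)


class TestRescheduling:
    def test_anticipation_moves_spike_earlier(self):
        net = make_motif({"A": 1}, [], neuron_params=MOTIF_PARAMS)
        base = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0)])],
                   t_stop=10.0, backend="python")
        t_plain = base.internal_firing()["t"].iloc[0]
        boosted = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0), (1.5, 0, 0.5)])],
                      t_stop=10.0, backend="python")
        t_boost = boosted.internal_firing()["t"].iloc[0]
        assert t_boost < t_plain

    def test_inhibition_cancels_spike(self):
        net = make_motif({"A": 1}, [], neuron_params=MOTIF_PARAMS)
        res = run(net, [stream_batch(net, "A", [(1.0, 0, 1.5), (1.2, 0, -1.0)])],
                  t_stop=10.0, backend="python")
        assert len(res.internal_firing()) == 0

    def test_zero_weight_pulse_preserves_spike_time(self):
        """No-input invariance: a 0-amplitude pulse must not move the spike."""
        net = make_motif({"A": 1}, [], neuron_params=MOTIF_PARAMS)
        base = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0)])],
                   t_stop=10.0, backend="python")
        poked = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0), (1.5, 0, 0.0)])],
                    t_stop=10.0, backend="python")
        t0 = base.internal_firing()["t"].iloc[0]
        t1 = poked.internal_firing()["t"].iloc[0]
        assert t1 == pytest.approx(t0, abs=1e-12)

    def test_refractory_pulse_discarded_then_accepted(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.01, D_exc=20.0, t_arp=5.0)
        net = make_motif({"A": 1}, [], neuron_params=p)
        # fire at t=2 (refractory until 7); pulse at 6.9 discarded, at 7.1 lands
        res = run(net, [stream_batch(net, "A", [(1.0, 0, 2.0), (6.9, 0, 2.0),
                                                (7.1, 0, 2.0)])],
                  t_stop=20.0, backend="python")
        times = res.internal_firing()["t"].tolist()
        assert times[0] == pytest.approx(2.0)
        assert len(times) == 2 and times[1] == pytest.approx(7.1 + 1.0)
        assert res.counts["discarded"] == 1


class TestDeterminismAndBackends:
    def test_identical_seeds_identical_logs(self, small_random_net):
        stim = [PoissonInputSpec(target_node="A", n_ext=40, r_hz=60.0,
                                 t_end=200.0, amplitude=0.9, targets_per_source=4)]
        b = realize_stimuli(stim, small_random_net, 21)
        r1 = run(small_random_net, b, t_stop=200.0, backend="python")
        r2 = run(small_random_net, b, t_stop=200.0, backend="python")
        assert r1.firing.equals(r2.firing)
        assert r1.counts == r2.counts

    def test_kernel_matches_python(self, small_random_net):
        """Compiled kernel and reference loop produce the same event log."""
        net = small_random_net
        rng = np.random.default_rng(5)
        S0 = rng.uniform(0, 1, net.n_neurons)
        stim = [PoissonInputSpec(target_node="A", n_ext=60, r_hz=60.0,
                                 t_end=400.0, amplitude=0.9, targets_per_source=5),
                PoissonInputSpec(target_node="B", n_ext=50, r_hz=40.0,
                                 t_end=400.0, amplitude=0.9, targets_per_source=5)]
        batches = realize_stimuli(stim, net, 11)
        r_py = run(net, batches, t_stop=400.0, init_S=S0, backend="python",
                   record_burning=True)
        r_kn = run(net, batches, t_stop=400.0, init_S=S0, backend="kernel",
                   record_burning=True)
        assert r_py.counts == r_kn.counts
        assert len(r_py.firing) == len(r_kn.firing)
        assert (r_py.firing["neuron"].values == r_kn.firing["neuron"].values).all()
        assert np.abs(r_py.firing["t"].values - r_kn.firing["t"].values).max() < 1e-9
        assert r_py.burning["t_burn"].tolist() == r_kn.burning["t_burn"].tolist()

    def test_lif_mode_fires_without_latency(self):
        net = make_motif({"A": 1}, [], neuron_params=MOTIF_PARAMS)
        cfg = GlobalConfig(t_stop=10.0, N_m="LIF")
        res = run(net, [stream_batch(net, "A", [(1.0, 0, 1.5)])], cfg,
                  backend="python")
        assert res.internal_firing()["t"].tolist() == [1.0]


class TestOracleEquivalence:
    def _feedforward_motif(self, seed):
        """External drive -> layer A -> layer B, unambiguous triggers."""
        rng = np.random.default_rng(seed)
        syn = []
        for j in range(4, 8):  # each B neuron: 2 strong delayed inputs from A
            for i in rng.choice(4, 2, replace=False):
                syn.append((int(i), j, 1.5, float(rng.uniform(0.5, 3.0))))
        return make_motif({"A": 4, "B": 4}, syn, neuron_params=MOTIF_PARAMS)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_event_driven_matches_clock_driven(self, seed):
        net = self._feedforward_motif(seed)
        rng = np.random.default_rng(100 + seed)
        events = [(float(t), int(rng.integers(0, 4)), float(rng.uniform(1.2, 1.8)))
                  for t in np.sort(rng.uniform(0, 80, 30))]
        batch = stream_batch(net, "A", events)
        dt = 1e-4
        res = run(net, [batch], t_stop=100.0, backend="python")
        ev_t = res.internal_firing()["t"].to_numpy()
        or_t, _ = clock_driven_oracle(net, [batch], dt=dt, t_stop=100.0)
        assert len(ev_t) == len(or_t)          # spike counts exactly equal
        assert len(ev_t) > 20                  # the motif is actually active
        assert np.abs(ev_t - np.sort(np.asarray(or_t))).max() <= 2 * dt

    def test_timing_error_scales_with_dt(self):
        """Single suprathreshold pulse: oracle error is O(dt)."""
        net = make_motif({"A": 1, "B": 1}, [(0, 1, 0.2, 1.0)],
                         neuron_params=MOTIF_PARAMS)
        # off-grid pulse: S = 1.9 => latency 1/0.9 ms
        batch = stream_batch(net, "A", [(1.0003, 0, 1.9)])
        exact = 1.0003 + 1.0 / 0.9
        errs = {}
        for dt in (1e-2, 1e-3):
            t, _ = clock_driven_oracle(net, [batch], dt=dt, t_stop=10.0)
            errs[dt] = abs(t[0] - exact)
        assert errs[1e-2] <= 1e-2
        assert errs[1e-3] <= 1e-3
        assert errs[1e-3] < errs[1e-2] / 5     # ~linear in dt

    def test_zero_input_is_silent(self):
        net = make_motif({"A": 2}, [(0, 1, 0.5, 1.0)], neuron_params=MOTIF_PARAMS)
        t, _ = clock_driven_oracle(net, [], dt=1e-3, t_stop=50.0)
        assert len(t) == 0


class TestFlushAndMemory:
    def _driven_net(self):
        net = make_motif({"A": 4}, [], neuron_params=MOTIF_PARAMS)
        return net

    def test_flush_blocks_and_completeness(self, tmp_path):
        net = self._driven_net()
        spec = ConstantInputSpec(target_node="A", n_ext=1, interval=1.0,
                                 t_start=0.0, t_end=625.0, amplitude=2.0,
                                 targets_per_source=4)
        batches = realize_stimuli([spec], net, 0)
        sink = CsvSink(tmp_path / "firing.csv", FIRING_HEADER, S_b=1000)
        cfg = GlobalConfig(t_stop=625.0, S_b=1000)
        res = run(net, batches, cfg, firing_sink=sink, record_firing=False,
                  backend="python")
        sink.close()
        lines = (tmp_path / "firing.csv").read_text().splitlines()
        n_rows = len(lines) - 1
        # internal emissions + external source emissions all present
        assert n_rows == res.counts["firing"] + 625
        assert sink.n_flushes >= 2
        assert sink.max_buffered <= 1000

    def test_peak_buffer_independent_of_duration(self, tmp_path):
        net = self._driven_net()
        peaks = []
        for t_stop in (400.0, 1600.0):
            spec = ConstantInputSpec(target_node="A", n_ext=1, interval=1.0,
                                     t_start=0.0, t_end=t_stop, amplitude=2.0,
                                     targets_per_source=4)
            batches = realize_stimuli([spec], net, 0)
            sink = CsvSink(tmp_path / f"f{t_stop}.csv", FIRING_HEADER, S_b=200)
            cfg = GlobalConfig(t_stop=t_stop, S_b=200)
            run(net, batches, cfg, firing_sink=sink, record_firing=False,
                backend="python")
            sink.close()
            peaks.append(sink.max_buffered)
        assert peaks[0] == peaks[1] == 200

    def test_empty_simulation_headers_only(self, tmp_path):
        net = self._driven_net()
        sink = CsvSink(tmp_path / "firing.csv", FIRING_HEADER, S_b=10)
        run(net, [], t_stop=100.0, firing_sink=sink, record_firing=False,
            backend="python")
        sink.close()
        assert (tmp_path / "firing.csv").read_text() == "t,node,neuron,external\n"


class TestValidation:
    def test_zero_delay_cycle_without_refractoriness_rejected(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.01, D_exc=20.0, t_arp=0.0)
        net = make_motif({"A": 2}, [(0, 1, 0.5, 0.0), (1, 0, 0.5, 0.0)],
                         neuron_params=p)
        with pytest.raises(ConfigError, match="zero-delay"):
            run(net, [], t_stop=10.0, backend="python")

    def test_zero_delay_chain_is_fine(self):
        p = NeuronParams(a=1.0, b=0.0, c=0.01, D_exc=20.0, t_arp=0.0)
        net = make_motif({"A": 2}, [(0, 1, 0.5, 0.0)], neuron_params=p)
        run(net, [], t_stop=10.0, backend="python")

    def test_unknown_noi_rejected(self):
        net = make_motif({"A": 2}, [], neuron_params=MOTIF_PARAMS)
        with pytest.raises(KeyError):
            run(net, [], t_stop=10.0, noi=["nope"], backend="python")

    def test_kernel_refuses_plasticity(self):
        from liflsim.stdp import StdpParams
        net = make_motif({"A": 2}, [(0, 1, 0.5, 0.0)],
                         neuron_params=MOTIF_PARAMS,
                         stdp={"A": StdpParams()})
        with pytest.raises(ConfigError):
            run(net, [], t_stop=10.0, backend="kernel")
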