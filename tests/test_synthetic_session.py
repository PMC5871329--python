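"""Generator correctness: attention process, Poisson statistics, pupil, determinism."""

import numpy as np
import pytest

from attnorm.attention_model import attention_weight
from attnorm.synthetic_session import (
    GroundTruthNeuron,
    PupilGroundTruth,
    SessionConfig,
    draw_attention_trace,
    default_neuron_population,
    rate_function,
    simulate_neuron_bin_counts,
    simulate_pupil_trace,
    simulate_session,
    simulate_spike_train,
)
from attnorm.task_core import Condition, Cue, Trial

V8, V4, V2, V0 = Cue("v8", 8), Cue("v4", 4), Cue("v2", 2), Cue("v0", 0)


class TestAttentionTrace:
    def test_single_cue_attended_throughout(self, rng):
        trace = draw_attention_trace(Condition(None, V4), 5.0, 1.0, rng)
        assert trace.segments == [(0.0, 1000.0, "right")]
        assert not trace.shifted

    def test_double_cue_attends_higher(self, rng):
        trace = draw_attention_trace(Condition(V2, V8), 5.0, 1.0, rng)
        assert trace.segments == [(0.0, 1000.0, "right")]

    def test_d_zero_never_shifts(self, rng):
        cond = Condition(V8, V2, "right")  # lower cue perturbed
        assert not any(
            draw_attention_trace(cond, 5.0, 0.0, rng).shifted for _ in range(500)
        )

    def test_c0_d2_always_shifts(self, rng):
        cond = Condition(V8, V2, "right")
        traces = [draw_attention_trace(cond, 0.0, 2.0, rng) for _ in range(500)]
        assert all(t.shifted for t in traces)
        # the switch happens at perturbation onset + default 100 ms latency
        assert traces[0].segments == [(0.0, 300.0, "left"), (300.0, 1000.0, "right")]

    def test_higher_cue_perturbation_never_shifts(self, rng):
        cond = Condition(V8, V2, "left")
        assert not any(
            draw_attention_trace(cond, 0.0, 2.0, rng).shifted for _ in range(500)
        )

    def test_c0_d1_shifts_half_the_time(self, rng):
        cond = Condition(V8, V2, "right")
        n = 10_000
        frac = np.mean(
            [draw_attention_trace(cond, 0.0, 1.0, rng).shifted for _ in range(n)]
        )
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_shift_fraction_follows_sigmoid_across_value_grid(self, rng):
        """Empirical shift probability matches d/(1+exp(c|dV|/8)) per pair."""
        c, d, n = 4.0, 1.5, 2000
        for vh, vl in [(8, 4), (8, 0), (4, 2), (2, 1), (1, 0)]:
            cond = Condition(Cue("h", vh), Cue("l", vl), "right")
            frac = np.mean(
                [draw_attention_trace(cond, c, d, rng).shifted for _ in range(n)]
            )
            a = float(attention_weight((vh - vl) / 8.0, c, d))
            assert abs(frac - a) < 4 * np.sqrt(a * (1 - a) / n) + 1e-9


class TestSpikeTrains:
    def test_zero_rate_produces_no_spikes(self, rng):
        neuron = GroundTruthNeuron("z", tuning="non-visual", baseline_rate=0.0)
        trial = Trial(0, 0, "S:v8|-")
        trace = draw_attention_trace(Condition(V8, None), 1.0, 1.0, rng)
        assert simulate_spike_train(neuron, trial, trace, rng).size == 0

    def test_baseline_poisson_mean(self, rng):
        """Baseline-only neuron: mean count over the pre-cue second is rate x time."""
        neuron = GroundTruthNeuron("b", tuning="non-visual", baseline_rate=10.0)
        trace = draw_attention_trace(Condition(V8, None), 1.0, 1.0, rng)
        trial = Trial(0, 0, "S:v8|-")
        counts = []
        for _ in range(3000):
            t = simulate_spike_train(neuron, trial, trace, rng)
            counts.append(np.count_nonzero((t >= -1000) & (t < 0)))
        sem = np.sqrt(10.0 / 3000)
        assert abs(np.mean(counts) - 10.0) < 4 * sem

    def test_spike_times_sorted_and_in_range(self, rng):
        neuron = GroundTruthNeuron("s")
        trace = draw_attention_trace(Condition(V8, None), 1.0, 1.0, rng)
        t = simulate_spike_train(neuron, Trial(0, 0, "S:v8|-"), trace, rng)
        assert np.all(np.diff(t) >= 0)
        assert t.min() >= -2000 and t.max() < 1200

    def test_psth_converges_to_programmed_rate(self, rng):
        """Empirical bin means converge to the rate function (sup-norm, MC tolerance)."""
        neuron = GroundTruthNeuron("p", tuning="positive")
        cond = Condition(V8, None)
        n = 10_000
        edges, counts, _ = simulate_neuron_bin_counts(neuron, [cond] * n, rng)
        trace = draw_attention_trace(cond, neuron.c, neuron.d, rng)
        _, rate = rate_function(neuron, trace)
        emp = counts.mean(axis=0) / 0.01  # 10 ms bins
        # per-bin MC error: sd = sqrt(rate/0.01)/sqrt(n); allow 5 sigma sup-norm
        tol = 5 * np.sqrt(np.maximum(rate, 1.0) / 0.01 / n)
        assert np.all(np.abs(emp - rate) < tol)

    def test_bin_counts_match_spike_train_distribution(self, rng):
        """The vectorized count path and the spike-train path agree in mean."""
        neuron = GroundTruthNeuron("e", tuning="positive", d=0.0)
        cond = Condition(V8, V0, "right")
        n = 4000
        _, counts, _ = simulate_neuron_bin_counts(neuron, [cond] * n, rng)
        trace = draw_attention_trace(cond, neuron.c, 0.0, rng)
        trial = Trial(0, 0, cond.condition_id)
        direct = []
        for _ in range(300):
            t = simulate_spike_train(neuron, trial, trace, rng)
            direct.append(np.count_nonzero((t >= 200) & (t < 1000)))
        win = counts[:, (np.arange(320) * 10 - 2000 >= 200) & (np.arange(320) * 10 - 2000 < 1000)]
        m1, m2 = win.sum(axis=1).mean(), np.mean(direct)
        pooled_sem = np.sqrt(win.sum(axis=1).var() / n + np.var(direct) / 300)
        assert abs(m1 - m2) < 5 * pooled_sem


class TestPupil:
    def test_noise_free_value_scaling(self):
        gt = PupilGroundTruth(noise_sd=0.0, amplitude_per_drop=5.0)
        rng = np.random.default_rng(0)
        trial = Trial(0, 0, "S:v8|-")
        t, tr8 = simulate_pupil_trace(trial, 8.0, gt, rng)
        _, tr0 = simulate_pupil_trace(trial, 0.0, gt, rng)
        post = (t >= 3000) & (t < 4000)  # the 1 s after cue offset
        assert np.isclose(tr8[post].mean() - tr0[post].mean(), 8 * 5.0)

    def test_double_cue_equals_single_higher(self):
        """Winner-take-all pupil: 8-vs-2 pair is identical to single 8 in expectation."""
        gt = PupilGroundTruth(noise_sd=0.0)
        rng = np.random.default_rng(0)
        trial = Trial(0, 0, "x")
        _, a = simulate_pupil_trace(trial, 8.0, gt, rng)
        _, b = simulate_pupil_trace(trial, 8.0, gt, rng)
        assert np.array_equal(a, b)

    def test_sampling_rate(self):
        gt = PupilGroundTruth()
        t, y = simulate_pupil_trace(Trial(0, 0, "x"), 4.0, gt, np.random.default_rng(0))
        assert np.allclose(np.diff(t), 2.0)  # 500 Hz
        assert t.size == y.size == 2250


class TestSession:
    def test_block_count(self, tiny_session):
        assert len(tiny_session.trials) == 2 * 85
        assert tiny_session.trials["completed"].all()

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SessionConfig(
            n_blocks=1,
            neurons=default_neuron_population(5, 1, 1, 0, 0),
            include_pupil=False,
        )
        for d in ("a", "b"):
            simulate_session(cfg, 99).save(tmp_path / d)
        for f in ("trials.csv", "spikes.csv", "neurons_truth.csv", "conditions.csv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_truth_roundtrip(self, tiny_session, tmp_path):
        from attnorm.synthetic_session import SessionData

        tiny_session.save(tmp_path)
        loaded = SessionData.load(tmp_path)
        assert list(loaded.neurons["neuron_id"]) == list(
            tiny_session.neurons["neuron_id"]
        )
        assert np.allclose(loaded.neurons["c"], tiny_session.neurons["c"])
        assert len(loaded.spikes) == len(tiny_session.spikes)

    def test_invalid_config_rejected(self):
        cfg = SessionConfig(n_blocks=0)
        with pytest.raises(ValueError, match="n_blocks"):
            simulate_session(cfg, 1)
        cfg = SessionConfig(incomplete_rate=1.5)
        with pytest.raises(ValueError, match="incomplete_rate"):
            simulate_session(cfg, 1)

    def test_incomplete_trials_marked_and_conditions_repeated(self):
        cfg = SessionConfig(
            n_blocks=1,
            neurons=[],
            incomplete_rate=0.2,
            include_pupil=False,
            include_spikes=False,
        )
        s = simulate_session(cfg, 3)
        completed = s.trials[s.trials["completed"]]
        assert len(completed) == 85  # every condition still completed once
        assert (~s.trials["completed"]).sum() > 0
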