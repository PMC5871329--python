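"""PSTH machinery, FDR control, modulation windows, MI, consistency, controls."""

import numpy as np
import pandas as pd
import pytest

from attnorm import perturbation_analysis as pa
from attnorm.task_core import condition_lookup
from conftest import make_deterministic_spikes


class TestPsth:
    def test_single_spike_kernel(self):
        """One spike at 500 ms reads 20 spikes/s in every covering 50 ms window."""
        spikes = pd.DataFrame({"neuron_id": "n0", "trial_id": 0, "t_ms": [500.0]})
        trials = pd.DataFrame(
            {"trial_id": [0], "condition_id": ["x"], "completed": [True]}
        )
        psth = pa.compute_psth(spikes, trials, "n0", [0], baseline=0.0)
        covered = np.abs(psth.bin_centers - 500.0) < 25.0
        assert np.allclose(psth.rates[covered], 20.0)
        assert np.allclose(psth.rates[~covered], 0.0)

    def test_count_conservation_at_step_50(self):
        """Non-overlapping 50 ms bins: sum(rate)*0.05 recovers the spike count."""
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(-175.0, 975.0, size=200))
        spikes = pd.DataFrame({"neuron_id": "n0", "trial_id": 0, "t_ms": t})
        trials = pd.DataFrame(
            {"trial_id": [0], "condition_id": ["x"], "completed": [True]}
        )
        psth = pa.compute_psth(spikes, trials, "n0", [0], step_ms=50.0, baseline=0.0)
        assert np.isclose(psth.rates.sum() * 0.05, 200)

    def test_empty_group_rejected(self):
        spikes = pd.DataFrame(columns=["neuron_id", "trial_id", "t_ms"])
        trials = pd.DataFrame(columns=["trial_id", "condition_id", "completed"])
        with pytest.raises(ValueError):
            pa.compute_psth(spikes, trials, "n0", [])


class TestPointwiseTest:
    def test_label_swap_symmetry(self, rng):
        a = rng.poisson(5, size=(20, 30)).astype(float)
        b = rng.poisson(7, size=(25, 30)).astype(float)
        assert np.allclose(
            pa.pointwise_rotation_test(a, b), pa.pointwise_rotation_test(b, a)
        )

    def test_degenerate_bins_get_p_one(self):
        a = np.ones((5, 3))
        b = np.ones((4, 3))
        assert np.all(pa.pointwise_rotation_test(a, b) == 1.0)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        """Step-up by hand: 0.01,0.02,0.03 rejected at q=0.05; 0.5 kept."""
        mask = pa.benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_all_tiny_all_rejected(self):
        assert pa.benjamini_hochberg(np.full(10, 0.001)).all()

    def test_empty_and_invalid(self):
        assert pa.benjamini_hochberg(np.array([])).size == 0
        with pytest.raises(ValueError):
            pa.benjamini_hochberg(np.array([1.2]))

    def test_matches_brute_force_step_up(self, rng):
        """Mask equals the sorted-threshold definition on random p-vectors."""
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.uniform(0, 1, size=m)
            p[: m // 4] = rng.uniform(0, 0.02, size=m // 4)
            mask = pa.benjamini_hochberg(p, q=0.05)
            order = np.argsort(p)
            sp = p[order]
            ok = np.nonzero(sp <= 0.05 * np.arange(1, m + 1) / m)[0]
            expected = np.zeros(m, dtype=bool)
            if ok.size:
                expected[p <= sp[ok[-1]]] = True
            assert np.array_equal(mask, expected)


class TestModulationWindow:
    centers = np.arange(-200.0, 1001.0, 10.0)

    def _pvals(self, sig_ranges):
        p = np.full(self.centers.size, 0.5)
        for lo, hi in sig_ranges:
            p[(self.centers >= lo) & (self.centers <= hi)] = 0.001
        return p

    def test_qualifying_run_returned(self):
        w = pa.find_modulation_window(self.centers, self._pvals([(300, 550)]))
        assert w == (300.0, 550.0)

    def test_short_run_absent(self):
        assert pa.find_modulation_window(self.centers, self._pvals([(300, 440)])) is None

    def test_longest_run_wins(self):
        w = pa.find_modulation_window(
            self.centers, self._pvals([(250, 460), (600, 890)])
        )
        assert w == (600.0, 890.0)

    def test_restricted_to_search_interval(self):
        """Significance before the perturbation onset does not count."""
        assert pa.find_modulation_window(self.centers, self._pvals([(-100, 150)])) is None


class TestIndicesAndZscores:
    def test_modulation_index_values(self):
        assert pa.modulation_index(1, 1) == 0
        assert pa.modulation_index(3, 1) == 0.5
        assert pa.modulation_index(1, 3) == -0.5
        with pytest.raises(pa.UndefinedMIError):
            pa.modulation_index(0, 0)

    def test_zscore_properties(self, rng):
        a = rng.normal(10, 2, 50)
        b = rng.normal(12, 2, 50)
        z1 = pa.zscore_modulation(a, b)
        z2 = pa.zscore_modulation(a + 100, b + 100)
        assert np.allclose(z1, z2)
        ze = pa.zscore_modulation(a, a)
        assert np.isclose(ze[0], ze[1])
        with pytest.raises(ValueError):
            pa.zscore_modulation(np.ones(5), np.ones(5))


class TestConsistency:
    def _setup(self, conditions, pert_level):
        """Single-cue levels value/8; unperturbed pairs at higher; perturbed at pert_level."""
        lookup = condition_lookup(conditions)
        rows, rates = [], {}
        tid = 0
        for rep in range(3):
            for c in conditions:
                if c.is_single:
                    r = 10 * c.single_cue.value / 8.0 + 2
                elif not c.is_perturbed:
                    r = 10 * c.higher_value / 8.0 + 2
                elif c.perturbed_target == "lower":
                    r = pert_level(c)
                else:
                    r = 10 * c.higher_value / 8.0 + 2
                rows.append(
                    {"trial_id": tid, "condition_id": c.condition_id, "completed": True}
                )
                rates[tid] = r
                tid += 1
        trials = pd.DataFrame(rows)
        spikes = make_deterministic_spikes(rates, window=(200, 1000))
        return spikes, trials

    def test_shift_toward_single_cue_is_consistent(self, conditions):
        spikes, trials = self._setup(
            conditions, lambda c: 10 * c.lower_value / 8.0 + 2
        )
        assert (
            pa.classify_consistency(spikes, trials, conditions, "n0", (200, 1000))
            == "consistent"
        )

    def test_shift_away_is_inconsistent(self, conditions):
        spikes, trials = self._setup(
            conditions, lambda c: 10 * c.higher_value / 8.0 + 8
        )
        assert (
            pa.classify_consistency(spikes, trials, conditions, "n0", (200, 1000))
            == "inconsistent"
        )


class TestFirstBlockControl:
    def test_small_blocks_balanced_identity(self, tiny_session, conditions):
        out = pa.first_block_control(tiny_session.trials, conditions, 5, n=50)
        lookup = condition_lookup(conditions)
        kept_first = (
            tiny_session.trials.groupby("block_index").head(50)["trial_id"]
        )
        assert set(out["trial_id"]).issubset(set(kept_first))
        pairs = {}
        for row in out.itertuples(index=False):
            c = lookup[row.condition_id]
            if c.is_double:
                key = (c.left_cue.value, c.right_cue.value)
                pairs.setdefault(key, [0, 0])[int(c.is_perturbed)] += 1
        for key, (unpert, pert) in pairs.items():
            assert unpert == pert, key

    def test_reproducible_given_seed(self, tiny_session, conditions):
        a = pa.first_block_control(tiny_session.trials, conditions, 11)
        b = pa.first_block_control(tiny_session.trials, conditions, 11)
        assert a["trial_id"].tolist() == b["trial_id"].tolist()


def test_strongly_shifting_neuron_is_detected(conditions):
    """A d=2, c=0 generator neuron shows a modulation window after 300 ms,
    positive MI, z_high > z_low, and consistent classification."""
    from attnorm.synthetic_session import GroundTruthNeuron
    from attnorm.studies import _mini_session

    neuron = GroundTruthNeuron(
        "m", tuning="positive", baseline_rate=10.0, value_gain=25.0, c=0.0, d=2.0
    )
    spikes, trials, conds = _mini_session(neuron, 6, np.random.default_rng(5))
    res = pa.analyze_modulation(spikes, trials, conds, "m")
    assert res.modulated
    assert res.window[0] >= 290.0  # shift latency: nothing before onset + 100 ms
    assert res.mi > 0.05
    assert res.z_high > res.z_low
    assert res.consistency == "consistent"


def test_no_shift_neuron_modulation_is_rare(conditions):
    """With d=0 the rotation groups are exchangeable; contrasts come out null."""
    from attnorm.synthetic_session import GroundTruthNeuron
    from attnorm.studies import _mini_session
    from scipy import stats as sstats

    hits = 0
    for seed in range(8):
        neuron = GroundTruthNeuron(
            "q", tuning="positive", baseline_rate=10.0, value_gain=20.0, d=0.0
        )
        spikes, trials, conds = _mini_session(neuron, 4, np.random.default_rng(seed))
        res = pa.analyze_modulation(spikes, trials, conds, "q")
        hits += res.modulated
    assert hits <= 2  # contiguity rule is anticonservative but should stay rare
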