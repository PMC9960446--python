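"""Trial-type significance, subensemble assignment, outcome/port analyses."""

import numpy as np
import pytest

from caensembles.subtypes import (
    SubtypeConfig,
    UNTESTABLE,
    previous_outcome_modulation,
    port_preference,
    subtype_poking,
    subtype_population,
    subtype_reward,
    trialtype_significance,
)
from caensembles.synthetic import NeuronSpec, SessionConfig, simulate_session
from caensembles.ensembles import ClassifierConfig, classify_population


class TestTrialTypeSignificance:
    def test_zero_responses_not_significant(self, rng):
        flag = trialtype_significance(np.zeros(10), rng.normal(size=50), rng=rng)
        assert flag is False

    def test_alpha_one_always_true(self, rng):
        assert trialtype_significance(np.zeros(5), np.zeros(20), alpha=1.0) is True

    def test_too_few_trials_untestable_never_false(self):
        assert trialtype_significance(np.array([5.0, 5.0]), np.zeros(20)) == UNTESTABLE

    def test_strong_response_detected_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trial_means = rng.normal(5.0, 1.0, 30)
            baseline = rng.normal(0.0, 1.0, 100)
            hits += trialtype_significance(trial_means, baseline, rng=rng) is True
        assert hits >= 19


class TestSubtypeRules:
    def _responses(self, flags):
        import pandas as pd

        return pd.DataFrame(
            [(0, tt, 1.0, sig) for tt, sig in flags.items()],
            columns=["neuron_id", "trial_type", "mean_z", "significant"],
        )

    def test_correct_only_is_attention_like(self):
        r = self._responses({"correct": True, "incorrect": False})
        assert subtype_poking(r, 0, np.array([0.3])) == "Attention-like"

    def test_outcome_independent_pre_onset_is_trigger_like(self):
        r = self._responses({"correct": True, "incorrect": True})
        assert subtype_poking(r, 0, np.array([-0.4, -0.2, 0.1])) == "Trigger-like"

    def test_post_onset_outcome_independent_is_visual_stim(self):
        r = self._responses({"correct": True, "incorrect": True})
        assert subtype_poking(r, 0, np.array([0.3, 0.5, 0.8])) == "Visual-stim"

    def test_no_significant_window_is_unclassified(self):
        r = self._responses({"correct": False, "incorrect": False})
        assert subtype_poking(r, 0, np.array([-0.1])) == "Unclassified"
        assert subtype_reward(r, 0) == "Unclassified"

    def test_reward_rules(self):
        both = self._responses({"correct": True, "incorrect": True, "licking_only": False})
        assert subtype_reward(both, 0) == "Reward-pursuing"
        only = self._responses({"correct": True, "incorrect": False, "licking_only": False})
        assert subtype_reward(only, 0) == "Rewarded"

    def test_untestable_propagates_to_unclassified(self):
        r = self._responses({"correct": True, "incorrect": UNTESTABLE})
        assert subtype_poking(r, 0, np.array([-0.1])) == "Unclassified"


class TestSubtypeRecovery:
    def test_partition_and_accuracy_on_planted_population(
        self, planted_session, planted_labels
    ):
        """Planted subtypes (amplitude 5, noise SD 1, 100 trials) recover at
        >= 85% accuracy, and every ON neuron gets exactly one subtype."""
        bundle, truth = planted_session
        sub = subtype_population(
            bundle, planted_labels, SubtypeConfig(n_perm=500, seed=2)
        )
        assert sub.groupby(["neuron_id", "behavior"]).size().eq(1).all()
        valid = {
            "poking": {"Trigger-like", "Attention-like", "Visual-stim", "Unclassified"},
            "reward": {"Reward-pursuing", "Rewarded", "Unclassified"},
        }
        for behavior, group in sub.groupby("behavior"):
            assert set(group.subtype) <= valid[behavior]
        tmap = dict(zip(truth.neuron_id, truth.tuning_class))
        planted = sub[sub.neuron_id < 40]
        accuracy = np.mean(
            [tmap[r.neuron_id] == r.subtype for r in planted.itertuples()]
        )
        assert accuracy >= 0.85


class TestPreviousOutcome:
    def test_first_trial_excluded_from_bookkeeping(self, rng):
        outcomes = ["correct"] * 10 + ["incorrect"] * 10
        resp = rng.normal(size=20)
        res = previous_outcome_modulation(resp, outcomes, n_perm=200, seed=0)
        assert res.n_after_correct + res.n_after_incorrect == len(outcomes) - 1

    def test_symmetric_fixture_has_no_effect(self):
        diffs, ps = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            outcomes = list(rng.choice(["correct", "incorrect"], 60))
            resp = rng.normal(size=60)
            res = previous_outcome_modulation(resp, outcomes, n_perm=300, seed=seed)
            diffs.append(res.difference)
            ps.append(res.p_value)
        assert abs(np.mean(diffs)) < 0.3
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2  # ~5% nominal false-positive rate

    def test_planted_gain_detected(self):
        """A 1.5x gain after correct trials is detected at alpha=0.05 in >= 90%
        of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            outcomes = list(rng.choice(["correct", "incorrect"], 80))
            base = rng.normal(1.0, 0.2, 80)
            prev_correct = np.array([False] + [o == "correct" for o in outcomes[:-1]])
            resp = np.where(prev_correct, base * 1.5, base)
            res = previous_outcome_modulation(resp, outcomes, n_perm=500, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 18

    def test_split_half_slice_restricts_trials(self, rng):
        outcomes = ["correct", "incorrect"] * 30
        resp = rng.normal(size=60)
        full = previous_outcome_modulation(resp, outcomes, n_perm=100, seed=0)
        half = previous_outcome_modulation(
            resp, outcomes, n_perm=100, seed=0, trial_slice=slice(0, 30)
        )
        assert half.n_after_correct + half.n_after_incorrect < (
            full.n_after_correct + full.n_after_incorrect
        )

    def test_insufficient_trials_untestable(self):
        out = previous_outcome_modulation(
            np.ones(4), ["correct", "correct", "correct", "incorrect"], seed=0
        )
        assert out == UNTESTABLE


class TestPortPreference:
    def test_zero_response_neuron_has_no_preference(self):
        sides = ["left", "right"] * 10
        assert port_preference(np.zeros(20), sides, seed=0) == "none"

    def test_planted_left_bias_detected(self, rng):
        sides = np.array(["left", "right"] * 20)
        resp = np.where(sides == "left", 2.0, 1.0) + rng.normal(0, 0.2, 40)
        assert port_preference(resp, sides, seed=1) == "left"

    def test_unbiased_fixture_mostly_none(self):
        outcomes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sides = rng.choice(["left", "right"], 40)
            resp = rng.normal(1.0, 0.5, 40)
            outcomes.append(port_preference(resp, sides, seed=seed))
        assert np.mean([o == "none" for o in outcomes]) >= 0.85

    def test_one_sided_session_untestable(self):
        assert port_preference(np.ones(6), ["left"] * 6, seed=0) == UNTESTABLE
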