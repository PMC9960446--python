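"""Generator invariants: determinism, vector/table consistency, planted effects."""

import numpy as np
import pytest

from caensembles.containers import BEHAVIOR_POKING, BEHAVIOR_REWARD, seconds_to_frames
from caensembles.ensembles import minmax_scale, similarity
from caensembles.synthetic import (
    NeuronSpec,
    SessionConfig,
    TrackedPairConfig,
    TransientKernel,
    simulate_session,
    simulate_tracked_pair,
)


class TestValidation:
    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="n_trials"):
            SessionConfig(n_trials=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_correct": 1.2},
            {"p_correct": 0.8, "p_incorrect": 0.3},
            {"frame_rate": 0.0},
            {"poking_window": (1.5, -0.5)},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SessionConfig(**kwargs)

    def test_empty_spec_list_rejected(self):
        with pytest.raises(ValueError, match="NeuronSpec"):
            simulate_session(SessionConfig(n_trials=5), [])

    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            TransientKernel(rise_time=2.0, decay_time=1.0)
        k = TransientKernel().evaluate(10.0)
        assert k.max() == pytest.approx(1.0)
        assert (k >= 0).all()


def test_identical_seeds_give_identical_sessions():
    config = SessionConfig(n_trials=20, seed=42)
    specs = [NeuronSpec("Trigger-like"), NeuronSpec("Other", response_amplitude=0.0)]
    b1, t1 = simulate_session(config, specs)
    b2, t2 = simulate_session(config, specs)
    assert np.array_equal(b1.traces, b2.traces)
    assert b1.trials.equals(b2.trials)
    assert all(np.array_equal(b1.behaviors[k], b2.behaviors[k]) for k in b1.behaviors)
    assert b1.rois.equals(b2.rois)


def test_traces_are_nonnegative_dff(small_session):
    bundle, _ = small_session
    assert bundle.traces.min() >= 0.0


def test_behavior_vectors_round_trip_to_trial_table(small_session):
    """Every poke/reward epoch in the table appears in the vector and vice versa."""
    bundle, _ = small_session
    fr = bundle.frame_rate
    pre = seconds_to_frames(-0.5, fr)
    starts = np.flatnonzero(np.diff(np.concatenate(([0], bundle.behaviors[BEHAVIOR_POKING]))) == 1)
    pokes = np.sort(
        bundle.trials.loc[bundle.trials.poke_onset_frame >= 0, "poke_onset_frame"].to_numpy()
    )
    assert np.array_equal(starts - pre, pokes)
    rstarts = np.flatnonzero(np.diff(np.concatenate(([0], bundle.behaviors[BEHAVIOR_REWARD]))) == 1)
    rewards = np.sort(
        bundle.trials.loc[bundle.trials.reward_frame >= 0, "reward_frame"].to_numpy()
    )
    assert np.array_equal(rstarts - pre, rewards)


def test_untuned_neuron_uncorrelated_with_behavior():
    """Amplitude-0 neurons are pure noise: correlation with the poking vector
    averages to ~0 over seeds (within 2 SE)."""
    corrs = []
    for seed in range(25):
        config = SessionConfig(n_trials=15, seed=seed)
        bundle, _ = simulate_session(config, [NeuronSpec("Other", response_amplitude=0.0)])
        corrs.append(
            np.corrcoef(bundle.traces[0], bundle.behaviors[BEHAVIOR_POKING])[0, 1]
        )
    corrs = np.asarray(corrs)
    se = corrs.std(ddof=1) / np.sqrt(len(corrs))
    assert abs(corrs.mean()) < 2 * se + 1e-3


def test_rewarded_neuron_elevated_only_in_correct_reward_windows():
    config = SessionConfig(n_trials=60, seed=2, noise_sd=1e-9)
    bundle, _ = simulate_session(
        config, [NeuronSpec("Rewarded", response_amplitude=5.0)]
    )
    trace = bundle.traces[0]
    rew = bundle.behaviors[BEHAVIOR_REWARD].astype(bool)
    inside = trace[rew].mean()
    outside = trace[~rew].mean()
    assert inside > outside + 1.0
    # incorrect-trial windows stay at baseline (far below the planted response;
    # "outside" itself is inflated by decay tails past the annotated window)
    fr = bundle.frame_rate
    r0, r1 = (seconds_to_frames(t, fr) for t in config.reward_window)
    inc = bundle.trials.query("outcome == 'incorrect'")["choice_frame"].to_numpy()
    vals = [trace[c + r0 : c + r1 + 1].mean() for c in inc]
    assert np.mean(vals) < 0.2 * inside


def test_amplitude_monotone_in_matched_similarity():
    """Raising planted amplitude never lowers the matched-behavior similarity
    (averaged over a seed ensemble)."""
    mean_sims = []
    for amp in (0.0, 2.0, 5.0):
        sims = []
        for seed in range(8):
            config = SessionConfig(n_trials=25, seed=seed)
            bundle, _ = simulate_session(
                config, [NeuronSpec("Trigger-like", response_amplitude=amp)]
            )
            sims.append(
                similarity(bundle.behaviors[BEHAVIOR_POKING], minmax_scale(bundle.traces[0]))
            )
        mean_sims.append(np.mean(sims))
    assert mean_sims[0] < mean_sims[1] < mean_sims[2]


class TestTrackedPair:
    def test_full_overlap_identity_retention(self, small_session):
        _, truth = small_session
        identity = {
            c: {c2: 1.0 if c2 == c else 0.0 for c2 in set(truth.tuning_class) | {"Other"}}
            for c in set(truth.tuning_class)
        }
        config = TrackedPairConfig(
            overlap_fraction=1.0, retention=identity, n_new_neurons=0, seed=0
        )
        _, truth2, idmap = simulate_tracked_pair(
            config, truth, SessionConfig(n_trials=10, seed=1)
        )
        assert len(idmap) == len(truth)
        c1 = truth.set_index("neuron_id").tuning_class
        c2 = truth2.set_index("neuron_id").tuning_class
        for row in idmap.itertuples():
            assert c1.loc[row.stage1_id] == c2.loc[row.stage2_id]

    def test_overlap_count_matches_configured_fraction(self):
        import pandas as pd

        truth = pd.DataFrame(
            {"neuron_id": range(521), "tuning_class": ["Other"] * 521}
        )
        config = TrackedPairConfig(overlap_fraction=0.67, n_new_neurons=0, seed=4)
        _, _, idmap = simulate_tracked_pair(
            config, truth, SessionConfig(n_trials=5, seed=0)
        )
        assert len(idmap) in (349, 350)
        assert idmap.stage1_id.is_unique and idmap.stage2_id.is_unique

    def test_retention_rows_must_sum_to_one(self):
        bad = {"Other": {"Other": 0.5}}
        with pytest.raises(ValueError, match="sums to"):
            TrackedPairConfig(retention=bad)
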