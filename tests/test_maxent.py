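"""Exact inference: partition function, marginals, policies, sampling."""

import numpy as np
import pytest

from clinicirl.mdp import Action, DynamicsParams, State, Trajectory, build_clinic_mdp
from clinicirl.maxent import (
    enumerate_trajectories,
    expected_features,
    local_policies,
    partition_function,
    sample_trajectories,
    state_action_marginals,
    trajectory_log_likelihood,
)
from clinicirl.mdp import ValidationError, trajectory_features


class TestEnumeration:
    def test_uniform_policy_mass_conservation(self):
        m = build_clinic_mdp(horizon=1)
        pairs = enumerate_trajectories(m, 1)
        total = sum(w * 0.5 ** len(t.actions) for t, w in pairs)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_raw_environment_weight_of_known_trajectory(self):
        m = build_clinic_mdp(horizon=1)
        target = Trajectory((State.IP, State.DIS), (Action.ATT,))
        weights = {t: w for t, w in enumerate_trajectories(m, 1)}
        assert weights[target] == pytest.approx(0.95 * 0.0975, abs=1e-15)

    def test_no_modality_mixing_without_switching(self):
        m = build_clinic_mdp(DynamicsParams(sigma_a=0.0, sigma_n=0.0), horizon=3)
        for traj, _ in enumerate_trajectories(m, 3):
            mods = {s for s in traj.states if s in (State.IP, State.TH)}
            assert len(mods) == 1

    def test_enumeration_guard(self, mdp):
        with pytest.raises(ValidationError, match="max_len"):
            enumerate_trajectories(mdp, 8)


class TestPartitionFunction:
    def test_z_is_two_at_zero_reward_horizon_one(self):
        m = build_clinic_mdp(horizon=1)
        assert np.exp(partition_function(m, np.zeros(5))) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("horizon", [2, 4])
    def test_matches_oracle(self, oracle_factory, horizon):
        oracle = oracle_factory(horizon)
        rng = np.random.default_rng(3)
        for _ in range(5):
            th = rng.uniform(-1, 1, 5)
            assert partition_function(oracle.mdp, th) == pytest.approx(
                oracle.log_partition(th), abs=1e-10
            )

    def test_not_invariant_to_constant_reward_shift(self, mdp, theta_all):
        # trajectory lengths differ, so a constant shift changes Z
        shifted = np.clip(theta_all + 0.5, -1, 1)
        assert abs(
            partition_function(mdp, shifted) - partition_function(mdp, theta_all)
        ) > 0.1


class TestMarginals:
    def test_initial_state_marginal_at_zero_reward(self, mdp):
        table = state_action_marginals(mdp, np.zeros(5))
        assert table.state_marginals[0, State.IP] == pytest.approx(0.95, abs=1e-12)

    def test_matches_oracle(self, oracle_factory):
        oracle = oracle_factory(4)
        rng = np.random.default_rng(4)
        for _ in range(5):
            th = rng.uniform(-1, 1, 5)
            table = state_action_marginals(oracle.mdp, th)
            assert np.allclose(
                table.state_marginals, oracle.state_marginals(th), atol=1e-10
            )
            assert np.allclose(
                table.state_action_marginals,
                oracle.state_action_marginals(th),
                atol=1e-10,
            )

    def test_normalization_and_consistency(self, mdp, theta_all):
        table = state_action_marginals(mdp, theta_all)
        assert np.allclose(table.state_marginals.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(table.state_marginals >= 0)
        assert np.all(table.state_action_marginals >= 0)
        # summing actions recovers the state marginal at non-terminal states
        sa_sum = table.state_action_marginals.sum(axis=2)
        for s in (State.IP, State.TH):
            assert np.allclose(
                sa_sum[:, s], table.state_marginals[:-1, s], atol=1e-10
            )

    def test_tidy_export_shape(self, theta_all):
        m = build_clinic_mdp(horizon=3)
        frame = state_action_marginals(m, theta_all).to_frame()
        assert set(frame.columns) == {"t", "state", "action", "probability"}
        assert len(frame) == 4 * 6 + 3 * 2 * 2


class TestExpectedFeatures:
    def test_matches_oracle_expectation(self, oracle_factory):
        oracle = oracle_factory(3)
        th = np.array([-0.4, 0.2, 0.7, -0.9, 0.1])
        assert np.allclose(
            expected_features(oracle.mdp, th), oracle.expected_features(th), atol=1e-10
        )

    def test_gradient_of_log_partition(self, mdp, theta_all):
        eps = 1e-5
        grad = expected_features(mdp, theta_all)
        for j in range(5):
            e = np.zeros(5)
            e[j] = eps
            fd = (
                partition_function(mdp, theta_all + e)
                - partition_function(mdp, theta_all - e)
            ) / (2 * eps)
            assert fd == pytest.approx(grad[j], rel=1e-6, abs=1e-9)

    def test_monte_carlo_feature_mean(self, mdp, theta_all):
        n = 20000
        trajs = sample_trajectories(mdp, theta_all, n, seed=11)
        phis = np.array([trajectory_features(t, mdp.discount) for t in trajs])
        se = phis.std(axis=0, ddof=1) / np.sqrt(n)
        diff = np.abs(phis.mean(axis=0) - expected_features(mdp, theta_all))
        assert np.all(diff <= 3.5 * se + 1e-12)


class TestLikelihood:
    def test_hand_computed_single_step(self):
        m = build_clinic_mdp(horizon=1)
        traj = Trajectory((State.IP, State.DIS), (Action.ATT,))
        ll = trajectory_log_likelihood(m, np.zeros(5), traj)
        assert ll == pytest.approx(np.log(0.95 * 0.0975 / 2.0), abs=1e-12)

    def test_probabilities_sum_to_one_over_event_space(self, oracle_factory):
        oracle = oracle_factory(3)
        th = np.array([0.3, -0.6, 0.9, -0.2, -0.8])
        total = sum(
            np.exp(trajectory_log_likelihood(oracle.mdp, th, t))
            for t in oracle.trajectories
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_trajectory_rejected(self, mdp, theta_all):
        bad = Trajectory((State.IP, State.REM), (Action.ATT,))
        with pytest.raises(ValidationError):
            trajectory_log_likelihood(mdp, theta_all, bad)


class TestLocalPolicies:
    def test_rows_normalized_and_symmetric_at_equal_rewards(self):
        m = build_clinic_mdp(DynamicsParams(p_ip=0.5))
        pol = local_policies(m, np.zeros(5)).probs
        assert np.allclose(pol[:, :2, :].sum(axis=2), 1.0, atol=1e-10)
        assert np.allclose(pol[:, State.IP, :], pol[:, State.TH, :], atol=1e-12)

    def test_rollout_reproduces_trajectory_distribution(self, oracle_factory):
        from clinicirl.maxent import _tilted_start, _tilted_transitions

        oracle = oracle_factory(4)
        m = oracle.mdp
        th = np.array([-0.7, 0.4, 0.9, -0.3, -1.0])
        pol = local_policies(m, th).probs
        start = _tilted_start(m, th)
        trans = _tilted_transitions(m, th)
        probs = oracle.probabilities(th)
        for traj, p_model in zip(oracle.trajectories, probs):
            p_roll = start[traj.states[0]]
            for t, a in enumerate(traj.actions):
                p_roll *= pol[t, traj.states[t], a]
                p_roll *= trans[t, traj.states[t], a, traj.states[t + 1]]
            assert p_roll == pytest.approx(p_model, abs=1e-10)


class TestSampling:
    def test_deterministic_given_seed(self, mdp, theta_all):
        a = sample_trajectories(mdp, theta_all, 50, seed=9)
        b = sample_trajectories(mdp, theta_all, 50, seed=9)
        assert a == b

    def test_samples_are_valid(self, mdp, theta_all):
        from clinicirl.mdp import validate_trajectory

        for traj in sample_trajectories(mdp, theta_all, 200, seed=10):
            ok, reason = validate_trajectory(traj, mdp)
            assert ok, reason
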