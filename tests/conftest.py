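"""Shared fixtures: MDPs, reference weights, and the enumeration oracle."""

from __future__ import annotations

import numpy as np
import pytest

from clinicirl.mdp import build_clinic_mdp, trajectory_features
from clinicirl.maxent import enumerate_trajectories
from clinicirl.reference import reference_theta


@pytest.fixture(scope="session")
def mdp():
    """Default clinic process: expert dynamics, horizon 13, undiscounted."""
    return build_clinic_mdp()


@pytest.fixture(scope="session")
def theta_all():
    return reference_theta("all")


class EnumerationOracle:
    """Brute-force view of the trajectory distribution at short horizons.

    Enumerates every trajectory once and exposes vectorized evaluation of
    the partition function, trajectory probabilities and time-indexed
    marginals for arbitrary reward vectors — fully independent of the
    message-passing implementation it is used to check.
    """

    def __init__(self, mdp, max_len: int):
        self.mdp = mdp
        pairs = enumerate_trajectories(mdp, max_len)
        self.trajectories = [p[0] for p in pairs]
        self.weights = np.array([p[1] for p in pairs])
        self.features = np.array(
            [trajectory_features(t, mdp.discount) for t in self.trajectories]
        )
        self.max_len = max_len
        # index arrays for marginal accumulation (state occupancy incl. padding)
        occ_traj, occ_t, occ_s = [], [], []
        act_traj, act_t, act_s, act_a = [], [], [], []
        for i, traj in enumerate(self.trajectories):
            for t in range(max_len + 1):
                s = traj.states[t] if t < len(traj.states) else 5
                occ_traj.append(i)
                occ_t.append(t)
                occ_s.append(s)
            for t, a in enumerate(traj.actions):
                act_traj.append(i)
                act_t.append(t)
                act_s.append(traj.states[t])
                act_a.append(a)
        self._occ = (np.array(occ_traj), np.array(occ_t), np.array(occ_s))
        self._act = (
            np.array(act_traj),
            np.array(act_t),
            np.array(act_s),
            np.array(act_a),
        )

    def probabilities(self, theta) -> np.ndarray:
        unnorm = self.weights * np.exp(self.features @ np.asarray(theta))
        return unnorm / unnorm.sum()

    def log_partition(self, theta) -> float:
        unnorm = self.weights * np.exp(self.features @ np.asarray(theta))
        return float(np.log(unnorm.sum()))

    def state_marginals(self, theta) -> np.ndarray:
        p = self.probabilities(theta)
        out = np.zeros((self.max_len + 1, 6))
        ti, tt, ts = self._occ
        np.add.at(out, (tt, ts), p[ti])
        return out

    def state_action_marginals(self, theta) -> np.ndarray:
        p = self.probabilities(theta)
        out = np.zeros((self.max_len, 5, 2))
        ti, tt, ts, ta = self._act
        np.add.at(out, (tt, ts, ta), p[ti])
        return out

    def expected_features(self, theta) -> np.ndarray:
        return self.probabilities(theta) @ self.features


@pytest.fixture(scope="session")
def oracle_factory():
    cache: dict[int, EnumerationOracle] = {}

    def make(horizon: int) -> EnumerationOracle:
        if horizon not in cache:
            cache[horizon] = EnumerationOracle(
                build_clinic_mdp(horizon=horizon), horizon
            )
        return cache[horizon]

    return make
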