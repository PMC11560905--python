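"""Exact finite-horizon inference for the maximum-entropy trajectory model.

The behaviour model assigns each feasible trajectory ``tau`` a probability
proportional to its environment weight times the exponentiated linear
reward,

    p_theta(tau)  proportional to  p0(s0) * prod_t T(s_t, a_t, s_{t+1})
                                   * exp(theta . phi(tau)),

where ``phi(tau)`` is the (optionally discounted) sum of one-hot state
indicators over the visited states.  Actions carry implicit weight one, so
the partition function Z sums environment mass over both actions at every
decision point (Z = 2 at theta = 0, horizon 1).

Variable-length interactions are handled by an absorbing padding
convention: terminal states transition with probability one into a
zero-reward padding state, so every trajectory has nominal length equal to
the horizon ``L`` and the fixed-horizon dynamic programme is exact.
Interactions still open at the horizon (censored) are part of the event
space with their prefix weight.

Message passing runs in linear space with per-step renormalization (the
scaling trick familiar from hidden-Markov-model inference), which is
immune to under/overflow at any horizon while keeping every step a small
dense matrix product; cost is ``O(L * |S|^2 * |A|)``, negligible for the
5-state clinic process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp import (
    ACTION_NAMES,
    N_ACTIONS,
    N_STATES,
    NONTERMINAL_STATES,
    STATE_NAMES,
    Action,
    ClinicMDP,
    State,
    Trajectory,
    ValidationError,
    trajectory_features,
    validate_trajectory,
)

__all__ = [
    "RewardParams",
    "MarginalTable",
    "LocalPolicy",
    "enumerate_trajectories",
    "partition_function",
    "state_action_marginals",
    "expected_features",
    "trajectory_log_likelihood",
    "local_policies",
    "sample_trajectories",
]

_PAD = N_STATES  # index of the zero-reward padding state in extended vectors

#: Box bound on every reward component, making weights interpretable as
#: relative preferences.
THETA_BOX = (-1.0, 1.0)


def as_theta(theta) -> np.ndarray:
    """Validate and coerce a reward parameter vector.

    Accepts any length-5 sequence; enforces the [-1, +1] box.
    """
    th = np.asarray(theta, dtype=float)
    if th.shape != (N_STATES,):
        raise ValidationError(f"theta must have shape (5,), got {th.shape}")
    if np.any(th < THETA_BOX[0] - 1e-12) or np.any(th > THETA_BOX[1] + 1e-12):
        raise ValidationError(f"theta components must lie in [-1, +1], got {th}")
    return th


# Kept as a named alias so signatures read like the domain: a RewardParams
# is simply a length-5 float vector in the fixed state order.
RewardParams = np.ndarray


@dataclass(frozen=True)
class MarginalTable:
    """Time-indexed marginals of the trajectory distribution at a fixed theta.

    Attributes
    ----------
    state_marginals
        Array ``(L+1, 6)``: probability of occupying each of the five
        clinic states, plus the padding state (last column), at each time
        ``t = 0..L``.  Each row sums to one.
    state_action_marginals
        Array ``(L, 5, 2)``: probability of being in state ``s`` and
        taking action ``a`` at time ``t = 0..L-1``.  Rows for terminal
        states are identically zero (no actions there).
    log_partition
        ``log Z`` of the trajectory distribution.
    horizon, discount
        Copied from the MDP used to build the table.
    """

    state_marginals: np.ndarray
    state_action_marginals: np.ndarray
    log_partition: float
    horizon: int
    discount: float

    def to_frame(self):
        """Tidy export: columns t, state, action, probability.

        State rows carry action ``""``; the padding state is labelled
        ``PAD``.  Useful for CSV reporting.
        """
        import pandas as pd

        rows = []
        names = STATE_NAMES + ("PAD",)
        for t in range(self.horizon + 1):
            for s, name in enumerate(names):
                rows.append((t, name, "", self.state_marginals[t, s]))
        for t in range(self.horizon):
            for s in NONTERMINAL_STATES:
                for a in Action:
                    rows.append(
                        (t, STATE_NAMES[s], ACTION_NAMES[a],
                         self.state_action_marginals[t, s, a])
                    )
        return pd.DataFrame(rows, columns=["t", "state", "action", "probability"])


@dataclass(frozen=True)
class LocalPolicy:
    """Per-time-step action distributions pi_t(a|s) for non-terminal states.

    ``probs`` has shape ``(L, 5, 2)``; rows for terminal states are zero.
    Rolling this policy out against the (reward-tilted) dynamics
    reproduces the maximum-entropy trajectory distribution exactly.
    """

    probs: np.ndarray
    horizon: int


def _weights(mdp: ClinicMDP, theta: np.ndarray) -> np.ndarray:
    """Per-time state reward weight, extended with the padding column.

    ``w[t, s] = exp(discount**t * theta_s)`` for clinic states, 1 for
    padding.
    """
    L = mdp.horizon
    disc = mdp.discount ** np.arange(L + 1)
    w = np.ones((L + 1, N_STATES + 1))
    w[:, :N_STATES] = np.exp(disc[:, None] * theta[None, :])
    return w


class _Messages:
    """Scaled forward/backward messages of the padded fixed-horizon chain.

    ``alpha_hat[t]`` is the forward message (past weight into each
    extended state at time ``t``, reward of the state included),
    renormalized to sum to one; the running log-normalizer makes
    ``log Z`` the accumulated log-sum at ``t = L``.  ``beta_hat[t]`` is
    the backward message (future weight from time ``t``, own reward
    excluded), max-renormalized per step.  Per-time marginals are formed
    from same-``t`` products, where the scale factors cancel.
    """

    __slots__ = ("alpha_hat", "beta_hat", "w", "log_z", "L")

    def __init__(self, mdp: ClinicMDP, theta: np.ndarray) -> None:
        L = mdp.horizon
        w = _weights(mdp, theta)
        T = mdp.T  # (5, 2, 5); terminal rows all zero
        n_ext = N_STATES + 1

        beta_hat = np.zeros((L + 1, n_ext))
        beta_hat[L] = 1.0
        for t in range(L - 1, -1, -1):
            nxt = w[t + 1] * beta_hat[t + 1]  # (6,)
            b = np.empty(n_ext)
            # terminal and padding states absorb into padding, weight 1
            b[State.DIS :] = nxt[_PAD]
            q = T[: len(NONTERMINAL_STATES)] @ nxt[:N_STATES]  # (2, 2)
            b[: len(NONTERMINAL_STATES)] = q.sum(axis=1)
            scale = b.max()
            beta_hat[t] = b / scale
            # the backward scale is only needed relative to time; logZ
            # comes from the forward pass

        alpha_hat = np.zeros((L + 1, n_ext))
        a = np.zeros(n_ext)
        a[:N_STATES] = mdp.p0 * w[0, :N_STATES]
        log_z = 0.0
        s0 = a.sum()
        log_z += np.log(s0)
        alpha_hat[0] = a / s0
        for t in range(L):
            new = np.empty(n_ext)
            live = np.einsum("s,sab->b", alpha_hat[t, : len(NONTERMINAL_STATES)],
                             T[: len(NONTERMINAL_STATES)])
            new[:N_STATES] = live * w[t + 1, :N_STATES]
            new[_PAD] = alpha_hat[t, State.DIS :].sum()
            st = new.sum()
            log_z += np.log(st)
            alpha_hat[t + 1] = new / st
        self.alpha_hat = alpha_hat
        self.beta_hat = beta_hat
        self.w = w
        self.log_z = float(log_z)
        self.L = L

    def q_values(self, mdp: ClinicMDP, t: int) -> np.ndarray:
        """Unnormalized backward action messages at time ``t``, shape (2, 2)."""
        nxt = self.w[t + 1, :N_STATES] * self.beta_hat[t + 1, :N_STATES]
        return mdp.T[: len(NONTERMINAL_STATES)] @ nxt

    def marginal_tables(self, mdp: ClinicMDP) -> tuple[np.ndarray, np.ndarray]:
        """Normalized state and state-action marginals over time."""
        L = self.L
        n_live = len(NONTERMINAL_STATES)
        state_marg = np.zeros((L + 1, N_STATES + 1))
        sa = np.zeros((L, N_STATES, N_ACTIONS))
        for t in range(L + 1):
            if t < L:
                q = self.q_values(mdp, t)  # same scale as beta_hat[t]*max
                b = np.empty(N_STATES + 1)
                b[State.DIS :] = self.w[t + 1, _PAD] * self.beta_hat[t + 1, _PAD]
                b[:n_live] = q.sum(axis=1)
                joint_sa = self.alpha_hat[t, :n_live, None] * q
            else:
                b = np.ones(N_STATES + 1)
                joint_sa = None
            m = self.alpha_hat[t] * b
            norm = m.sum()
            state_marg[t] = m / norm
            if joint_sa is not None:
                sa[t, :n_live, :] = joint_sa / norm
        return state_marg, sa


def partition_function(mdp: ClinicMDP, theta) -> float:
    """log Z: the log normalizing constant of the trajectory distribution.

    Equals the log of the sum, over every trajectory of length up to the
    horizon (terminal-padded, censored prefixes included), of
    ``p0 * prod T * exp(theta . phi)``; computed by the scaled forward
    recursion.
    """
    return _Messages(mdp, as_theta(theta)).log_z


def state_action_marginals(mdp: ClinicMDP, theta) -> MarginalTable:
    """Exact time-indexed state and state-action marginals at ``theta``.

    Terminal mass moves to the padding column one step after entry, so
    each terminal state is occupied for exactly one time step per
    trajectory; the five clinic states plus padding sum to one at every
    ``t``.
    """
    theta = as_theta(theta)
    msg = _Messages(mdp, theta)
    state_marg, sa = msg.marginal_tables(mdp)
    return MarginalTable(
        state_marginals=state_marg,
        state_action_marginals=sa,
        log_partition=msg.log_z,
        horizon=mdp.horizon,
        discount=mdp.discount,
    )


def expected_features(mdp: ClinicMDP, theta) -> np.ndarray:
    """Model-expected discounted feature counts E_theta[phi(tau)].

    Equals the gradient of ``log Z`` with respect to ``theta`` (padding
    excluded: it carries no reward).
    """
    table = state_action_marginals(mdp, theta)
    disc = mdp.discount ** np.arange(mdp.horizon + 1)
    return disc @ table.state_marginals[:, :N_STATES]


def log_partition_and_features(mdp: ClinicMDP, theta) -> tuple[float, np.ndarray]:
    """``(log Z, E_theta[phi])`` in a single message-passing sweep.

    The fast path for likelihood optimization, where both the objective
    and its gradient are needed at every iterate.
    """
    theta = as_theta(theta)
    msg = _Messages(mdp, theta)
    state_marg, _ = msg.marginal_tables(mdp)
    disc = mdp.discount ** np.arange(mdp.horizon + 1)
    return msg.log_z, disc @ state_marg[:, :N_STATES]


def trajectory_log_likelihood(mdp: ClinicMDP, theta, traj: Trajectory) -> float:
    """Log-probability of one trajectory under the model at ``theta``.

    ``log p0(s0) + log T(tau) + theta . phi(tau) - log Z``.  Censored
    trajectories use their prefix environment weight and accrued
    features; the padding convention adds neither reward nor transition
    mass, so the value is invariant to padding.
    """
    theta = as_theta(theta)
    ok, reason = validate_trajectory(traj, mdp)
    if not ok:
        raise ValidationError(f"invalid trajectory: {reason}")
    logw_env = np.log(mdp.p0[traj.states[0]])
    for t, a in enumerate(traj.actions):
        logw_env += np.log(mdp.T[traj.states[t], a, traj.states[t + 1]])
    phi = trajectory_features(traj, mdp.discount)
    return float(logw_env + theta @ phi - partition_function(mdp, theta))


def local_policies(mdp: ClinicMDP, theta) -> LocalPolicy:
    """Time-indexed soft action policies pi_t(a|s) realizing the model.

    ``pi_t(a|s)`` is proportional to the backward message through
    ``(s, a)`` at time ``t``; rolling it out against the reward-tilted
    dynamics reproduces the trajectory distribution exactly.
    """
    theta = as_theta(theta)
    msg = _Messages(mdp, theta)
    L = mdp.horizon
    n_live = len(NONTERMINAL_STATES)
    probs = np.zeros((L, N_STATES, N_ACTIONS))
    for t in range(L):
        q = msg.q_values(mdp, t)
        probs[t, :n_live, :] = q / q.sum(axis=1, keepdims=True)
    return LocalPolicy(probs=probs, horizon=L)


def _tilted_transitions(mdp: ClinicMDP, theta) -> np.ndarray:
    """Posterior next-state distributions p_t(s'|s, a) of the model.

    Shape ``(L, 5, 2, 5)``; the environment transition is tilted by the
    downstream reward weight so that policy rollout matches the exact
    trajectory distribution.
    """
    theta = as_theta(theta)
    msg = _Messages(mdp, theta)
    L = mdp.horizon
    n_live = len(NONTERMINAL_STATES)
    out = np.zeros((L, N_STATES, N_ACTIONS, N_STATES))
    for t in range(L):
        nxt = msg.w[t + 1, :N_STATES] * msg.beta_hat[t + 1, :N_STATES]
        tilted = mdp.T[:n_live] * nxt[None, None, :]
        out[t, :n_live] = tilted / tilted.sum(axis=2, keepdims=True)
    return out


def _tilted_start(mdp: ClinicMDP, theta) -> np.ndarray:
    theta = as_theta(theta)
    msg = _Messages(mdp, theta)
    row = mdp.p0 * msg.w[0, :N_STATES] * msg.beta_hat[0, :N_STATES]
    return row / row.sum()


def sample_trajectories(
    mdp: ClinicMDP, theta, n: int, seed: int | np.random.Generator
) -> list[Trajectory]:
    """Draw ``n`` independent trajectories from the model at ``theta``.

    Exact ancestral sampling through the local policies and the tilted
    dynamics; fully reproducible given ``seed`` (an int or an existing
    :class:`numpy.random.Generator`).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    policy = local_policies(mdp, theta).probs
    trans = _tilted_transitions(mdp, theta)
    start = _tilted_start(mdp, theta)
    L = mdp.horizon

    out: list[Trajectory] = []
    for _ in range(n):
        s = int(rng.choice(N_STATES, p=start))
        states = [s]
        actions: list[int] = []
        for t in range(L):
            if State(s).terminal:
                break
            a = int(rng.choice(N_ACTIONS, p=policy[t, s]))
            s = int(rng.choice(N_STATES, p=trans[t, s, a]))
            actions.append(a)
            states.append(s)
        censored = not State(states[-1]).terminal
        out.append(Trajectory(tuple(states), tuple(actions), censored=censored))
    return out


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------

_MAX_ENUM_LEN = 7


def enumerate_trajectories(
    mdp: ClinicMDP, max_len: int
) -> list[tuple[Trajectory, float]]:
    """Enumerate every positive-weight trajectory up to ``max_len`` steps.

    Returns ``(trajectory, weight)`` pairs where ``weight`` is the raw
    environment mass ``p0(s0) * prod T`` — actions are not weighted
    (their implicit weight of one belongs to the behaviour model, not the
    environment).  Censored length-``max_len`` prefixes are included, so
    weighting each trajectory by ``(1/|A|)**n_actions`` recovers total
    mass one.

    This is the independent oracle for the dynamic-programming routines;
    it is deliberately guarded to short horizons.
    """
    if max_len > _MAX_ENUM_LEN:
        raise ValidationError(
            f"enumeration limited to max_len <= {_MAX_ENUM_LEN}, got {max_len}"
        )
    if max_len < 1:
        raise ValidationError(f"max_len must be >= 1, got {max_len}")

    out: list[tuple[Trajectory, float]] = []

    def recurse(states: list[int], actions: list[int], weight: float) -> None:
        s = states[-1]
        if State(s).terminal:
            out.append(
                (Trajectory(tuple(states), tuple(actions), censored=False), weight)
            )
            return
        if len(actions) == max_len:
            out.append(
                (Trajectory(tuple(states), tuple(actions), censored=True), weight)
            )
            return
        for a in Action:
            for s2 in range(N_STATES):
                p = mdp.T[s, a, s2]
                if p > 0.0:
                    recurse(states + [s2], actions + [a], weight * p)

    for s0 in range(N_STATES):
        if mdp.p0[s0] > 0.0:
            recurse([s0], [], float(mdp.p0[s0]))
    return out
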