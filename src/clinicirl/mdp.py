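"""Clinic decision process: states, actions, dynamics, and trajectories.

A patient's interaction with a mixed in-person/telehealth outpatient clinic
is modelled as a small finite-horizon Markov decision process with five
states and two actions.  The patient controls attendance; the clinic (the
environment) controls booking modality and service exit:

* ``IP`` -- an in-person consult is scheduled (non-terminal),
* ``TH`` -- a telehealth consult is scheduled (non-terminal),
* ``DIS`` -- discharged from the roster (terminal),
* ``ADM`` -- admitted as an inpatient (terminal),
* ``REM`` -- removed from the roster after non-attendance (terminal).

The two actions, available only at the non-terminal modality states, are
``ATT`` (attend the scheduled consult) and ``NA`` (fail to attend).

Transition dynamics are governed by six scalar parameters estimated by
clinic subject-matter experts (:class:`DynamicsParams`): the probability of
starting in-person, per-consult exit probabilities after attendance and
non-attendance, the discharge/admission split, and the per-consult modality
switching chances.  Attendance exits split between discharge and admission;
non-attendance exits go to removal.

The fixed state order ``(IP, TH, DIS, ADM, REM)`` indexes every vector and
tensor in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "State",
    "Action",
    "DynamicsParams",
    "ClinicMDP",
    "Trajectory",
    "STATE_NAMES",
    "ACTION_NAMES",
    "TERMINAL_STATES",
    "NONTERMINAL_STATES",
    "build_clinic_mdp",
    "feature_vector",
    "trajectory_features",
    "validate_trajectory",
]


class State(IntEnum):
    """Clinic states in the fixed vector order."""

    IP = 0
    TH = 1
    DIS = 2
    ADM = 3
    REM = 4

    @property
    def terminal(self) -> bool:
        return self >= State.DIS


class Action(IntEnum):
    """Patient actions, defined only at non-terminal states."""

    ATT = 0
    NA = 1


STATE_NAMES = ("IP", "TH", "DIS", "ADM", "REM")
ACTION_NAMES = ("ATT", "NA")
TERMINAL_STATES = (State.DIS, State.ADM, State.REM)
NONTERMINAL_STATES = (State.IP, State.TH)

N_STATES = 5
N_ACTIONS = 2


class ValidationError(ValueError):
    """Raised when a parameter or structure fails a domain constraint."""


@dataclass(frozen=True)
class DynamicsParams:
    """Expert-estimated transition dynamics of the clinic.

    Parameters
    ----------
    p_ip
        Probability that a patient's first consult is in-person.
    p_n
        Probability of exiting the service after not attending a consult
        (routed to removal, ``REM``).
    p_a
        Probability of exiting the service after attending a consult
        (split between discharge and admission by ``d``).
    d
        Proportion of attendance exits that are discharges rather than
        admissions (0.65 for "65%").
    sigma_a
        Per-consult chance of switching modality after attending.
    sigma_n
        Per-consult chance of switching modality after not attending.
    strict_odds
        If True, interpret the switching chances quoted as "1 in N" odds
        strictly, i.e. ``x`` becomes ``x / (1 + x)``.  Default False:
        colloquial usage, "1 in 1,000" means probability 0.001.  The
        difference is below every reported precision.
    """

    p_ip: float = 0.95
    p_n: float = 0.55
    p_a: float = 0.15
    d: float = 0.65
    sigma_a: float = 0.001
    sigma_n: float = 0.0001
    strict_odds: bool = False

    def __post_init__(self) -> None:
        for name in ("p_ip", "p_n", "p_a", "d", "sigma_a", "sigma_n"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"dynamics parameter {name!r} must lie in [0, 1], got {v!r}"
                )

    @property
    def switch_att(self) -> float:
        """Effective modality-switch probability after attendance."""
        return self.sigma_a / (1.0 + self.sigma_a) if self.strict_odds else self.sigma_a

    @property
    def switch_na(self) -> float:
        """Effective modality-switch probability after non-attendance."""
        return self.sigma_n / (1.0 + self.sigma_n) if self.strict_odds else self.sigma_n


@dataclass(frozen=True)
class ClinicMDP:
    """The assembled clinic decision process.

    Attributes
    ----------
    T
        Transition tensor of shape ``(5, 2, 5)`` indexed
        ``(state, action, next_state)``.  Rows for terminal states are all
        zero: terminal states have no outgoing action transitions (they
        absorb into a zero-reward padding state during inference).
    p0
        Initial-state distribution over the five states; mass only on the
        modality states ``IP`` and ``TH``.
    horizon
        Maximum number of decision steps ``L``.  The data motivating the
        default show interactions of 1-13 scheduled consults, hence 13.
    discount
        Discount factor applied to feature accumulation over time.  The
        default 1.0 counts state visits undiscounted; a far-sighted
        0.999 is numerically indistinguishable at horizon 13.
    params
        The :class:`DynamicsParams` the tensor was built from.
    """

    T: np.ndarray
    p0: np.ndarray
    horizon: int
    discount: float
    params: DynamicsParams

    @property
    def n_states(self) -> int:
        return N_STATES

    @property
    def n_actions(self) -> int:
        return N_ACTIONS


def build_clinic_mdp(
    params: DynamicsParams | None = None,
    horizon: int = 13,
    discount: float = 1.0,
) -> ClinicMDP:
    """Compose the transition tensor and initial distribution.

    From a modality state ``M`` (``IP`` or ``TH``), attendance leads to
    discharge with probability ``p_a * d``, admission with ``p_a * (1-d)``,
    and otherwise re-books the patient in the same modality with
    probability ``(1-p_a)*(1-sigma_a)`` or the other with
    ``(1-p_a)*sigma_a``.  Non-attendance leads to removal with probability
    ``p_n`` and otherwise re-books similarly with the ``sigma_n`` switch
    chance.

    Raises
    ------
    ValidationError
        If a dynamics parameter lies outside [0, 1], ``horizon < 1``, or
        ``discount`` outside (0, 1].
    """
    if params is None:
        params = DynamicsParams()
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    if not (0.0 < discount <= 1.0):
        raise ValidationError(f"discount must lie in (0, 1], got {discount}")

    sa, sn = params.switch_att, params.switch_na
    T = np.zeros((N_STATES, N_ACTIONS, N_STATES))
    for m in NONTERMINAL_STATES:
        other = State.TH if m is State.IP else State.IP
        T[m, Action.ATT, State.DIS] = params.p_a * params.d
        T[m, Action.ATT, State.ADM] = params.p_a * (1.0 - params.d)
        T[m, Action.ATT, m] = (1.0 - params.p_a) * (1.0 - sa)
        T[m, Action.ATT, other] = (1.0 - params.p_a) * sa
        T[m, Action.NA, State.REM] = params.p_n
        T[m, Action.NA, m] = (1.0 - params.p_n) * (1.0 - sn)
        T[m, Action.NA, other] = (1.0 - params.p_n) * sn

    p0 = np.zeros(N_STATES)
    p0[State.IP] = params.p_ip
    p0[State.TH] = 1.0 - params.p_ip
    return ClinicMDP(T=T, p0=p0, horizon=int(horizon), discount=float(discount), params=params)


def feature_vector(state: State | int) -> np.ndarray:
    """One-hot state-indicator feature in the fixed state order."""
    s = int(state)
    if not 0 <= s < N_STATES:
        raise ValidationError(f"unknown state {state!r}")
    phi = np.zeros(N_STATES)
    phi[s] = 1.0
    return phi


@dataclass(frozen=True)
class Trajectory:
    """One patient's alternating state-action sequence.

    ``states`` has exactly one more element than ``actions``.  The final
    state is terminal unless the interaction was censored at the horizon,
    in which case ``censored`` is True and the final state is a modality
    state.
    """

    states: tuple[int, ...]
    actions: tuple[int, ...] = ()
    censored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))
        object.__setattr__(self, "actions", tuple(int(a) for a in self.actions))
        if len(self.states) != len(self.actions) + 1:
            raise ValidationError(
                "states must have exactly one more element than actions "
                f"(got {len(self.states)} states, {len(self.actions)} actions)"
            )
        for s in self.states[:-1]:
            if State(s).terminal:
                raise ValidationError("only the final state may be terminal")
        final_terminal = State(self.states[-1]).terminal
        if not self.censored and not final_terminal:
            raise ValidationError(
                "uncensored trajectory must end in a terminal state"
            )
        if self.censored and final_terminal:
            raise ValidationError("censored trajectory cannot end terminal")

    def __len__(self) -> int:
        """Number of decision steps (actions)."""
        return len(self.actions)


def trajectory_features(
    traj: Trajectory, discount: float = 1.0
) -> np.ndarray:
    """Discounted state-visit feature counts of a trajectory.

    Sums ``discount**t * feature_vector(s_t)`` over every visited state
    including the final (terminal or censored) state once; no features
    accrue after termination.  With ``discount=1`` this is the integer
    visit-count vector.
    """
    if not (0.0 < discount <= 1.0):
        raise ValidationError(f"discount must lie in (0, 1], got {discount}")
    phi = np.zeros(N_STATES)
    for t, s in enumerate(traj.states):
        phi[s] += discount**t
    return phi


def validate_trajectory(
    traj: Trajectory, mdp: ClinicMDP
) -> tuple[bool, str]:
    """Check a trajectory against the MDP's support and horizon.

    Returns ``(ok, reason)`` where ``reason`` is an empty string when the
    trajectory is valid, and otherwise names the first violated rule:
    every transition must have positive probability under ``mdp.T``, the
    start state must have positive initial mass, the length must not
    exceed the horizon, and a censored trajectory must run the full
    horizon.
    """
    if len(traj) > mdp.horizon:
        return False, f"length {len(traj)} exceeds horizon {mdp.horizon}"
    if traj.censored and len(traj) != mdp.horizon:
        return False, (
            f"censored trajectory must have exactly horizon={mdp.horizon} "
            f"decision steps, got {len(traj)}"
        )
    if mdp.p0[traj.states[0]] <= 0.0:
        return False, f"start state {STATE_NAMES[traj.states[0]]} has zero initial mass"
    for t, a in enumerate(traj.actions):
        s, s_next = traj.states[t], traj.states[t + 1]
        if State(s).terminal:
            return False, f"action taken from terminal state at step {t}"
        if mdp.T[s, a, s_next] <= 0.0:
            return False, (
                f"zero-probability transition ({STATE_NAMES[s]}, "
                f"{ACTION_NAMES[a]}, {STATE_NAMES[s_next]}) at step {t}"
            )
    return True, ""
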