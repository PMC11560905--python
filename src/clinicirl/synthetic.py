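"""Synthetic clinic extracts with the statistical structure of the study data.

The real scheduling extract is ethics-restricted, so every pipeline stage
is exercised against synthetic cohorts that emulate it: demographic
marginals matching the published cohort description (N = 1,026 patient
interactions), expert-estimated transition dynamics, and attendance
behaviour sampled from the maximum-entropy model itself at configurable
(by default, the published group-level) reward weights.  Sampling
behaviour from the fitted model class makes parameter recovery a
well-posed test; an explicit attendance-probability mode supports
model-misspecification experiments.

Demographic keys are drawn independently (only marginal frequencies are
published, not the joint distribution) — a documented simplification.
Dates are ordinal integers, not calendars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mdp import ClinicMDP, State, Action, Trajectory, ValidationError
from .maxent import sample_trajectories

__all__ = [
    "CohortConfig",
    "BehaviourSpec",
    "generate_cohort",
    "generate_clinic_extract",
    "render_trajectory_rows",
    "window_filter",
    "OUTCOME_CODES",
    "EXTRACT_COLUMNS",
]

OUTCOME_CODES = (
    "rebooked_in_person",
    "rebooked_telehealth",
    "discharged",
    "admitted",
    "removed",
    "censored",
)

EXTRACT_COLUMNS = [
    "patient_id",
    "consult_index",
    "modality",
    "attended",
    "outcome",
    "scheduled_date",
    "sex",
    "funding",
    "interpreter",
    "first_nations",
    "age_band",
]

_MODALITY_OF_STATE = {State.IP: "in_person", State.TH: "telehealth"}
_TERMINAL_OUTCOME = {
    State.DIS: "discharged",
    State.ADM: "admitted",
    State.REM: "removed",
}
_REBOOK_OUTCOME = {State.IP: "rebooked_in_person", State.TH: "rebooked_telehealth"}

AGE_BANDS = ("<30", "30-39", "40-49", "50-59", "60-69", ">=70")


@dataclass(frozen=True)
class CohortConfig:
    """Demographic mix of the synthetic cohort.

    Defaults reproduce the published cohort margins: 35.96% male, 0.78%
    privately funded, 3.08% requiring an interpreter (53/1026 missing),
    3.13% identifying as First Nations (67/1026 missing), and the six
    age-band shares.  ``n_patients`` defaults to the analysed cohort
    size of 1,026 interactions.
    """

    n_patients: int = 1026
    p_male: float = 0.3596
    p_private: float = 0.0078
    p_interpreter: float = 0.0308
    p_first_nations: float = 0.0313
    age_band_probs: tuple[float, ...] = (
        0.1852, 0.2056, 0.1803, 0.1745, 0.1394, 0.1150,
    )
    missing_interpreter: float = 53 / 1026
    missing_first_nations: float = 67 / 1026
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in (
            "p_male", "p_private", "p_interpreter", "p_first_nations",
            "missing_interpreter", "missing_first_nations",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"age_band_probs must sum to 1, got {sum(self.age_band_probs)}"
            )


@dataclass(frozen=True)
class BehaviourSpec:
    """Reward weights governing sampled attendance behaviour.

    Either a single global ``theta`` for the whole cohort, or a
    ``group_key`` (demographic column) plus a ``theta_by_level`` map from
    level to weights.  Patients whose level is missing fall back to the
    global ``theta`` when given, else raise.

    ``attend_prob``, if set, switches to the explicit
    attendance-probability mode: actions are i.i.d. Bernoulli draws and
    next states follow the raw environment dynamics.  Data generated this
    way sit outside the maximum-entropy model class, for
    misspecification experiments.
    """

    theta: tuple[float, ...] | None = None
    group_key: str | None = None
    theta_by_level: dict | None = None
    attend_prob: float | None = None

    def resolve(self, row: pd.Series, patient_id) -> np.ndarray:
        if self.group_key is not None:
            level = row[self.group_key]
            table = self.theta_by_level or {}
            if level is not None and not (isinstance(level, float) and np.isnan(level)):
                if level in table:
                    return np.asarray(table[level], dtype=float)
            if self.theta is not None:
                return np.asarray(self.theta, dtype=float)
            raise ValidationError(
                f"cannot resolve reward weights for patient {patient_id}: "
                f"level {level!r} of {self.group_key!r} has no entry and no "
                "global fallback theta is set"
            )
        if self.theta is None:
            raise ValidationError("BehaviourSpec needs a global theta or a group map")
        return np.asarray(self.theta, dtype=float)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a demographic table by independent categorical sampling.

    Missingness (empty values) is applied after level assignment, so a
    missing entry hides a real underlying level rather than being a
    separate category.  Reproducible by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    funding = np.where(rng.random(n) < config.p_private, "private", "public")
    interpreter = np.where(
        rng.random(n) < config.p_interpreter, "required", "not_required"
    ).astype(object)
    first_nations = np.where(
        rng.random(n) < config.p_first_nations, "yes", "no"
    ).astype(object)
    age_band = rng.choice(AGE_BANDS, size=n, p=config.age_band_probs)
    interpreter[rng.random(n) < config.missing_interpreter] = None
    first_nations[rng.random(n) < config.missing_first_nations] = None
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "sex": sex,
            "funding": funding,
            "interpreter": interpreter,
            "first_nations": first_nations,
            "age_band": age_band,
        }
    )


def render_trajectory_rows(
    traj: Trajectory,
    patient_id,
    start_date: int,
    demographics: dict,
    consult_spacing: int = 30,
) -> list[dict]:
    """Render one trajectory as long-form extract rows.

    Row ``t`` (1-based consult index) carries the modality of state
    ``s_t``, the attendance flag of action ``a_t``, and an outcome code
    naming the next state (re-booking or a terminal exit).  A
    horizon-censored interaction gets one extra row for its final
    scheduled-but-uncaptured consult: modality known, attendance missing,
    outcome ``censored``.
    """
    rows = []
    for t, a in enumerate(traj.actions):
        s, s_next = State(traj.states[t]), State(traj.states[t + 1])
        if s_next.terminal:
            outcome = _TERMINAL_OUTCOME[s_next]
        else:
            outcome = _REBOOK_OUTCOME[s_next]
        rows.append(
            {
                "patient_id": patient_id,
                "consult_index": t + 1,
                "modality": _MODALITY_OF_STATE[s],
                "attended": a == Action.ATT,
                "outcome": outcome,
                "scheduled_date": start_date + t * consult_spacing,
                **demographics,
            }
        )
    if traj.censored:
        t = len(traj.actions)
        rows.append(
            {
                "patient_id": patient_id,
                "consult_index": t + 1,
                "modality": _MODALITY_OF_STATE[State(traj.states[-1])],
                "attended": None,
                "outcome": "censored",
                "scheduled_date": start_date + t * consult_spacing,
                **demographics,
            }
        )
    return rows


def generate_clinic_extract(
    cohort: pd.DataFrame,
    behaviour: BehaviourSpec,
    mdp: ClinicMDP,
    seed: int,
    date_range: tuple[int, int] = (0, 1000),
    consult_spacing: int = 30,
) -> pd.DataFrame:
    """Sample one trajectory per patient and render the long-form extract.

    Patients sharing resolved reward weights are sampled in one batch so
    the whole extract costs a handful of message-passing sweeps.
    """
    rng = np.random.default_rng(seed)
    demo_cols = ["sex", "funding", "interpreter", "first_nations", "age_band"]

    traj_of: dict[int, Trajectory] = {}
    if behaviour.attend_prob is not None:
        for i in range(len(cohort)):
            traj_of[i] = _rollout_bernoulli(mdp, behaviour.attend_prob, rng)
    else:
        thetas: dict[tuple, tuple[np.ndarray, list[int]]] = {}
        for i, row in cohort.iterrows():
            th = behaviour.resolve(row, row["patient_id"])
            key = tuple(np.round(th, 12))
            thetas.setdefault(key, (th, []))[1].append(i)
        for th, indices in thetas.values():
            samples = sample_trajectories(mdp, th, len(indices), rng)
            for i, tr in zip(indices, samples):
                traj_of[i] = tr

    start_dates = rng.integers(date_range[0], date_range[1] + 1, size=len(cohort))
    all_rows: list[dict] = []
    for i, row in cohort.iterrows():
        demo = {k: row[k] for k in demo_cols}
        all_rows.extend(
            render_trajectory_rows(
                traj_of[i],
                row["patient_id"],
                int(start_dates[i]),
                demo,
                consult_spacing,
            )
        )
    return pd.DataFrame(all_rows, columns=EXTRACT_COLUMNS)


def _rollout_bernoulli(
    mdp: ClinicMDP, attend_prob: float, rng: np.random.Generator
) -> Trajectory:
    """Environment rollout with i.i.d. Bernoulli attendance decisions."""
    s = int(rng.choice(mdp.n_states, p=mdp.p0))
    states, actions = [s], []
    for _ in range(mdp.horizon):
        if State(s).terminal:
            break
        a = Action.ATT if rng.random() < attend_prob else Action.NA
        s = int(rng.choice(mdp.n_states, p=mdp.T[s, a]))
        actions.append(int(a))
        states.append(s)
    return Trajectory(
        tuple(states), tuple(actions), censored=not State(states[-1]).terminal
    )


def window_filter(
    extract: pd.DataFrame, window_start: int, window_end: int
) -> tuple[pd.DataFrame, int]:
    """Drop interactions whose first consult predates the capture window.

    Mirrors the study's exclusion of partially captured interactions: an
    interaction is kept iff its first scheduled consult falls on or after
    ``window_start``.  Returns the retained extract and the number of
    excluded interactions.
    """
    if window_end < window_start:
        raise ValidationError("window_end must be >= window_start")
    first = extract.groupby("patient_id")["scheduled_date"].transform("min")
    keep = first >= window_start
    excluded = extract.loc[~keep, "patient_id"].nunique()
    return extract.loc[keep].reset_index(drop=True), int(excluded)
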