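"""Group partitioning, bootstrap uncertainty, and the preference test.

Uncertainty for every reported quantity comes from the nonparametric
bootstrap: whole patient trajectories (with their demographics) are
resampled with replacement — never individual consult rows, which are
dependent within a patient — and the reward weights refitted per
resample.  Confidence intervals default to the normal/symmetric form
(point estimate +/- 1.96 resample standard deviations), matching the
symmetric "value +/- halfwidth" reporting convention; percentile
intervals are available.

The modality preference test inverts the bootstrap CI of the contrast
``theta_TH - theta_IP`` against the null of no difference: the preference
is called significant at level alpha when the (1 - alpha) CI excludes
zero.  Between-group contrasts are deliberately unsupported: resamples of
different groups are not coupled, so their bootstrap distributions do not
license a between-group test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FitConfig, FitResult, fit_reward
from .mdp import ClinicMDP, State, Trajectory, ValidationError, trajectory_features
from .maxent import as_theta

__all__ = [
    "GroupSpec",
    "AnalysisConfig",
    "TrajectoryDataset",
    "BootstrapResult",
    "PreferenceTestResult",
    "partition_records",
    "bootstrap_fit",
    "preference_difference_test",
    "summarize_group_rewards",
]

#: Demographic columns a GroupSpec may partition on.
DEMOGRAPHIC_KEYS = ("sex", "funding", "interpreter", "first_nations", "age_band")


@dataclass(frozen=True)
class GroupSpec:
    """A demographic subgroup: one column and the level defining membership."""

    key: str
    level: str

    def __post_init__(self) -> None:
        if self.key not in DEMOGRAPHIC_KEYS:
            raise ValidationError(
                f"unknown demographic key {self.key!r}; valid keys: "
                f"{DEMOGRAPHIC_KEYS}"
            )


@dataclass(frozen=True)
class AnalysisConfig:
    """Bootstrap and test settings."""

    n_boot: int = 100
    alpha: float = 0.05
    seed: int = 0
    ci_method: str = "normal_symmetric"

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValidationError("n_boot must be >= 2")
        if not 0.0 < self.alpha < 0.5:
            raise ValidationError("alpha must lie in (0, 0.5)")
        if self.ci_method not in ("normal_symmetric", "percentile"):
            raise ValidationError(
                "ci_method must be 'normal_symmetric' or 'percentile'"
            )
        if self.ci_method == "percentile" and self.n_boot < 200:
            import logging

            logging.getLogger(__name__).warning(
                "percentile CIs with n_boot=%d < 200 are coarse; consider "
                "more resamples or the normal_symmetric method", self.n_boot,
            )


@dataclass
class TrajectoryDataset:
    """Trajectories with per-patient demographics, kept aligned by position."""

    trajectories: list[Trajectory]
    demographics: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.trajectories) != len(self.demographics):
            raise ValidationError(
                "trajectories and demographics must have equal length"
            )
        self.demographics = self.demographics.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.trajectories)

    def subset(self, mask: np.ndarray) -> "TrajectoryDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return TrajectoryDataset(
            [self.trajectories[i] for i in idx],
            self.demographics.iloc[idx],
        )


def partition_records(
    dataset: TrajectoryDataset, spec: GroupSpec
) -> tuple[TrajectoryDataset, TrajectoryDataset, TrajectoryDataset]:
    """Split a dataset into (group, complement, excluded-missing).

    Records whose value for ``spec.key`` is missing go to the excluded
    set; the three parts are disjoint and exhaust the input.
    """
    col = dataset.demographics[spec.key]
    missing = col.isna() | (col.astype(object) == "")
    in_group = (~missing) & (col == spec.level)
    complement = (~missing) & (col != spec.level)
    return (
        dataset.subset(in_group.to_numpy()),
        dataset.subset(complement.to_numpy()),
        dataset.subset(missing.to_numpy()),
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate plus resample distribution of the reward weights."""

    point: FitResult
    resamples: np.ndarray  # (B, 5)
    ci_halfwidth: np.ndarray  # (5,)
    ci_method: str
    seed: int

    @property
    def theta(self) -> np.ndarray:
        return self.point.theta_hat

    @property
    def n_boot(self) -> int:
        return self.resamples.shape[0]


def _precompute(mdp: ClinicMDP, data: list[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    phis = np.zeros((len(data), mdp.n_states))
    log_envs = np.zeros(len(data))
    for i, traj in enumerate(data):
        phis[i] = trajectory_features(traj, mdp.discount)
        lw = np.log(mdp.p0[traj.states[0]])
        for t, a in enumerate(traj.actions):
            lw += np.log(mdp.T[traj.states[t], a, traj.states[t + 1]])
        log_envs[i] = lw
    return phis, log_envs


def bootstrap_fit(
    mdp: ClinicMDP,
    data: list[Trajectory] | TrajectoryDataset,
    config: AnalysisConfig,
    fit_config: FitConfig | None = None,
) -> BootstrapResult:
    """Fit the reward weights and bootstrap them at the trajectory level.

    Draws ``config.n_boot`` resamples of size ``len(data)`` with
    replacement (seeded by ``config.seed``), refits each, and derives the
    CI halfwidth per ``config.ci_method``.  Fully reproducible by seed.
    """
    trajs = data.trajectories if isinstance(data, TrajectoryDataset) else data
    if not trajs:
        raise ValidationError("dataset must be non-empty")
    if fit_config is None:
        fit_config = FitConfig()
    phis, log_envs = _precompute(mdp, trajs)
    n = len(trajs)

    point = fit_reward(
        mdp, trajs, fit_config, _precomputed=(phis.mean(axis=0), log_envs.mean())
    )
    rng = np.random.default_rng(config.seed)
    resamples = np.zeros((config.n_boot, mdp.n_states))
    for b in range(config.n_boot):
        idx = rng.integers(0, n, n)
        try:
            res = fit_reward(
                mdp,
                trajs,
                fit_config,
                _precomputed=(phis[idx].mean(axis=0), log_envs[idx].mean()),
            )
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"bootstrap resample {b} failed: {exc}") from exc
        resamples[b] = res.theta_hat

    if config.ci_method == "normal_symmetric":
        sd = resamples.std(axis=0, ddof=1)
        halfwidth = 1.959963984540054 * sd
    else:
        lo = np.percentile(resamples, 100 * (config.alpha / 2), axis=0)
        hi = np.percentile(resamples, 100 * (1 - config.alpha / 2), axis=0)
        halfwidth = (hi - lo) / 2.0
    return BootstrapResult(
        point=point,
        resamples=resamples,
        ci_halfwidth=halfwidth,
        ci_method=config.ci_method,
        seed=config.seed,
    )


@dataclass(frozen=True)
class PreferenceTestResult:
    """Outcome of the telehealth-vs-in-person preference test."""

    difference: float  # theta_TH - theta_IP at the point estimate
    ci: tuple[float, float]
    significant: bool
    preferred: str  # "telehealth" | "in_person" | "none"


def preference_difference_test(
    boot: BootstrapResult, config: AnalysisConfig
) -> PreferenceTestResult:
    """Test H0: theta_TH - theta_IP = 0 by bootstrap CI inversion.

    The CI of the contrast comes from the resample distribution of the
    difference; significance at level ``config.alpha`` means the
    (1 - alpha) CI excludes zero, and the sign of the point contrast
    names the preferred modality.
    """
    if boot.n_boot < 2:
        raise ValidationError("need at least 2 resamples")
    diff_point = float(boot.theta[State.TH] - boot.theta[State.IP])
    diffs = boot.resamples[:, State.TH] - boot.resamples[:, State.IP]
    if config.ci_method == "normal_symmetric":
        from scipy.stats import norm

        z = norm.ppf(1 - config.alpha / 2)
        hw = z * diffs.std(ddof=1)
        ci = (diff_point - hw, diff_point + hw)
    else:
        ci = (
            float(np.percentile(diffs, 100 * (config.alpha / 2))),
            float(np.percentile(diffs, 100 * (1 - config.alpha / 2))),
        )
    significant = not (ci[0] <= 0.0 <= ci[1])
    if not significant:
        preferred = "none"
    else:
        preferred = "telehealth" if diff_point > 0 else "in_person"
    return PreferenceTestResult(
        difference=diff_point, ci=ci, significant=significant, preferred=preferred
    )


def preference_contrast(theta, direction: str = "telehealth") -> float:
    """Point contrast between modality preferences.

    ``telehealth`` returns theta_TH - theta_IP; ``in_person`` the
    negation.  A convenience for worked examples on published weight
    tables.
    """
    th = as_theta(theta)
    d = float(th[State.TH] - th[State.IP])
    return d if direction == "telehealth" else -d


def _fmt(value: float, hw: float) -> str:
    return f"{value:.2f} ± {hw:.2f}"


def summarize_group_rewards(
    results: dict[str, BootstrapResult],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Render the per-group reward table with CIs and preference flags.

    One row per group; five "value +/- halfwidth" cells rounded to two
    decimals; where the preference test is significant the preferred
    modality's cell is wrapped in a bold marker (``**``).  Between-group
    p-values are deliberately absent: the groupwise bootstrap does not
    support between-group testing.
    """
    if config is None:
        config = AnalysisConfig()
    rows = []
    labels = ("theta_IP", "theta_TH", "theta_DIS", "theta_ADM", "theta_REM")
    for name, boot in results.items():
        test = preference_difference_test(boot, config)
        cells = {
            lab: _fmt(boot.theta[j], boot.ci_halfwidth[j])
            for j, lab in enumerate(labels)
        }
        if test.preferred == "telehealth":
            cells["theta_TH"] = f"**{cells['theta_TH']}**"
        elif test.preferred == "in_person":
            cells["theta_IP"] = f"**{cells['theta_IP']}**"
        rows.append({"group": name, **cells, "preferred": test.preferred})
    return pd.DataFrame(
        rows, columns=["group", *labels, "preferred"]
    )
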