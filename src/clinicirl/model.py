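"""Model/Results front end for the attendance-preference analysis.

`ClinicPreferenceModel` bundles a trajectory dataset with the clinic
decision process; ``fit()`` runs the box-constrained maximum-likelihood
estimation and returns a :class:`ClinicPreferenceResults` carrying the
reward-weight estimates, their bootstrap uncertainty, the modality
preference test, and odds-ratio derivations.

    >>> mdp = build_clinic_mdp()
    >>> model = ClinicPreferenceModel.from_extract(extract_df, mdp)
    >>> res = model.fit()
    >>> print(res.summary())

The heavy lifting lives in the functional modules (``maxent``, ``fit``,
``stats``, ``oddsratio``); this class only orchestrates and presents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mdp import ClinicMDP, STATE_NAMES, State, Trajectory, ValidationError, build_clinic_mdp
from .fit import FitConfig, FitResult, fit_reward, nll_and_gradient
from .maxent import expected_features, sample_trajectories, state_action_marginals
from .stats import (
    AnalysisConfig,
    BootstrapResult,
    GroupSpec,
    PreferenceTestResult,
    TrajectoryDataset,
    bootstrap_fit,
    partition_records,
    preference_difference_test,
)
from .oddsratio import ORResult, bootstrap_odds_ratio, modality_na_odds_ratio

__all__ = ["ClinicPreferenceModel", "ClinicPreferenceResults"]


class ClinicPreferenceModel:
    """Maximum-entropy behaviour model of outpatient attendance.

    Parameters
    ----------
    data
        Trajectories, optionally with demographics
        (:class:`TrajectoryDataset`).
    mdp
        The clinic decision process; defaults to the expert-estimated
        dynamics at horizon 13.
    """

    def __init__(
        self,
        data: list[Trajectory] | TrajectoryDataset,
        mdp: ClinicMDP | None = None,
    ) -> None:
        self.mdp = mdp if mdp is not None else build_clinic_mdp()
        if isinstance(data, TrajectoryDataset):
            self.dataset: TrajectoryDataset | None = data
            self.trajectories = data.trajectories
        else:
            self.dataset = None
            self.trajectories = list(data)
        if not self.trajectories:
            raise ValidationError("model needs at least one trajectory")

    @classmethod
    def from_extract(
        cls, extract: pd.DataFrame, mdp: ClinicMDP | None = None
    ) -> "ClinicPreferenceModel":
        """Build from a long-form extract DataFrame (one row per consult)."""
        from .io import extract_trajectories

        mdp = mdp if mdp is not None else build_clinic_mdp()
        return cls(extract_trajectories(extract, mdp), mdp)

    def subset(self, spec: GroupSpec) -> "ClinicPreferenceModel":
        """The model restricted to one demographic group."""
        if self.dataset is None:
            raise ValidationError("subsetting requires demographics")
        group, _, _ = partition_records(self.dataset, spec)
        return ClinicPreferenceModel(group, self.mdp)

    def loglike(self, theta) -> float:
        """Mean log-likelihood of the data at ``theta``."""
        nll, _ = nll_and_gradient(self.mdp, self.trajectories, theta)
        return -nll

    def score(self, theta) -> np.ndarray:
        """Gradient of the mean log-likelihood at ``theta``."""
        _, grad = nll_and_gradient(self.mdp, self.trajectories, theta)
        return -grad

    def fit(
        self,
        config: FitConfig | None = None,
        bootstrap: bool = False,
        analysis: AnalysisConfig | None = None,
    ) -> "ClinicPreferenceResults":
        """Estimate the reward weights; optionally bootstrap them."""
        config = config or FitConfig()
        boot = None
        if bootstrap:
            boot = bootstrap_fit(
                self.mdp, self.trajectories, analysis or AnalysisConfig(), config
            )
            point = boot.point
        else:
            point = fit_reward(self.mdp, self.trajectories, config)
        return ClinicPreferenceResults(self, point, boot, analysis or AnalysisConfig())


class ClinicPreferenceResults:
    """Fitted reward weights with uncertainty and derived quantities."""

    def __init__(
        self,
        model: ClinicPreferenceModel,
        point: FitResult,
        boot: BootstrapResult | None,
        analysis: AnalysisConfig,
    ) -> None:
        self.model = model
        self.point = point
        self.boot = boot
        self.analysis = analysis

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """Reward-weight estimates in the fixed state order."""
        return self.point.theta_hat

    @property
    def nll(self) -> float:
        return self.point.nll

    def conf_int(self) -> np.ndarray:
        """95% bootstrap confidence intervals, shape (5, 2)."""
        self._require_boot()
        hw = self.boot.ci_halfwidth
        return np.column_stack([self.params - hw, self.params + hw])

    def bse(self) -> np.ndarray:
        """Bootstrap standard errors of the weights."""
        self._require_boot()
        return self.boot.resamples.std(axis=0, ddof=1)

    # -- inference ---------------------------------------------------------

    def preference_test(self) -> PreferenceTestResult:
        """Bootstrap test of telehealth-vs-in-person preference."""
        self._require_boot()
        return preference_difference_test(self.boot, self.analysis)

    def modality_odds_ratio(self) -> float:
        """Point non-attendance odds ratio, telehealth vs in-person."""
        return modality_na_odds_ratio(self.model.mdp, self.params)

    def modality_odds_ratio_bootstrap(self) -> ORResult:
        self._require_boot()
        return bootstrap_odds_ratio(
            self.model.mdp, self.boot, None, self.analysis,
            comparison="Telehealth/in person",
        )

    # -- model quantities --------------------------------------------------

    def fittedvalues(self) -> np.ndarray:
        """Model-expected feature counts at the estimate."""
        return expected_features(self.model.mdp, self.params)

    def marginals(self):
        """Time-indexed state/state-action marginal table at the estimate."""
        return state_action_marginals(self.model.mdp, self.params)

    def simulate(self, n: int, seed: int) -> list[Trajectory]:
        """Sample trajectories from the fitted behaviour model."""
        return sample_trajectories(self.model.mdp, self.params, n, seed)

    def plot_marginals(self, ax=None):
        """Plot state-occupancy marginals over time (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.marginals()
        for j, name in enumerate(STATE_NAMES):
            ax.plot(table.state_marginals[:, j], label=name)
        ax.set_xlabel("decision step")
        ax.set_ylabel("occupancy probability")
        ax.legend()
        return ax

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        n = len(self.model.trajectories)
        lines = [
            "Maximum-entropy attendance preference model",
            "=" * 55,
            f"No. trajectories: {n:>6}    Horizon: {self.model.mdp.horizon}",
            f"Mean NLL: {self.nll:>12.6f}    Converged: {self.point.converged}",
            "-" * 55,
        ]
        if self.boot is not None:
            lines.append(f"{'state':>6} {'theta':>9} {'std err':>9} {'95% CI':>21}")
            se = self.bse()
            ci = self.conf_int()
            for j, name in enumerate(STATE_NAMES):
                lines.append(
                    f"{name:>6} {self.params[j]:>9.3f} {se[j]:>9.3f} "
                    f"[{ci[j, 0]:>8.3f}, {ci[j, 1]:>8.3f}]"
                )
            test = self.preference_test()
            lines.append("-" * 55)
            lines.append(
                f"theta_TH - theta_IP: {test.difference:+.3f}  "
                f"CI [{test.ci[0]:+.3f}, {test.ci[1]:+.3f}]  "
                f"preferred: {test.preferred}"
            )
        else:
            lines.append(f"{'state':>6} {'theta':>9} {'at bound':>9}")
            for j, name in enumerate(STATE_NAMES):
                bound = "yes" if self.point.at_bound[j] else ""
                lines.append(f"{name:>6} {self.params[j]:>9.3f} {bound:>9}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def _require_boot(self) -> None:
        if self.boot is None:
            raise ValidationError(
                "this quantity needs bootstrap resamples; call "
                "fit(bootstrap=True)"
            )
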