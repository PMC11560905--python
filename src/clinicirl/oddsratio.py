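"""Non-attendance odds ratios derived from the behaviour model.

Two model-derived odds ratios translate learned reward weights into the
standard health-economic effect measure:

* the *modality* odds ratio compares the model's conditional
  non-attendance probability at telehealth versus in-person states within
  one reward vector,

      OR = [ sum_{t=1}^{L-1} p_t(TH, NA) / p_t(TH) ]
         / [ sum_{t=1}^{L-1} p_t(IP, NA) / p_t(IP) ] ,

* the *trait* odds ratio compares the summed conditional non-attendance
  probability over the non-terminal states between two groups' reward
  vectors (non-attendance is undefined at terminal states, whose terms
  are identically zero; the padding state is excluded).

Both use the exact time-indexed marginals of the trajectory distribution;
``t = 0`` is excluded by default, exactly as the sums are printed, with an
``include_t0`` switch for sensitivity analysis.  The inner sums are sums
of conditional probabilities and may exceed one; they are used as printed,
not renormalized.  Terms with zero state probability contribute zero.

These are model-derived associations, not causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mdp import ClinicMDP, State, Action, ValidationError
from .maxent import as_theta, state_action_marginals
from .stats import AnalysisConfig, BootstrapResult

__all__ = [
    "ORResult",
    "UndefinedORError",
    "modality_na_odds_ratio",
    "trait_na_odds_ratio",
    "bootstrap_odds_ratio",
    "odds_ratio_report",
]


class UndefinedORError(ZeroDivisionError):
    """The odds-ratio denominator carries no probability mass."""


@dataclass(frozen=True)
class ORResult:
    """A bootstrap odds ratio: mean over resamples with a symmetric 95% CI."""

    value: float
    ci: tuple[float, float]
    n_boot: int
    comparison: str

    def interpretation(self) -> str:
        """Reading of the estimate in the reporting convention."""
        if self.ci[0] <= 1.0 <= self.ci[1]:
            return "Inconclusive."
        side = "increased" if self.value > 1.0 else "decreased"
        strength = "Marginal " if abs(self.value - 1.0) < 0.1 else ""
        text = f"{strength}{side} NA predicted for {self.comparison.split('/')[0]}."
        return text[0].upper() + text[1:]


def _conditional_na_sums(
    mdp: ClinicMDP, theta, include_t0: bool
) -> np.ndarray:
    """Per-state sums over time of p_t(s, NA) / p_t(s), s in {IP, TH}.

    Zero-probability (unreachable) terms contribute zero.
    """
    if mdp.horizon < 2:
        raise ValidationError("odds ratios need horizon >= 2")
    table = state_action_marginals(mdp, as_theta(theta))
    t_start = 0 if include_t0 else 1
    out = np.zeros(2)
    for s in (State.IP, State.TH):
        total = 0.0
        for t in range(t_start, mdp.horizon):
            ps = table.state_marginals[t, s]
            if ps > 0.0:
                total += table.state_action_marginals[t, s, Action.NA] / ps
        out[s] = total
    return out


def modality_na_odds_ratio(
    mdp: ClinicMDP, theta, include_t0: bool = False
) -> float:
    """Telehealth-vs-in-person non-attendance odds ratio at one theta."""
    sums = _conditional_na_sums(mdp, theta, include_t0)
    if sums[State.IP] == 0.0:
        raise UndefinedORError(
            "in-person states carry no probability mass; modality OR undefined"
        )
    return float(sums[State.TH] / sums[State.IP])


def trait_na_odds_ratio(
    mdp: ClinicMDP, theta_b, theta_not_b, include_t0: bool = False
) -> float:
    """Trait-present vs trait-absent non-attendance odds ratio."""
    num = _conditional_na_sums(mdp, theta_b, include_t0).sum()
    den = _conditional_na_sums(mdp, theta_not_b, include_t0).sum()
    if den == 0.0:
        raise UndefinedORError("trait-absent group has zero NA mass; OR undefined")
    return float(num / den)


def bootstrap_odds_ratio(
    mdp: ClinicMDP,
    boot_b: BootstrapResult,
    boot_not_b: BootstrapResult | None,
    config: AnalysisConfig,
    comparison: str = "",
    include_t0: bool = False,
) -> ORResult:
    """Odds ratio with bootstrap uncertainty.

    With ``boot_not_b`` None the modality OR is computed per resample of
    ``boot_b``; otherwise the trait OR pairs resample ``i`` of the two
    bootstraps.  Reported value is the mean over resamples with a
    symmetric 95% CI (1.96 resample standard deviations).
    """
    if boot_not_b is not None and boot_not_b.n_boot != boot_b.n_boot:
        raise ValidationError(
            f"paired bootstraps must have equal resample counts "
            f"({boot_b.n_boot} != {boot_not_b.n_boot})"
        )
    ors = np.zeros(boot_b.n_boot)
    for i in range(boot_b.n_boot):
        if boot_not_b is None:
            ors[i] = modality_na_odds_ratio(mdp, boot_b.resamples[i], include_t0)
        else:
            ors[i] = trait_na_odds_ratio(
                mdp, boot_b.resamples[i], boot_not_b.resamples[i], include_t0
            )
    mean = float(ors.mean())
    hw = 1.959963984540054 * float(ors.std(ddof=1)) if len(ors) > 1 else 0.0
    return ORResult(
        value=mean, ci=(mean - hw, mean + hw), n_boot=len(ors), comparison=comparison
    )


def odds_ratio_report(results: list[ORResult]) -> pd.DataFrame:
    """Tabulate odds ratios with 95% CIs and interpretation strings."""
    rows = [
        {
            "comparison": r.comparison,
            "odds_ratio": round(r.value, 4),
            "ci_95": f"{r.ci[0]:.4f}–{r.ci[1]:.4f}",
            "interpretation": r.interpretation(),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["comparison", "odds_ratio", "ci_95", "interpretation"]
    )
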