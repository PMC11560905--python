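"""Extract I/O, trajectory conversion, configuration, and the pipeline.

The long-form extract is a CSV with one row per scheduled consult; a
machine-readable codebook declares every column, its type, allowed levels
and the missing token (empty field by default).  ``extract_trajectories``
converts extract rows back into state-action trajectories and is the
exact inverse of the synthetic renderer.

``run_full_analysis`` orchestrates the end-to-end pipeline: window
filtering, trajectory conversion, per-group bootstrap reward fits,
preference tests, odds ratios, and report/manifest output — deterministic
given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .mdp import (
    ClinicMDP,
    DynamicsParams,
    State,
    Trajectory,
    ValidationError,
    build_clinic_mdp,
    validate_trajectory,
)
from .fit import FitConfig
from .stats import (
    AnalysisConfig,
    BootstrapResult,
    GroupSpec,
    TrajectoryDataset,
    bootstrap_fit,
    partition_records,
    summarize_group_rewards,
    DEMOGRAPHIC_KEYS,
)
from .oddsratio import bootstrap_odds_ratio, odds_ratio_report
from .synthetic import (
    BehaviourSpec,
    CohortConfig,
    EXTRACT_COLUMNS,
    OUTCOME_CODES,
    generate_clinic_extract,
    generate_cohort,
    window_filter,
)
from .reference import REFERENCE_REWARDS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CODEBOOK",
    "read_extract",
    "write_extract",
    "extract_trajectories",
    "PipelineConfig",
    "load_config",
    "run_full_analysis",
    "markdown_table",
]

_STATE_OF_MODALITY = {"in_person": State.IP, "telehealth": State.TH}
_NEXT_STATE_OF_OUTCOME = {
    "rebooked_in_person": State.IP,
    "rebooked_telehealth": State.TH,
    "discharged": State.DIS,
    "admitted": State.ADM,
    "removed": State.REM,
}

#: Canonical codebook: column -> (type, allowed levels or None, nullable).
DEFAULT_CODEBOOK: dict[str, tuple[str, tuple[str, ...] | None, bool]] = {
    "patient_id": ("int", None, False),
    "consult_index": ("int", None, False),
    "modality": ("category", ("in_person", "telehealth"), False),
    # attendance is missing exactly on the final scheduled-but-uncaptured
    # consult of a horizon-censored interaction
    "attended": ("bool", None, True),
    "outcome": ("category", OUTCOME_CODES, False),
    "scheduled_date": ("int", None, False),
    "sex": ("category", ("male", "female"), True),
    "funding": ("category", ("private", "public"), True),
    "interpreter": ("category", ("required", "not_required"), True),
    "first_nations": ("category", ("yes", "no"), True),
    "age_band": ("category", ("<30", "30-39", "40-49", "50-59", "60-69", ">=70"), True),
}


def write_extract(extract: pd.DataFrame, path) -> None:
    """Write an extract as CSV; missing demographics become empty fields."""
    df = extract.copy()
    df["attended"] = df["attended"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, na_rep="")


def read_extract(path, codebook: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-form extract CSV.

    Raises with the offending row number on unknown levels, unparseable
    values, or duplicate (patient, consult index) pairs.  Empty fields in
    nullable columns become missing values; row order is preserved.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in codebook if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"extract is missing columns: {missing_cols}")

    out = {}
    for col, (ctype, levels, nullable) in codebook.items():
        vals = df[col]
        if ctype == "int":
            try:
                out[col] = vals.astype(int)
            except ValueError as exc:
                bad = vals[~vals.str.fullmatch(r"-?\d+")]
                row = bad.index[0] + 2  # 1-based + header
                raise ValidationError(
                    f"column {col!r}: unparseable value {bad.iloc[0]!r} at "
                    f"file row {row}"
                ) from exc
        elif ctype == "bool":
            allowed = ["true", "false"] + ([""] if nullable else [])
            bad = vals[~vals.isin(allowed)]
            if len(bad):
                raise ValidationError(
                    f"column {col!r}: unparseable boolean {bad.iloc[0]!r} at "
                    f"file row {bad.index[0] + 2}"
                )
            out[col] = vals.map({"true": True, "false": False, "": None})
        else:  # category
            v = vals.replace("", None)
            bad = v[~(v.isna() | v.isin(levels))]
            if len(bad):
                raise ValidationError(
                    f"column {col!r}: unknown level {bad.iloc[0]!r} at file "
                    f"row {bad.index[0] + 2}"
                )
            if not nullable and v.isna().any():
                row = v[v.isna()].index[0] + 2
                raise ValidationError(
                    f"column {col!r}: missing value at file row {row}"
                )
            out[col] = v
    result = pd.DataFrame(out)[list(codebook)]
    dup = result.duplicated(subset=["patient_id", "consult_index"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2
        raise ValidationError(
            f"duplicate (patient_id, consult_index) at file row {row}"
        )
    return result


def extract_trajectories(
    rows: pd.DataFrame, mdp: ClinicMDP
) -> TrajectoryDataset:
    """Convert extract rows into validated trajectories with demographics.

    Per patient: state ``t`` is the modality of consult ``t+1`` (consult
    indices are 1-based, trajectory time 0-based), the action is the
    attendance flag, and the final outcome code supplies the last state
    or the censoring flag.  Structural violations (terminal outcome on a
    non-final row, a final re-booking without censoring, or a
    zero-probability transition under the MDP) raise with the patient id.
    """
    trajectories: list[Trajectory] = []
    demo_rows = []
    demo_cols = list(DEMOGRAPHIC_KEYS)
    for pid, grp in rows.groupby("patient_id", sort=True):
        grp = grp.sort_values("consult_index")
        idx = grp["consult_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(grp) + 1)):
            raise ValidationError(
                f"patient {pid}: consult_index must run 1..n consecutively"
            )
        states = [int(_STATE_OF_MODALITY[m]) for m in grp["modality"]]
        attended = list(grp["attended"])
        outcomes = list(grp["outcome"])
        for j, oc in enumerate(outcomes[:-1]):
            if oc not in ("rebooked_in_person", "rebooked_telehealth"):
                raise ValidationError(
                    f"patient {pid}: non-final consult {j + 1} has "
                    f"terminal outcome {oc!r}"
                )
            if attended[j] is None:
                raise ValidationError(
                    f"patient {pid}: missing attendance on non-final "
                    f"consult {j + 1}"
                )
            nxt = int(_NEXT_STATE_OF_OUTCOME[oc])
            if nxt != states[j + 1]:
                raise ValidationError(
                    f"patient {pid}: outcome {oc!r} of consult {j + 1} "
                    f"contradicts modality of consult {j + 2}"
                )
        last = outcomes[-1]
        censored = last == "censored"
        if censored:
            # final scheduled consult fell outside the capture window:
            # its attendance and outcome are unobserved
            if attended[-1] is not None:
                raise ValidationError(
                    f"patient {pid}: censored final consult cannot carry an "
                    "attendance flag"
                )
            actions = [1 - int(a) for a in attended[:-1]]  # ATT=0, NA=1
        elif last in ("rebooked_in_person", "rebooked_telehealth"):
            raise ValidationError(
                f"patient {pid}: final consult re-books without a censor flag"
            )
        else:
            if attended[-1] is None:
                raise ValidationError(
                    f"patient {pid}: missing attendance on final consult"
                )
            actions = [1 - int(a) for a in attended]
            states.append(int(_NEXT_STATE_OF_OUTCOME[last]))
        traj = Trajectory(tuple(states), tuple(actions), censored=censored)
        ok, reason = validate_trajectory(traj, mdp)
        if not ok:
            raise ValidationError(f"patient {pid}: {reason}")
        trajectories.append(traj)
        demo = grp.iloc[0]
        demo_rows.append({"patient_id": pid, **{k: demo[k] for k in demo_cols}})
    return TrajectoryDataset(trajectories, pd.DataFrame(demo_rows))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class DynamicsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_ip: float = 0.95
    p_n: float = 0.55
    p_a: float = 0.15
    d: float = 0.65
    sigma_a: float = 0.001
    sigma_n: float = 0.0001
    horizon: int = 13
    discount: float = 1.0


class FitBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    box_lower: float = -1.0
    box_upper: float = 1.0
    gradient_tolerance: float = 1e-6
    max_iterations: int = 500


class AnalysisBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boot: int = 100
    alpha: float = 0.05
    ci_method: str = "normal_symmetric"


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 1026
    behaviour_group: str = "all"


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    dynamics: DynamicsBlock = Field(default_factory=DynamicsBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    groups: list[str] = ["sex", "funding", "interpreter", "first_nations"]
    extract_path: str | None = None
    window: tuple[int, int] | None = None
    output_dir: str = "clinicirl_output"
    seed: int = 0

    def build_mdp(self) -> ClinicMDP:
        d = self.dynamics
        return build_clinic_mdp(
            DynamicsParams(
                p_ip=d.p_ip, p_n=d.p_n, p_a=d.p_a, d=d.d,
                sigma_a=d.sigma_a, sigma_n=d.sigma_n,
            ),
            horizon=d.horizon,
            discount=d.discount,
        )

    def fit_config(self) -> FitConfig:
        return FitConfig(
            box_lower=self.fit.box_lower,
            box_upper=self.fit.box_upper,
            gradient_tolerance=self.fit.gradient_tolerance,
            max_iterations=self.fit.max_iterations,
        )

    def analysis_config(self, seed_offset: int = 0) -> AnalysisConfig:
        return AnalysisConfig(
            n_boot=self.analysis.n_boot,
            alpha=self.analysis.alpha,
            seed=self.seed + seed_offset,
            ci_method=self.analysis.ci_method,
        )


def load_config(path_or_dict) -> PipelineConfig:
    """Load and validate a pipeline config from YAML (path) or a dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = path_or_dict
    for key in raw.get("groups", []):
        if key not in DEMOGRAPHIC_KEYS:
            raise ValidationError(
                f"group key {key!r} is not a demographic column; valid keys: "
                f"{DEMOGRAPHIC_KEYS}"
            )
    return PipelineConfig.model_validate(raw)


def markdown_table(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown rendering of a DataFrame."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |"]
    lines.append("|" + "|".join(" --- " for _ in cols) + "|")
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _level_pairs(key: str) -> tuple[tuple[str, str], str]:
    """Comparison (B level, notB level) and label for a demographic key."""
    table = {
        "sex": (("female", "male"), "Female/Male"),
        "funding": (("private", "public"), "Private/Public"),
        "interpreter": (
            ("required", "not_required"),
            "Interpreter required/No interpreter required",
        ),
        "first_nations": (
            ("yes", "no"),
            "First Nations individuals/Non-First Nations individuals",
        ),
    }
    return table[key]


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write reports.

    Stages: obtain the extract (read or simulate), window-filter, convert
    to trajectories, bootstrap-fit per demographic group and its
    complement, run modality preference tests, compute the registry odds
    ratios, and write the reward table, odds-ratio table, marginal table,
    and a JSON run manifest into ``config.output_dir``.

    Returns a dict bundling every in-memory product.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mdp = config.build_mdp()

    stage = "input"
    try:
        if config.extract_path:
            extract = read_extract(config.extract_path)
        else:
            cohort = generate_cohort(
                CohortConfig(n_patients=config.simulate.n_patients, seed=config.seed)
            )
            behaviour = BehaviourSpec(
                theta=tuple(REFERENCE_REWARDS[config.simulate.behaviour_group])
            )
            extract = generate_clinic_extract(
                cohort, behaviour, mdp, seed=config.seed + 1
            )
        n_excluded = 0
        if config.window is not None:
            stage = "window_filter"
            extract, n_excluded = window_filter(extract, *config.window)

        stage = "extract_trajectories"
        dataset = extract_trajectories(extract, mdp)
        logger.info("converted %d interactions (%d excluded pre-window)",
                    len(dataset), n_excluded)

        stage = "fit"
        fit_cfg = config.fit_config()
        boots: dict[str, BootstrapResult] = {}
        boots["all"] = bootstrap_fit(mdp, dataset, config.analysis_config(), fit_cfg)
        pair_of_key: dict[str, tuple[str, str]] = {}
        offset = 1
        for key in config.groups:
            (lev_b, lev_nb), label = _level_pairs(key)
            for lev in (lev_b, lev_nb):
                group, complement, excluded = partition_records(
                    dataset, GroupSpec(key, lev)
                )
                name = f"{key}={lev}"
                if len(group) == 0:
                    logger.warning("group %s is empty; skipped", name)
                    continue
                boots[name] = bootstrap_fit(
                    mdp, group, config.analysis_config(offset), fit_cfg
                )
                offset += 1
            pair_of_key[key] = (f"{key}={lev_b}", f"{key}={lev_nb}")

        stage = "reports"
        reward_table = summarize_group_rewards(boots, config.analysis_config())
        or_results = [
            bootstrap_odds_ratio(
                mdp, boots["all"], None, config.analysis_config(),
                comparison="Telehealth/in person",
            )
        ]
        for key, (name_b, name_nb) in pair_of_key.items():
            if name_b in boots and name_nb in boots:
                _, label = _level_pairs(key)
                or_results.append(
                    bootstrap_odds_ratio(
                        mdp, boots[name_b], boots[name_nb],
                        config.analysis_config(), comparison=label,
                    )
                )
        or_table = odds_ratio_report(or_results)
        marginals = state_action_marginals_frame(mdp, boots["all"].theta)

        reward_table.to_csv(outdir / "reward_table.csv", index=False)
        (outdir / "reward_table.md").write_text(markdown_table(reward_table))
        or_table.to_csv(outdir / "odds_ratios.csv", index=False)
        (outdir / "odds_ratios.md").write_text(markdown_table(or_table))
        marginals.to_csv(outdir / "marginals.csv", index=False)

        manifest = {
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "n_interactions": len(dataset),
            "n_excluded_pre_window": n_excluded,
            "groups": sorted(boots),
            "versions": _versions(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
    return {
        "extract": extract,
        "dataset": dataset,
        "bootstraps": boots,
        "reward_table": reward_table,
        "odds_ratios": or_table,
        "manifest": manifest,
    }


def state_action_marginals_frame(mdp: ClinicMDP, theta) -> pd.DataFrame:
    from .maxent import state_action_marginals

    return state_action_marginals(mdp, theta).to_frame()


def _versions() -> dict:
    import numpy, pandas, scipy

    from . import __version__

    return {
        "clinicirl": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
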