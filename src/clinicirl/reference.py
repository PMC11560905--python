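"""Published reference values used as worked-example inputs.

``REFERENCE_REWARDS`` holds the reward-weight point estimates reported for
an Australian immunology outpatient clinic cohort (N = 1,026 patient
interactions), by demographic group, in the fixed state order
``(IP, TH, DIS, ADM, REM)``.  They serve three purposes in this package:

* ground-truth values for parameter-recovery experiments on synthetic data,
* inputs to the worked examples (preference contrasts, odds ratios),
* default behaviour for the synthetic cohort generator.

``REFERENCE_HALFWIDTHS`` carries the matching 95% bootstrap CI halfwidths
(100 resamples in the source analysis).  ``COMPARISON_REGISTRY`` fixes the
five standard odds-ratio comparisons reported for this cohort.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "REFERENCE_REWARDS",
    "REFERENCE_HALFWIDTHS",
    "REFERENCE_GROUP_SPECS",
    "COMPARISON_REGISTRY",
    "reference_theta",
]

REFERENCE_REWARDS: dict[str, np.ndarray] = {
    k: np.asarray(v, dtype=float)
    for k, v in {
        "all": (-0.76, -0.71, 0.95, -0.63, -0.98),
        "male": (-0.80, -0.77, 0.94, -0.72, -0.85),
        "female": (-0.74, -0.69, 0.96, -0.55, -1.00),
        "public": (-0.76, -0.75, 0.97, -0.66, -0.99),
        "private": (-1.00, -0.29, 0.10, -1.00, -0.73),
        "interpreter_required": (-0.77, -1.00, 0.56, -1.00, -0.74),
        "no_interpreter_required": (-0.75, -0.69, 0.98, -0.53, -1.00),
        "first_nations": (-0.86, -0.63, 0.29, -0.22, -0.19),
        "non_first_nations": (-0.74, -0.72, 0.98, -0.58, -1.00),
        "age_lt30": (-0.76, -0.83, 0.76, -0.89, -0.72),
        "age_30s": (-0.78, -0.78, 0.42, 0.01, -0.78),
        "age_40s": (-0.74, -0.72, 0.97, -0.70, -0.92),
        "age_50s": (-0.78, -0.70, 0.98, -0.85, -1.00),
        "age_60s": (-0.74, -0.66, 1.00, -0.69, -1.00),
        "age_ge70": (-0.80, -0.75, 0.99, -0.34, -1.00),
    }.items()
}

REFERENCE_HALFWIDTHS: dict[str, np.ndarray] = {
    k: np.asarray(v, dtype=float)
    for k, v in {
        "all": (0.01, 0.01, 0.02, 0.09, 0.02),
        "male": (0.01, 0.03, 0.04, 0.10, 0.05),
        "female": (0.01, 0.02, 0.02, 0.10, 0.00),
        "public": (0.01, 0.02, 0.02, 0.08, 0.01),
        "private": (0.00, 0.04, 0.35, 0.00, 0.15),
        "interpreter_required": (0.03, 0.00, 0.20, 0.00, 0.12),
        "no_interpreter_required": (0.01, 0.02, 0.02, 0.10, 0.00),
        "first_nations": (0.03, 0.06, 0.25, 0.26, 0.15),
        "non_first_nations": (0.01, 0.02, 0.02, 0.10, 0.00),
        "age_lt30": (0.01, 0.03, 0.07, 0.09, 0.06),
        "age_30s": (0.01, 0.04, 0.09, 0.14, 0.06),
        "age_40s": (0.02, 0.05, 0.03, 0.13, 0.04),
        "age_50s": (0.01, 0.03, 0.02, 0.09, 0.01),
        "age_60s": (0.02, 0.04, 0.01, 0.14, 0.00),
        "age_ge70": (0.02, 0.04, 0.02, 0.18, 0.00),
    }.items()
}

#: (demographic key, level) behind each reference group, for partitioning a
#: cohort the same way.  "all" has no key (whole cohort).
REFERENCE_GROUP_SPECS: dict[str, tuple[str, str] | None] = {
    "all": None,
    "male": ("sex", "male"),
    "female": ("sex", "female"),
    "public": ("funding", "public"),
    "private": ("funding", "private"),
    "interpreter_required": ("interpreter", "required"),
    "no_interpreter_required": ("interpreter", "not_required"),
    "first_nations": ("first_nations", "yes"),
    "non_first_nations": ("first_nations", "no"),
    "age_lt30": ("age_band", "<30"),
    "age_30s": ("age_band", "30-39"),
    "age_40s": ("age_band", "40-49"),
    "age_50s": ("age_band", "50-59"),
    "age_60s": ("age_band", "60-69"),
    "age_ge70": ("age_band", ">=70"),
}

#: The five standard odds-ratio comparisons: label -> (group_B, group_notB).
#: group_notB None marks the within-group modality comparison.
COMPARISON_REGISTRY: dict[str, tuple[str, str | None]] = {
    "Telehealth/in person": ("all", None),
    "Female/Male": ("female", "male"),
    "Private/Public": ("private", "public"),
    "Interpreter required/No interpreter required": (
        "interpreter_required",
        "no_interpreter_required",
    ),
    "First Nations individuals/Non-First Nations individuals": (
        "first_nations",
        "non_first_nations",
    ),
}


def reference_theta(group: str) -> np.ndarray:
    """Reference reward weights for a named demographic group (a copy)."""
    try:
        return REFERENCE_REWARDS[group].copy()
    except KeyError:
        raise KeyError(
            f"unknown reference group {group!r}; valid groups: "
            f"{sorted(REFERENCE_REWARDS)}"
        ) from None
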