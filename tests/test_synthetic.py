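"""Synthetic cohort and extract generation."""

import numpy as np
import pytest

from clinicirl.mdp import State, build_clinic_mdp
from clinicirl.reference import reference_theta
from clinicirl.synthetic import (
    BehaviourSpec,
    CohortConfig,
    generate_clinic_extract,
    generate_cohort,
    window_filter,
)
from clinicirl.io import extract_trajectories
from clinicirl.mdp import ValidationError


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(seed=101))


@pytest.fixture(scope="module")
def extract(cohort, mdp):
    behaviour = BehaviourSpec(theta=tuple(reference_theta("all")))
    return generate_clinic_extract(cohort, behaviour, mdp, seed=102)


def _binomial_band(n, p, z=3.0):
    sd = np.sqrt(n * p * (1 - p))
    return n * p - z * sd, n * p + z * sd


class TestCohort:
    def test_male_count_near_published_share(self, cohort):
        lo, hi = _binomial_band(1026, 0.3596)
        assert lo <= (cohort["sex"] == "male").sum() <= hi

    def test_interpreter_missingness_near_published_count(self, cohort):
        lo, hi = _binomial_band(1026, 53 / 1026)
        assert lo <= cohort["interpreter"].isna().sum() <= hi

    def test_age_bands_cover_cohort(self, cohort):
        assert cohort["age_band"].notna().all()
        assert set(cohort["age_band"]) == {
            "<30", "30-39", "40-49", "50-59", "60-69", ">=70",
        }

    def test_deterministic_given_seed(self, cohort):
        again = generate_cohort(CohortConfig(seed=101))
        assert cohort.equals(again)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            CohortConfig(age_band_probs=(0.5, 0.5, 0.1, 0.0, 0.0, 0.0))


class TestExtract:
    def test_first_consult_mostly_in_person(self, extract):
        first = extract[extract["consult_index"] == 1]
        n = len(first)
        lo, hi = _binomial_band(n, 0.95)
        assert lo <= (first["modality"] == "in_person").sum() <= hi

    def test_row_counts_bounded(self, extract, mdp):
        counts = extract.groupby("patient_id").size()
        # censored interactions carry one extra scheduled-but-uncaptured row
        assert counts.min() >= 1
        assert counts.max() <= mdp.horizon + 1

    def test_exactly_one_closing_row_per_patient(self, extract):
        closing = extract[
            ~extract["outcome"].isin(["rebooked_in_person", "rebooked_telehealth"])
        ]
        assert closing.groupby("patient_id").size().eq(1).all()
        last = extract.groupby("patient_id").tail(1)
        assert (
            ~last["outcome"].isin(["rebooked_in_person", "rebooked_telehealth"])
        ).all()

    def test_round_trip_reproduces_sampled_trajectories(self, cohort, mdp):
        from clinicirl.maxent import sample_trajectories

        behaviour = BehaviourSpec(theta=tuple(reference_theta("all")))
        extract = generate_clinic_extract(cohort, behaviour, mdp, seed=103)
        dataset = extract_trajectories(extract, mdp)
        # regenerating with the same seed must give identical trajectories
        expected = sample_trajectories(
            mdp, reference_theta("all"), len(cohort), np.random.default_rng(103)
        )
        assert dataset.trajectories == expected

    def test_interaction_lengths_match_clinic_profile(self, extract, mdp):
        dataset = extract_trajectories(extract, mdp)
        lengths = np.array([len(t) for t in dataset.trajectories])
        assert 2.2 <= lengths.mean() <= 3.2
        assert np.median(lengths) <= lengths.mean()  # right-skewed

    def test_discharge_admission_split_follows_behaviour_model(self, extract, mdp):
        # the trajectory-level behaviour model tilts stochastic environment
        # outcomes by the exponentiated downstream reward, so the discharge
        # share among attended exits exceeds the environment's raw 65% and
        # must match the model-implied (reward-tilted) proportion instead
        theta = reference_theta("all")
        tilt_dis = 0.65 * np.exp(theta[State.DIS])
        tilt_adm = 0.35 * np.exp(theta[State.ADM])
        p_model = tilt_dis / (tilt_dis + tilt_adm)  # ~0.90
        exits = extract[extract["outcome"].isin(["discharged", "admitted"])]
        n = len(exits)
        lo, hi = _binomial_band(n, p_model, z=3.5)
        assert lo <= (exits["outcome"] == "discharged").sum() <= hi

    def test_environment_faithful_mode_recovers_raw_split(self, mdp):
        # the Bernoulli attendance mode rolls out the true clinic dynamics,
        # so it reproduces the environment's 65:35 discharge:admission split
        cohort = generate_cohort(CohortConfig(n_patients=1026, seed=11))
        extract = generate_clinic_extract(
            cohort, BehaviourSpec(attend_prob=0.8), mdp, seed=12
        )
        exits = extract[extract["outcome"].isin(["discharged", "admitted"])]
        lo, hi = _binomial_band(len(exits), 0.65)
        assert lo <= (exits["outcome"] == "discharged").sum() <= hi

    def test_group_keyed_behaviour_resolution(self, mdp):
        cohort = generate_cohort(CohortConfig(n_patients=60, seed=5))
        behaviour = BehaviourSpec(
            theta=tuple(reference_theta("all")),
            group_key="sex",
            theta_by_level={
                "female": tuple(reference_theta("female")),
                "male": tuple(reference_theta("male")),
            },
        )
        extract = generate_clinic_extract(cohort, behaviour, mdp, seed=6)
        assert extract["patient_id"].nunique() == 60

    def test_unresolvable_group_raises(self, mdp):
        cohort = generate_cohort(CohortConfig(n_patients=5, seed=5))
        behaviour = BehaviourSpec(group_key="sex", theta_by_level={})
        with pytest.raises(ValidationError, match="cannot resolve"):
            generate_clinic_extract(cohort, behaviour, mdp, seed=6)

    def test_bernoulli_attendance_mode(self, mdp):
        cohort = generate_cohort(CohortConfig(n_patients=80, seed=7))
        behaviour = BehaviourSpec(attend_prob=0.8)
        extract = generate_clinic_extract(cohort, behaviour, mdp, seed=8)
        attended = extract["attended"].dropna()
        assert 0.65 <= attended.mean() <= 0.92


class TestWindowFilter:
    def test_pre_window_interactions_dropped(self, mdp):
        cohort = generate_cohort(CohortConfig(n_patients=30, seed=9))
        behaviour = BehaviourSpec(theta=tuple(reference_theta("all")))
        extract = generate_clinic_extract(
            cohort, behaviour, mdp, seed=10, date_range=(0, 200)
        )
        first = extract.groupby("patient_id")["scheduled_date"].min()
        cut = int(first.median())
        kept, excluded = window_filter(extract, cut, 10_000)
        assert excluded == (first < cut).sum()
        assert kept.groupby("patient_id")["scheduled_date"].min().ge(cut).all()

    def test_boundary_interaction_retained(self, extract):
        first = extract.groupby("patient_id")["scheduled_date"].min()
        boundary = int(first.min())
        kept, excluded = window_filter(extract, boundary, 10_000)
        assert excluded == 0
        assert len(kept) == len(extract)

    def test_bad_window_rejected(self, extract):
        with pytest.raises(ValidationError):
            window_filter(extract, 10, 5)
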