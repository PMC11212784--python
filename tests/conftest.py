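"""Shared fixtures: reference cohorts and configuration helpers."""

import warnings

import pytest
from hypothesis import settings

import intero_update as iu

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=100
)
settings.load_profile("ci")

# Mixed-model fits on small simulated cohorts routinely emit convergence
# chatter that is irrelevant to the assertions.
warnings.filterwarnings("ignore", module="statsmodels")


def equal_group_config(n_per_group: int = 30) -> iu.GeneratorConfig:
    """All group parameters equal: the null condition for calibration."""
    eq = lambda v: {"AN": v, "p-AN": v, "HC": v}  # noqa: E731
    return iu.default_config().replace(
        n_per_group=n_per_group,
        prior_belief_mean_by_group=eq(55.0),
        prior_confidence_mean_by_group=eq(55.0),
        lambda_mean_by_group=eq(0.47),
        resting_hr_mean_by_group=eq(71.0),
        edi_mean_by_group=eq(11.0),
        dass_depression_mean_by_group=eq(10.0),
        dass_anxiety_mean_by_group=eq(9.0),
        dass_stress_mean_by_group=eq(15.0),
        age_mean_by_group=eq(24.0),
        bmi_mean_by_group=eq(20.0),
    )


def zero_noise_config(**overrides) -> iu.GeneratorConfig:
    """All observation-noise SDs zero, so derived quantities are exact."""
    kwargs = dict(
        trial_confidence_jitter_sd=0.0,
        prospective_noise_sd=0.0,
        retrospective_noise_sd=0.0,
        trial_fraction_jitter_sd=0.0,
        beat_jitter_sd=0.0,
    )
    kwargs.update(overrides)
    return iu.default_config().replace(**kwargs)


@pytest.fixture(scope="session")
def reference_cohort() -> iu.Cohort:
    """One cohort under the reference (paper-condition) configuration."""
    return iu.generate_cohort(iu.default_config(), seed=11)


@pytest.fixture(scope="session")
def reference_derived(reference_cohort) -> "object":
    return iu.derived_table(
        reference_cohort.participants, reference_cohort.trials
    )


@pytest.fixture(scope="session")
def trials_long(reference_cohort, reference_derived):
    tl = reference_cohort.trials.merge(
        reference_derived[["id", "group", "site", "age"]], on="id"
    )
    tl["performance"] = 100.0 * (
        1.0
        - (tl["recorded_beats"] - tl["counted_beats"]).abs()
        / tl["recorded_beats"]
    )
    return tl
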