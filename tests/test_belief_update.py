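"""Belief-update equation, learning-rate, and model-registry tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import intero_update as iu
from intero_update.errors import (
    ConfigurationError,
    DomainError,
    UndefinedUpdateError,
)
from tests.conftest import zero_noise_config

beliefs = st.floats(0, 100, allow_nan=False)
precisions = st.floats(0, 100, allow_nan=False)


@pytest.mark.parametrize(
    "prior,evidence,pi_prior,pi_evidence,expected",
    [
        (40, 60, 10, 10, 50.0),  # equal precisions: midpoint
        (40, 60, 10, 0, 40.0),  # zero evidence weight returns the prior
        (40, 60, 0, 10, 60.0),  # zero prior weight returns the evidence
        (30, 70, 20, 60, 60.0),  # 30 + 0.75 * 40
    ],
)
def test_posterior_belief(prior, evidence, pi_prior, pi_evidence, expected):
    x = iu.BeliefUpdateInputs(prior, evidence, pi_prior, pi_evidence)
    assert iu.posterior_belief(x) == pytest.approx(expected)


def test_both_precisions_zero_is_undefined():
    with pytest.raises(UndefinedUpdateError):
        iu.BeliefUpdateInputs(40, 60, 0, 0)
    with pytest.raises(UndefinedUpdateError):
        iu.precision_weighted_lambda(0, 0)


@pytest.mark.parametrize(
    "pi_prior,pi_evidence,expected",
    [(50, 50, 0.5), (7, 0, 0.0), (0, 7, 1.0), (20, 60, 0.75)],
)
def test_precision_weighted_lambda(pi_prior, pi_evidence, expected):
    assert iu.precision_weighted_lambda(pi_prior, pi_evidence) == (
        pytest.approx(expected)
    )


def test_lambda_monotone_in_precisions():
    base = iu.precision_weighted_lambda(30, 30)
    assert iu.precision_weighted_lambda(30, 40) > base
    assert iu.precision_weighted_lambda(40, 30) < base


@pytest.mark.parametrize(
    "prior,evidence,posterior,expected",
    [
        (40, 60, 40, 0.0),  # no update
        (40, 60, 60, 1.0),  # full update
        (40, 60, 55, 0.75),  # 15/20
        (40, 60, 70, 1.5),  # overshoot reported unclamped
    ],
)
def test_actual_lambda(prior, evidence, posterior, expected):
    assert iu.actual_lambda(prior, evidence, posterior) == (
        pytest.approx(expected)
    )


def test_actual_lambda_degenerate_denominator():
    with pytest.raises(DomainError):
        iu.actual_lambda(50, 50, 60)


@given(
    prior=beliefs,
    evidence=beliefs,
    pi_prior=precisions,
    pi_evidence=precisions,
)
def test_update_composition_identity(prior, evidence, pi_prior, pi_evidence):
    """Recomputing the realised rate from the model's own posterior returns
    the precision ratio: the algebraic inverse linking the three equations."""
    if pi_prior + pi_evidence == 0 or abs(evidence - prior) <= 1e-6:
        return
    x = iu.BeliefUpdateInputs(prior, evidence, pi_prior, pi_evidence)
    post = iu.posterior_belief(x)
    lam = iu.precision_weighted_lambda(pi_prior, pi_evidence)
    assert iu.actual_lambda(prior, evidence, post) == pytest.approx(
        lam, abs=1e-10
    )
    # convex combination: posterior between prior and evidence
    assert min(prior, evidence) - 1e-12 <= post <= max(prior, evidence) + 1e-12


@pytest.mark.parametrize(
    "raw,max_raw,expected",
    [(0, 36, 100.0), (36, 36, 0.0), (9, 36, 75.0), (5, 10, 50.0)],
)
def test_rescale_edi(raw, max_raw, expected):
    assert iu.rescale_edi(raw, max_raw) == pytest.approx(expected)


def test_rescale_edi_domain_errors():
    with pytest.raises(DomainError):
        iu.rescale_edi(-1, 36)
    with pytest.raises(DomainError):
        iu.rescale_edi(40, 36)
    with pytest.raises(DomainError):
        iu.rescale_edi(5, 0)


def test_registry_enumerates_the_grid():
    targets = iu.target_model_registry()
    combos = {(s.evidence_source, s.precision_proxy) for s in targets}
    assert len(targets) == 4 and len(combos) == 4
    assert all(s.baseline_mode == "none" for s in targets)
    assert len(iu.full_model_registry()) == 7
    with pytest.raises(ConfigurationError):
        iu.spec_by_label("9.9")


def test_modelspec_validation():
    with pytest.raises(ConfigurationError):
        iu.ModelSpec("nonsense", "performance_confidence")
    with pytest.raises(ConfigurationError):
        iu.ModelSpec("performance", "performance_confidence", "maybe")


def test_baseline_predictions_are_evidence_and_prior(reference_derived):
    lam_one = iu.predict_cohort(
        reference_derived, iu.spec_by_label("b.2")
    )
    lam_zero = iu.predict_cohort(
        reference_derived, iu.spec_by_label("b.0")
    )
    obs = reference_derived.set_index("id")
    assert np.allclose(
        lam_one.to_numpy(),
        obs.loc[lam_one.index, "retrospective_belief"].to_numpy(),
    )
    assert np.allclose(
        lam_zero.to_numpy(),
        obs.loc[lam_zero.index, "prior_belief"].to_numpy(),
    )


def test_baselines_bracket_target_predictions(reference_derived):
    """Every precision-weighted prediction lies between the no-learning and
    full-learning baselines participant-wise."""
    spec = iu.spec_by_label("x.2")
    pred = iu.predict_cohort(reference_derived, spec)
    lam_one = iu.predict_cohort(reference_derived, iu.spec_by_label("b.2"))
    lam_zero = iu.predict_cohort(reference_derived, iu.spec_by_label("b.0"))
    common = pred.index.intersection(lam_one.index).intersection(
        lam_zero.index
    )
    low = np.minimum(lam_one[common], lam_zero[common])
    high = np.maximum(lam_one[common], lam_zero[common])
    assert ((pred[common] >= low - 1e-12) & (pred[common] <= high + 1e-12)).all()


@pytest.mark.parametrize("label", ["x.1", "x.2", "x.3", "x.4"])
def test_zero_noise_roundtrip_per_spec(label):
    """A noise-free cohort generated under a spec is predicted exactly by
    that spec."""
    spec = iu.spec_by_label(label)
    cfg = zero_noise_config(
        n_per_group=30,
        generating_evidence=spec.evidence_source,
        generating_proxy=spec.precision_proxy,
    )
    cohort = iu.generate_cohort(cfg, seed=3)
    derived = iu.derived_table(cohort.participants, cohort.trials)
    pred = iu.predict_cohort(derived, spec)
    obs = derived.set_index("id").loc[pred.index, "posterior_prospective"]
    assert np.max(np.abs(obs.to_numpy() - pred.to_numpy())) < 1e-9


def test_cohort_learning_rates_flags_degenerates(reference_derived):
    rates = iu.cohort_learning_rates(
        reference_derived, iu.spec_by_label("x.2")
    )
    assert ((rates["lambda_weighted"] >= 0) & (
        rates["lambda_weighted"] <= 1
    )).all()
    ok = rates[~rates["degenerate"]]
    assert np.allclose(
        ok["optimality_gap"],
        (ok["lambda_actual"] - ok["lambda_weighted"]).abs(),
    )
    assert rates.loc[rates["degenerate"], "lambda_actual"].isna().all()
    with pytest.raises(ConfigurationError):
        iu.cohort_learning_rates(reference_derived, iu.spec_by_label("b.0"))
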