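"""Group-regression, mixed-model, Bayes-factor, Holm, and mediation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import intero_update as iu
from intero_update.errors import DomainError
from intero_update.inference import icc_from_components
from intero_update.pipeline import stage_seed
from tests.conftest import equal_group_config


def _toy_frame():
    rng = np.random.default_rng(0)
    n = 60
    groups = np.repeat(["HC", "AN", "p-AN"], n // 3)
    x = rng.normal(size=n)
    return pd.DataFrame(
        {"group": groups, "x": x, "y": 1.0 + 2.0 * x, "age": rng.normal(25, 4, n)}
    )


def test_ols_exact_linear_fit_recovers_slope():
    df = _toy_frame()
    res = iu.ols_group_regression(df, "y", covariates=("x",), group_term=False)
    assert res.coef("x")["beta"] == pytest.approx(2.0)
    assert res.coef("Intercept")["beta"] == pytest.approx(1.0)
    assert res.r2_adj == pytest.approx(1.0)


def test_ols_hand_least_squares():
    df = pd.DataFrame(
        {"x": [0.0, 1.0, 2.0, 3.0], "y": [1.0, 3.0, 5.0, 7.0],
         "group": ["HC", "HC", "AN", "AN"]}
    )
    res = iu.ols_group_regression(
        df, "y", covariates=("x",), group_term=False
    )
    assert res.coef("x")["beta"] == pytest.approx(2.0)
    assert res.coef("Intercept")["beta"] == pytest.approx(1.0)


def test_ols_group_reference_is_hc(reference_derived):
    res = iu.ols_group_regression(reference_derived, "prior_belief", ())
    terms = set(res.terms["term"])
    assert {"Intercept", "AN", "p-AN"} <= terms
    # intercept estimates the HC mean
    hc_mean = reference_derived.loc[
        reference_derived["group"] == "HC", "prior_belief"
    ].mean()
    assert res.coef("Intercept")["beta"] == pytest.approx(hc_mean)
    ci = res.coef("AN")
    assert ci["ci_low"] <= ci["beta"] <= ci["ci_high"]


def test_ols_outcome_rescaling_equivariance(reference_derived):
    a = iu.ols_group_regression(reference_derived, "prior_belief", ())
    scaled = reference_derived.assign(
        prior_belief=lambda d: 3.0 * d["prior_belief"] + 7.0
    )
    b = iu.ols_group_regression(scaled, "prior_belief", ())
    assert b.coef("AN")["beta"] == pytest.approx(3.0 * a.coef("AN")["beta"])
    assert b.coef("AN")["se"] == pytest.approx(3.0 * a.coef("AN")["se"])
    assert b.coef("AN")["t"] == pytest.approx(a.coef("AN")["t"])
    assert b.coef("AN")["p"] == pytest.approx(a.coef("AN")["p"])


def test_ols_collinearity_error():
    df = _toy_frame().assign(x2=lambda d: 2.0 * d["x"])
    with pytest.raises(DomainError):
        iu.ols_group_regression(
            df, "y", covariates=("x", "x2"), group_term=False
        )


def test_mlm_reports_components_and_matches_ols_in_degenerate_limit():
    """With no participant/site variance the mixed model collapses to OLS.

    The estimated variance components (and hence the GLS/OLS gap) vanish
    only asymptotically, so this uses a reasonably large cohort.
    """
    rng = np.random.default_rng(2)
    n = 600
    groups = np.repeat(["HC", "AN", "p-AN"], n // 3)
    age = rng.normal(25, 4, n)
    df = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            # interleave sites so they are not aliased with group
            "site": [f"S{i % 3}" for i in range(n)],
            "group": groups,
            "age": age,
        }
    )
    long = df.loc[df.index.repeat(4)].reset_index(drop=True)
    long["performance"] = 50.0 + rng.normal(0, 10, len(long))
    mlm = iu.mlm_performance(long)
    ols = iu.ols_group_regression(long, "performance")
    assert mlm.coef("AN")["beta"] == pytest.approx(
        ols.coef("AN")["beta"], abs=1e-3
    )
    assert mlm.icc == pytest.approx(0.0, abs=0.05)
    assert set(mlm.variance_components) == {
        "sigma2",
        "tau_participant",
        "tau_site",
    }
    assert 0 <= mlm.r2_marginal <= mlm.r2_conditional <= 1


def test_mlm_detects_participant_variance(trials_long):
    res = iu.mlm_performance(trials_long)
    vc = res.variance_components
    assert vc["tau_participant"] > vc["tau_site"]
    assert res.icc > 0.3  # persistent counting style dominates trial noise


def test_mlm_single_site_drops_component(trials_long):
    one_site = trials_long.assign(site="S0")
    with pytest.warns(UserWarning, match="single level"):
        res = iu.mlm_performance(one_site)
    assert res.variance_components["tau_site"] == 0.0


def test_icc_from_reported_variance_components():
    # components in the style of the per-trial performance model
    assert icc_from_components(678.62, 30.48, 227.25) == pytest.approx(
        0.757, abs=1e-3
    )


def test_bayes_factor_algebra(reference_derived):
    res = iu.bayes_factor_group(reference_derived, "performance")
    assert res.bf10 == pytest.approx(
        np.exp((res.bic_null - res.bic_alternative) / 2)
    )
    # identical BICs -> BF 1 (inconclusive); boundary at 2 ln 3
    assert np.exp((0.0) / 2) == 1.0
    assert np.exp(2 * np.log(3) / 2) == pytest.approx(3.0)


def test_bayes_factor_null_cohorts_favour_null():
    bfs = []
    for rep in range(20):
        cohort = iu.generate_cohort(
            equal_group_config(40), seed=stage_seed(31, f"bf-{rep}")
        )
        derived = iu.derived_table(cohort.participants, cohort.trials)
        bfs.append(iu.bayes_factor_group(derived, "performance").bf10)
    assert np.median(bfs) < 1.0


@pytest.mark.parametrize(
    "pvalues,expected",
    [
        ([0.2], [0.2]),
        ([0.01, 0.04], [0.02, 0.04]),
        ([0.03, 0.03, 0.03], [0.09, 0.09, 0.09]),
        ([0.01, 0.02, 0.9], [0.03, 0.04, 0.9]),
    ],
)
def test_holm_hand_examples(pvalues, expected):
    assert iu.holm_correct(pvalues) == pytest.approx(expected)


def test_holm_rejects_invalid_p():
    with pytest.raises(DomainError):
        iu.holm_correct([0.5, 1.2])


def _holm_bruteforce(p):
    """Step-down definition applied literally."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8)
)
def test_holm_matches_stepdown_definition(pvalues):
    assert iu.holm_correct(pvalues) == pytest.approx(
        _holm_bruteforce(pvalues)
    )
    # adjusted values never decrease below the raw ones
    assert (iu.holm_correct(pvalues) >= np.asarray(pvalues) - 1e-12).all()


def test_mediation_mediator_independent_of_group_is_no_mediation():
    rng = np.random.default_rng(4)
    n = 300
    groups = np.repeat(["HC", "AN", "p-AN"], n // 3)
    shift = np.where(groups == "AN", -0.09, np.where(groups == "p-AN", -0.02, 0.0))
    df = pd.DataFrame(
        {
            "group": groups,
            "dass_depression": rng.normal(10, 5, n),  # no group shift
            "dass_stress": rng.normal(15, 6, n),
            "lambda_weighted": 0.47 + shift + rng.normal(0, 0.15, n),
        }
    )
    res = iu.mediation_analysis(df)
    assert res.verdict == "no_mediation"
    assert set(res.verdict_by_mediator.values()) == {"no_mediation"}


def test_mediation_full_chain_detected():
    cfg = iu.default_config().replace(
        n_per_group=200, mediation_mode="mood_mediated"
    )
    cohort = iu.generate_cohort(cfg, seed=37)
    derived = iu.derived_table(cohort.participants, cohort.trials)
    rates = iu.cohort_learning_rates(
        derived, iu.spec_by_label("x.2")
    ).reset_index()
    data = rates.merge(
        derived[["id", "dass_depression", "dass_stress"]], on="id"
    )
    res = iu.mediation_analysis(data)
    assert res.verdict == "mediation_consistent"
    assert res.attenuation["attenuated"]
    assert "AN" in res.followup or "p-AN" in res.followup
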