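"""Heartbeat-counting scoring and derived-measure tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import intero_update as iu
from intero_update.errors import DomainError, SchemaError


@pytest.mark.parametrize(
    "recorded,counted,expected",
    [
        (30, 30, 1.0),  # exact counting
        (30, 0, 0.0),  # nothing reported
        (40, 30, 0.75),  # 1 - 10/40
        (40, 50, 0.75),  # over-counting by the same margin
        (10, 25, -0.5),  # over-counting beyond 2x is negative, not clipped
    ],
)
def test_trial_accuracy(recorded, counted, expected):
    assert iu.score_trial(recorded, counted) == pytest.approx(expected)


def test_trial_accuracy_rejects_nonpositive_recorded():
    with pytest.raises(DomainError):
        iu.score_trial(0, 5)
    with pytest.raises(DomainError):
        iu.score_trial(10, -1)


@given(data=st.data(), recorded=st.integers(min_value=1, max_value=200))
def test_trial_accuracy_symmetric_in_miscount_direction(data, recorded):
    """Over- and under-counting by the same margin score identically."""
    delta = data.draw(st.integers(min_value=0, max_value=recorded))
    assert iu.score_trial(recorded, recorded + delta) == pytest.approx(
        iu.score_trial(recorded, recorded - delta)
    )


@pytest.mark.parametrize(
    "pairs,expected",
    [
        ([(30, 30), (45, 45), (60, 60)], 100.0),  # perfect on every trial
        ([(20, 0), (30, 0), (40, 0)], 0.0),  # zero reporting anchors at 0
        ([(20, 15), (30, 33), (40, 30)], 80.0),  # mean of .75, .9, .75
        ([(50, 25), (50, 25), (50, 25), (50, 25)], 50.0),  # 1/n generalises
    ],
)
def test_performance_score(pairs, expected):
    assert iu.performance_score(pairs) == pytest.approx(expected)


def test_performance_score_invariant_to_trial_order():
    pairs = [(20, 15), (30, 33), (40, 30), (55, 41)]
    assert iu.performance_score(pairs) == pytest.approx(
        iu.performance_score(pairs[::-1])
    )


def test_performance_score_empty_is_error():
    with pytest.raises(DomainError):
        iu.performance_score([])


def _participant(**overrides):
    fields = dict(
        id="P1",
        group="HC",
        site="S0",
        age=25.0,
        bmi=21.0,
        prior_prospective_belief=46.0,
        prior_prospective_confidence=50.0,
        trials=(
            iu.TrialRecord(25, 30, 30, 50.0),
            iu.TrialRecord(35, 40, 30, 60.0),
            iu.TrialRecord(45, 50, 40, 70.0),
            iu.TrialRecord(65, 70, 56, 80.0),
        ),
        posterior_retrospective_belief=60.0,
        posterior_prospective_half=40.0,
        posterior_prospective_double=60.0,
        edi3_id_raw=9.0,
        dass_depression=7.0,
        dass_anxiety=7.0,
        dass_stress=11.0,
    )
    fields.update(overrides)
    return iu.ParticipantRecord(**fields)


def test_derive_measures_composites():
    d = iu.derive_measures(_participant())
    # posterior prospective = midpoint of half/double forecasts
    assert d.posterior_prospective_belief == pytest.approx(50.0)
    # unweighted mean trial confidence
    assert d.performance_confidence == pytest.approx(65.0)
    # performance: mean of 1, .75, .8, .8 times 100
    assert d.performance == pytest.approx(100 * (1 + 0.75 + 0.8 + 0.8) / 4)
    assert d.prediction_error == pytest.approx(d.performance - 46.0)


def test_derive_measures_prediction_error_example():
    p = _participant(
        prior_prospective_belief=46.0,
        trials=(
            iu.TrialRecord(25, 30, 24, None),
            iu.TrialRecord(45, 50, 40, None),
        ),
    )
    d = iu.derive_measures(p)
    assert d.performance == pytest.approx(80.0)
    assert d.prediction_error == pytest.approx(34.0)
    # no confidences present: flagged missing, not zero
    assert d.performance_confidence is None


def test_participant_record_validates_bounds():
    with pytest.raises(DomainError):
        _participant(prior_prospective_belief=105.0)
    with pytest.raises(DomainError):
        _participant(group="XX")


def test_itpe_hand_example_and_anchors():
    # two-participant cohort, population-SD z-scores
    out = iu.itpe([10.0, 20.0], [80.0, 60.0])
    assert out == pytest.approx([-2.0, 2.0])
    # participant at the cohort mean on both measures scores 0
    out = iu.itpe([5.0, 10.0, 15.0], [30.0, 50.0, 70.0])
    assert out[1] == pytest.approx(0.0)


def test_itpe_zero_variance_is_error():
    with pytest.raises(DomainError):
        iu.itpe([5.0, 5.0], [1.0, 2.0])


@given(
    st.lists(
        st.tuples(
            st.floats(0, 40),
            st.floats(0, 100),
        ),
        min_size=3,
        max_size=30,
    )
)
def test_itpe_sums_to_zero(rows):
    sens = [r[0] for r in rows]
    acc = [r[1] for r in rows]
    if np.std(sens) == 0 or np.std(acc) == 0:
        return
    assert abs(iu.itpe(sens, acc).sum()) < 1e-9


def test_performance_table_matches_scalar_path(reference_cohort):
    """The vectorised trials-table scorer agrees with per-trial scoring."""
    table = iu.performance_table(reference_cohort.trials)
    first = reference_cohort.trials[
        reference_cohort.trials["id"] == "P0000"
    ]
    manual = iu.performance_score(
        list(zip(first["recorded_beats"], first["counted_beats"]))
    )
    assert table.loc["P0000", "performance"] == pytest.approx(manual)
    assert table.loc["P0000", "performance_confidence"] == pytest.approx(
        first["confidence"].mean()
    )


def test_derived_table_schema_errors(reference_cohort):
    with pytest.raises(SchemaError):
        iu.derived_table(
            reference_cohort.participants.drop(columns=["prior_belief"]),
            reference_cohort.trials,
        )
    dupes = pd.concat(
        [reference_cohort.participants, reference_cohort.participants.head(1)]
    )
    with pytest.raises(SchemaError):
        iu.derived_table(dupes, reference_cohort.trials)
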