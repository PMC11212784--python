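"""Heartbeat-counting task (HCT) scoring and participant-level derived measures.

Interoceptive accuracy on the heartbeat-counting task is scored with the
Schandry transformation: each counting trial contributes
``1 - |recorded - counted| / recorded`` and the participant's Performance is
100 times the mean over trials.  Scores are *not* clipped below zero — the
transformation permits negative values when a participant over-counts by more
than the number of recorded beats, and clipping would bias aggregates.

The module also derives the composite measures used downstream: the posterior
prospective self-efficacy belief (mean of the half- and double-duration
forecasts), performance confidence (mean of per-trial confidence ratings), the
prediction error (Performance minus prior prospective belief), and the
interoceptive trait prediction error (ITPE) z-difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

GROUP_LABELS = ("AN", "p-AN", "HC")

#: Columns required of a participants table (generated or observed).
PARTICIPANT_COLUMNS = (
    "id",
    "group",
    "site",
    "age",
    "bmi",
    "prior_belief",
    "prior_confidence",
    "retrospective_belief",
    "posterior_half",
    "posterior_double",
    "edi3_id",
    "dass_depression",
    "dass_anxiety",
    "dass_stress",
)

#: Columns required of a trials table.
TRIAL_COLUMNS = (
    "id",
    "trial",
    "duration_s",
    "recorded_beats",
    "counted_beats",
    "confidence",
)


@dataclass(frozen=True)
class TrialRecord:
    """One heartbeat-counting trial.

    Parameters
    ----------
    duration : float
        Counting-window length in seconds; must be positive.
    recorded_beats : int
        Actual heartbeats during the window (from the heart-rate monitor).
    counted_beats : int
        Heartbeats the participant reported feeling.
    confidence : float, optional
        Trial-wise confidence rating on 0-100; absent for protocols that did
        not collect it.
    """

    duration: float
    recorded_beats: int
    counted_beats: int
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError(f"duration must be positive, got {self.duration}")
        if self.recorded_beats <= 0:
            raise DomainError(
                f"recorded_beats must be positive, got {self.recorded_beats}"
            )
        if self.counted_beats < 0:
            raise DomainError(
                f"counted_beats must be nonnegative, got {self.counted_beats}"
            )
        if self.confidence is not None and not 0 <= self.confidence <= 100:
            raise DomainError(
                f"confidence must lie in [0, 100], got {self.confidence}"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """All per-participant measurements entering the analysis.

    Belief and confidence fields are 0-100 percentage ratings; ``group`` is one
    of ``AN`` (acute anorexia nervosa), ``p-AN`` (post-acute) or ``HC``
    (healthy control).
    """

    id: str
    group: str
    site: str
    age: float
    bmi: float
    prior_prospective_belief: float
    prior_prospective_confidence: float
    trials: tuple[TrialRecord, ...]
    posterior_retrospective_belief: float
    posterior_prospective_half: float
    posterior_prospective_double: float
    edi3_id_raw: float
    dass_depression: float
    dass_anxiety: float
    dass_stress: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise DomainError(
                f"group must be one of {GROUP_LABELS}, got {self.group!r}"
            )
        for name in (
            "prior_prospective_belief",
            "prior_prospective_confidence",
            "posterior_retrospective_belief",
            "posterior_prospective_half",
            "posterior_prospective_double",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 100:
                raise DomainError(f"{name} must lie in [0, 100], got {value}")


@dataclass(frozen=True)
class DerivedMeasures:
    """Participant-level summaries computed from raw records."""

    performance: float
    per_trial_performance: tuple[float, ...]
    performance_confidence: Optional[float]
    posterior_prospective_belief: float
    prediction_error: float
    itpe: Optional[float] = None


def score_trial(recorded_beats: float, counted_beats: float) -> float:
    """Schandry accuracy for a single trial: ``1 - |rec - cnt| / rec``.

    Returns 1 for exact counting, 0 when nothing is reported, and may be
    negative when the participant over-counts by more than the recorded
    number of beats (not clipped).
    """
    if recorded_beats <= 0:
        raise DomainError(
            f"recorded_beats must be positive, got {recorded_beats}"
        )
    if counted_beats < 0:
        raise DomainError(
            f"counted_beats must be nonnegative, got {counted_beats}"
        )
    return 1.0 - abs(recorded_beats - counted_beats) / recorded_beats


def performance_score(trials: Sequence[TrialRecord | tuple]) -> float:
    """Performance percentage: 100 x mean per-trial Schandry accuracy.

    The canonical three-trial 1/3 averaging is generalised to 1/n so the same
    scorer serves protocols with any trial count (the four-trial schedule uses
    1/4).  Accepts ``TrialRecord`` objects or ``(recorded, counted)`` pairs.
    """
    if len(trials) == 0:
        raise DomainError("performance_score requires at least one trial")
    scores = []
    for t in trials:
        if isinstance(t, TrialRecord):
            scores.append(score_trial(t.recorded_beats, t.counted_beats))
        else:
            recorded, counted = t[0], t[1]
            scores.append(score_trial(recorded, counted))
    return 100.0 * float(np.mean(scores))


def derive_measures(p: ParticipantRecord) -> DerivedMeasures:
    """Compute the derived summaries for one participant.

    ``performance_confidence`` is the unweighted mean of the trial confidences
    that are present; if no trial carries a confidence it is ``None`` (flagged
    missing, never silently zero).
    """
    per_trial = tuple(
        score_trial(t.recorded_beats, t.counted_beats) for t in p.trials
    )
    performance = 100.0 * float(np.mean(per_trial))
    confidences = [t.confidence for t in p.trials if t.confidence is not None]
    performance_confidence = (
        float(np.mean(confidences)) if confidences else None
    )
    posterior_prospective = (
        p.posterior_prospective_half + p.posterior_prospective_double
    ) / 2.0
    return DerivedMeasures(
        performance=performance,
        per_trial_performance=per_trial,
        performance_confidence=performance_confidence,
        posterior_prospective_belief=posterior_prospective,
        prediction_error=performance - p.prior_prospective_belief,
    )


def itpe(
    cohort_sensibility: Sequence[float], cohort_accuracy: Sequence[float]
) -> np.ndarray:
    """Interoceptive trait prediction error: z(sensibility) - z(accuracy).

    Both vectors are z-scored within the supplied cohort using the cohort mean
    and population (ddof=0) standard deviation, so the result sums to zero
    across the cohort.  Positive values indicate participants who rate their
    everyday interoceptive sensibility higher than their objective accuracy
    warrants.
    """
    sens = np.asarray(cohort_sensibility, dtype=float)
    acc = np.asarray(cohort_accuracy, dtype=float)
    if sens.shape != acc.shape:
        raise DomainError("sensibility and accuracy vectors differ in length")
    if sens.size < 2:
        raise DomainError("itpe requires at least two participants")
    sd_sens = sens.std()
    sd_acc = acc.std()
    if sd_sens == 0 or sd_acc == 0:
        raise DomainError("itpe requires nonzero variance in both vectors")
    return (sens - sens.mean()) / sd_sens - (acc - acc.mean()) / sd_acc


def _require_columns(
    df: pd.DataFrame, columns: Sequence[str], table: str
) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns: {missing}")


def performance_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant Performance and performance confidence from a long
    trials table.

    Returns a frame indexed by participant ``id`` with columns
    ``performance`` (percentage) and ``performance_confidence`` (mean trial
    confidence; NaN when no confidences are present).
    """
    _require_columns(
        trials,
        ("id", "recorded_beats", "counted_beats"),
        "trials",
    )
    if (trials["recorded_beats"] <= 0).any():
        bad = trials.loc[trials["recorded_beats"] <= 0, "id"].unique()
        raise DomainError(
            f"recorded_beats must be positive (participants {list(bad)})"
        )
    work = trials.copy()
    work["trial_score"] = 1.0 - (
        (work["recorded_beats"] - work["counted_beats"]).abs()
        / work["recorded_beats"]
    )
    grouped = work.groupby("id", sort=False)
    out = pd.DataFrame(
        {"performance": 100.0 * grouped["trial_score"].mean()}
    )
    if "confidence" in work.columns:
        out["performance_confidence"] = grouped["confidence"].mean()
    else:
        out["performance_confidence"] = np.nan
    return out


def derived_table(
    participants: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Join participants with trial-derived scores into the analysis table.

    This is the central per-participant table every downstream stage consumes:
    one row per participant with group, site, covariates, beliefs,
    confidences, Performance and the composite posterior prospective belief.
    """
    _require_columns(participants, PARTICIPANT_COLUMNS, "participants")
    if participants["id"].duplicated().any():
        dupes = participants.loc[participants["id"].duplicated(), "id"]
        raise SchemaError(f"duplicate participant ids: {list(dupes)}")
    unknown = set(participants["group"]) - set(GROUP_LABELS)
    if unknown:
        raise SchemaError(
            f"unknown group labels {sorted(unknown)}; expected {GROUP_LABELS}"
        )
    perf = performance_table(trials)
    df = participants.merge(perf, left_on="id", right_index=True, how="left")
    if df["performance"].isna().any():
        missing = df.loc[df["performance"].isna(), "id"]
        raise SchemaError(
            f"participants without trials: {list(missing)}"
        )
    df["posterior_prospective"] = (
        df["posterior_half"] + df["posterior_double"]
    ) / 2.0
    df["prediction_error"] = df["performance"] - df["prior_belief"]
    return df
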