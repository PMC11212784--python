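"""Conjugate-Gaussian belief updating, learning rates, and the model registry.

The core computation is a one-shot precision-weighted update of a prior belief
mu_theta toward a piece of evidence y,

    mu_post = mu_theta + pi_eps / (pi_theta + pi_eps) * (y - mu_theta),

where pi_theta and pi_eps are nonnegative precision weights for the prior and
the evidence.  The multiplier lambda = pi_eps / (pi_theta + pi_eps) is the
precision-weighted learning rate (Bayesian precision ratio); the empirically
realised update fraction lambda_actual = (mu_post - mu_theta) / (y - mu_theta)
recovers lambda exactly when the observed posterior follows the update rule.

A registry of competing prediction rules instantiates the update with
different observable stand-ins: the prior is always the prior prospective
self-efficacy belief with prior prospective confidence as its precision proxy;
the evidence is either measured Performance or the posterior retrospective
belief; the evidence precision proxy is either performance confidence or the
EDI-3 Interoceptive Deficits score rescaled to a 0-100 "success rate".
Baseline rules fix lambda at 1 (posterior = evidence) or 0 (posterior =
prior).  None of these rules has free parameters: each maps observed fields
directly to a predicted posterior prospective belief.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, UndefinedUpdateError

logger = logging.getLogger(__name__)

EVIDENCE_SOURCES = ("performance", "retrospective_belief")
PRECISION_PROXIES = ("performance_confidence", "edi3_id_rescaled")
BASELINE_MODES = ("none", "lambda_one", "lambda_zero")

#: Default maximum raw score of the EDI-3 Interoceptive Deficits subscale.
EDI3_ID_MAX_RAW = 36.0

#: |evidence - prior| below this is treated as a degenerate denominator.
DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one belief-update prediction rule.

    ``label`` follows the grid naming used in reports: ``x.1`` to ``x.4``
    index the evidence x proxy combinations (the ``x`` is replaced by the
    group-panel number when reporting), ``b.*`` are the fixed-lambda
    baselines.  When ``baseline_mode`` is not ``none`` the precision proxy is
    ignored because lambda is fixed.
    """

    evidence_source: str
    precision_proxy: str
    baseline_mode: str = "none"
    label: str = ""

    def __post_init__(self) -> None:
        if self.evidence_source not in EVIDENCE_SOURCES:
            raise ConfigurationError(
                f"evidence_source must be one of {EVIDENCE_SOURCES}, "
                f"got {self.evidence_source!r}"
            )
        if self.precision_proxy not in PRECISION_PROXIES:
            raise ConfigurationError(
                f"precision_proxy must be one of {PRECISION_PROXIES}, "
                f"got {self.precision_proxy!r}"
            )
        if self.baseline_mode not in BASELINE_MODES:
            raise ConfigurationError(
                f"baseline_mode must be one of {BASELINE_MODES}, "
                f"got {self.baseline_mode!r}"
            )


def target_model_registry() -> tuple[ModelSpec, ...]:
    """The four target rules: the 2x2 evidence x precision-proxy grid.

    x.1: Performance evidence, performance-confidence proxy.
    x.2: retrospective-belief evidence, performance-confidence proxy.
    x.3: Performance evidence, rescaled EDI-3-ID proxy.
    x.4: retrospective-belief evidence, rescaled EDI-3-ID proxy.
    """
    return (
        ModelSpec("performance", "performance_confidence", "none", "x.1"),
        ModelSpec(
            "retrospective_belief", "performance_confidence", "none", "x.2"
        ),
        ModelSpec("performance", "edi3_id_rescaled", "none", "x.3"),
        ModelSpec("retrospective_belief", "edi3_id_rescaled", "none", "x.4"),
    )


def baseline_model_registry() -> tuple[ModelSpec, ...]:
    """The three fixed-lambda baselines: lambda=1 under each evidence source
    (the posterior is the evidence itself) and lambda=0 (no learning)."""
    return (
        ModelSpec(
            "performance", "performance_confidence", "lambda_one", "b.1"
        ),
        ModelSpec(
            "retrospective_belief",
            "performance_confidence",
            "lambda_one",
            "b.2",
        ),
        ModelSpec(
            "retrospective_belief",
            "performance_confidence",
            "lambda_zero",
            "b.0",
        ),
    )


def full_model_registry() -> tuple[ModelSpec, ...]:
    """All seven rules: four targets plus three baselines."""
    return target_model_registry() + baseline_model_registry()


def spec_by_label(label: str) -> ModelSpec:
    """Look up a registry spec by its label."""
    for spec in full_model_registry():
        if spec.label == label:
            return spec
    raise ConfigurationError(f"unknown model label {label!r}")


@dataclass(frozen=True)
class BeliefUpdateInputs:
    """Inputs to one belief update: prior mean, evidence, precision weights."""

    prior_belief: float
    evidence: float
    prior_precision: float
    evidence_precision: float

    def __post_init__(self) -> None:
        if self.prior_precision < 0 or self.evidence_precision < 0:
            raise DomainError("precision weights must be nonnegative")
        if self.prior_precision == 0 and self.evidence_precision == 0:
            raise UndefinedUpdateError(
                "both precision weights are zero; the update is undefined"
            )


@dataclass(frozen=True)
class LearningRateResult:
    """Precision-weighted and realised learning rates for one participant.

    ``lambda_weighted`` lies in [0, 1] by construction; ``lambda_actual`` is
    reported unclamped (overshoot beyond the evidence, or updating away from
    it, is diagnostically meaningful).  ``degenerate`` flags an evidence equal
    to the prior, where the realised rate is undefined.
    """

    lambda_weighted: float
    lambda_actual: float | None
    optimality_gap: float | None
    degenerate: bool = False


def precision_weighted_lambda(
    prior_precision: float, evidence_precision: float
) -> float:
    """Precision ratio pi_eps / (pi_theta + pi_eps) in [0, 1]."""
    if prior_precision < 0 or evidence_precision < 0:
        raise DomainError("precision weights must be nonnegative")
    total = prior_precision + evidence_precision
    if total == 0:
        raise UndefinedUpdateError(
            "both precision weights are zero; lambda is undefined"
        )
    return evidence_precision / total


def posterior_belief(x: BeliefUpdateInputs) -> float:
    """Posterior mean of the conjugate-Gaussian update.

    Always a convex combination of prior and evidence, so the result lies in
    the closed interval between them.
    """
    lam = precision_weighted_lambda(x.prior_precision, x.evidence_precision)
    return x.prior_belief + lam * (x.evidence - x.prior_belief)


def actual_lambda(
    prior_belief: float, evidence: float, observed_posterior: float
) -> float:
    """Realised update fraction (posterior - prior) / (evidence - prior).

    0 when the posterior equals the prior, 1 when it equals the evidence;
    not clamped.  Undefined (raises) when evidence equals the prior.
    """
    denom = evidence - prior_belief
    if abs(denom) <= DEGENERATE_TOL:
        raise DomainError(
            "evidence equals prior belief; the realised learning rate is "
            "undefined (degenerate denominator)"
        )
    return (observed_posterior - prior_belief) / denom


def learning_rates(
    prior_belief: float,
    evidence: float,
    observed_posterior: float,
    prior_precision: float,
    evidence_precision: float,
) -> LearningRateResult:
    """Joint precision-weighted / realised learning-rate computation."""
    lam = precision_weighted_lambda(prior_precision, evidence_precision)
    if abs(evidence - prior_belief) <= DEGENERATE_TOL:
        return LearningRateResult(lam, None, None, degenerate=True)
    actual = actual_lambda(prior_belief, evidence, observed_posterior)
    return LearningRateResult(lam, actual, abs(actual - lam))


def rescale_edi(raw: float, max_raw: float = EDI3_ID_MAX_RAW) -> float:
    """Rescale an EDI-3-ID raw score to a 0-100 "success percentage rate".

    Higher interoceptive-deficit scores map to *lower* values, so the result
    can stand alongside Performance and confidence ratings as a precision
    weight: ``(1 - raw / max_raw) * 100``.
    """
    if max_raw <= 0:
        raise DomainError(f"max_raw must be positive, got {max_raw}")
    raw_arr = np.asarray(raw, dtype=float)
    if np.any(raw_arr < 0) or np.any(raw_arr > max_raw):
        raise DomainError(
            f"raw score must lie in [0, {max_raw}], got {raw}"
        )
    out = (1.0 - raw_arr / max_raw) * 100.0
    return float(out) if np.isscalar(raw) else out


def prediction_inputs(
    derived: pd.DataFrame,
    spec: ModelSpec,
    edi_max_raw: float = EDI3_ID_MAX_RAW,
) -> pd.DataFrame:
    """Per-participant update inputs and validity flags for one spec.

    Returns a frame indexed like ``derived`` with columns ``prior``,
    ``evidence``, ``prior_precision``, ``evidence_precision``, ``valid`` and
    ``exclusion_reason``.  Participants whose required fields are missing, or
    whose precision weights are both zero, are flagged invalid (and logged by
    the callers), never silently imputed.
    """
    prior = derived["prior_belief"].astype(float)
    if spec.evidence_source == "performance":
        evidence = derived["performance"].astype(float)
    else:
        evidence = derived["retrospective_belief"].astype(float)
    prior_precision = derived["prior_confidence"].astype(float)
    if spec.precision_proxy == "performance_confidence":
        evidence_precision = derived["performance_confidence"].astype(float)
    else:
        evidence_precision = pd.Series(
            rescale_edi(derived["edi3_id"].to_numpy(float), edi_max_raw),
            index=derived.index,
        )
    out = pd.DataFrame(
        {
            "prior": prior,
            "evidence": evidence,
            "prior_precision": prior_precision,
            "evidence_precision": evidence_precision,
        }
    )
    reason = pd.Series("", index=derived.index, dtype=object)
    missing = out.isna().any(axis=1)
    reason[missing] = "missing_field"
    if spec.baseline_mode == "none":
        both_zero = (out["prior_precision"] == 0) & (
            out["evidence_precision"] == 0
        )
        reason[both_zero & ~missing] = "zero_precisions"
    out["valid"] = reason == ""
    out["exclusion_reason"] = reason
    return out


def predict_cohort(
    derived: pd.DataFrame,
    spec: ModelSpec,
    edi_max_raw: float = EDI3_ID_MAX_RAW,
) -> pd.Series:
    """Predicted posterior prospective beliefs under one spec.

    ``derived`` is the per-participant analysis table (see
    ``scoring.derived_table``).  Returns a float Series indexed by participant
    ``id`` containing only the participants valid under the spec; excluded
    ids are logged with their reasons.
    """
    inputs = prediction_inputs(derived, spec, edi_max_raw)
    excluded = derived.loc[~inputs["valid"], "id"]
    if len(excluded):
        logger.info(
            "model %s: excluded %d participants (%s)",
            spec.label or spec.evidence_source,
            len(excluded),
            dict(
                inputs.loc[~inputs["valid"], "exclusion_reason"]
                .value_counts()
            ),
        )
    ok = inputs[inputs["valid"]]
    ids = derived.loc[ok.index, "id"]
    if spec.baseline_mode == "lambda_one":
        values = ok["evidence"].to_numpy(float)
    elif spec.baseline_mode == "lambda_zero":
        values = ok["prior"].to_numpy(float)
    else:
        lam = ok["evidence_precision"] / (
            ok["prior_precision"] + ok["evidence_precision"]
        )
        values = (
            ok["prior"] + lam * (ok["evidence"] - ok["prior"])
        ).to_numpy(float)
    return pd.Series(values, index=pd.Index(ids, name="id"), name=spec.label)


def cohort_learning_rates(
    derived: pd.DataFrame,
    spec: ModelSpec,
    edi_max_raw: float = EDI3_ID_MAX_RAW,
) -> pd.DataFrame:
    """Per-participant learning rates under one (non-baseline) spec.

    Returns a frame indexed by participant id with ``group``,
    ``lambda_weighted``, ``lambda_actual``, ``optimality_gap`` and
    ``degenerate``.  The realised rate uses the observed posterior prospective
    belief; participants with evidence equal to the prior keep their
    precision-weighted rate but carry NaN realised rate and gap.
    """
    if spec.baseline_mode != "none":
        raise ConfigurationError(
            "learning rates are defined only for baseline_mode='none' specs"
        )
    inputs = prediction_inputs(derived, spec, edi_max_raw)
    ok = inputs[inputs["valid"]]
    sub = derived.loc[ok.index]
    lam = (
        ok["evidence_precision"]
        / (ok["prior_precision"] + ok["evidence_precision"])
    ).to_numpy(float)
    denom = (ok["evidence"] - ok["prior"]).to_numpy(float)
    degenerate = np.abs(denom) <= DEGENERATE_TOL
    posterior = sub["posterior_prospective"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        actual = (posterior - ok["prior"].to_numpy(float)) / denom
    actual[degenerate] = np.nan
    gap = np.abs(actual - lam)
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info(
            "model %s: %d participants with evidence == prior excluded from "
            "realised-learning-rate analyses",
            spec.label,
            n_deg,
        )
    return pd.DataFrame(
        {
            "group": sub["group"].to_numpy(),
            "lambda_weighted": lam,
            "lambda_actual": actual,
            "optimality_gap": gap,
            "degenerate": degenerate,
        },
        index=pd.Index(sub["id"], name="id"),
    )
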