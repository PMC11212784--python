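"""Model fit (MAE, BIC), model comparison, and Bayesian-optimality analysis.

Each candidate update rule maps observed fields to predicted posterior
prospective beliefs with no fitted parameters, so models are compared purely
on their residuals.  BIC uses a Gaussian residual likelihood with the variance
profiled out: ``n * ln(RSS / n) + k * ln(n)``, with ``k = 1`` (the residual
variance) for every rule in the registry so penalties are comparable; the
residual sum of squares is floored at a small epsilon to avoid minus
infinity on exact fits.  Comparisons are computed on the intersection of
participants valid under every compared rule, so all BIC values share the
same n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .update import (
    ModelSpec,
    cohort_learning_rates,
    prediction_inputs,
)

logger = logging.getLogger(__name__)

GROUP_SCOPES = ("all", "HC", "AN", "p-AN")

#: Panel numbers used in report labels: 1 = all participants, 2 = HC,
#: 3 = AN, 4 = p-AN (so a spec labelled "x.2" becomes "2.2" on the HC panel).
PANEL_NUMBER = {"all": "1", "HC": "2", "AN": "3", "p-AN": "4"}


def mae(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError(
            f"observed and predicted lengths differ: "
            f"{obs.shape} vs {pred.shape}"
        )
    if obs.size < 1:
        raise DomainError("mae requires at least one observation")
    return float(np.mean(np.abs(obs - pred)))


def bic(
    observed: Sequence[float],
    predicted: Sequence[float],
    k: int = 1,
    rss_floor: float = 1e-9,
) -> float:
    """Gaussian-profile BIC: ``n * ln(RSS / n) + k * ln(n)``.

    ``k`` counts the parameters charged to the rule (default 1, the profiled
    residual variance).  ``rss_floor`` guards the logarithm on exact fits.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError(
            f"observed and predicted lengths differ: "
            f"{obs.shape} vs {pred.shape}"
        )
    n = obs.size
    if n < 2:
        raise DomainError(f"bic requires n >= 2, got n={n}")
    if k < 0:
        raise DomainError(f"k must be nonnegative, got {k}")
    rss = max(float(np.sum((obs - pred) ** 2)), rss_floor)
    return n * np.log(rss / n) + k * np.log(n)


@dataclass(frozen=True)
class ModelFit:
    """Fit of one update rule on one participant panel."""

    spec: ModelSpec
    group_scope: str
    n: int
    residuals: np.ndarray
    mae: float
    bic: float
    k: int

    @property
    def panel_label(self) -> str:
        """Report label with the panel number substituted for the ``x``."""
        return self.spec.label.replace(
            "x", PANEL_NUMBER.get(self.group_scope, "x")
        )


@dataclass(frozen=True)
class ComparisonTable:
    """All fits on a common panel and participant set, with the winner."""

    group_scope: str
    fits: tuple[ModelFit, ...]
    winner: str
    participant_ids: tuple = field(repr=False, default=())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "panel": self.group_scope,
                "label": f.panel_label,
                "spec_label": f.spec.label,
                "evidence": f.spec.evidence_source,
                "proxy": f.spec.precision_proxy,
                "baseline": f.spec.baseline_mode,
                "n": f.n,
                "k": f.k,
                "mae": f.mae,
                "bic": f.bic,
                "winner": f.spec.label == self.winner,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)


def compare_models(
    derived: pd.DataFrame,
    specs: Sequence[ModelSpec],
    group_scope: str = "all",
    k: int = 1,
    edi_max_raw: float = 36.0,
) -> ComparisonTable:
    """Fit every spec on the common valid participant subset and pick the
    winner.

    The winner minimises BIC; ties break toward the lower ``k``, then toward
    the declared spec order (logged).  MAE is reported alongside as the
    secondary measure.
    """
    if len(specs) < 2:
        raise DomainError("compare_models requires at least two specs")
    if group_scope not in GROUP_SCOPES:
        raise DomainError(
            f"group_scope must be one of {GROUP_SCOPES}, got {group_scope!r}"
        )
    panel = (
        derived
        if group_scope == "all"
        else derived[derived["group"] == group_scope]
    )
    panel = panel.reset_index(drop=True)
    valid = np.ones(len(panel), dtype=bool)
    inputs_by_spec = {}
    for spec in specs:
        inputs = prediction_inputs(panel, spec, edi_max_raw)
        inputs_by_spec[spec.label] = inputs
        valid &= inputs["valid"].to_numpy()
    valid &= panel["posterior_prospective"].notna().to_numpy()
    common = panel[valid]
    if len(common) < 2:
        raise InsufficientDataError(
            f"fewer than 2 participants valid under all specs on panel "
            f"{group_scope!r} (got {len(common)})"
        )
    observed = common["posterior_prospective"].to_numpy(float)
    fits = []
    for spec in specs:
        ok = inputs_by_spec[spec.label].loc[common.index]
        if spec.baseline_mode == "lambda_one":
            pred = ok["evidence"].to_numpy(float)
        elif spec.baseline_mode == "lambda_zero":
            pred = ok["prior"].to_numpy(float)
        else:
            lam = ok["evidence_precision"] / (
                ok["prior_precision"] + ok["evidence_precision"]
            )
            pred = (
                ok["prior"] + lam * (ok["evidence"] - ok["prior"])
            ).to_numpy(float)
        residuals = observed - pred
        fits.append(
            ModelFit(
                spec=spec,
                group_scope=group_scope,
                n=len(common),
                residuals=residuals,
                mae=mae(observed, pred),
                bic=bic(observed, pred, k=k),
                k=k,
            )
        )
    order = {spec.label: i for i, spec in enumerate(specs)}
    ranked = sorted(
        fits, key=lambda f: (f.bic, f.k, order[f.spec.label])
    )
    best = ranked[0]
    near_ties = [
        f
        for f in ranked[1:]
        if np.isclose(f.bic, best.bic, rtol=0, atol=1e-12)
    ]
    if near_ties:
        logger.info(
            "panel %s: BIC tie between %s and %s resolved by (k, order)",
            group_scope,
            best.spec.label,
            [f.spec.label for f in near_ties],
        )
    return ComparisonTable(
        group_scope=group_scope,
        fits=tuple(fits),
        winner=best.spec.label,
        participant_ids=tuple(common["id"]),
    )


def comparison_grid(
    derived: pd.DataFrame,
    specs: Sequence[ModelSpec],
    k: int = 1,
    edi_max_raw: float = 36.0,
) -> pd.DataFrame:
    """Run ``compare_models`` on all four panels and stack the results."""
    frames = []
    for scope in GROUP_SCOPES:
        try:
            table = compare_models(derived, specs, scope, k, edi_max_raw)
        except InsufficientDataError as exc:
            logger.warning("panel %s skipped: %s", scope, exc)
            continue
        frames.append(table.to_frame())
    return pd.concat(frames, ignore_index=True)


def optimality_gap_analysis(
    derived: pd.DataFrame,
    spec: ModelSpec,
    edi_max_raw: float = 36.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant |lambda_actual - lambda| and group summaries.

    Returns ``(per_participant, by_group)``.  Participants with a degenerate
    denominator (evidence equal to the prior) are excluded from the summaries
    and counted in the ``n_degenerate`` column; realised rates are unclamped
    and the counts falling outside [0, 1] are summarised.
    """
    rates = cohort_learning_rates(derived, spec, edi_max_raw)
    ok = rates[~rates["degenerate"]]
    summaries = []
    for label, sub in [("all", ok)] + [
        (g, ok[ok["group"] == g]) for g in ("HC", "AN", "p-AN")
    ]:
        n_deg = int(
            rates["degenerate"].sum()
            if label == "all"
            else rates.loc[rates["group"] == label, "degenerate"].sum()
        )
        summaries.append(
            {
                "group": label,
                "n": len(sub),
                "n_degenerate": n_deg,
                "lambda_weighted_mean": sub["lambda_weighted"].mean(),
                "lambda_actual_mean": sub["lambda_actual"].mean(),
                "gap_mean": sub["optimality_gap"].mean(),
                "gap_sd": sub["optimality_gap"].std(),
                "n_actual_outside_unit": int(
                    (
                        (sub["lambda_actual"] < 0)
                        | (sub["lambda_actual"] > 1)
                    ).sum()
                ),
            }
        )
    return rates, pd.DataFrame(summaries)
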