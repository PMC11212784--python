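"""Group-level statistics: regressions, the per-trial mixed model, Bayes
factors, Holm correction, and Baron-Kenny mediation.

Conventions throughout: HC is the reference level of the group factor (dummy
coding), tests are two-sided at alpha = 0.05, and confidence intervals are
95%.  Ordinary regressions delegate to statsmodels OLS; the per-trial
performance model is a linear mixed model with random intercepts for
participant and study site, fit by restricted maximum likelihood, with
p-values from a t distribution on the residual-degrees-of-freedom
approximation.  The Bayes factor uses the BIC approximation
``BF10 = exp((BIC_null - BIC_alt) / 2)`` (unit-information prior), comparing
``outcome ~ covariates`` against ``outcome ~ group + covariates``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

ALPHA = 0.05
GROUP_TERM = "C(group, Treatment('HC'))"


def _term_name(raw: str) -> str:
    """Readable coefficient names: the treatment-coded group dummies become
    plain group labels."""
    if raw.startswith(GROUP_TERM):
        return raw[len(GROUP_TERM) + 3 : -1]  # strip "[T." and "]"
    return raw


@dataclass(frozen=True)
class RegressionResult:
    """Coefficient table plus fit summaries for one regression.

    ``terms`` has one row per coefficient: beta, se, t, p, ci_low, ci_high.
    For mixed models ``variance_components``, ``icc`` and the marginal /
    conditional R-squared are populated; for OLS ``r2_adj`` is.
    """

    outcome: str
    terms: pd.DataFrame
    n: int
    r2_adj: float | None = None
    variance_components: Mapping[str, float] | None = None
    icc: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    bic: float | None = None

    def coef(self, term: str) -> pd.Series:
        """Row of the coefficient table for one term."""
        match = self.terms[self.terms["term"] == term]
        if match.empty:
            raise KeyError(
                f"term {term!r} not in {list(self.terms['term'])}"
            )
        return match.iloc[0]


@dataclass(frozen=True)
class BayesFactorResult:
    """BF10 for a group effect with its conventional interpretation."""

    bf10: float
    interpretation: str
    bic_null: float
    bic_alternative: float


@dataclass(frozen=True)
class MediationResult:
    """Baron-Kenny steps and verdict for a set of candidate mediators.

    ``step1`` maps each mediator to its mediator ~ group regression;
    ``step2`` is the outcome ~ mediators regression; ``step3`` adds group.
    ``group_only`` is the outcome ~ group reference model used to judge
    attenuation of the AN coefficient.  ``verdict_by_mediator`` marks a
    mediator consistent only when its step-1 and step-2 effects are
    significant and the group coefficient attenuates in step 3.
    """

    group_only: RegressionResult
    step1: Mapping[str, RegressionResult]
    step2: RegressionResult
    step3: RegressionResult
    verdict: str
    verdict_by_mediator: Mapping[str, str]
    attenuation: Mapping[str, float | bool] = field(default_factory=dict)
    followup: Mapping[str, pd.DataFrame] = field(default_factory=dict)


def _terms_from_ols(fit) -> pd.DataFrame:
    ci = fit.conf_int(alpha=ALPHA)
    return pd.DataFrame(
        {
            "term": [_term_name(t) for t in fit.params.index],
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
        }
    )


def _check_rank(fit, formula: str) -> None:
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        names = fit.model.exog_names
        raise DomainError(
            f"rank-deficient design for {formula!r}: aliased terms among "
            f"{names}"
        )


def ols_group_regression(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age",),
    group_term: bool = True,
) -> RegressionResult:
    """Least-squares regression of ``outcome`` on group (HC reference) and
    covariates, with two-sided t-based p-values and 95% CIs."""
    rhs = ([GROUP_TERM] if group_term else []) + list(covariates)
    formula = f"{outcome} ~ " + (" + ".join(rhs) if rhs else "1")
    work = data.dropna(subset=[outcome, *covariates]).copy()
    n_terms = len(rhs) + (2 if group_term else 0)
    if len(work) <= n_terms + 1:
        raise InsufficientDataError(
            f"{len(work)} rows is too few for {formula!r}"
        )
    fit = smf.ols(formula, data=work).fit()
    _check_rank(fit, formula)
    return RegressionResult(
        outcome=outcome,
        terms=_terms_from_ols(fit),
        n=int(fit.nobs),
        r2_adj=float(fit.rsquared_adj),
        bic=float(fit.bic),
    )


def mlm_performance(
    trials_long: pd.DataFrame,
    outcome: str = "performance",
    covariates: Sequence[str] = ("age",),
    participant_col: str = "id",
    site_col: str = "site",
) -> RegressionResult:
    """Per-trial linear mixed model with participant and site random
    intercepts (participants nested in sites), fit by REML.

    Reports the fixed effects with residual-df t-based p-values, the variance
    components (sigma2 residual, tau_participant, tau_site), the intraclass
    correlation ICC = (tau_p + tau_s) / (tau_p + tau_s + sigma2), and
    marginal / conditional R-squared by variance partition.  A site factor
    with a single level is dropped with a warning (degenerate grouping).
    """
    work = trials_long.dropna(
        subset=[outcome, *covariates, participant_col, site_col]
    ).copy()
    fixed = f"{outcome} ~ {GROUP_TERM} + " + " + ".join(covariates)
    n_sites = work[site_col].nunique()
    use_site = n_sites > 1
    if not use_site:
        warnings.warn(
            "site grouping has a single level; dropping the site random "
            "intercept",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_site:
            model = smf.mixedlm(
                fixed,
                data=work,
                groups=work[site_col],
                re_formula="1",
                vc_formula={"participant": f"0 + C({participant_col})"},
            )
        else:
            model = smf.mixedlm(
                fixed, data=work, groups=work[participant_col]
            )
        # Gradient optimizers can stall when a variance component sits on
        # the zero boundary; fall back to derivative-free Powell and keep
        # the solution with the better restricted likelihood.
        fit = model.fit(reml=True)
        if not fit.converged or not np.isfinite(fit.llf):
            fit_powell = model.fit(reml=True, method="powell")
            if np.isfinite(fit_powell.llf) and (
                not np.isfinite(fit.llf) or fit_powell.llf >= fit.llf
            ):
                fit = fit_powell
    sigma2 = float(fit.scale)
    if use_site:
        tau_site = float(fit.cov_re.iloc[0, 0])
        tau_participant = float(fit.vcomp[0])
    else:
        tau_site = 0.0
        tau_participant = float(fit.cov_re.iloc[0, 0])
    tau_total = tau_participant + tau_site
    icc = tau_total / (tau_total + sigma2) if tau_total + sigma2 > 0 else 0.0

    params = fit.fe_params
    bse = fit.bse_fe
    tvals = params / bse
    df_resid = len(work) - len(params)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    crit = stats.t.ppf(1 - ALPHA / 2, df_resid)
    terms = pd.DataFrame(
        {
            "term": [_term_name(t) for t in params.index],
            "beta": params.to_numpy(),
            "se": bse.to_numpy(),
            "t": tvals.to_numpy(),
            "p": pvals,
            "ci_low": (params - crit * bse).to_numpy(),
            "ci_high": (params + crit * bse).to_numpy(),
        }
    )
    fixed_pred = fit.predict(exog=work)
    var_fixed = float(np.var(fixed_pred, ddof=0))
    denom = var_fixed + tau_total + sigma2
    return RegressionResult(
        outcome=outcome,
        terms=terms,
        n=int(len(work)),
        variance_components={
            "sigma2": sigma2,
            "tau_participant": tau_participant,
            "tau_site": tau_site,
        },
        icc=icc,
        r2_marginal=var_fixed / denom if denom > 0 else 0.0,
        r2_conditional=(var_fixed + tau_total) / denom if denom > 0 else 0.0,
    )


def icc_from_components(
    tau_participant: float, tau_site: float, sigma2: float
) -> float:
    """ICC = (tau_participant + tau_site) / (total variance)."""
    total = tau_participant + tau_site + sigma2
    if total <= 0:
        raise DomainError("variance components must sum to a positive total")
    return (tau_participant + tau_site) / total


def bayes_factor_group(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age",),
) -> BayesFactorResult:
    """BF10 for the group effect via the BIC approximation.

    Compares ``outcome ~ covariates`` (null) with ``outcome ~ group +
    covariates`` (alternative) on the same rows:
    ``BF10 = exp((BIC_null - BIC_alt) / 2)``.  BF10 > 3 is read as evidence
    for the alternative, BF10 < 1/3 as evidence for the null, anything
    between as inconclusive.
    """
    work = data.dropna(subset=[outcome, *covariates]).copy()
    counts = work.groupby("group").size()
    if (counts < 3).any() or len(counts) < 2:
        raise InsufficientDataError(
            f"bayes_factor_group requires >= 3 participants per group, "
            f"got {dict(counts)}"
        )
    null = ols_group_regression(work, outcome, covariates, group_term=False)
    alt = ols_group_regression(work, outcome, covariates, group_term=True)
    bf10 = float(np.exp((null.bic - alt.bic) / 2.0))
    if bf10 > 3:
        interpretation = "evidence_alternative"
    elif bf10 < 1 / 3:
        interpretation = "evidence_null"
    else:
        interpretation = "inconclusive"
    return BayesFactorResult(
        bf10=bf10,
        interpretation=interpretation,
        bic_null=null.bic,
        bic_alternative=alt.bic,
    )


def holm_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving.

    Delegates to the standard step-down implementation; inputs outside
    [0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise DomainError(f"p-values must lie in [0, 1], got {pvalues}")
    return multipletests(p, method="holm")[1]


def mediation_analysis(
    data: pd.DataFrame,
    mediators: Sequence[str] = ("dass_depression", "dass_stress"),
    outcome: str = "lambda_weighted",
    group_coef: str = "AN",
    attenuation_fraction: float = 0.30,
) -> MediationResult:
    """Baron-Kenny mediation of a group effect through candidate mediators.

    Step 1 regresses each mediator on group; step 2 regresses the outcome on
    the mediators jointly; step 3 regresses the outcome on group plus
    mediators.  Attenuation of the ``group_coef`` (default AN vs HC) is
    operationalised as losing significance at alpha = 0.05 in step 3 or
    shrinking by at least ``attenuation_fraction`` in magnitude versus the
    group-only model.  A mediator is ``mediation_consistent`` only when its
    step-1 and step-2 effects are significant and the group effect
    attenuates; the overall verdict is consistent when any mediator is.
    Per-group (AN-only and p-AN-only) follow-up regressions of the outcome on
    the mediators are reported with Holm-corrected p-values.
    """
    work = data.dropna(subset=[outcome, *mediators]).copy()
    group_only = ols_group_regression(work, outcome, covariates=())
    step1 = {
        m: ols_group_regression(work, m, covariates=()) for m in mediators
    }
    med_formula = " + ".join(mediators)
    step2_fit = smf.ols(f"{outcome} ~ {med_formula}", data=work).fit()
    step2 = RegressionResult(
        outcome=outcome,
        terms=_terms_from_ols(step2_fit),
        n=int(step2_fit.nobs),
        r2_adj=float(step2_fit.rsquared_adj),
        bic=float(step2_fit.bic),
    )
    step3_fit = smf.ols(
        f"{outcome} ~ {GROUP_TERM} + {med_formula}", data=work
    ).fit()
    step3 = RegressionResult(
        outcome=outcome,
        terms=_terms_from_ols(step3_fit),
        n=int(step3_fit.nobs),
        r2_adj=float(step3_fit.rsquared_adj),
        bic=float(step3_fit.bic),
    )

    beta_total = group_only.coef(group_coef)
    beta_direct = step3.coef(group_coef)
    shrink = (
        1.0 - abs(beta_direct["beta"]) / abs(beta_total["beta"])
        if beta_total["beta"] != 0
        else 0.0
    )
    attenuated = bool(
        beta_direct["p"] > ALPHA or shrink >= attenuation_fraction
    )
    attenuation = {
        "beta_total": float(beta_total["beta"]),
        "beta_direct": float(beta_direct["beta"]),
        "shrinkage": float(shrink),
        "direct_p": float(beta_direct["p"]),
        "attenuated": attenuated,
        "total_significant": bool(beta_total["p"] < ALPHA),
    }

    verdict_by_mediator = {}
    for m in mediators:
        s1_p = step1[m].coef(group_coef)["p"]
        s2_p = step2.coef(m)["p"]
        chain = s1_p < ALPHA and s2_p < ALPHA
        if not chain:
            verdict_by_mediator[m] = "no_mediation"
        elif attenuated:
            verdict_by_mediator[m] = "mediation_consistent"
        elif beta_direct["p"] < ALPHA:
            verdict_by_mediator[m] = "no_mediation"
        else:
            verdict_by_mediator[m] = "inconclusive"
    verdicts = set(verdict_by_mediator.values())
    if "mediation_consistent" in verdicts:
        verdict = "mediation_consistent"
    elif verdicts == {"no_mediation"}:
        verdict = "no_mediation"
    else:
        verdict = "inconclusive"

    # Per-group follow-up regressions (outcome ~ mediators within AN and
    # p-AN separately), Holm-corrected across the mediator p-values.
    followup = {}
    raw_p, keys = [], []
    tables = {}
    for g in ("AN", "p-AN"):
        sub = work[work["group"] == g]
        if len(sub) <= len(mediators) + 2:
            continue
        fit_g = smf.ols(f"{outcome} ~ {med_formula}", data=sub).fit()
        table = _terms_from_ols(fit_g)
        tables[g] = table
        for m in mediators:
            raw_p.append(float(table.loc[table["term"] == m, "p"].iloc[0]))
            keys.append((g, m))
    if raw_p:
        adjusted = holm_correct(raw_p)
        for (g, m), p_adj in zip(keys, adjusted):
            table = tables[g]
            table.loc[table["term"] == m, "p_holm"] = p_adj
        followup = tables
    return MediationResult(
        group_only=group_only,
        step1=step1,
        step2=step2,
        step3=step3,
        verdict=verdict,
        verdict_by_mediator=verdict_by_mediator,
        attenuation=attenuation,
        followup=followup,
    )
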