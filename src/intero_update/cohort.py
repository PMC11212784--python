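"""Seeded synthetic cohorts with the statistical structure the analysis
assumes.

The generator emulates a three-group heartbeat-counting study (acute anorexia
nervosa AN, post-acute p-AN, healthy controls HC): group-shifted prior
prospective self-efficacy beliefs, group-equal counting accuracy, group-shifted
depression/stress scores, and posterior prospective beliefs produced by the
precision-weighted update rule with group-specific learning rates plus noise.

Generative scheme per participant (all bounded draws are truncated normal, not
clipped, so configured means are approximately honoured without point masses
at the bounds):

1. A resting heart rate and a counting fraction (the fraction of true beats
   the participant reports) are drawn; recorded beats per trial follow the
   heart rate and trial duration with small jitter, counted beats follow the
   counting fraction.  The counting fraction has group-equal parameters,
   matching the null performance difference the analysis assumes.
2. The participant's learning rate lambda is the primary draw.  Prior
   confidence and performance confidence are then derived by splitting a drawn
   total-precision budget C as pi_theta = (1 - lambda) * C and
   pi_eps = lambda * C, so the precision-weighted learning rate recomputed
   from the generated confidences equals the generative lambda exactly while
   both confidences stay inside [0, 100].
3. The posterior retrospective belief is the Performance score plus noise.
   The latent posterior prospective belief applies the update rule to the
   realised prior, evidence and precision proxies of the configured
   generating model; the half- and double-duration ratings are that latent
   value plus independent noise, and are averaged downstream.
4. Under ``mediation_mode="mood_mediated"`` the learning rate (and hence
   performance confidence) is a decreasing function of depression + stress,
   with group differences carried entirely by the mood scores; under
   ``"direct_only"`` mood scores are group-shifted but lambda depends only on
   group.
5. Sites are assigned round-robin with a small site-level random intercept on
   beliefs and performance so multilevel machinery is exercised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .errors import ConfigurationError, SchemaError
from .scoring import GROUP_LABELS, PARTICIPANT_COLUMNS, TRIAL_COLUMNS
from .update import EVIDENCE_SOURCES, PRECISION_PROXIES, rescale_edi

logger = logging.getLogger(__name__)

MEDIATION_MODES = ("none", "mood_mediated", "direct_only")


def _group_dict(an: float, pan: float, hc: float) -> dict[str, float]:
    return {"AN": an, "p-AN": pan, "HC": hc}


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic-cohort generator.

    Percentage-scale parameters live on 0-100; learning-rate means on [0, 1];
    SDs are nonnegative.  ``n_per_group`` may be a single integer or a mapping
    per group label.
    """

    n_per_group: int | Mapping[str, int] = field(
        default_factory=lambda: {"AN": 35, "p-AN": 40, "HC": 117}
    )
    group_labels: tuple[str, ...] = GROUP_LABELS
    n_sites: int = 4
    site_sd: float = 3.0
    # Beliefs (0-100): HC mean with the AN shift observed behaviourally
    # (about -13.6) and a smaller p-AN shift.
    prior_belief_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(41.4, 50.9, 55.0)
    )
    prior_belief_sd: float = 15.0
    prior_confidence_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(45.0, 50.0, 55.0)
    )
    confidence_budget_sd: float = 15.0
    # Learning rates: HC 0.47 with the AN deficit -0.09 and a small p-AN one.
    lambda_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(0.38, 0.45, 0.47)
    )
    lambda_sd: float = 0.15
    # Resting heart rate (bpm).
    resting_hr_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(69.29, 71.26, 73.03)
    )
    resting_hr_sd: float = 10.0
    # Counting model: group-equal fraction of true beats reported.
    counting_fraction_mean: float = 0.55
    counting_fraction_sd: float = 0.20
    # Trial-to-trial wobble of the counting fraction: sets the
    # within-participant share of performance variance (the between /
    # within split drives the intraclass correlation of the trial model).
    trial_fraction_jitter_sd: float = 0.12
    beat_jitter_sd: float = 1.0
    trial_durations: tuple[float, ...] = (25.0, 35.0, 45.0, 65.0)
    trial_confidence_jitter_sd: float = 4.0
    retrospective_noise_sd: float = 10.0
    prospective_noise_sd: float = 5.0
    # Questionnaires (raw scores).
    edi_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(14.0, 13.16, 9.5)
    )
    edi_sd: float = 9.5
    edi_max_raw: float = 36.0
    dass_depression_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(20.26, 14.0, 6.94)
    )
    dass_depression_sd: float = 11.0
    dass_anxiety_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(13.13, 11.87, 6.92)
    )
    dass_anxiety_sd: float = 8.5
    dass_stress_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(22.87, 21.2, 11.13)
    )
    dass_stress_sd: float = 10.5
    # Demographics.
    age_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(22.0, 26.51, 24.67)
    )
    age_sd: float = 6.0
    bmi_mean_by_group: dict[str, float] = field(
        default_factory=lambda: _group_dict(16.13, 19.93, 20.48)
    )
    bmi_sd: float = 2.0
    mediation_mode: str = "none"
    # Which update rule generates the posterior prospective beliefs.
    generating_evidence: str = "retrospective_belief"
    generating_proxy: str = "performance_confidence"
    # Optional per-field missingness (trial confidences) for robustness tests.
    missingness_rate: float = 0.0
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ConfigurationError`` naming the first offending field."""
        labels = tuple(self.group_labels)
        if len(labels) != 3 or len(set(labels)) != 3:
            raise ConfigurationError(
                f"group_labels: exactly three distinct labels required, "
                f"got {labels}"
            )
        for label, n in self._n_by_group().items():
            if n < 1:
                raise ConfigurationError(
                    f"n_per_group[{label}]: must be >= 1, got {n}"
                )
        if self.n_sites < 1:
            raise ConfigurationError(
                f"n_sites: must be >= 1, got {self.n_sites}"
            )
        for name in (
            "site_sd",
            "prior_belief_sd",
            "confidence_budget_sd",
            "lambda_sd",
            "resting_hr_sd",
            "counting_fraction_sd",
            "trial_fraction_jitter_sd",
            "beat_jitter_sd",
            "trial_confidence_jitter_sd",
            "retrospective_noise_sd",
            "prospective_noise_sd",
            "edi_sd",
            "dass_depression_sd",
            "dass_anxiety_sd",
            "dass_stress_sd",
            "age_sd",
            "bmi_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(
                    f"{name}: must be >= 0, got {getattr(self, name)}"
                )
        for name in (
            "prior_belief_mean_by_group",
            "prior_confidence_mean_by_group",
        ):
            for label in labels:
                value = self._by_group(name)[label]
                if not 0 <= value <= 100:
                    raise ConfigurationError(
                        f"{name}[{label}]: must lie in [0, 100], got {value}"
                    )
        for label in labels:
            lam = self._by_group("lambda_mean_by_group")[label]
            if not 0 <= lam <= 1:
                raise ConfigurationError(
                    f"lambda_mean_by_group[{label}]: must lie in [0, 1], "
                    f"got {lam}"
                )
        if not 0 <= self.counting_fraction_mean <= 1.2:
            raise ConfigurationError(
                "counting_fraction_mean: must lie in [0, 1.2], "
                f"got {self.counting_fraction_mean}"
            )
        if len(self.trial_durations) < 1 or any(
            d <= 0 for d in self.trial_durations
        ):
            raise ConfigurationError(
                f"trial_durations: positive durations required, "
                f"got {self.trial_durations}"
            )
        if self.edi_max_raw <= 0:
            raise ConfigurationError(
                f"edi_max_raw: must be positive, got {self.edi_max_raw}"
            )
        if self.mediation_mode not in MEDIATION_MODES:
            raise ConfigurationError(
                f"mediation_mode: must be one of {MEDIATION_MODES}, "
                f"got {self.mediation_mode!r}"
            )
        if self.generating_evidence not in EVIDENCE_SOURCES:
            raise ConfigurationError(
                f"generating_evidence: must be one of {EVIDENCE_SOURCES}, "
                f"got {self.generating_evidence!r}"
            )
        if self.generating_proxy not in PRECISION_PROXIES:
            raise ConfigurationError(
                f"generating_proxy: must be one of {PRECISION_PROXIES}, "
                f"got {self.generating_proxy!r}"
            )
        if not 0 <= self.missingness_rate < 1:
            raise ConfigurationError(
                f"missingness_rate: must lie in [0, 1), "
                f"got {self.missingness_rate}"
            )

    # -- helpers ----------------------------------------------------------
    def _by_group(self, name: str) -> dict[str, float]:
        mapping = getattr(self, name)
        missing = [g for g in self.group_labels if g not in mapping]
        if missing:
            raise ConfigurationError(f"{name}: missing groups {missing}")
        return mapping

    def _n_by_group(self) -> dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            missing = [
                g for g in self.group_labels if g not in self.n_per_group
            ]
            if missing:
                raise ConfigurationError(
                    f"n_per_group: missing groups {missing}"
                )
            return {g: int(self.n_per_group[g]) for g in self.group_labels}
        return {g: int(self.n_per_group) for g in self.group_labels}

    def replace(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["group_labels"] = list(self.group_labels)
        out["trial_durations"] = list(self.trial_durations)
        if isinstance(out["n_per_group"], Mapping):
            out["n_per_group"] = dict(out["n_per_group"])
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        kwargs = dict(data)
        if "group_labels" in kwargs:
            kwargs["group_labels"] = tuple(kwargs["group_labels"])
        if "trial_durations" in kwargs:
            kwargs["trial_durations"] = tuple(kwargs["trial_durations"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(
                f"unknown generator-config fields: {sorted(unknown)}"
            )
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config() -> GeneratorConfig:
    """The reference configuration: the study conditions the generator
    emulates (group sample sizes 35/40/117, HC learning-rate mean 0.47 with
    AN mean 0.38, resting heart rates near 69.3/71.3/73.0 bpm, group-shifted
    depression/stress, prior-belief AN-HC shift near -13.6)."""
    cfg = GeneratorConfig()
    cfg.validate()
    return cfg


@dataclass
class Cohort:
    """A generated (or loaded) cohort: participants and trials tables.

    ``participants`` has one row per participant (``PARTICIPANT_COLUMNS``
    plus generator-only latent columns prefixed ``latent_``); ``trials`` is
    long-format with one row per counting trial.  ``provenance`` records the
    generator config and seed, or ``"observed"`` for loaded data.
    """

    participants: pd.DataFrame
    trials: pd.DataFrame
    provenance: dict | str = "observed"

    def __post_init__(self) -> None:
        missing = [
            c for c in PARTICIPANT_COLUMNS if c not in self.participants
        ]
        if missing:
            raise SchemaError(
                f"participants table is missing columns: {missing}"
            )
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials]
        if missing:
            raise SchemaError(f"trials table is missing columns: {missing}")
        if self.participants["id"].duplicated().any():
            raise SchemaError("participant identifiers are not unique")

    def write(self, directory: str | Path) -> None:
        """Write the two delimited tables (and config, if generated)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / "participants.csv", index=False)
        self.trials.to_csv(directory / "trials.csv", index=False)
        if isinstance(self.provenance, dict):
            config = self.provenance.get("config")
            if isinstance(config, GeneratorConfig):
                config.to_yaml(directory / "generator_config.yaml")
                logger.info(
                    "wrote cohort to %s (seed=%s, config=%s)",
                    directory,
                    self.provenance.get("seed"),
                    config.content_hash(),
                )

    @classmethod
    def read(cls, directory: str | Path) -> "Cohort":
        """Load a cohort from ``participants.csv`` / ``trials.csv``."""
        directory = Path(directory)
        participants = pd.read_csv(directory / "participants.csv")
        trials = pd.read_csv(directory / "trials.csv")
        provenance: dict | str = "observed"
        config_path = directory / "generator_config.yaml"
        if config_path.exists():
            config = GeneratorConfig.from_yaml(config_path)
            provenance = {"config": config, "seed": config.seed}
        return cls(participants, trials, provenance)


def _truncated_normal(rng, mean, sd, low, high, size=None):
    """Truncated-normal draw; degenerates to the clipped mean when sd = 0."""
    mean = np.asarray(mean, dtype=float)
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if sd == 0:
        out = np.clip(np.broadcast_to(mean, np.broadcast_shapes(
            mean.shape, low.shape, high.shape
        ) if size is None else size), low, high)
        return np.array(out, dtype=float)
    a = (low - mean) / sd
    b = (high - mean) / sd
    return truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=size, random_state=rng
    )


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> Cohort:
    """Generate a deterministic synthetic cohort.

    ``seed`` overrides ``config.seed`` when given.  The draw order is fixed,
    so identical (config, seed) pairs yield field-for-field identical
    cohorts.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    labels = list(config.group_labels)
    n_by_group = config._n_by_group()
    groups = np.concatenate(
        [np.repeat(g, n_by_group[g]) for g in labels]
    )
    n = len(groups)
    ids = np.array([f"P{i:04d}" for i in range(n)])

    def per_group(name: str) -> np.ndarray:
        mapping = config._by_group(name)
        return np.array([mapping[g] for g in groups], dtype=float)

    # Sites: round-robin assignment, one random intercept per site
    # (percentage points, applied to beliefs and - scaled - to the counting
    # fraction so per-trial performance carries site variance).
    site_idx = np.arange(n) % config.n_sites
    sites = np.array([f"S{s}" for s in site_idx])
    site_effect_by_site = rng.normal(0.0, config.site_sd, config.n_sites)
    u_site = site_effect_by_site[site_idx]

    # Demographics and questionnaires.
    age = _truncated_normal(
        rng, per_group("age_mean_by_group"), config.age_sd, 18.0, 45.0
    )
    bmi = _truncated_normal(
        rng, per_group("bmi_mean_by_group"), config.bmi_sd, 13.0, 35.0
    )
    edi = _truncated_normal(
        rng,
        per_group("edi_mean_by_group"),
        config.edi_sd,
        0.0,
        config.edi_max_raw,
    )
    dass_dep = _truncated_normal(
        rng,
        per_group("dass_depression_mean_by_group"),
        config.dass_depression_sd,
        0.0,
        42.0,
    )
    dass_anx = _truncated_normal(
        rng,
        per_group("dass_anxiety_mean_by_group"),
        config.dass_anxiety_sd,
        0.0,
        42.0,
    )
    dass_stress = _truncated_normal(
        rng,
        per_group("dass_stress_mean_by_group"),
        config.dass_stress_sd,
        0.0,
        42.0,
    )

    # Learning rate: primary draw.  Under mood mediation its mean is a
    # decreasing function of depression + stress, anchored so the configured
    # HC and AN lambda means are reproduced at the HC and AN mood means.
    lam_cfg = config._by_group("lambda_mean_by_group")
    if config.mediation_mode == "mood_mediated":
        mood = dass_dep + dass_stress
        dep_cfg = config._by_group("dass_depression_mean_by_group")
        str_cfg = config._by_group("dass_stress_mean_by_group")
        mood_hc = dep_cfg["HC"] + str_cfg["HC"]
        mood_an = dep_cfg["AN"] + str_cfg["AN"]
        if mood_an == mood_hc:
            raise ConfigurationError(
                "mediation_mode=mood_mediated requires different AN and HC "
                "mood means (dass_depression/stress_mean_by_group)"
            )
        slope = (lam_cfg["HC"] - lam_cfg["AN"]) / (mood_an - mood_hc)
        lam_mean = lam_cfg["HC"] - slope * (mood - mood_hc)
    else:
        lam_mean = per_group("lambda_mean_by_group")
    lam = _truncated_normal(rng, lam_mean, config.lambda_sd, 0.0, 1.0)

    # Confidence budget C: pi_theta = (1 - lambda) C, pi_eps = lambda C.
    # The budget mean targets the configured prior-confidence group means;
    # under mood mediation group confidence differences must be carried by
    # mood (through lambda), so the HC anchor is used for every group.
    conf_cfg = config._by_group("prior_confidence_mean_by_group")
    if config.mediation_mode == "mood_mediated":
        budget_mean = np.full(
            n, conf_cfg["HC"] / max(1e-9, 1.0 - lam_cfg["HC"])
        )
    else:
        budget_mean = np.array(
            [
                conf_cfg[g] / max(1e-9, 1.0 - lam_cfg[g])
                for g in groups
            ]
        )
    budget_high = np.minimum(
        190.0, 100.0 / np.maximum(lam, 1.0 - lam)
    )
    budget_low = np.minimum(10.0, budget_high)
    budget = _truncated_normal(
        rng,
        np.minimum(budget_mean, budget_high),
        config.confidence_budget_sd,
        budget_low,
        budget_high,
    )
    prior_conf = (1.0 - lam) * budget
    perf_conf_target = lam * budget

    # Prior prospective belief (with site intercept).
    prior_belief = _truncated_normal(
        rng,
        per_group("prior_belief_mean_by_group") + u_site,
        config.prior_belief_sd,
        0.0,
        100.0,
    )

    # Heartbeat-counting trials.
    hr = _truncated_normal(
        rng,
        per_group("resting_hr_mean_by_group"),
        config.resting_hr_sd,
        40.0,
        120.0,
    )
    frac = _truncated_normal(
        rng,
        config.counting_fraction_mean + u_site / 100.0,
        config.counting_fraction_sd,
        0.0,
        1.2,
    )
    durations = np.array(config.trial_durations, dtype=float)
    n_trials = len(durations)
    true_beats = hr[:, None] * durations[None, :] / 60.0
    if config.beat_jitter_sd > 0:
        true_beats = true_beats + rng.normal(
            0.0, config.beat_jitter_sd, true_beats.shape
        )
    recorded = np.maximum(1, np.rint(true_beats)).astype(int)
    if config.trial_fraction_jitter_sd > 0:
        frac_trial = _truncated_normal(
            rng,
            np.broadcast_to(frac[:, None], recorded.shape),
            config.trial_fraction_jitter_sd,
            0.0,
            1.2,
            size=recorded.shape,
        )
    else:
        frac_trial = np.broadcast_to(frac[:, None], recorded.shape)
    counted = np.maximum(0, np.rint(recorded * frac_trial)).astype(int)
    trial_conf = _truncated_normal(
        rng,
        np.broadcast_to(perf_conf_target[:, None], recorded.shape),
        config.trial_confidence_jitter_sd,
        0.0,
        100.0,
        size=recorded.shape,
    )
    if config.missingness_rate > 0:
        mask = rng.random(trial_conf.shape) < config.missingness_rate
        trial_conf = np.where(mask, np.nan, trial_conf)

    per_trial_score = 1.0 - np.abs(recorded - counted) / recorded
    performance = 100.0 * per_trial_score.mean(axis=1)
    with np.errstate(invalid="ignore"):
        perf_conf_realised = np.nanmean(trial_conf, axis=1)

    # Posterior retrospective belief: Performance plus noise.
    retro = _truncated_normal(
        rng,
        np.clip(performance, 0.0, 100.0),
        config.retrospective_noise_sd,
        0.0,
        100.0,
    )

    # Posterior prospective beliefs from the generating update rule, using
    # the *realised* evidence and precision quantities so downstream
    # re-derivation is exact in the zero-noise limit.
    if config.generating_evidence == "performance":
        evidence = np.clip(performance, 0.0, 100.0)
    else:
        evidence = retro
    if config.generating_proxy == "performance_confidence":
        evid_precision = np.where(
            np.isnan(perf_conf_realised), 0.0, perf_conf_realised
        )
    else:
        evid_precision = rescale_edi(edi, config.edi_max_raw)
    lam_gen = evid_precision / (prior_conf + evid_precision)
    latent_posterior = prior_belief + lam_gen * (evidence - prior_belief)
    posterior_half = _truncated_normal(
        rng, latent_posterior, config.prospective_noise_sd, 0.0, 100.0
    )
    posterior_double = _truncated_normal(
        rng, latent_posterior, config.prospective_noise_sd, 0.0, 100.0
    )

    participants = pd.DataFrame(
        {
            "id": ids,
            "group": groups,
            "site": sites,
            "age": age,
            "bmi": bmi,
            "prior_belief": prior_belief,
            "prior_confidence": prior_conf,
            "retrospective_belief": retro,
            "posterior_half": posterior_half,
            "posterior_double": posterior_double,
            "edi3_id": edi,
            "dass_depression": dass_dep,
            "dass_anxiety": dass_anx,
            "dass_stress": dass_stress,
            "resting_hr": hr,
            "latent_lambda": lam,
            "latent_lambda_generating": lam_gen,
        }
    )
    trials = pd.DataFrame(
        {
            "id": np.repeat(ids, n_trials),
            "trial": np.tile(np.arange(n_trials), n),
            "duration_s": np.tile(durations, n),
            "recorded_beats": recorded.ravel(),
            "counted_beats": counted.ravel(),
            "confidence": trial_conf.ravel(),
        }
    )
    return Cohort(
        participants,
        trials,
        provenance={"config": config, "seed": seed},
    )
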