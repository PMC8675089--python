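"""Ground-truth synthetic cohorts for end-to-end validation.

No raw behavioral data from the original experiments are public, so every
downstream stage (estimation, model selection, group inference, mediation)
is validated on simulated cohorts with known generative parameters.

Each participant draws guilt sensitivity ``gamma`` and inequity sensitivity
``alpha`` from sex-specific log-normal distributions (log-normality keeps
both non-negative and lets sex shift the median multiplicatively).  Choices
are Bernoulli draws from the softmax choice rule on a trial design, with the
trial sequence permuted per participant.  The cohort also carries:

* three ordinal post-task questionnaire items (1-5) generated by a Gaussian
  copula correlated with log gamma — they probe whether the fitted guilt
  coefficient tracks self-reported guilt experience;
* Big Five and socioeconomic covariates with sex-specific means/SDs taken
  from the large online-sample descriptives, with a configurable
  Agreeableness effect on log gamma in both sexes and a Conscientiousness
  effect in men only;
* a scalar "connectivity" mediator M: by default the entire male-female
  shift in log gamma flows through M (complete mediation,
  ``log gamma = b*M + c'*male + ...`` with ``M = a*male + noise`` and
  ``c' = 0``), emulating the brain-connectivity mediator consumed by the
  mediation analysis.

Sex coding downstream follows the analyses' convention: men = 1 for guilt
contrasts, women = 1 for inequity contrasts; the cohort stores a single
string label and coders map per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import AgentParams, choice_prob
from .task_design import Design

__all__ = [
    "CohortConfig",
    "MediationConfig",
    "ParticipantRecord",
    "ONLINE_COVARIATE_STATS",
    "COVARIATE_NAMES",
    "simulate_cohort",
    "strong_effects_config",
    "simulate_questionnaire",
    "simulate_mediator",
    "cohort_frames",
    "write_cohort",
    "read_cohort",
]

#: per-sex (mean, SD) of the 11 covariates, from the online-sample descriptives
ONLINE_COVARIATE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "age": (39.585, 15.318),
        "neuroticism": (47.433, 9.7900),
        "extraversion": (45.426, 9.1431),
        "openness": (50.699, 9.4570),
        "agreeableness": (42.780, 10.636),
        "conscientiousness": (49.068, 9.3706),
        "self_edu_history": (5.3197, 1.1422),
        "parents_edu_history": (4.6511, 1.4190),
        "income": (2.7296, 1.4772),
        "occupation": (2.2477, 1.6859),
        "subjective_ses": (5.2513, 2.0408),
    },
    "female": {
        "age": (36.751, 15.273),
        "neuroticism": (46.731, 9.9606),
        "extraversion": (46.244, 9.2942),
        "openness": (47.640, 9.3566),
        "agreeableness": (44.333, 10.448),
        "conscientiousness": (48.076, 9.3299),
        "self_edu_history": (5.0431, 1.0410),
        "parents_edu_history": (4.7947, 1.3323),
        "income": (1.6153, 0.9299),
        "occupation": (3.4439, 1.8253),
        "subjective_ses": (5.2700, 1.7901),
    },
}

COVARIATE_NAMES = list(ONLINE_COVARIATE_STATS["male"])
#: SES-type items stored as non-negative integers (rounded Gaussian draws)
_ORDINAL_COVARIATES = {"age", "self_edu_history", "parents_edu_history",
                       "income", "occupation", "subjective_ses"}


@dataclass(frozen=True)
class MediationConfig:
    """Generative paths of the sex -> mediator -> log gamma model.

    ``a`` is the sex effect (men = 1) on the mediator, ``b`` the mediator
    effect on log gamma, ``c_prime`` the direct sex effect on log gamma.
    The default is complete mediation: c' = 0 and a*b = log 2, i.e. the male
    gamma median is twice the female one entirely via the mediator.
    """

    a: float = 1.0
    b: float = float(np.log(2.0))
    c_prime: float = 0.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the cohort generator.

    gamma/alpha scales are per yen (matching the regressors), so the
    defaults put fitted guilt/inequity coefficients in the 1e-3 range
    observed in the behavioral fits.
    """

    n_per_sex: int = 26
    # log-normal medians; the male gamma median is implied by the mediation
    # paths: gamma_base_median * exp(a*b + c_prime) with default = 0.0040
    gamma_base_median: float = 0.0020
    gamma_sigma_log: float = 0.7
    alpha_median_male: float = 0.0018
    alpha_median_female: float = 0.0036
    alpha_sigma_log: float = 0.7
    reward_weight_median: float = 0.003
    reward_weight_sigma_log: float = 0.3
    intercept_mean: float = -0.2
    intercept_sd: float = 0.3
    # log-gamma shift per SD of the covariate
    agreeableness_effect: float = 0.15
    conscientiousness_effect_men: float = 0.25
    questionnaire_rho: float = 0.4
    mediation: MediationConfig = field(default_factory=MediationConfig)
    covariate_stats: dict = field(default_factory=lambda: ONLINE_COVARIATE_STATS)
    seed: int = 0

    def __post_init__(self):
        for name in ("gamma_sigma_log", "alpha_sigma_log", "reward_weight_sigma_log",
                     "intercept_sd", "n_per_sex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gamma_base_median < 0 or self.alpha_median_male < 0 or self.alpha_median_female < 0:
            raise ValueError("medians must be non-negative (0 disables the component)")
        if not -1 < self.questionnaire_rho < 1:
            raise ValueError("questionnaire_rho must lie in (-1, 1)")


@dataclass
class ParticipantRecord:
    """One simulated participant with full ground truth."""

    pid: str
    sex: str  # "male" | "female"
    true_params: AgentParams
    choices: np.ndarray          # indexed by design trial_id; 1 = Cooperate
    trial_order: np.ndarray      # presentation order (permutation of trial ids)
    questionnaire: tuple[int, int, int]
    mediator: float
    covariates: dict[str, float]


# five-point thresholds at standard-normal quintiles
_THRESHOLDS = [-0.8416212335729143, -0.2533471031357997,
               0.2533471031357997, 0.8416212335729143]


def _to_ordinal(latent: float) -> int:
    return int(1 + np.searchsorted(_THRESHOLDS, latent))


def simulate_questionnaire(gamma: float, correlation: float, rng: np.random.Generator,
                           log_loc: float = np.log(0.0014), log_scale: float = 0.7
                           ) -> tuple[int, int, int]:
    """Three ordinal items (1-5) correlated with log gamma.

    A Gaussian copula: each item's latent value is ``rho * z + sqrt(1-rho^2)
    * noise`` with z the standardized log guilt sensitivity, thresholded at
    standard-normal quintiles.
    """
    z = (np.log(gamma + 1e-12) - log_loc) / log_scale
    rho = correlation
    latents = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(3)
    return tuple(_to_ordinal(v) for v in latents)


def simulate_mediator(sex_male: int, a: float, noise_sd: float,
                      rng: np.random.Generator) -> float:
    """Scalar connectivity surrogate M = a*sex + Gaussian noise."""
    return float(a * sex_male + noise_sd * rng.standard_normal())


def _lognormal(median: float, sigma: float, rng: np.random.Generator) -> float:
    if median <= 0:
        return 0.0
    return float(np.exp(np.log(median) + sigma * rng.standard_normal()))


def strong_effects_config(design: Design, n_per_sex: int = 10,
                          seed: int = 0) -> CohortConfig:
    """Study conditions for model-selection validation: large, homogeneous
    guilt and inequity sensitivities with a centering intercept.

    Effects are sized so each utility component moves the choice log-odds
    by well over one standard deviation across trials (gamma 0.030, alpha
    0.015, reward weight 0.005 per yen, sigma_log 0.2 for all), and the
    population intercept cancels the mean log-odds so choices stay
    stochastic rather than saturating.  Sex shifts, covariate effects and
    the mediator path are switched off — the scenario isolates whether
    selection recovers the generating model (Reward + Guilt + combined
    Inequity), not group differences.
    """
    from .task_design import regressor_frame

    gamma, alpha, rw = 0.030, 0.015, 0.005
    rf = regressor_frame(design)
    intercept = -(gamma * rf["guilt"].mean() + alpha * rf["inequity"].mean()
                  + rw * rf["reward"].mean())
    return CohortConfig(
        n_per_sex=n_per_sex,
        gamma_base_median=gamma, gamma_sigma_log=0.2,
        alpha_median_male=alpha, alpha_median_female=alpha, alpha_sigma_log=0.2,
        reward_weight_median=rw, reward_weight_sigma_log=0.15,
        intercept_mean=float(intercept), intercept_sd=0.2,
        agreeableness_effect=0.0, conscientiousness_effect_men=0.0,
        mediation=MediationConfig(b=0.0),
        seed=seed,
    )


def simulate_cohort(design: Design, config: CohortConfig) -> list[ParticipantRecord]:
    """Draw a full cohort of simulated participants; deterministic given seed."""
    if len(design) == 0:
        raise ValueError("design has no trials")
    rng = np.random.default_rng(config.seed)
    med = config.mediation
    # standardization constants for the questionnaire copula: the population
    # log-gamma mean averaged over sexes
    log_gamma_loc = (np.log(config.gamma_base_median + 1e-12)
                     + 0.5 * (med.a * med.b + med.c_prime))
    records: list[ParticipantRecord] = []
    for sex in ("male", "female"):
        male = 1 if sex == "male" else 0
        stats = config.covariate_stats[sex]
        for i in range(config.n_per_sex):
            pid = f"{sex[0]}{i:04d}"
            covs = {}
            for name in COVARIATE_NAMES:
                mu, sd = stats[name]
                v = mu + sd * rng.standard_normal()
                if name in _ORDINAL_COVARIATES:
                    v = float(max(round(v), 0))
                covs[name] = float(v)
            mediator = simulate_mediator(male, med.a, med.noise_sd, rng)
            z_agree = (covs["agreeableness"] - stats["agreeableness"][0]) / stats["agreeableness"][1]
            z_consc = (covs["conscientiousness"] - stats["conscientiousness"][0]) / stats["conscientiousness"][1]
            if config.gamma_base_median > 0:
                log_gamma = (
                    np.log(config.gamma_base_median)
                    + med.b * mediator
                    + med.c_prime * male
                    + config.agreeableness_effect * z_agree
                    + config.conscientiousness_effect_men * z_consc * male
                    + config.gamma_sigma_log * rng.standard_normal()
                )
                gamma = float(np.exp(log_gamma))
            else:
                gamma = 0.0
            alpha_median = config.alpha_median_male if male else config.alpha_median_female
            alpha = _lognormal(alpha_median, config.alpha_sigma_log, rng)
            params = AgentParams(
                gamma=gamma,
                alpha=alpha,
                reward_weight=_lognormal(config.reward_weight_median,
                                         config.reward_weight_sigma_log, rng),
                intercept=float(config.intercept_mean
                                + config.intercept_sd * rng.standard_normal()),
            )
            order = rng.permutation(len(design))
            choices = np.empty(len(design), dtype=int)
            for tid in order:  # presentation order; stored by trial_id
                p = choice_prob(design.trials[tid], params)
                choices[tid] = int(rng.random() < p)
            questionnaire = simulate_questionnaire(
                gamma, config.questionnaire_rho, rng,
                log_loc=log_gamma_loc, log_scale=config.gamma_sigma_log,
            )
            records.append(ParticipantRecord(
                pid=pid, sex=sex, true_params=params, choices=choices,
                trial_order=order, questionnaire=questionnaire,
                mediator=mediator, covariates=covs,
            ))
    return records


def cohort_frames(records: list[ParticipantRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long choices table and wide covariates table for a cohort."""
    choice_rows = []
    cov_rows = []
    for rec in records:
        for tid, c in enumerate(rec.choices):
            choice_rows.append({"pid": rec.pid, "trial_id": tid, "choice": int(c)})
        row = {"pid": rec.pid, "sex": rec.sex}
        row.update(rec.covariates)
        row.update(q_a=rec.questionnaire[0], q_b=rec.questionnaire[1],
                   q_c=rec.questionnaire[2], mediator=rec.mediator,
                   true_gamma=rec.true_params.gamma, true_alpha=rec.true_params.alpha,
                   true_reward_weight=rec.true_params.reward_weight,
                   true_intercept=rec.true_params.intercept)
        cov_rows.append(row)
    return pd.DataFrame(choice_rows), pd.DataFrame(cov_rows)


def write_cohort(records: list[ParticipantRecord], choices_path, covariates_path) -> None:
    """Serialize a cohort to a choices CSV and a covariates CSV."""
    choices, covs = cohort_frames(records)
    choices.to_csv(choices_path, index=False)
    covs.to_csv(covariates_path, index=False)


def read_cohort(choices_path, covariates_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the CSV pair written by :func:`write_cohort`."""
    choices = pd.read_csv(choices_path)
    covs = pd.read_csv(covariates_path)
    for col in ("pid", "trial_id", "choice"):
        if col not in choices.columns:
            raise ValueError(f"choices CSV missing column {col!r}")
    if "pid" not in covs.columns or "sex" not in covs.columns:
        raise ValueError("covariates CSV missing pid/sex columns")
    return choices, covs
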