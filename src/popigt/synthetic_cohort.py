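"""Synthetic accelerated-longitudinal cohort generator.

Emulates the study design the pipeline is built for: two recruitment
cohorts (ages 9–10 and 12–13 at baseline) assessed up to five times at
~9-month spacing, with attrition from 208 baseline participants down to 73
at the final wave, 36% prevalence of maternal depression history, nonverbal
IQ and sex covariates, and a shift to partially remote administration in
the last two waves.  Each retained subject-wave carries *true* PoP-ORL
parameters produced by a per-parameter linear effect map over centred age,
risk group and covariates (on the unconstrained scales, learning rates
through the standard-normal CDF), plus subject-level random intercepts and
wave-level noise; sessions are then simulated from those parameters on the
fixed task schedule.  The ground-truth table makes the generator usable as
a recovery harness for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .igt_task import SessionLog, TaskConfig, default_task_config
from .pop_orl import ModelConfig, simulate_agent
from .hier_fit import PARAM_NAMES, theta_to_params
from .growth_models import AGE_CENTER

#: wave-by-wave retained counts of the emulated study
DEFAULT_RETENTION = (208, 157, 135, 98, 73)
#: probability a session is administered on-site, per wave (waves 4 and 5
#: were partially remote)
DEFAULT_ONSITE = (1.0, 1.0, 1.0, 0.89, 0.41)


@dataclass(frozen=True)
class EffectMap:
    """Linear predictor of one parameter's true value on its generating scale.

    value = intercept + age_slope*age_c + quad*age_c^2 + hx_offset*hx
            + iq_coef*(iq-100) + sex_coef*sex + onsite_coef*(onsite-1)
            + subject random intercept (SD subject_sd)
            + wave-level noise (SD wave_sd)

    The intercept therefore refers to a typical on-site, average-IQ, male,
    low-risk child at the 10.98-year baseline age.
    """

    intercept: float
    age_slope: float = 0.0
    quad: float = 0.0
    hx_offset: float = 0.0
    iq_coef: float = 0.0
    sex_coef: float = 0.0
    onsite_coef: float = 0.0
    subject_sd: float = 0.3
    wave_sd: float = 0.2


def default_effect_maps() -> dict[str, EffectMap]:
    """Effect maps shipped with the package (see data/default_cohort.yaml)."""
    ref = resources.files("popigt.data").joinpath("default_cohort.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {name: EffectMap(**vals) for name, vals in raw["effect_maps"].items()}


@dataclass(frozen=True)
class CohortConfig:
    n_baseline: int = 208
    cohort_split: float = 0.5  # fraction recruited at 9-10 vs 12-13
    waves: int = 5
    wave_spacing: float = 0.75  # years (~9 months)
    retention: tuple[int, ...] = DEFAULT_RETENTION
    maternal_hx_prev: float = 0.36
    iq_mean: float = 101.8
    iq_sd: float = 15.0
    female_prob: float = 0.59
    onsite_probs: tuple[float, ...] = DEFAULT_ONSITE
    effect_maps: dict[str, EffectMap] | None = None
    timeout_prob: float = 0.0

    def __post_init__(self) -> None:
        if any(b > a for a, b in zip(self.retention, self.retention[1:])):
            raise ValueError("retention must be non-increasing")
        if self.retention != DEFAULT_RETENTION and \
                self.retention[0] > self.n_baseline:
            # custom retention counts must fit the sample; the shipped
            # default profile is rescaled to n_baseline instead
            raise ValueError("retention cannot exceed n_baseline")
        for p in (self.cohort_split, self.maternal_hx_prev, self.female_prob,
                  *self.onsite_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.wave_spacing <= 0:
            raise ValueError("wave_spacing must be positive")

    def scaled_retention(self) -> tuple[int, ...]:
        """Retention counts rescaled to n_baseline, shape preserved."""
        if self.n_baseline == DEFAULT_RETENTION[0] and \
                self.retention == DEFAULT_RETENTION:
            return self.retention[: self.waves]
        base = self.retention[0]
        return tuple(
            max(2, round(r * self.n_baseline / base))
            for r in self.retention[: self.waves]
        )


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> pd.DataFrame:
    """Ground-truth table: one row per retained subject-wave.

    Columns: subject_id, wave, age, age_c, maternal_hx, sex, iq, onsite,
    internalizing, dropout_wave, and the true parameters A_rew, A_pun,
    beta_f, beta_b (plus A_rew_z / A_pun_z on the generating probit scale).
    """
    rng = np.random.default_rng(seed)
    n = config.n_baseline
    effect_maps = config.effect_maps or default_effect_maps()

    young = rng.random(n) < config.cohort_split
    base_age = np.where(young, rng.uniform(9.0, 10.0, n), rng.uniform(12.0, 13.0, n))
    hx = (rng.random(n) < config.maternal_hx_prev).astype(int)
    sex = (rng.random(n) < config.female_prob).astype(int)
    iq = rng.normal(config.iq_mean, config.iq_sd, n)
    # baseline internalizing symptoms, loosely elevated in the risk group
    internalizing = rng.normal(50.0 + 3.0 * hx, 10.0)

    retention = config.scaled_retention()
    # missing-at-random monotone dropout: a random subset (independent of
    # everything else) leaves after each wave
    order = rng.permutation(n)
    dropout_wave = np.full(n, config.waves + 1)
    cut = n
    for w in range(2, config.waves + 1):
        lost = cut - retention[w - 1]
        cut -= lost
        dropout_wave[order[cut: cut + lost]] = w

    subj_re = {p: rng.normal(0.0, em.subject_sd, n)
               for p, em in effect_maps.items()}
    rows = []
    for w in range(1, config.waves + 1):
        retained = np.where(dropout_wave > w)[0]
        onsite = (rng.random(n) < config.onsite_probs[w - 1]).astype(int)
        for i in retained:
            age = base_age[i] + (w - 1) * config.wave_spacing
            age_c = age - AGE_CENTER
            row = {
                "subject_id": f"s{i:04d}", "wave": w, "age": age,
                "age_c": age_c, "maternal_hx": int(hx[i]), "sex": int(sex[i]),
                "iq": float(iq[i]), "onsite": int(onsite[i]),
                "internalizing": float(internalizing[i]),
                "dropout_wave": int(dropout_wave[i]),
            }
            theta = np.empty(4)
            for k, p in enumerate(PARAM_NAMES):
                em = effect_maps[p]
                theta[k] = (
                    em.intercept + em.age_slope * age_c + em.quad * age_c**2
                    + em.hx_offset * hx[i] + em.iq_coef * (iq[i] - 100.0)
                    + em.sex_coef * sex[i] + em.onsite_coef * (onsite[i] - 1)
                    + subj_re[p][i] + rng.normal(0.0, em.wave_sd)
                )
            params = theta_to_params(theta)
            row.update({
                "A_rew": params.A_rew, "A_pun": params.A_pun,
                "beta_f": params.beta_f, "beta_b": params.beta_b,
                "A_rew_z": theta[0], "A_pun_z": theta[1],
            })
            rows.append(row)
    truth = pd.DataFrame(rows)
    counts = truth.groupby("wave")["subject_id"].size().tolist()
    assert counts == list(retention), (counts, retention)
    return truth


def simulate_study(
    config: CohortConfig = CohortConfig(),
    task_config: TaskConfig | None = None,
    model_config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> tuple[list[SessionLog], pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: (sessions, demographics table, ground truth).

    One session per retained subject-wave, simulated at that row's true
    parameters on the fixed task schedule; fully reproducible given seed.
    """
    truth = generate_cohort(config, seed)
    task_config = task_config or default_task_config()
    rng = np.random.default_rng(seed + 1)
    sessions = []
    for row in truth.itertuples():
        params = theta_to_params(
            np.array([row.A_rew_z, row.A_pun_z, row.beta_f, row.beta_b])
        )
        log = simulate_agent(
            params, task_config, model_config,
            seed=int(rng.integers(2**31)),
            subject_id=row.subject_id, wave=row.wave,
        )
        log.administration_modality = "onsite" if row.onsite else "remote"
        sessions.append(log)
    demographics = truth[[
        "subject_id", "wave", "age", "maternal_hx", "sex", "iq", "onsite",
        "internalizing",
    ]].copy()
    return sessions, demographics, truth


def truth_long_metrics(truth: pd.DataFrame) -> pd.DataFrame:
    """Reshape ground-truth parameters into the long metric table the
    growth stage consumes (useful for oracle tests of the ladder)."""
    rows = []
    for metric in ("A_rew_z", "A_pun_z", "beta_f", "beta_b"):
        sub = truth[["subject_id", "wave", "age_c", "maternal_hx", "sex",
                     "iq", "onsite"]].copy()
        sub["metric_name"] = metric
        sub["value"] = truth[metric].to_numpy()
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)
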