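"""Synthetic ICU cohort generator.

Emulates the data structure the hyperoxemia analysis consumes: an
admissions table (one row per ICU episode with covariates, exclusion flags,
length of stay and ICU death) and a long blood-gas table of irregular
(time, PaO2) samples.  The generating model is fully specified:

* length of stay is log-normal (median ~3.5 d, IQR ~2-6.6 d);
* blood gases arrive at log-normal inter-sample gaps (median 3 h) capped at
  12 h, with a configurable probability of an untrusted >12 h gap;
* each episode's latent PaO2 is a piecewise-constant patient mean (an early
  and a late phase, the late phase typically lower as oxygen is weaned)
  plus Gaussian sampling noise, clamped to a physiologic range; a
  configurable "spike-at-zero" fraction of episodes is constrained below
  the hyperoxemia threshold throughout;
* ICU death is Bernoulli from a logistic model on the any-exposure
  indicator, the hyperoxemia dose and the covariates, where the exposure
  terms are computed by the package's own exposure engine on the generated
  samples (so parameter-recovery checks are not confounded by imputation
  error); death is recorded at ICU discharge.

Everything is driven by one integer seed; the same config yields
byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exposure import DEFAULT_THRESHOLD_KPA, compute_exposure_table

AGE_CENTER = 62.0
WEIGHT_CENTER = 77.0
APACHE_CENTER = 16.0
LOS_CENTER_DAYS = 3.5

#: log-odds scale; rate-style coefficients are per stated unit
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "intercept": -4.1,
    "any_exposure": math.log(1.5),
    "dose_kpa": 0.0,
    "respiratory_dx": 0.3,
    "sex_male": 0.1,
    "prior_dependency": 0.4,
    "medical": 0.35,
    "continuous_mv": 0.5,
    "age_per_10yr": 0.2,
    "weight_per_10kg": -0.05,
    "apache_per_point": 0.08,
    "los_per_day": 0.0,
}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Data-generating model for the synthetic ICU cohort.

    Defaults target the marginal structure of a large mixed UK ICU
    population: ~5% ICU mortality, ~77% any-hyperoxemia prevalence in the
    first day, log-normal stays with median 3.5 days.
    """

    n_patients: int = 5000
    seed: int = 0

    # ICU length of stay (log-normal, days)
    los_median_days: float = 3.5
    los_sigma: float = 0.885
    los_min_days: float = 0.25
    los_max_days: float = 45.0

    # blood-gas sampling process (hours)
    gap_median_h: float = 3.0
    gap_sigma: float = 0.5
    gap_cap_h: float = 12.0
    p_long_gap: float = 0.08
    long_gap_min_h: float = 12.5
    long_gap_max_h: float = 24.0
    first_sample_min_h: float = 0.25
    first_sample_max_h: float = 2.0

    # latent PaO2 trajectory (kPa)
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA
    p_never_hyperoxemic: float = 0.08
    mu_hyper_mean: float = 13.8
    mu_hyper_sd: float = 2.5
    mu_never_mean: float = 10.5
    mu_never_sd: float = 1.5
    late_shift_mean: float = -0.3
    late_shift_sd: float = 0.8
    pao2_noise_sd: float = 1.5
    pao2_min: float = 4.0
    pao2_max: float = 60.0

    # covariates
    age_mean: float = 62.0
    age_sd: float = 16.0
    age_min: float = 16.0
    age_max: float = 95.0
    weight_mean: float = 77.0
    weight_sd: float = 20.0
    weight_min: float = 35.0
    weight_max: float = 180.0
    p_male: float = 0.60
    apache_mean: float = 16.0
    apache_sd: float = 6.0
    p_respiratory_dx: float = 0.25
    p_prior_dependency: float = 0.18
    p_surgical: float = 0.45
    p_vent_none: float = 0.40
    p_vent_one: float = 0.45  # remainder get two intervals

    # admission bookkeeping / exclusion flags
    p_readmission: float = 0.05
    p_treatment_limitation: float = 0.03
    p_cpr_pre_24h: float = 0.02
    p_qc_fail: float = 0.01
    p_missing_covariate: float = 0.004

    # outcome model
    outcome_window_h: float = 24.0
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in (
            "p_long_gap",
            "p_never_hyperoxemic",
            "p_male",
            "p_respiratory_dx",
            "p_prior_dependency",
            "p_surgical",
            "p_vent_none",
            "p_vent_one",
            "p_readmission",
            "p_treatment_limitation",
            "p_cpr_pre_24h",
            "p_qc_fail",
            "p_missing_covariate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.p_vent_none + self.p_vent_one > 1.0:
            raise ConfigurationError("ventilation interval probabilities exceed 1")
        for name in ("los_median_days", "gap_median_h", "los_min_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        missing = set(DEFAULT_TRUE_COEFFICIENTS) - set(self.true_coefficients)
        if missing:
            raise ConfigurationError(
                f"true_coefficients missing entries: {sorted(missing)}"
            )

    def with_coefficients(self, **updates: float) -> "GeneratorConfig":
        coefs = dict(self.true_coefficients)
        coefs.update(updates)
        return replace(self, true_coefficients=coefs)


@dataclass(frozen=True)
class EpisodeParams:
    """Latent per-episode parameters for one blood-gas series."""

    episode_id: str
    los_h: float
    never_hyperoxemic: bool
    mu_pao2: float
    late_shift: float


# ---------------------------------------------------------------------------
# sampling internals (shared by the single-episode API and the bulk path)
# ---------------------------------------------------------------------------


def _draw_sample_times(
    rng: np.random.Generator, los_h: np.ndarray, cfg: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Flat (episode_index, t_h) arrays of blood-gas draw times."""
    n = los_h.size
    first = rng.uniform(cfg.first_sample_min_h, cfg.first_sample_max_h, n)
    mean_gap = cfg.gap_median_h * math.exp(0.5 * cfg.gap_sigma**2)
    caps = np.ceil(los_h / mean_gap * 1.7).astype(int) + 8
    total = int(caps.sum())
    ep = np.repeat(np.arange(n), caps)

    base = rng.lognormal(math.log(cfg.gap_median_h), cfg.gap_sigma, total)
    base = np.minimum(base, cfg.gap_cap_h)
    is_long = rng.random(total) < cfg.p_long_gap
    long_gaps = rng.uniform(cfg.long_gap_min_h, cfg.long_gap_max_h, total)
    gaps = np.where(is_long, long_gaps, base)

    starts = np.concatenate(([0], np.cumsum(caps)[:-1]))
    gaps[starts] = 0.0  # first sample sits at its own draw time
    cs = np.cumsum(gaps)
    offset = np.repeat(cs[starts], caps)
    t = first[ep] + (cs - offset)
    keep = t <= los_h[ep]
    return ep[keep], t[keep]


def _draw_pao2(
    rng: np.random.Generator,
    ep: np.ndarray,
    t: np.ndarray,
    los_h: np.ndarray,
    never: np.ndarray,
    mu: np.ndarray,
    shift: np.ndarray,
    cfg: GeneratorConfig,
) -> np.ndarray:
    level = mu[ep] + shift[ep] * (t > los_h[ep] / 2.0)
    p = level + rng.normal(0.0, cfg.pao2_noise_sd, t.size)
    p = np.clip(p, cfg.pao2_min, cfg.pao2_max)
    cap = np.where(never[ep], cfg.threshold_kpa - 0.1, cfg.pao2_max)
    return np.minimum(p, cap)


def simulate_blood_gas_series(
    params: EpisodeParams, rng: np.random.Generator, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Blood-gas samples for a single episode.

    Runs the same sampling model as the bulk generator: times in
    ``(0, los_h]`` with configured inter-sample gaps; never-hyperoxemic
    episodes stay strictly below the threshold.
    """
    if params.los_h <= 0:
        raise ConfigurationError("episode length of stay must be positive")
    los = np.array([params.los_h])
    ep, t = _draw_sample_times(rng, los, cfg)
    p = _draw_pao2(
        rng,
        ep,
        t,
        los,
        np.array([params.never_hyperoxemic]),
        np.array([params.mu_pao2]),
        np.array([params.late_shift]),
        cfg,
    )
    return pd.DataFrame(
        {"episode_id": params.episode_id, "t_h": t, "pao2_kpa": p}
    )


def simulate_outcome(
    true_dose: np.ndarray,
    any_exposure: np.ndarray,
    covariates: Mapping[str, np.ndarray],
    coefficients: Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli ICU-death draw from the logistic outcome model.

    ``covariates`` must provide respiratory_dx, sex_male, prior_dependency,
    medical, continuous_mv, age_years, weight_kg, apache_ii and los_days;
    continuous covariates enter centred (age 62 y, weight 77 kg, APACHE II
    16, LOS 3.5 d) at the per-unit scales of the coefficient names.
    """
    missing = set(DEFAULT_TRUE_COEFFICIENTS) - set(coefficients)
    if missing:
        raise ConfigurationError(f"missing coefficients: {sorted(missing)}")
    c = coefficients
    lp = (
        c["intercept"]
        + c["any_exposure"] * np.asarray(any_exposure, dtype=float)
        + c["dose_kpa"] * np.asarray(true_dose, dtype=float)
        + c["respiratory_dx"] * covariates["respiratory_dx"]
        + c["sex_male"] * covariates["sex_male"]
        + c["prior_dependency"] * covariates["prior_dependency"]
        + c["medical"] * covariates["medical"]
        + c["continuous_mv"] * covariates["continuous_mv"]
        + c["age_per_10yr"] * (covariates["age_years"] - AGE_CENTER) / 10.0
        + c["weight_per_10kg"] * (covariates["weight_kg"] - WEIGHT_CENTER) / 10.0
        + c["apache_per_point"] * (covariates["apache_ii"] - APACHE_CENTER)
        + c["los_per_day"] * (covariates["los_days"] - LOS_CENTER_DAYS)
    )
    p = 1.0 / (1.0 + np.exp(-np.clip(lp, -500.0, 500.0)))
    return rng.random(p.size) < p


def _continuous_mv(
    window_h: float,
    v1s: np.ndarray,
    v1e: np.ndarray,
    v2s: np.ndarray,
    v2e: np.ndarray,
) -> np.ndarray:
    """Vectorized: does the (<=2-interval) ventilation union cover [0, w]?"""
    direct = (v1s <= 0.0) & (v1e >= window_h)
    chained = (
        (v1s <= 0.0) & (v2s <= v1e) & (np.fmax(v1e, v2e) >= window_h)
    )
    return np.where(
        np.isnan(v1s), False, direct | np.where(np.isnan(v2s), False, chained)
    )


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the admissions and blood-gas tables.

    Returns ``(admissions, blood_gas)``; admissions has one row per ICU
    episode (index admissions plus a small readmission fraction), blood_gas
    one row per arterial sample with strictly increasing times within an
    episode.  Deterministic in ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    # --- covariates -------------------------------------------------------
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), cfg.age_min, cfg.age_max)
    weight = np.clip(
        rng.normal(cfg.weight_mean, cfg.weight_sd, n), cfg.weight_min, cfg.weight_max
    )
    male = rng.random(n) < cfg.p_male
    apache = np.clip(np.rint(rng.normal(cfg.apache_mean, cfg.apache_sd, n)), 0, 50)
    resp = rng.random(n) < cfg.p_respiratory_dx
    dep = rng.random(n) < cfg.p_prior_dependency
    surgical = rng.random(n) < cfg.p_surgical

    tlim = rng.random(n) < cfg.p_treatment_limitation
    cpr = rng.random(n) < cfg.p_cpr_pre_24h
    qc = rng.random(n) < cfg.p_qc_fail

    # --- stay and latent oxygen trajectory --------------------------------
    los_d = np.clip(
        rng.lognormal(math.log(cfg.los_median_days), cfg.los_sigma, n),
        cfg.los_min_days,
        cfg.los_max_days,
    )
    los_h = los_d * 24.0
    never = rng.random(n) < cfg.p_never_hyperoxemic
    mu = np.where(
        never,
        rng.normal(cfg.mu_never_mean, cfg.mu_never_sd, n),
        rng.normal(cfg.mu_hyper_mean, cfg.mu_hyper_sd, n),
    )
    shift = rng.normal(cfg.late_shift_mean, cfg.late_shift_sd, n)

    ep_idx, t = _draw_sample_times(rng, los_h, cfg)
    pao2 = _draw_pao2(rng, ep_idx, t, los_h, never, mu, shift, cfg)

    episode_ids = np.array([f"E{i:06d}" for i in range(n)])
    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    blood_gas = pd.DataFrame(
        {
            "episode_id": episode_ids[ep_idx],
            "t_h": t,
            "pao2_kpa": pao2,
        }
    )

    # --- ventilation intervals (0-2 per episode) --------------------------
    u = rng.random(n)
    n_vent = np.where(u < cfg.p_vent_none, 0, np.where(u < cfg.p_vent_none + cfg.p_vent_one, 1, 2))
    v1_end_frac = rng.uniform(0.3, 1.0, n)
    v1s = np.where(n_vent >= 1, 0.0, np.nan)
    v1e = np.where(n_vent >= 1, v1_end_frac * los_h, np.nan)
    gap_after = rng.uniform(1.0, 10.0, n)
    v2s_raw = v1e + gap_after
    v2e_raw = np.minimum(v2s_raw + rng.uniform(5.0, 48.0, n), los_h)
    two_ok = (n_vent == 2) & (v2e_raw > v2s_raw) & (v2s_raw < los_h)
    v2s = np.where(two_ok, v2s_raw, np.nan)
    v2e = np.where(two_ok, v2e_raw, np.nan)

    # --- outcome from the model's own exposure metric ----------------------
    expo = compute_exposure_table(
        blood_gas,
        episode_ids,
        cfg.outcome_window_h,
        threshold_kpa=cfg.threshold_kpa,
    )
    cmv = _continuous_mv(cfg.outcome_window_h, v1s, v1e, v2s, v2e)
    death = simulate_outcome(
        expo["dose_kpa"].to_numpy(),
        expo["any_exposure"].to_numpy(dtype=float),
        {
            "respiratory_dx": resp.astype(float),
            "sex_male": male.astype(float),
            "prior_dependency": dep.astype(float),
            "medical": (~surgical).astype(float),
            "continuous_mv": cmv.astype(float),
            "age_years": age,
            "weight_kg": weight,
            "apache_ii": apache,
            "los_days": los_d,
        },
        cfg.true_coefficients,
        rng,
    )

    admissions = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "episode_id": episode_ids,
            "admission_seq": 1,
            "age_years": np.round(age, 1),
            "weight_kg": np.round(weight, 1),
            "sex": np.where(male, "M", "F"),
            "apache_ii": apache.astype(int),
            "respiratory_dx": resp.astype(int),
            "prior_dependency": dep.astype(int),
            "patient_type": np.where(surgical, "surgical", "medical"),
            "vent_1_start_h": v1s,
            "vent_1_end_h": np.round(v1e, 2),
            "vent_2_start_h": np.round(v2s, 2),
            "vent_2_end_h": np.round(v2e, 2),
            "treatment_limitation": tlim.astype(int),
            "cpr_pre_24h": cpr.astype(int),
            "qc_fail": qc.astype(int),
            "los_h": np.round(los_h, 2),
            "icu_death": death.astype(int),
        }
    )

    # --- readmission episodes (excluded downstream as non-index) ----------
    n_re = int(rng.binomial(n, cfg.p_readmission))
    if n_re > 0:
        who = rng.choice(n, size=n_re, replace=False)
        re_los_d = np.clip(
            rng.lognormal(math.log(cfg.los_median_days * 0.7), cfg.los_sigma, n_re),
            cfg.los_min_days,
            cfg.los_max_days,
        )
        re_los_h = re_los_d * 24.0
        re_ids = np.array([f"R{i:06d}" for i in range(n_re)])
        re_ep, re_t = _draw_sample_times(rng, re_los_h, cfg)
        re_p = _draw_pao2(
            rng, re_ep, re_t, re_los_h, never[who], mu[who], shift[who], cfg
        )
        blood_gas = pd.concat(
            [
                blood_gas,
                pd.DataFrame(
                    {
                        "episode_id": re_ids[re_ep],
                        "t_h": re_t,
                        "pao2_kpa": re_p,
                    }
                ),
            ],
            ignore_index=True,
        )
        re_rows = admissions.iloc[who].copy().reset_index(drop=True)
        re_rows["episode_id"] = re_ids
        re_rows["admission_seq"] = 2
        re_rows["los_h"] = np.round(re_los_h, 2)
        re_rows["icu_death"] = rng.random(n_re) < 0.08
        re_rows["icu_death"] = re_rows["icu_death"].astype(int)
        admissions = pd.concat([admissions, re_rows], ignore_index=True)

    # --- sparse missingness (exercises the complete-case filter) ----------
    miss = rng.random(len(admissions)) < cfg.p_missing_covariate
    admissions.loc[miss, "weight_kg"] = np.nan

    return admissions, blood_gas
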