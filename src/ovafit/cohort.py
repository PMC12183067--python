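"""Seedable generator of clinic-shaped synthetic cohorts.

No raw clinic data ship with the package, so every analysis is exercised on
synthetic cohorts carrying exactly the statistical structure the models
assume, calibrated by default to the published parameter estimates:

* per-age live-birth counts are binomial draws whose success rate follows
  the fitted logistic decline in age (nationwide-registry column: maximum
  42.7%, half-peak age 40.1 y, decline width 3.02 y, ~125,674 cycles);
* ovarian-reserve measurements are gamma draws whose age-indexed mean and
  mode follow the published logistic curves (e.g. AMH mean maximum
  6.5 ng/mL at half-peak age 35.5 y), with count factors rounded to integers;
* per-transfer and per-retrieval outcomes are Bernoulli draws from the
  published logit equations on scaled covariates, the covariates sampled
  uniformly over clinic-plausible scaled ranges;
* the retrieval-cycle generator can also emit patient trajectories (stop at
  live birth, a cycle cap, or random censoring at the published exclusion
  rates: 14/4,181 spontaneous pregnancies, 54/4,181 patient reasons).

A single global seed expands into independent named substreams, so adding a
stream never perturbs existing output, and identical configurations yield
byte-identical data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .curves import LogisticDeclineParams, gamma_from_mean_mode, logistic_decline
from .errors import DomainError, InvalidSurfaceError
from .quantity import COUNT_FACTORS, FACTORS
from .wnlsr import WeightedAgeSeries

__all__ = [
    "CohortConfig",
    "QUALITY_CALIBRATIONS",
    "RESERVE_CALIBRATIONS",
    "SVBT_LOGIT",
    "OPU_LOGITS",
    "generate_quality_series",
    "generate_reserve_cohort",
    "generate_svbt_cohort",
    "generate_opu_scaled_cohort",
    "generate_opu_cohort",
]

# Published calibration: logistic decline of live-birth rate per transfer.
QUALITY_CALIBRATIONS: Dict[str, LogisticDeclineParams] = {
    "registry": LogisticDeclineParams(42.7, 40.1, 3.02),
    "pgta": LogisticDeclineParams(44.9, 40.3, 2.89),
    "clinic": LogisticDeclineParams(49.4, 39.6, 3.07),
    "euploidy": LogisticDeclineParams(74.9, 40.3, 2.89),
}

# Published calibration: (mean curve, mode curve) per quantifying factor.
RESERVE_CALIBRATIONS: Dict[str, Tuple[LogisticDeclineParams, LogisticDeclineParams]] = {
    "AMH": (LogisticDeclineParams(6.5, 35.5, 5.7), LogisticDeclineParams(3.8, 34.3, 3.4)),
    "AFC": (LogisticDeclineParams(22.6, 35.7, 7.2), LogisticDeclineParams(18.0, 34.8, 6.3)),
    "mature_oocyte": (LogisticDeclineParams(14.5, 38.6, 5.9), LogisticDeclineParams(9.8, 36.7, 4.1)),
    "transferable_embryo": (LogisticDeclineParams(5.3, 38.7, 4.5), LogisticDeclineParams(2.8, 37.8, 3.1)),
}

# Published logit equations on scaled covariates: (const, age, grade, culture)
SVBT_LOGIT = np.array([4.552, -0.129, -0.328, -0.502])
# (const, age, factor, cycle) per quantifying factor
OPU_LOGITS: Dict[str, np.ndarray] = {
    "AMH": np.array([4.922, -0.158, 0.286, -0.185]),
    "AFC": np.array([2.683, -0.159, 0.211, -0.200]),
    "mature_oocyte": np.array([1.646, -0.164, 0.369, -0.145]),
    "transferable_embryo": np.array([-1.935, -0.164, 1.361, -0.054]),
}

_CENSOR_SPONTANEOUS = 14 / 4181  # per-cycle censoring hazards
_CENSOR_PATIENT = 54 / 4181

# named substreams off the global seed
_STREAMS = {"quality": 1, "reserve": 2, "svbt": 3, "opu_scaled": 4, "opu": 5}


@dataclass(frozen=True)
class CohortConfig:
    """Calibration bundle for the synthetic generators (seed-deterministic)."""

    seed: int = 0
    age_min: int = 27
    age_max: int = 45
    quality_total_n: int = 125_674
    quality_params: LogisticDeclineParams = QUALITY_CALIBRATIONS["registry"]
    surface_params: Dict[str, Tuple[LogisticDeclineParams, LogisticDeclineParams]] = field(
        default_factory=lambda: dict(RESERVE_CALIBRATIONS)
    )
    reserve_total_n: Dict[str, int] = field(
        default_factory=lambda: {
            "AMH": 5_638, "AFC": 2_698, "mature_oocyte": 2_698,
            "transferable_embryo": 2_698,
        }
    )
    svbt_logit: np.ndarray = field(default_factory=lambda: SVBT_LOGIT.copy())
    opu_logits: Dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in OPU_LOGITS.items()}
    )
    # scaled-covariate sampling ranges
    age_scaled_range: Tuple[float, float] = (10.0, 45.0)
    grade_scaled_range: Tuple[float, float] = (0.0, 3.0)
    factor_scaled_range: Tuple[float, float] = (0.0, 10.0)
    cycle_scaled_range: Tuple[float, float] = (1.0, 6.0)
    max_cycles: int = 6
    censor_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "spontaneous_pregnancy": _CENSOR_SPONTANEOUS,
            "patient_reasons": _CENSOR_PATIENT,
        }
    )

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic substream for a named generator."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_STREAMS[stream],))
        )


def _age_profile(cfg: CohortConfig, total_n: int, peak: float = 38.0) -> np.ndarray:
    """Clinic-like per-age sample sizes: triangular profile peaking near the
    given age over a small uniform base, rounded to sum exactly to total_n."""
    ages = cfg.ages.astype(float)
    half_span = max(peak - ages.min(), ages.max() - peak) + 1.0
    shape = 0.15 + np.maximum(0.0, 1.0 - np.abs(ages - peak) / half_span)
    frac = shape / shape.sum()
    n = np.floor(frac * total_n).astype(int)
    # largest-remainder rounding keeps the total exact
    remainder = frac * total_n - n
    short = total_n - int(n.sum())
    n[np.argsort(remainder)[::-1][:short]] += 1
    return np.maximum(n, 1)


def generate_quality_series(cfg: CohortConfig) -> WeightedAgeSeries:
    """Per-age binomial live-birth series from the quality decline curve."""
    rng = cfg.rng("quality")
    ages = cfg.ages
    n = _age_profile(cfg, cfg.quality_total_n)
    p = logistic_decline(ages.astype(float), cfg.quality_params) / 100.0
    successes = rng.binomial(n, p)
    return WeightedAgeSeries(
        x=ages.astype(float), y=100.0 * successes / n, n=n
    )


def generate_reserve_cohort(cfg: CohortConfig, factor: str) -> pd.DataFrame:
    """Per-patient ``(age, value)`` records drawn from the gamma surface;
    count factors are rounded to the nearest integer (non-negative)."""
    if factor not in FACTORS:
        raise DomainError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    mean_curve, mode_curve = cfg.surface_params[factor]
    rng = cfg.rng("reserve")
    ages = cfg.ages
    n = _age_profile(cfg, cfg.reserve_total_n[factor], peak=36.0)
    mean = logistic_decline(ages.astype(float), mean_curve)
    mode = logistic_decline(ages.astype(float), mode_curve)
    if np.any(mean <= mode) or np.any(mode <= 0):
        raise InvalidSurfaceError(
            "configured surface violates mean > mode > 0 over the age range"
        )
    frames = []
    for a, na, m, mo in zip(ages, n, mean, mode):
        g = gamma_from_mean_mode(float(m), float(mo))
        vals = rng.gamma(g.shape, g.scale, size=na)
        if factor in COUNT_FACTORS:
            vals = np.maximum(np.rint(vals), 0.0)
        frames.append(pd.DataFrame({"age": a, "value": vals}))
    return pd.concat(frames, ignore_index=True)


def _bernoulli_from_logit(rng, X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    lp = beta[0] + X @ beta[1:]
    return (rng.random(X.shape[0]) < expit(lp)).astype(int)


def generate_svbt_cohort(cfg: CohortConfig, n: int = 50_000) -> pd.DataFrame:
    """Per-transfer rows with scaled covariates and Bernoulli outcomes from
    the published per-transfer logit."""
    rng = cfg.rng("svbt")
    age = rng.uniform(*cfg.age_scaled_range, size=n)
    grade = rng.uniform(*cfg.grade_scaled_range, size=n)
    culture = rng.integers(0, 2, size=n).astype(float)
    X = np.column_stack([age, grade, culture])
    y = _bernoulli_from_logit(rng, X, cfg.svbt_logit)
    return pd.DataFrame(
        {"age_scaled": age, "grade_scaled": grade, "culture_day": culture,
         "live_birth": y}
    )


def generate_opu_scaled_cohort(
    cfg: CohortConfig, factor: str = "AMH", n: int = 50_000
) -> pd.DataFrame:
    """Per-retrieval rows with independently sampled scaled covariates and
    Bernoulli outcomes from the published per-retrieval logit for ``factor``."""
    if factor not in cfg.opu_logits:
        raise DomainError(f"no per-retrieval logit for factor {factor!r}")
    rng = cfg.rng("opu_scaled")
    age = rng.uniform(*cfg.age_scaled_range, size=n)
    fac = rng.uniform(*cfg.factor_scaled_range, size=n)
    cyc = rng.uniform(*cfg.cycle_scaled_range, size=n)
    X = np.column_stack([age, fac, cyc])
    y = _bernoulli_from_logit(rng, X, cfg.opu_logits[factor])
    return pd.DataFrame(
        {"age_scaled": age, "factor_scaled": fac, "cycle_scaled": cyc,
         "live_birth": y}
    )


def generate_opu_cohort(
    cfg: CohortConfig, factor: str = "AMH", n_patients: int = 2_000
) -> pd.DataFrame:
    """Patient retrieval trajectories: successive cycles until live birth,
    the cycle cap, or random censoring.

    Each patient keeps fixed scaled age and factor level; the cycle covariate
    is the 1-based cycle index. Censored cycles carry no outcome (NaN) and a
    reason; all other cycles, including failures, are emitted.
    """
    if factor not in cfg.opu_logits:
        raise DomainError(f"no per-retrieval logit for factor {factor!r}")
    rng = cfg.rng("opu")
    beta = cfg.opu_logits[factor]
    reasons = list(cfg.censor_rates)
    hazards = np.array([cfg.censor_rates[r] for r in reasons])
    rows = []
    for pid in range(n_patients):
        age = rng.uniform(*cfg.age_scaled_range)
        fac = rng.uniform(*cfg.factor_scaled_range)
        for cyc in range(1, cfg.max_cycles + 1):
            u = rng.random(hazards.size)
            hit = np.nonzero(u < hazards)[0]
            if hit.size:
                rows.append((pid, age, cyc, fac, np.nan, reasons[hit[0]]))
                break
            lp = beta[0] + beta[1] * age + beta[2] * fac + beta[3] * cyc
            birth = int(rng.random() < expit(lp))
            rows.append((pid, age, cyc, fac, birth, "none"))
            if birth:
                break
    return pd.DataFrame(
        rows,
        columns=["patient", "age_scaled", "cycle_index", "factor_scaled",
                 "live_birth", "censored_reason"],
    )
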