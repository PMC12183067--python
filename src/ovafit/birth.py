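"""Scaled logistic-regression models of live birth per embryo transfer and
per oocyte retrieval.

Stage two of the pipeline turns the fitted marginal decline curves into
predictors. Each continuous covariate is *scaled* by mapping its raw value
through the covariate's own weighted nonlinear least-squares fit of the
marginal live-birth rate and then taking the logit of that rate — a
transform that makes the relationship between the covariate and the logit of
the outcome approximately linear, so a plain logistic regression on the
scaled covariates captures a nonlinear marginal effect. Binary covariates
(day-5 versus day-6 blastocyst culture) pass through unchanged.

The per-transfer model uses age, ordinal Gardner blastocyst grade
(excellent AA = 0, good AB/BA = 1, average BB/AC = 2, fair BC/CB = 3; CA and
CC excluded) and culture day. The per-retrieval models use age, one
ovarian-reserve "quantifying factor" at a time (the four factors are too
strongly correlated to enter jointly) and the retrieval-cycle index, which
also yields a cumulative live-birth rate over successive cycles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit as _logit
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DataError, DomainError, RankDeficiencyError, SeparationError
from .wnlsr import FitResult

logger = logging.getLogger("ovafit")

__all__ = [
    "GRADE_GROUPS",
    "EXCLUDED_GRADES",
    "map_grade",
    "scale_covariate",
    "inverse_scale",
    "ScaledDesign",
    "LogitModel",
    "fit_logit",
    "predict_live_birth",
    "cumulative_live_birth",
    "evaluate_model",
    "aor_from_coefficient",
    "filter_opu_cohort",
    "fit_svbt_pipeline",
    "fit_opu_pipeline",
]

# Gardner two-letter grades -> ordinal quality groups
GRADE_GROUPS: Dict[str, int] = {
    "AA": 0,           # excellent
    "AB": 1, "BA": 1,  # good
    "BB": 2, "AC": 2,  # average (AC outcomes track BB)
    "BC": 3, "CB": 3,  # fair
}
EXCLUDED_GRADES = frozenset({"CA", "CC"})
KNOWN_GRADES = frozenset(GRADE_GROUPS) | EXCLUDED_GRADES


def map_grade(gardner: str) -> Optional[int]:
    """Ordinal grade group for a Gardner string, or ``None`` for the excluded
    CA/CC grades. Unknown strings raise :class:`DataError`."""
    g = str(gardner).strip().upper()
    if g in GRADE_GROUPS:
        return GRADE_GROUPS[g]
    if g in EXCLUDED_GRADES:
        return None
    raise DataError(f"unknown Gardner grade {gardner!r}")


_RATE_CLIP = (0.1, 99.9)  # percent


def scale_covariate(raw, curve: FitResult):
    """Scale a raw covariate through its fitted marginal live-birth curve.

    Returns ``logit(yhat(raw) / 100)`` where ``yhat`` is the curve's fitted
    rate in percent, clipped to [0.1, 99.9] before the logit. Monotone in
    ``raw`` wherever the curve is.
    """
    if curve is None:
        raise DataError("covariate curve has not been fitted")
    rate = np.clip(np.asarray(curve.predict(raw), dtype=float), *_RATE_CLIP)
    out = _logit(rate / 100.0)
    return out if np.ndim(out) else float(out)


def inverse_scale(scaled, curve: FitResult, bracket=(0.0, 100.0)):
    """Invert :func:`scale_covariate` on a monotone region of the curve by
    bisection on the fitted rate."""
    from scipy.optimize import brentq

    scaled = np.atleast_1d(np.asarray(scaled, dtype=float))
    out = np.empty_like(scaled)
    for i, s in enumerate(scaled):
        out[i] = brentq(
            lambda x: scale_covariate(x, curve) - s, bracket[0], bracket[1],
            xtol=1e-12,
        )
    return out if out.size > 1 else float(out[0])


@dataclass
class ScaledDesign:
    """Design matrix of scaled covariates plus the scaling metadata (the
    fitted curve per covariate, ``None`` for pass-through binaries) that
    makes the raw -> scaled map reproducible and invertible."""

    data: pd.DataFrame
    scalers: Dict[str, Optional[FitResult]] = field(default_factory=dict)

    @classmethod
    def from_raw(
        cls, raw: pd.DataFrame, scalers: Dict[str, Optional[FitResult]]
    ) -> "ScaledDesign":
        cols = {}
        for col in raw.columns:
            curve = scalers.get(col)
            vals = raw[col].to_numpy(dtype=float)
            cols[col] = scale_covariate(vals, curve) if curve is not None else vals
        return cls(pd.DataFrame(cols, index=raw.index), dict(scalers))

    @property
    def columns(self) -> Sequence[str]:
        return list(self.data.columns)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class LogitModel:
    """Fitted logistic-regression model on scaled covariates.

    Coefficients include the intercept (named ``const``); ``aor`` is the
    exponentiated coefficient (adjusted odds ratio). ``auc``, ``threshold``
    and ``accuracy`` are filled by :func:`evaluate_model`.
    """

    names: Sequence[str]
    coef: np.ndarray
    se: np.ndarray
    ci95: np.ndarray
    pvalues: np.ndarray
    n: int
    auc: Optional[float] = None
    threshold: Optional[float] = None
    accuracy: Optional[float] = None

    @property
    def aor(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def aor_ci95(self) -> np.ndarray:
        return np.exp(self.ci95)

    def coef_named(self, name: str) -> float:
        return float(self.coef[list(self.names).index(name)])

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.names) - 1:
            raise DataError(
                f"expected {len(self.names) - 1} covariates, got {X.shape[1]}"
            )
        return self.coef[0] + X @ self.coef[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.names),
                "coef": self.coef,
                "se": self.se,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "aor": self.aor,
                "aor_ci_low": self.aor_ci95[:, 0],
                "aor_ci_high": self.aor_ci95[:, 1],
                "p": self.pvalues,
            }
        )


def fit_logit(design, outcomes) -> LogitModel:
    """Maximum-likelihood logistic regression with Wald SEs and 95% CIs.

    ``design`` may be a :class:`ScaledDesign`, a DataFrame or an array of
    scaled covariates (no intercept column; one is added). Raises
    :class:`SeparationError` on complete separation and
    :class:`RankDeficiencyError` on a collinear design.
    """
    if isinstance(design, ScaledDesign):
        X = design.data
    elif isinstance(design, pd.DataFrame):
        X = design
    else:
        X = pd.DataFrame(np.atleast_2d(np.asarray(design, dtype=float)))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("outcomes contain a single class; cannot fit")
    if not set(classes) <= {0.0, 1.0}:
        raise DataError("outcomes must be 0/1")
    if X.shape[1] == 0:
        Xc = pd.DataFrame({"const": np.ones(y.size)})
    else:
        Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise RankDeficiencyError("design matrix is rank-deficient (collinear covariates)")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        if "separation" in str(exc).lower() or type(exc).__name__.startswith("PerfectSeparation"):
            raise SeparationError(str(exc)) from exc
        raise
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError("non-finite standard errors (quasi-separation)")
    ci = np.asarray(res.conf_int())
    return LogitModel(
        names=list(Xc.columns),
        coef=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        ci95=ci,
        pvalues=np.asarray(res.pvalues, dtype=float),
        n=int(y.size),
    )


def predict_live_birth(model: LogitModel, covariates) -> np.ndarray:
    """Per-record live-birth probability: inverse-logit of the linear
    predictor on scaled covariates (intercept handled by the model)."""
    p = expit(model.linear_predictor(covariates))
    return p if p.size > 1 else float(p[0])


def cumulative_live_birth(
    model: LogitModel,
    base_covariates: Dict[str, float],
    n_cycles: int,
    cycle_var: str = "cycle",
    cycle_values: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-cycle and cumulative live-birth probabilities over retrieval cycles.

    Holding all other covariates fixed, the per-cycle probability ``p_i`` is
    the model prediction with the cycle covariate set to cycle ``i`` (or to
    ``cycle_values[i-1]`` when the cycle covariate is on a scaled scale), and

        CLBR(n) = 1 - prod_{i=1..n} (1 - p_i),

    assuming independence of cycles given the covariates. Non-decreasing in
    ``n`` and bounded by 1.
    """
    if n_cycles < 1:
        raise DomainError("n_cycles must be >= 1")
    cov_names = [nm for nm in model.names if nm != "const"]
    if cycle_var not in cov_names:
        raise DataError(f"model has no cycle covariate named {cycle_var!r}")
    vals = (
        np.asarray(cycle_values, dtype=float)
        if cycle_values is not None
        else np.arange(1, n_cycles + 1, dtype=float)
    )
    if vals.size < n_cycles:
        raise DataError("cycle_values shorter than n_cycles")
    rows = []
    for i in range(1, n_cycles + 1):
        cov = dict(base_covariates)
        cov[cycle_var] = vals[i - 1]
        x = np.array([[cov[nm] for nm in cov_names]])
        rows.append(float(expit(model.linear_predictor(x))[0]))
    p = np.array(rows)
    clbr = 1.0 - np.cumprod(1.0 - p)
    return pd.DataFrame(
        {"cycle": np.arange(1, n_cycles + 1), "p_cycle": p, "clbr": clbr}
    )


def evaluate_model(model: LogitModel, design, outcomes) -> LogitModel:
    """Attach discrimination metrics: rank-statistic AUC, the Youden-J
    optimal probability threshold, and accuracy at that threshold."""
    if isinstance(design, ScaledDesign):
        X = design.to_numpy()
    elif isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(outcomes, dtype=float)
    if np.unique(y).size < 2:
        raise DataError("AUC undefined: outcomes contain a single class")
    scores = expit(model.linear_predictor(X))
    model.auc = float(roc_auc_score(y, scores))
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = float(min(thresholds[best], 1.0))
    model.threshold = thr
    model.accuracy = float(np.mean((scores >= thr) == (y == 1)))
    return model


def aor_from_coefficient(coef: float, se: float):
    """Adjusted odds ratio ``exp(coef)`` with 95% CI ``exp(coef ± 1.96·se)``."""
    coef = float(coef)
    se = float(se)
    return np.exp(coef), (np.exp(coef - 1.96 * se), np.exp(coef + 1.96 * se))


def fit_svbt_pipeline(records: pd.DataFrame, seed: int = 0):
    """Full per-transfer pipeline on raw rows
    ``(age, gardner, culture_day, live_birth)``.

    Maps Gardner grades to ordinal groups (dropping CA/CC), fits the marginal
    age curve (logistic) and grade line (linear) by weighted nonlinear least
    squares, scales both through the logit of their fitted rates, recodes
    culture day as a 0/1 indicator (day 6 = 1), and fits and evaluates the
    logistic regression. Returns ``(model, design, outcomes, scalers)``.
    """
    from .wnlsr import aggregate_by_age, fit_wnlsr

    df = records.copy()
    groups = df["gardner"].map(map_grade)
    kept = groups.notna()
    dropped = int((~kept).sum())
    if dropped:
        logger.info("fit_svbt_pipeline: excluded %d CA/CC transfers", dropped)
    df = df[kept].assign(grade=groups[kept].astype(int))
    df["day6"] = (df["culture_day"].astype(int) == 6).astype(float)

    age_fit = fit_wnlsr(
        aggregate_by_age(df.rename(columns={"age": "x", "live_birth": "outcome"})),
        "logistic", seed=seed,
    )
    grade_fit = fit_wnlsr(
        aggregate_by_age(
            df.rename(columns={"grade": "x", "live_birth": "outcome"}), x_range=None
        ),
        "linear", seed=seed,
    )
    scalers = {"age": age_fit, "grade": grade_fit, "day6": None}
    design = ScaledDesign.from_raw(df[["age", "grade", "day6"]], scalers)
    y = df["live_birth"].to_numpy(dtype=float)
    model = evaluate_model(fit_logit(design, y), design, y)
    return model, design, y, scalers


def fit_opu_pipeline(records: pd.DataFrame, factor: str = "AMH", seed: int = 0):
    """Full per-retrieval pipeline on raw rows
    ``(age, cycle_index, factor_value, live_birth, censored_reason)``.

    Censored cycles are removed (and tallied), then the three marginal curves
    are fitted by weighted nonlinear least squares — age: logistic decline;
    quantifying factor: saturating curve (continuous factors binned to the
    nearest 0.5 for rate aggregation); cycle index: exponential decay — and
    the scaled logistic regression is fitted and evaluated. Returns
    ``(model, design, outcomes, scalers, exclusion_report)``.
    """
    from .wnlsr import aggregate_by_age, fit_wnlsr

    df, report = filter_opu_cohort(records)
    if len(df) == 0:
        raise DataError("no retrieval cycles left after censoring exclusions")
    df = df.copy()
    df["factor_bin"] = (
        df["factor_value"].round()
        if factor != "AMH"
        else (2.0 * df["factor_value"]).round() / 2.0
    )
    age_fit = fit_wnlsr(
        aggregate_by_age(df.rename(columns={"age": "x", "live_birth": "outcome"})),
        "logistic", seed=seed,
    )
    factor_fit = fit_wnlsr(
        aggregate_by_age(
            df.rename(columns={"factor_bin": "x", "live_birth": "outcome"}),
            x_range=None,
        ),
        "saturating", seed=seed,
    )
    cycle_fit = fit_wnlsr(
        aggregate_by_age(
            df.rename(columns={"cycle_index": "x", "live_birth": "outcome"}),
            x_range=None,
        ),
        "exp_decay", seed=seed,
    )
    scalers = {"age": age_fit, "factor_value": factor_fit, "cycle": cycle_fit}
    raw = df[["age", "factor_value", "cycle_index"]].rename(
        columns={"cycle_index": "cycle"}
    )
    design = ScaledDesign.from_raw(raw, scalers)
    y = df["live_birth"].to_numpy(dtype=float)
    model = evaluate_model(fit_logit(design, y), design, y)
    return model, design, y, scalers, report


def filter_opu_cohort(records: pd.DataFrame):
    """Drop censored retrieval cycles (outcome unknowable) and tally them by
    reason; zero-yield cycles are retained.

    Returns ``(included, report)`` where ``report`` maps censoring reason to
    count.
    """
    if records is None or len(records) == 0:
        return (
            records if records is not None else pd.DataFrame(),
            {},
        )
    reasons = records.get("censored_reason")
    if reasons is None:
        return records.copy(), {}
    reasons = reasons.fillna("none").replace("", "none")
    censored = reasons != "none"
    report = reasons[censored].value_counts().to_dict()
    included = records[~censored].copy()
    if report:
        logger.info("filter_opu_cohort: excluded %d censored cycles: %s",
                    int(censored.sum()), report)
    return included, report
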