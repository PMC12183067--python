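"""Weighted nonlinear least-squares fitting of registered curves.

Observations at each predictor value (typically an age in years) carry a
sample size, and the fit minimizes the sample-size-weighted sum of squared
residuals

    SSE_w(theta) = sum_i w_i * (y_i - f(x_i; theta))^2,   w_i = n_i / sum(n)

so that sparsely populated ages (the youngest and oldest groups in a clinic
cohort) do not dominate the curve. Goodness of fit is reported as adjusted
R-squared about the weighted mean, and parameter uncertainty as asymptotic
t-based Wald intervals from the weighted Jacobian at the optimum.

The optimizer is a bounded trust-region least-squares solver with a small
deterministic multi-start (perturbed initializations) to guard against the
mild non-convexity of the logistic fit in (x0, omega).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import CurveSpec, get_curve
from .errors import ConvergenceError, DataError, DomainError, RankDeficiencyError

logger = logging.getLogger("ovafit")

__all__ = [
    "WeightedAgeSeries",
    "FitResult",
    "aggregate_by_age",
    "fit_wnlsr",
    "adjusted_r2",
    "param_ci",
    "euploidy_to_lbr",
]

DEFAULT_AGE_RANGE = (27, 45)


@dataclass(frozen=True)
class WeightedAgeSeries:
    """Per-age observations with sample-size weights.

    ``x``: predictor values (unique); ``y``: observed response (percent rate
    or measured level); ``n``: positive integer sample size at each ``x``.
    """

    x: np.ndarray
    y: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        n = np.asarray(self.n)
        if not (x.shape == y.shape == n.shape) or x.ndim != 1:
            raise DataError("x, y, n must be 1-D arrays of equal length")
        if x.size == 0:
            raise DataError("empty series")
        if np.unique(x).size != x.size:
            raise DataError("x values must be unique after aggregation")
        if np.any(np.asarray(n, dtype=float) < 1):
            raise DataError("sample sizes must be >= 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", np.asarray(n, dtype=float))

    @property
    def weights(self) -> np.ndarray:
        """Weights normalized to sum to one."""
        return self.n / self.n.sum()

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "WeightedAgeSeries":
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["n"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "n": self.n.astype(int)})


@dataclass
class FitResult:
    """Result of a weighted nonlinear least-squares fit."""

    curve: str
    params: object
    theta: np.ndarray
    param_names: Sequence[str]
    se: np.ndarray
    ci95: np.ndarray  # shape (p, 2)
    r2_adj: float
    n_points: int
    n_total: int
    sse_w: float
    residuals: np.ndarray  # weighted residuals sqrt(w)*(y - yhat)
    converged: bool
    level: float = 0.95
    jac: Optional[np.ndarray] = field(default=None, repr=False)

    def predict(self, x):
        spec = get_curve(self.curve)
        out = spec.func(np.asarray(x, dtype=float), self.theta)
        return out if np.ndim(out) else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": list(self.param_names),
                "estimate": self.theta,
                "se": self.se,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
            }
        )


def aggregate_by_age(
    records: pd.DataFrame,
    x_range: Optional[tuple] = DEFAULT_AGE_RANGE,
) -> WeightedAgeSeries:
    """Collapse raw event rows ``(x, outcome)`` to a per-age rate series.

    Each distinct ``x`` becomes one row with ``y = 100 * successes / trials``
    and ``n = trials``. Rows with ``x`` outside ``x_range`` (inclusive) are
    dropped, with the count logged; pass ``x_range=None`` to keep all rows.
    """
    if records is None or len(records) == 0:
        raise DataError("empty input: no event records to aggregate")
    df = records[["x", "outcome"]].copy()
    if x_range is not None:
        lo, hi = x_range
        in_range = (df["x"] >= lo) & (df["x"] <= hi)
        dropped = int((~in_range).sum())
        if dropped:
            logger.warning(
                "aggregate_by_age: dropped %d records outside x range [%s, %s]",
                dropped, lo, hi,
            )
        df = df[in_range]
    if len(df) == 0:
        raise DataError("empty series after range filtering")
    grouped = df.groupby("x")["outcome"].agg(["sum", "count"])
    return WeightedAgeSeries(
        x=grouped.index.to_numpy(dtype=float),
        y=100.0 * grouped["sum"].to_numpy() / grouped["count"].to_numpy(),
        n=grouped["count"].to_numpy(),
    )


def _weighted_residuals(theta, spec: CurveSpec, x, y, sqrt_w):
    return sqrt_w * (y - spec.func(x, theta))


def fit_wnlsr(
    series: WeightedAgeSeries,
    curve: str = "logistic",
    init: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_starts: int = 5,
    level: float = 0.95,
) -> FitResult:
    """Fit a registered curve to a weighted series.

    Runs a bounded least-squares solve from the default (data-driven)
    initialization plus ``n_starts - 1`` deterministic perturbed restarts and
    keeps the solution with the smallest weighted SSE. Requires at least
    ``p + 2`` distinct x values for a p-parameter curve.
    """
    spec = get_curve(curve)
    p = spec.n_params
    if len(series) < p + 2:
        raise DataError(
            f"need >= {p + 2} distinct x values to fit {curve!r}, got {len(series)}"
        )
    x, y, w = series.x, series.y, series.weights
    sqrt_w = np.sqrt(w)
    lo, hi = spec.bounds(x, y)
    theta0 = np.asarray(init, dtype=float) if init is not None else spec.init(x, y)
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        start = theta0.copy()
        if k > 0:
            scale = np.where(np.isfinite(hi - lo), (hi - lo) / 20.0, 0.2 * (1 + np.abs(start)))
            start = np.clip(start + rng.normal(0, 1, p) * scale, lo + 1e-12, hi - 1e-12)
        try:
            res = optimize.least_squares(
                _weighted_residuals,
                start,
                args=(spec, x, y, sqrt_w),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # pragma: no cover - solver-internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConvergenceError(f"all {n_starts} starts failed for curve {curve!r}")

    theta = best.x
    resid = _weighted_residuals(theta, spec, x, y, sqrt_w)
    sse_w = float(resid @ resid)
    m = len(series)

    se, ci = _wald_intervals(best.jac, sse_w, m, p, theta, level)
    r2a = _adjusted_r2_from_sse(series, sse_w, p)

    fit = FitResult(
        curve=curve,
        params=spec.to_params(theta),
        theta=theta,
        param_names=tuple(spec.param_names),
        se=se,
        ci95=ci,
        r2_adj=r2a,
        n_points=m,
        n_total=series.n_total,
        sse_w=sse_w,
        residuals=resid,
        converged=bool(best.success),
        level=level,
        jac=best.jac,
    )
    if not best.success:
        raise ConvergenceError(
            f"least-squares did not converge for curve {curve!r}", best_fit=fit
        )
    return fit


def _wald_intervals(jac, sse_w, m, p, theta, level):
    """Asymptotic t-based Wald intervals from the weighted Jacobian."""
    dof = m - p
    if dof <= 0:
        raise DataError("no residual degrees of freedom for uncertainty estimates")
    jtj = jac.T @ jac
    if np.linalg.matrix_rank(jtj) < p:
        raise RankDeficiencyError("Jacobian is rank-deficient at the optimum")
    s2 = sse_w / dof
    cov = s2 * np.linalg.inv(jtj)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    ci = np.column_stack([theta - tcrit * se, theta + tcrit * se])
    return se, ci


def _adjusted_r2_from_sse(series: WeightedAgeSeries, sse_w: float, p: int) -> float:
    w = series.weights
    ybar = float(w @ series.y)
    sst_w = float(w @ (series.y - ybar) ** 2)
    m = len(series)
    if m <= p + 1:
        raise DataError("adjusted R-squared undefined: too few points")
    r2 = 1.0 - sse_w / sst_w if sst_w > 0 else 1.0
    return 1.0 - (1.0 - r2) * (m - 1) / (m - p - 1)


def adjusted_r2(series: WeightedAgeSeries, fit: FitResult) -> float:
    """Adjusted R-squared of ``fit`` on ``series`` (weighted, about the
    weighted mean): ``1 - (1 - R^2)(m - 1)/(m - p - 1)``."""
    spec = get_curve(fit.curve)
    resid = np.sqrt(series.weights) * (series.y - spec.func(series.x, fit.theta))
    return _adjusted_r2_from_sse(series, float(resid @ resid), spec.n_params)


def param_ci(fit: FitResult, level: float = 0.95) -> np.ndarray:
    """Per-parameter Wald confidence intervals at the requested level.

    Covariance is ``s^2 (J^T W J)^-1`` with ``s^2 = SSE_w / (m - p)`` (the
    Jacobian returned by the fit already carries the sqrt-weights).
    """
    if fit.jac is None:
        raise DataError("fit carries no Jacobian; refit before requesting CIs")
    p = len(fit.theta)
    _, ci = _wald_intervals(fit.jac, fit.sse_w, fit.n_points, p, fit.theta, level)
    return ci


def euploidy_to_lbr(euploidy_rate):
    """Approximate live-birth rate (%) as 0.6 x euploidy rate (%).

    The 0.6 factor is the reported live-birth rate following euploid
    blastocyst transfer.
    """
    arr = np.asarray(euploidy_rate, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise DomainError("euploidy rate must lie in [0, 100] percent")
    out = 0.6 * arr
    return out if out.ndim else float(out)
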