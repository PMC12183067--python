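"""Parametric model curves for age-dependent fertility decline.

Every fitted relationship in the pipeline is built from a small set of
interpretable curve families:

* a declining logistic (Verhulst-type) curve ``y0 / (1 + exp((x - x0)/omega))``
  whose parameters are the maximum value ``y0``, the half-peak age ``x0`` (the
  age at which the curve reaches half its maximum) and the decline width
  ``omega`` controlling steepness;
* a gamma distribution parameterized by its mean and mode, used to describe
  the right-skewed within-age distribution of ovarian-reserve measures;
* a straight line (live-birth rate versus ordinal blastocyst grade);
* an exponential decay in retrieval-cycle index;
* a saturating (exponential-CDF shaped) curve in a reserve measure.

Rates are carried on the percent scale (0-100) throughout the curve layer;
conversion to probabilities happens only at the regression boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np

from .errors import DomainError, InvalidSurfaceError

__all__ = [
    "LogisticDeclineParams",
    "GammaParams",
    "LinearParams",
    "ExpDecayParams",
    "SaturatingParams",
    "logistic_decline",
    "percent_of_peak_age",
    "gamma_from_mean_mode",
    "exp_decay",
    "saturating_curve",
    "CurveSpec",
    "CURVE_REGISTRY",
    "get_curve",
]


def _require_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class LogisticDeclineParams:
    """Parameters of the declining logistic curve.

    ``y0``: maximum value (percent for rates, ng/mL or count for quantities);
    ``x0``: half-peak age in years; ``omega``: decline width in years.
    """

    y0: float
    x0: float
    omega: float

    def __post_init__(self):
        for name in ("y0", "x0", "omega"):
            _require_finite(name, getattr(self, name))
        if self.y0 <= 0:
            raise DomainError(f"y0 must be > 0, got {self.y0}")
        if self.omega <= 0:
            raise DomainError(f"omega must be > 0, got {self.omega}")


@dataclass(frozen=True)
class GammaParams:
    """Gamma distribution with ``shape`` > 1 (so the mode is positive) and
    ``scale`` > 0 in the units of the measured variable."""

    shape: float
    scale: float

    def __post_init__(self):
        if not (self.shape > 1):
            raise InvalidSurfaceError(f"shape must be > 1, got {self.shape}")
        if not (self.scale > 0):
            raise InvalidSurfaceError(f"scale must be > 0, got {self.scale}")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def mode(self) -> float:
        return (self.shape - 1.0) * self.scale


@dataclass(frozen=True)
class LinearParams:
    """Straight line: rate = intercept + slope * x (percent scale)."""

    intercept: float
    slope: float

    def __post_init__(self):
        _require_finite("intercept", self.intercept)
        _require_finite("slope", self.slope)


@dataclass(frozen=True)
class ExpDecayParams:
    """Exponential decay over cycle index: ``y1`` is the first-cycle rate in
    percent, ``lam`` the per-cycle decay constant (>= 0)."""

    y1: float
    lam: float

    def __post_init__(self):
        if not (0 < self.y1 <= 100):
            raise DomainError(f"y1 must be in (0, 100], got {self.y1}")
        if self.lam < 0:
            raise DomainError(f"lam must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class SaturatingParams:
    """Saturating curve ``ymax * (1 - exp(-x/tau))`` rising from 0 to ``ymax``
    (percent) with characteristic count ``tau`` > 0."""

    ymax: float
    tau: float

    def __post_init__(self):
        if not (0 < self.ymax <= 100):
            raise DomainError(f"ymax must be in (0, 100], got {self.ymax}")
        if not (self.tau > 0):
            raise DomainError(f"tau must be > 0, got {self.tau}")


def logistic_decline(x, p: LogisticDeclineParams):
    """Declining logistic curve ``y0 / (1 + exp((x - x0)/omega))``.

    Strictly decreasing in ``x``; tends to ``y0`` as ``x -> -inf`` and to 0 as
    ``x -> +inf``; equals ``y0/2`` exactly at ``x = x0``. Total function: no
    overflow for any finite ``x``.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        out = p.y0 / (1.0 + np.exp((x - p.x0) / p.omega))
    return out if out.ndim else float(out)


def percent_of_peak_age(p: LogisticDeclineParams, frac: float) -> float:
    """Age at which the logistic decline reaches ``frac`` of its maximum.

    Closed form ``x0 + omega * ln(1/frac - 1)``; by construction
    ``logistic_decline`` at the returned age equals ``frac * y0`` to machine
    precision. ``frac`` must lie strictly inside (0, 1).
    """
    if not (0.0 < frac < 1.0):
        raise DomainError(f"frac must be in (0, 1), got {frac}")
    return p.x0 + p.omega * np.log(1.0 / frac - 1.0)


def gamma_from_mean_mode(mean: float, mode: float) -> GammaParams:
    """Gamma parameters with the given mean and mode.

    With shape ``k`` and scale ``theta``, mean = k*theta and mode =
    (k-1)*theta, so ``theta = mean - mode`` and ``k = mean / (mean - mode)``.
    Requires ``mean > mode > 0`` (equivalently shape > 1).
    """
    if not (mode > 0):
        raise InvalidSurfaceError(f"mode must be > 0, got {mode}")
    if not (mean > mode):
        raise InvalidSurfaceError(
            f"mean must exceed mode, got mean={mean}, mode={mode}"
        )
    scale = mean - mode
    return GammaParams(shape=mean / scale, scale=scale)


def exp_decay(c, p: ExpDecayParams):
    """Per-cycle rate ``y1 * exp(-lam * (c - 1))`` for cycle index ``c >= 1``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 1):
        raise DomainError("cycle index must be >= 1")
    out = p.y1 * np.exp(-p.lam * (c - 1.0))
    return out if out.ndim else float(out)


def saturating_curve(x, p: SaturatingParams):
    """Saturating rate ``ymax * (1 - exp(-x/tau))`` for ``x >= 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("factor value must be >= 0")
    out = p.ymax * (1.0 - np.exp(-x / p.tau))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Curve registry for the weighted nonlinear least-squares engine.
# Each entry maps a flat parameter vector theta to curve values and supplies
# data-driven initialization and box bounds. The registry is open: a variant
# (e.g. a gamma-CDF shaped saturating curve) can be registered without
# touching the fitting engine.
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveSpec:
    name: str
    param_names: Sequence[str]
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    init: Callable[[np.ndarray, np.ndarray], np.ndarray]
    bounds: Callable[[np.ndarray, np.ndarray], tuple]
    to_params: Callable[[np.ndarray], object]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _logistic_func(x, theta):
    y0, x0, omega = theta
    with np.errstate(over="ignore"):
        return y0 / (1.0 + np.exp((x - x0) / omega))


def _logistic_init(x, y):
    y0 = float(np.max(y))
    if y0 <= 0:
        y0 = 1.0
    # half-peak guess: the x whose observation is nearest y0/2
    x0 = float(x[np.argmin(np.abs(y - y0 / 2.0))])
    return np.array([y0, x0, 3.0])


def _logistic_bounds(x, y):
    ymax = max(float(np.max(y)), 1e-6)
    return (np.array([1e-9, 20.0, 0.1]), np.array([2.0 * ymax, 60.0, 20.0]))


def _linear_func(x, theta):
    a, b = theta
    return a + b * x


def _exp_decay_func(x, theta):
    y1, lam = theta
    return y1 * np.exp(-lam * (x - 1.0))


def _saturating_func(x, theta):
    ymax, tau = theta
    return ymax * (1.0 - np.exp(-x / tau))


def _gamma_cdf_func(x, theta):
    # configurable alternative saturating shape: ymax * GammaCDF(x; k, theta)
    from scipy.stats import gamma as _gamma

    ymax, shape, scale = theta
    return ymax * _gamma.cdf(x, shape, scale=scale)


CURVE_REGISTRY: Dict[str, CurveSpec] = {}


def _register(spec: CurveSpec) -> CurveSpec:
    CURVE_REGISTRY[spec.name] = spec
    return spec


_register(
    CurveSpec(
        name="logistic",
        param_names=("y0", "x0", "omega"),
        func=_logistic_func,
        init=_logistic_init,
        bounds=_logistic_bounds,
        to_params=lambda t: LogisticDeclineParams(*map(float, t)),
    )
)

_register(
    CurveSpec(
        name="linear",
        param_names=("intercept", "slope"),
        func=_linear_func,
        init=lambda x, y: np.array(
            [float(np.mean(y)), 0.0 if np.ptp(x) == 0 else float(np.polyfit(x, y, 1)[0])]
        ),
        bounds=lambda x, y: (np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf])),
        to_params=lambda t: LinearParams(*map(float, t)),
    )
)

_register(
    CurveSpec(
        name="exp_decay",
        param_names=("y1", "lam"),
        func=_exp_decay_func,
        init=lambda x, y: np.array([max(float(y[np.argmin(x)]), 1e-3), 0.2]),
        bounds=lambda x, y: (np.array([1e-9, 0.0]), np.array([100.0, 5.0])),
        to_params=lambda t: ExpDecayParams(*map(float, t)),
    )
)

_register(
    CurveSpec(
        name="saturating",
        param_names=("ymax", "tau"),
        func=_saturating_func,
        init=lambda x, y: np.array(
            [min(max(float(np.max(y)), 1e-3), 100.0), max(float(np.median(x)), 0.5)]
        ),
        bounds=lambda x, y: (np.array([1e-9, 1e-3]), np.array([100.0, 1e3])),
        to_params=lambda t: SaturatingParams(*map(float, t)),
    )
)

_register(
    CurveSpec(
        name="saturating_gamma_cdf",
        param_names=("ymax", "shape", "scale"),
        func=_gamma_cdf_func,
        init=lambda x, y: np.array(
            [min(max(float(np.max(y)), 1e-3), 100.0), 1.5, max(float(np.median(x)), 0.5)]
        ),
        bounds=lambda x, y: (
            np.array([1e-9, 0.05, 1e-3]),
            np.array([100.0, 50.0, 1e3]),
        ),
        to_params=lambda t: tuple(map(float, t)),
    )
)


def get_curve(curve: str) -> CurveSpec:
    try:
        return CURVE_REGISTRY[curve]
    except KeyError:
        raise KeyError(
            f"unknown curve {curve!r}; registered: {sorted(CURVE_REGISTRY)}"
        ) from None
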