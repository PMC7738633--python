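"""Gompertz growth modeling, per-patient rate estimation, and initiation times.

The tumor volume X(t) follows a Gompertz law

    X(t) = K * exp( ln(X0/K) * exp(-alpha * t) )

with carrying capacity K (maximum volume supportable by the host, fixed at
180 cm^3 = 180,000 mm^3, the volume of a 7-cm sphere), first-observation
volume X0 taken from the data, and growth-rate constant alpha (month^-1).
Only alpha is estimated per patient; 1/alpha is the characteristic growth
time. Backward projection of the fitted curve yields the initiation time:
the modeled time to grow from a single cell (1e-6 mm^3) to a detectable
10 mm^3 mass (10 million cells). Cohort initiation times are characterized
by a lognormal distribution fit by maximum likelihood.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort, DeltaClass, LesionObservation

logger = logging.getLogger(__name__)

DEFAULT_K_MM3 = 180_000.0
SINGLE_CELL_MM3 = 1e-6
DETECTABLE_MASS_MM3 = 10.0
DEFAULT_ALPHA0 = 0.05
DEFAULT_ALPHA_BOUNDS = (1e-4, 2.0)


class CarryingCapacityError(ValueError):
    """Observed volume at or above the carrying capacity K."""


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters: alpha (month^-1), X0 and K (mm^3), 0 < X0 < K."""

    alpha: float
    x0: float
    k: float = DEFAULT_K_MM3

    def __post_init__(self) -> None:
        if not (0 < self.x0 < self.k):
            raise ValueError(f"require 0 < X0 < K, got X0={self.x0}, K={self.k}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def gompertz_volume(t, params: GompertzParams):
    """Gompertz volume X(t) in mm^3 at time t (months); vectorized in t."""
    t = np.asarray(t, dtype=float)
    out = params.k * np.exp(np.log(params.x0 / params.k) * np.exp(-params.alpha * t))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GompertzFit:
    """Per-patient fit: estimated params, Pearson R of observed vs fitted
    volumes, volume-scale residuals (fitted - observed), and convergence."""

    params: GompertzParams
    pearson_r: float
    residuals: np.ndarray
    n_obs: int
    converged: bool

    @property
    def alpha(self) -> float:
        return self.params.alpha


def _pearson(observed: np.ndarray, fitted: np.ndarray) -> float:
    # constant vectors make r undefined; exact fits there are still perfect
    if np.std(observed) == 0 or np.std(fitted) == 0:
        return 1.0 if np.allclose(observed, fitted) else float("nan")
    return float(stats.pearsonr(observed, fitted).statistic)


def fit_gompertz(
    observations: list[LesionObservation],
    k: float = DEFAULT_K_MM3,
    alpha0: float = DEFAULT_ALPHA0,
    alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS,
    log_scale: bool = False,
) -> GompertzFit:
    """Estimate alpha by Levenberg-Marquardt nonlinear least squares.

    X0 is anchored at the first observed volume and K is fixed; alpha is the
    only free parameter, minimizing squared volume residuals (or squared
    log-volume residuals with log_scale=True). Estimates landing outside
    alpha_bounds are clamped to the bound and flagged non-converged — this
    happens when the data are non-increasing, which the Gompertz law cannot
    represent.
    """
    if len(observations) < 2:
        raise ValueError(f"need >=2 observations, got {len(observations)}")
    times = np.array([o.time for o in observations])
    volumes = np.array([o.volume_mm3 for o in observations])
    if np.any(volumes >= k):
        raise CarryingCapacityError(
            f"observed volume {volumes.max():.1f} mm^3 >= carrying capacity {k} mm^3"
        )
    x0 = float(volumes[0])
    lo, hi = alpha_bounds

    def residual(theta):
        pred = k * np.exp(np.log(x0 / k) * np.exp(-theta[0] * times))
        if log_scale:
            return np.log(np.maximum(pred, 1e-300)) - np.log(volumes)
        return pred - volumes

    sol = optimize.least_squares(residual, x0=[alpha0], method="lm")
    alpha = float(sol.x[0])
    converged = bool(sol.success)
    if not (lo <= alpha <= hi):
        alpha = min(max(alpha, lo), hi)
        converged = False
        logger.warning("alpha estimate clamped to bound %.4g; fit flagged", alpha)
    params = GompertzParams(alpha=alpha, x0=x0, k=k)
    fitted = gompertz_volume(times, params)
    return GompertzFit(
        params=params,
        pearson_r=_pearson(volumes, fitted),
        residuals=fitted - volumes,
        n_obs=len(observations),
        converged=converged,
    )


def cohort_fit_quality(
    fits: dict[str, GompertzFit], cohort: Cohort
) -> dict[DeltaClass, float]:
    """Pooled Pearson R between observed and fitted volumes per delta class.

    Observations of all patients in a class are pooled into one
    (observed, fitted) cloud before correlating.
    """
    pooled: dict[DeltaClass, list[np.ndarray]] = {}
    for patient in cohort:
        fit = fits.get(patient.patient_id)
        if fit is None:
            continue
        observed = patient.volumes_mm3
        fitted = observed + fit.residuals
        pooled.setdefault(patient.delta_class, []).append(
            np.column_stack([observed, fitted])
        )
    out = {}
    for dclass, chunks in pooled.items():
        cloud = np.concatenate(chunks)
        if len(cloud) < 2:
            raise ValueError(f"class {dclass.value}: need >=2 pooled points for R")
        out[dclass] = _pearson(cloud[:, 0], cloud[:, 1])
    return out


def characteristic_time(alpha: float) -> float:
    """Characteristic growth time 1/alpha, months."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return 1.0 / alpha


def initiation_time(
    alpha: float,
    x0: float,
    k: float = DEFAULT_K_MM3,
    x_start: float = SINGLE_CELL_MM3,
    x_end: float = DETECTABLE_MASS_MM3,
) -> float:
    """Backward-projected time (months) to grow from x_start to x_end.

    Computes T = |t(x_start)| - |t(x_end)| where t(X) is the signed time at
    which the fitted Gompertz curve (anchored at X0 at t=0) crosses volume X:

        t(X) = -(1/alpha) * ln( ln(X/K) / ln(X0/K) )

    When X0 > x_end (always true here: observed lesions exceed the 10 mm^3
    detectable mass) both crossings lie in the past and T reduces to the
    X0-free closed form (1/alpha) * ln( ln(x_start/K) / ln(x_end/K) ),
    which serves as an internal cross-check.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not (0 < x_start < x_end < k):
        raise ValueError(
            f"require 0 < x_start < x_end < K, got {x_start}, {x_end}, {k}"
        )
    if not (0 < x0 < k):
        raise ValueError(f"require 0 < X0 < K, got {x0}")

    def crossing(x):
        return -(1.0 / alpha) * math.log(math.log(x / k) / math.log(x0 / k))

    t = abs(crossing(x_start)) - abs(crossing(x_end))
    if x0 > x_end:
        closed_form = (1.0 / alpha) * math.log(math.log(x_start / k) / math.log(x_end / k))
        if not math.isclose(t, closed_form, rel_tol=1e-9, abs_tol=1e-9):
            warnings.warn(
                "initiation-time cross-check mismatch: "
                f"{t} vs closed form {closed_form}",
                RuntimeWarning,
            )
    return t


@dataclass(frozen=True)
class InitiationDistribution:
    """Lognormal characterization of cohort initiation times.

    mu and sigma are the mean and standard deviation of log initiation
    time (maximum-likelihood, population 1/n variance by default).
    """

    mu: float
    sigma: float
    n: int
    degenerate: bool = False

    def _dist(self):
        if self.sigma <= 0:
            raise ValueError("degenerate distribution (sigma=0) has no density")
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))

    @property
    def mode(self) -> float:
        """Most probable initiation time, exp(mu - sigma^2)."""
        return math.exp(self.mu - self.sigma**2)

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def pdf(self, t):
        return self._dist().pdf(t)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t > 0, self._dist().cdf(np.maximum(t, 1e-300)), 0.0)
        return float(out) if out.ndim == 0 else out

    def quantile(self, q):
        return self._dist().ppf(q)


def fit_lognormal(samples, ddof: int = 0) -> InitiationDistribution:
    """Maximum-likelihood lognormal fit: mu, sigma from the log-samples.

    ddof=0 gives the ML (1/n) sigma; ddof=1 the unbiased-variance variant.
    Identical samples yield sigma=0 with the degenerate flag set.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need >=2 samples, got {len(x)}")
    if np.any(x <= 0):
        raise ValueError("all samples must be positive")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=ddof))
    return InitiationDistribution(mu=mu, sigma=sigma, n=len(x), degenerate=sigma == 0.0)


def cumulative_initiation_probability(dist: InitiationDistribution, t) -> float:
    """P(initiation time <= t months) under the fitted lognormal."""
    return dist.cdf(t)
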