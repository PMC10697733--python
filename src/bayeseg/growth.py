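"""Growth-curve applications: OD linear range, log-phase detection, Monod fit.

The OD calibration analysis partitions OD versus dilution factor and reports
the linear segment that starts at the smallest OD, its maximal OD, and the
conversion factor back to OD units.  Log-phase detection partitions log(OD)
versus time and selects the segment with the greatest gradient, i.e. the
greatest specific growth rate.  The Monod fit maximizes a noise-marginalized
likelihood of rate-versus-concentration data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import CoefficientPrior, DataValidationError, TimeSeries
from .engine import PartitionResult, partition
from .segstats import SegmentStats, build_coefficient_prior, select_segment

__all__ = [
    "ODLinearRange",
    "GrowthPhaseResult",
    "MonodFit",
    "od_linear_range",
    "find_log_phase",
    "monod_rate",
    "monod_loglik",
    "fit_monod",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ODLinearRange:
    """Linear-range report for an OD-versus-dilution calibration curve."""

    result: PartitionResult
    segments: list[SegmentStats]
    linear_segment: SegmentStats
    highest_r2_segment: SegmentStats
    od_max: float
    dilution_at_od_max: float
    scale_factor: float
    note: str | None = None


@dataclass(frozen=True)
class GrowthPhaseResult:
    """Log-phase report for a growth curve (log OD versus time)."""

    result: PartitionResult
    segments: list[SegmentStats]
    log_phase: SegmentStats
    specific_growth_rate: float
    time_range: tuple[float, float]


@dataclass(frozen=True)
class MonodFit:
    """Maximum-likelihood Monod parameters with inverse-Hessian errors."""

    lambda_max: float
    K_M: float
    err_lambda_max: float
    err_K_M: float
    loglik: float
    n_points: int


def od_linear_range(
    ts: TimeSeries,
    prior: CoefficientPrior | None = None,
    sigma="unknown",
    M_max: int | None = None,
) -> ODLinearRange:
    """Identify the dilution range over which OD is linear in cell number.

    ``ts.x`` is the dilution factor (relative cell number), ascending;
    ``ts.y`` the measured OD.  The linear range is the segment beginning at
    the smallest OD; the scale factor is its maximal OD divided by the
    dilution factor at the same boundary point.
    """
    if prior is None:
        prior = build_coefficient_prior(
            ts, y_range=(0.0, max(2.0, float(ts.y.max())))
        )
    res = partition(ts, prior=prior, sigma=sigma, M_max=M_max)
    stats = res.segment_stats
    linear = stats[0]  # segment beginning at the smallest OD (smallest x)
    best_r2 = select_segment(stats, "r2")
    end = linear.end
    od_max = float(ts.y[:, end].mean())
    dilution = float(ts.x[end])
    note = None
    if res.M_best == 1:
        note = "whole range is linear; scale factor taken from the last point"
        logger.info(note)
    if best_r2 is not linear:
        logger.info(
            "highest-R^2 segment (%d..%d) differs from the smallest-OD "
            "segment (%d..%d)", best_r2.start, best_r2.end, linear.start, linear.end,
        )
    return ODLinearRange(
        result=res,
        segments=stats,
        linear_segment=linear,
        highest_r2_segment=best_r2,
        od_max=od_max,
        dilution_at_od_max=dilution,
        scale_factor=od_max / dilution,
        note=note,
    )


def find_log_phase(
    ts: TimeSeries,
    prior: CoefficientPrior | None = None,
    sigma="unknown",
    M_max: int | None = None,
) -> GrowthPhaseResult:
    """Locate exponential growth on a growth curve of OD versus time.

    The natural log of OD is partitioned with the line basis; the segment
    whose best-fit line has the highest gradient is the log phase, and that
    gradient is the specific growth rate (per x-axis time unit).
    """
    bad = np.nonzero(~np.all(ts.y > 0, axis=0))[0]
    if bad.size:
        raise DataValidationError(
            f"OD must be positive to take logs; offending point indices "
            f"(0-based): {list(bad[:10])}"
        )
    log_ts = TimeSeries(x=ts.x, y=np.log(ts.y))
    if prior is None:
        prior = build_coefficient_prior(
            log_ts, y_range=(float(log_ts.y.min()), float(log_ts.y.max()))
        )
    res = partition(log_ts, prior=prior, sigma=sigma, M_max=M_max)
    stats = res.segment_stats
    phase = select_segment(stats, "gradient")
    return GrowthPhaseResult(
        result=res,
        segments=stats,
        log_phase=phase,
        specific_growth_rate=float(phase.gradient),
        time_range=(float(ts.x[phase.start]), float(ts.x[phase.end])),
    )


def monod_rate(s, lambda_max: float, K_M: float):
    """Monod's equation: growth rate at nutrient concentration s."""
    s = np.asarray(s, dtype=float)
    return lambda_max * s / (K_M + s)


def monod_loglik(lambda_max: float, K_M: float, lam, s) -> float:
    """Log likelihood of (rate, concentration) pairs, noise marginalized.

    With a 1/sigma prior on the Gaussian noise scale the marginal likelihood
    is proportional to (sum of squared residuals)^(-N/2); the returned value
    is its log up to an additive constant.
    """
    lam = np.asarray(lam, dtype=float)
    s = np.asarray(s, dtype=float)
    if lambda_max <= 0 or K_M <= 0:
        raise ValueError("lambda_max and K_M must be positive")
    resid = lam - monod_rate(s, lambda_max, K_M)
    rss = float(resid @ resid)
    if rss <= 0.0:
        raise DataValidationError("perfect Monod fit: zero residual sum")
    return -0.5 * lam.size * float(np.log(rss))


def _neg_loglik_logparams(p: np.ndarray, lam: np.ndarray, s: np.ndarray) -> float:
    lmax, km = np.exp(p)
    resid = lam - lmax * s / (km + s)
    rss = float(resid @ resid)
    if rss <= 0.0:
        return -np.inf
    return 0.5 * lam.size * float(np.log(rss))


def _hessian_fd(fun, x0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1e-8)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_monod(lam, s) -> MonodFit:
    """Fit Monod's equation by quasi-Newton maximization from multiple starts.

    Parameters are optimized on log scale to enforce positivity.  Standard
    errors are square roots of the diagonal of the inverse Hessian of the
    negative log likelihood at the optimum (in the original parameters).
    """
    lam = np.asarray(lam, dtype=float)
    s = np.asarray(s, dtype=float)
    if lam.size != s.size or lam.size < 3:
        raise DataValidationError("need at least 3 (rate, concentration) pairs")
    if np.unique(s).size < 2:
        raise DataValidationError("need at least 2 distinct concentrations")
    if np.any(s < 0):
        raise DataValidationError("concentrations must be non-negative")

    lmax0 = float(max(lam.max(), 1e-6))
    starts = [
        np.log([lmax0, max(float(np.min(s[s > 0])), 1e-9)]),
        np.log([lmax0, max(float(np.median(s)), 1e-9)]),
    ]
    best = None
    for p0 in starts:
        res = optimize.minimize(
            _neg_loglik_logparams, p0, args=(lam, s), method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("Monod fit did not converge from any start")
    lmax, km = np.exp(best.x)

    def nll(theta: np.ndarray) -> float:
        lm, k = theta
        if lm <= 0 or k <= 0:
            return np.inf
        resid = lam - lm * s / (k + s)
        return 0.5 * lam.size * float(np.log(resid @ resid))

    H = _hessian_fd(nll, np.array([lmax, km]))
    try:
        cov = np.linalg.inv(H)
        errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        errs = np.array([np.nan, np.nan])
        logger.warning("Hessian not invertible; standard errors unavailable")
    return MonodFit(
        lambda_max=float(lmax),
        K_M=float(km),
        err_lambda_max=float(errs[0]),
        err_K_M=float(errs[1]),
        loglik=-float(best.fun),
        n_points=int(lam.size),
    )
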