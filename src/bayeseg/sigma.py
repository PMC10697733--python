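"""Unknown measurement error: EM for the noise scale and marginalization.

When the per-point errors are unknown, a single shared scale sigma with a
bounded uniform prior is marginalized numerically.  For each sigma requested
by the quadrature, a full variable-elimination pass sums over boundary
vectors; the integrand is divided by its value at the most likely sigma
(found by expectation-maximization) so it stays of order one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .data import CoefficientPrior, DataValidationError, PerfectFitError
from .engine import (
    _backward,
    _forward,
    boundary_moments_for_matrix,
    count_valid_partitions,
    log_prior_boundaries,
)
from .marginal import SegmentTable

__all__ = [
    "SigmaEstimate",
    "UnknownSigmaEvidence",
    "default_sigma_bounds",
    "ensure_sigma_bounds",
    "em_sigma",
    "em_sigma_safe",
    "log_evidence_unknown_sigma",
    "posterior_boundaries_unknown_sigma",
]

logger = logging.getLogger(__name__)

EM_TOL = 1e-4
EM_MAX_ITER = 100
QUAD_RTOL = 1e-6
QUAD_LIMIT = 100  # max adaptive subintervals (~200 integrand evaluations)


@dataclass(frozen=True)
class SigmaEstimate:
    """EM estimate of the most likely shared noise scale for a given M."""

    sigma_hat: float
    iterations: int
    converged: bool
    log_scale: float  # log of the summed likelihood at sigma_hat


@dataclass(frozen=True)
class UnknownSigmaEvidence:
    log_evidence: float
    sigma_hat: float
    quad_error: float
    converged: bool


def _single_segment_residual_sd(table: SegmentTable) -> float:
    """Residual standard deviation of the best single-segment fit."""
    N = table.N
    if not table.valid[0, N - 1]:
        raise DataValidationError("full-series fit is degenerate")
    dof = table.N_r * N - table.K
    U = float(table.U[0, N - 1])
    return float(np.sqrt(max(2.0 * U, 0.0) / dof))


def default_sigma_bounds(table: SegmentTable) -> tuple[float, float]:
    """Bracket for sigma from the single-segment residual spread.

    Returns (max(1e-6, 1e-3*s), 10*s) with s the residual standard deviation
    of the best one-segment fit; for (near-)perfect fits s is floored at a
    tiny fraction of the data scale so the prior stays proper.
    """
    s = _single_segment_residual_sd(table)
    yscale = float(np.max(np.abs(table.ts.y)))
    floor = max(1e-9 * max(yscale, 1.0), 1e-12)
    if s < floor:
        s = floor
        logger.warning("data fit a single segment exactly; sigma bounds floored")
    lo = max(1e-6, 1e-3 * s)
    hi = max(10.0 * s, 100.0 * lo)
    return lo, hi


def ensure_sigma_bounds(
    table: SegmentTable, prior: CoefficientPrior
) -> CoefficientPrior:
    """Attach default sigma bounds to the prior when absent."""
    if prior.sigma_lo is not None:
        return prior
    lo, hi = default_sigma_bounds(table)
    return prior.with_sigma_bounds(lo, hi)


def _forward_backward(table: SegmentTable, M: int, sigma: float):
    G = table.log_marginal_at_sigma(sigma)
    F = _forward(G, table.N, M)
    B = _backward(G, table.N, M)
    return G, F, B, float(B[1][0])


def expected_total_U(table: SegmentTable, M: int, sigma: float) -> tuple[float, float]:
    """E[sum_i U_i] under the boundary posterior at the given sigma.

    Returns (expectation, log of the summed likelihood at sigma).
    """
    N = table.N
    G, F, B, logZ = _forward_backward(table, M, sigma)
    if not np.isfinite(logZ):
        raise DataValidationError("vanishing likelihood at this sigma")
    U = np.where(table.valid, table.U, 0.0)
    total = 0.0
    for k in range(1, M + 1):
        prev = F[k - 1][:N]  # start cut of segment k
        nxt = B[k + 1][1:]  # nxt[e] = B[k+1][e+1], e = 0..N-1
        lw = prev[:, None] + G + nxt[None, :] - logZ
        with np.errstate(invalid="ignore"):
            w = np.exp(lw)
        w[~np.isfinite(lw)] = 0.0
        total += float(np.sum(w * U))
    return total, logZ


def em_sigma(
    table: SegmentTable,
    M: int,
    prior: CoefficientPrior,
    init_sigma: float | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> SigmaEstimate:
    """EM iteration for the most likely shared noise scale at fixed M.

    The update is sigma^2 = 2 * E[sum U_i] / (N_r*N - M*K), with the
    expectation over the boundary posterior at the current sigma.
    """
    N, Nr, K = table.N, table.N_r, table.K
    denom = Nr * N - M * K
    if denom <= 0:
        raise DataValidationError("too few observations for this many segments")
    prior = ensure_sigma_bounds(table, prior)
    lo, hi = prior.sigma_lo, prior.sigma_hi
    sigma = float(init_sigma) if init_sigma else max(
        min(_single_segment_residual_sd(table), hi), lo
    )
    if sigma <= 0:
        sigma = 0.5 * (lo + hi)
    converged = False
    it = 0
    logZ = -np.inf
    for it in range(1, max_iter + 1):
        EU, logZ = expected_total_U(table, M, sigma)
        if EU <= 0 or 2.0 * EU / denom < 1e-24 * max(sigma, 1.0) ** 2:
            raise PerfectFitError(
                "residuals vanish for every plausible partition; the noise "
                "scale is unidentifiable (perfect fit)"
            )
        new = float(np.sqrt(2.0 * EU / denom))
        new = min(max(new, lo), hi)
        if abs(new - sigma) / sigma < tol:
            sigma = new
            converged = True
            break
        sigma = new
    _, logZ = expected_total_U(table, M, sigma)
    return SigmaEstimate(sigma_hat=sigma, iterations=it, converged=converged,
                         log_scale=logZ)


def em_sigma_safe(table, M, prior, **kw) -> SigmaEstimate | None:
    """As :func:`em_sigma` but mapping a perfect fit to None."""
    try:
        return em_sigma(table, M, prior, **kw)
    except PerfectFitError:
        return None


def _scale_point(table: SegmentTable, M: int, prior: CoefficientPrior) -> tuple[float, float]:
    """Sigma at which to scale the integrand, and log integrand there.

    Perfect fits pin the integrand's maximum at the lower sigma bound.
    """
    try:
        est = em_sigma(table, M, prior)
        return est.sigma_hat, est.log_scale
    except PerfectFitError:
        lo = prior.sigma_lo
        G = table.log_marginal_at_sigma(lo)
        B = _backward(G, table.N, M)
        return lo, float(B[1][0])


def _log_sum_likelihood(table: SegmentTable, M: int, sigma: float) -> float:
    G = table.log_marginal_at_sigma(sigma)
    B = _backward(G, table.N, M)
    return float(B[1][0])


def log_evidence_unknown_sigma(
    table: SegmentTable, M: int, prior: CoefficientPrior
) -> UnknownSigmaEvidence:
    """Log P(D | M) with sigma marginalized over its bounded uniform prior.

    The sigma integral runs over [sigma_lo, sigma_hi] by adaptive quadrature
    of the elimination sum scaled by its value at the most likely sigma; the
    constant prior density 1/(sigma_hi - sigma_lo) is included so values are
    comparable across M at fixed bounds.
    """
    if count_valid_partitions(table.N, M, table.lmin) == 0:
        return UnknownSigmaEvidence(-np.inf, np.nan, 0.0, True)
    prior = ensure_sigma_bounds(table, prior)
    lo, hi = prior.sigma_lo, prior.sigma_hi
    s_hat, log_scale = _scale_point(table, M, prior)

    def integrand(s: float) -> float:
        return float(np.exp(_log_sum_likelihood(table, M, s) - log_scale))

    import warnings as _warnings

    with np.errstate(over="ignore"), _warnings.catch_warnings():
        # steep integrands (e.g. near-perfect fits) make quad complain; the
        # achieved error estimate is checked explicitly below
        _warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            integrand, lo, hi, epsrel=QUAD_RTOL, limit=QUAD_LIMIT,
            points=[s_hat],
        )
    converged = err <= max(QUAD_RTOL * abs(val), 1e-300)
    if not converged:
        logger.warning(
            "sigma quadrature for M=%d did not reach rtol %.0e "
            "(estimate %.6g, error bound %.2g)", M, QUAD_RTOL, val, err,
        )
    if val <= 0:
        return UnknownSigmaEvidence(-np.inf, s_hat, err, converged)
    log_ev = (
        log_prior_boundaries(table.N, M, table.lmin)
        - np.log(hi - lo)
        + log_scale
        + float(np.log(val))
    )
    return UnknownSigmaEvidence(log_ev, s_hat, err, converged)


def _sigma_grid(lo: float, hi: float, s_hat: float, width: float) -> np.ndarray:
    coarse = np.linspace(lo, hi, 81)
    fine = np.clip(s_hat + width * np.linspace(-12.0, 12.0, 241), lo, hi)
    grid = np.unique(np.concatenate([coarse, fine]))
    return grid


def posterior_boundaries_unknown_sigma(
    table: SegmentTable, M: int, prior: CoefficientPrior
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior boundary means/variances with sigma integrated out.

    Uses a fixed sigma grid concentrated around the most likely sigma (where
    the scaled integrand carries its mass) and trapezoidal weights.
    """
    if M < 2:
        return np.empty(0), np.empty(0)
    prior = ensure_sigma_bounds(table, prior)
    lo, hi = prior.sigma_lo, prior.sigma_hi
    s_hat, log_scale = _scale_point(table, M, prior)
    dof = table.N_r * table.N - M * table.K
    width = s_hat / np.sqrt(max(2.0 * dof, 2.0))
    grid = _sigma_grid(lo, hi, s_hat, width)

    den = np.zeros(grid.size)
    num1 = np.zeros((grid.size, M - 1))
    num2 = np.zeros((grid.size, M - 1))
    for g, s in enumerate(grid):
        G = table.log_marginal_at_sigma(s)
        logS = _log_sum_likelihood(table, M, s)
        w = float(np.exp(logS - log_scale))
        if w == 0.0:
            continue
        means, variances = boundary_moments_for_matrix(G, table.N, M, table.lmin)
        den[g] = w
        num1[g] = w * means
        num2[g] = w * (variances + means**2)
    Z = np.trapezoid(den, grid)
    if Z <= 0:
        raise DataValidationError("sigma marginal has no mass on the grid")
    m1 = np.trapezoid(num1, grid, axis=0) / Z
    m2 = np.trapezoid(num2, grid, axis=0) / Z
    return m1, np.maximum(m2 - m1**2, 0.0)
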