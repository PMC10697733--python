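"""Evidence per segment count, model selection, and posterior boundaries.

The evidence for M segments is a sum of products of per-segment marginals
over all admissible boundary vectors.  Summing naively costs O(N^M); the
engine instead eliminates one boundary at a time, rightmost first, for
O(M N^2) log-sum-exp operations.  The same forward/backward quantities give
the posterior mean and variance of each boundary.

Boundary convention: internally segments are 0-based inclusive index pairs;
a "cut" c in 1..N-1 means the current segment ends at point c-1 and the next
starts at point c.  Cut values coincide with the 1-based index of the last
point of a segment, which is the convention used in reports.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    BasisSet,
    CoefficientPrior,
    DataValidationError,
    TimeSeries,
    make_linear_basis,
)
from .marginal import SegmentTable, precompute_segment_table
from .segstats import SegmentStats, segment_stats_from_table

__all__ = [
    "PartitionResult",
    "count_valid_partitions",
    "log_prior_boundaries",
    "log_evidence_known_sigma",
    "log_evidence_for_matrix",
    "select_M",
    "posterior_boundary_moments",
    "boundary_moments_for_matrix",
    "partition",
]

logger = logging.getLogger(__name__)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    """Log-sum-exp along ``axis`` that maps all--(-inf) slices to -inf."""
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore"):
        s = np.sum(np.exp(a - m_safe), axis=axis)
    m = np.squeeze(m, axis=axis)
    out = np.where(np.isfinite(m), np.log(np.where(s > 0, s, 1.0)) + m, -np.inf)
    return out


def count_valid_partitions(N: int, M: int, lmin: int) -> int:
    """Number of boundary vectors placing M segments of >= lmin points.

    Equals the closed form C(N - M*lmin + M - 1, M - 1); returns 0 when the
    configuration is infeasible.
    """
    if M < 1 or lmin < 1:
        raise ValueError("require M >= 1 and lmin >= 1")
    if N < M * lmin:
        logger.warning("infeasible: N=%d < M*lmin=%d", N, M * lmin)
        return 0
    return math.comb(N - M * lmin + M - 1, M - 1)


def log_prior_boundaries(N: int, M: int, lmin: int) -> float:
    """Log of the uniform prior over admissible boundary vectors."""
    count = count_valid_partitions(N, M, lmin)
    if count == 0:
        raise DataValidationError(f"no admissible partition for N={N}, M={M}, lmin={lmin}")
    return -math.log(count)


# ---------------------------------------------------------------------------
# variable elimination on a segment log-marginal matrix


def _backward(G: np.ndarray, N: int, M: int) -> list[np.ndarray]:
    """B[k][c] = log sum over placements of segments k..M covering c..N-1.

    Arrays are indexed by the cut position c in 0..N; B[M+1] is the terminal
    condition (zero at c=N).  Eliminates the rightmost boundary first.
    """
    B: list[np.ndarray] = [np.full(N + 1, -np.inf) for _ in range(M + 2)]
    B[M + 1][N] = 0.0
    for k in range(M, 0, -1):
        nxt = B[k + 1]
        v = nxt[1:]  # v[e] = B[k+1][e+1], e = 0..N-1
        B[k][:N] = _logsumexp(G + v[None, :], axis=1)
    return B


def _forward(G: np.ndarray, N: int, M: int) -> list[np.ndarray]:
    """F[k][c] = log sum over placements of segments 1..k covering 0..c-1."""
    F: list[np.ndarray] = [np.full(N + 1, -np.inf) for _ in range(M + 1)]
    F[0][0] = 0.0
    for k in range(1, M + 1):
        prev = F[k - 1]
        W = prev[:N, None] + G  # W[a, e] = F[k-1][a] + G[a, e]
        F[k][1:] = _logsumexp(W, axis=0)
    return F


def log_evidence_for_matrix(G: np.ndarray, N: int, M: int, lmin: int) -> float:
    """Log evidence from an N x N segment log-marginal matrix via elimination."""
    if count_valid_partitions(N, M, lmin) == 0:
        return -np.inf
    B = _backward(G, N, M)
    return float(log_prior_boundaries(N, M, lmin) + B[1][0])


def log_evidence_known_sigma(table: SegmentTable, M: int) -> float:
    """Log P(D | M) for known per-point errors."""
    return log_evidence_for_matrix(table.log_marginal_known(), table.N, M, table.lmin)


def select_M(M_values, log_evidence) -> int:
    """Segment count with the greatest log evidence; ties favour fewer segments."""
    M_values = list(M_values)
    log_evidence = np.asarray(log_evidence, dtype=float)
    if len(M_values) == 0 or len(M_values) != log_evidence.size:
        raise ValueError("need one log-evidence value per M")
    if not np.any(np.isfinite(log_evidence)):
        raise ValueError("no feasible M was evaluated")
    best = None
    best_val = -np.inf
    for m, v in sorted(zip(M_values, log_evidence)):
        if v > best_val:
            best, best_val = m, v
    return int(best)


def boundary_moments_for_matrix(
    G: np.ndarray, N: int, M: int, lmin: int
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of each of the M-1 boundary cuts.

    Boundary i is reported as the 1-based index of the last point of segment
    i, consistent with the cut convention.
    """
    if M < 2:
        return np.empty(0), np.empty(0)
    if count_valid_partitions(N, M, lmin) == 0:
        raise DataValidationError(f"no admissible partition for N={N}, M={M}")
    F = _forward(G, N, M)
    B = _backward(G, N, M)
    logZ = B[1][0]
    if not np.isfinite(logZ):
        raise DataValidationError("all partitions have vanishing likelihood")
    cuts = np.arange(N + 1, dtype=float)
    means = np.empty(M - 1)
    variances = np.empty(M - 1)
    for i in range(1, M):
        lp = F[i] + B[i + 1] - logZ
        with np.errstate(invalid="ignore"):
            p = np.exp(lp)
        p[~np.isfinite(lp)] = 0.0
        total = p.sum()
        p /= total
        mean = float(cuts @ p)
        means[i - 1] = mean
        variances[i - 1] = max(float((cuts - mean) ** 2 @ p), 0.0)
    return means, variances


def posterior_boundary_moments(
    table: SegmentTable, M: int
) -> tuple[np.ndarray, np.ndarray]:
    """Known-sigma posterior boundary moments for M segments."""
    return boundary_moments_for_matrix(
        table.log_marginal_known(), table.N, M, table.lmin
    )


def _repair_boundaries(means: np.ndarray, N: int, M: int, lmin: int) -> np.ndarray:
    """Round posterior means to the nearest admissible integer boundary vector.

    Minimizes total L1 displacement from the rounded means subject to the
    spacing constraints, by dynamic programming over the slack variables
    u_i = n_i - i*lmin (which must be non-decreasing in [0, N - M*lmin]).
    """
    if M < 2:
        return np.empty(0, dtype=int)
    targets = np.rint(means).astype(int)
    R = N - M * lmin
    offsets = lmin * np.arange(1, M)
    t = np.clip(targets - offsets, 0, R)
    vals = np.arange(R + 1)
    cost = np.abs(vals - t[0]).astype(float)
    choice = np.zeros((M - 1, R + 1), dtype=int)
    choice[0] = vals
    for i in range(1, M - 1):
        best = np.minimum.accumulate(cost)
        argbest = np.zeros(R + 1, dtype=int)
        run = 0
        for v in range(R + 1):
            if cost[v] < cost[run]:
                run = v
            argbest[v] = run
        choice[i] = argbest
        cost = best + np.abs(vals - t[i])
    v = int(np.argmin(cost))
    u = np.empty(M - 1, dtype=int)
    u[-1] = v
    for i in range(M - 2, 0, -1):
        v = int(choice[i][v])
        u[i - 1] = v
    return u + offsets


@dataclass
class PartitionResult:
    """Outcome of a full partition analysis.

    Boundary means/variances are in cut units (1-based index of the last
    point of each segment); ``segments`` are 0-based inclusive index pairs.
    """

    M_values: list[int]
    log_evidence: np.ndarray
    M_best: int
    boundaries_mean: np.ndarray
    boundaries_var: np.ndarray
    boundaries_index: np.ndarray
    segments: list[tuple[int, int]]
    segment_stats: list[SegmentStats]
    sigma_mode: str
    sigma_hat: float | None = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def segments_1based(self) -> list[tuple[int, int]]:
        return [(a + 1, b + 1) for a, b in self.segments]


def _segments_from_cuts(cuts: np.ndarray, N: int) -> list[tuple[int, int]]:
    edges = [0, *[int(c) for c in cuts], N]
    return [(edges[i], edges[i + 1] - 1) for i in range(len(edges) - 1)]


def partition(
    ts: TimeSeries,
    basis: BasisSet | None = None,
    prior: CoefficientPrior | None = None,
    sigma="unknown",
    M_max: int | None = None,
) -> PartitionResult:
    """Full analysis: evidence over M, model selection, boundaries, statistics.

    Parameters
    ----------
    sigma : "unknown", scalar, array, or None
        "unknown" marginalizes a shared noise scale numerically; a scalar or
        per-point array (or None with ``ts.sigma`` set) uses the known-error
        closed form.
    """
    from . import sigma as sigma_mod  # deferred: sigma module imports engine
    from .segstats import build_coefficient_prior

    if basis is None:
        basis = make_linear_basis()
    if prior is None:
        if basis.tag != "line":
            raise ValueError("a CoefficientPrior is required for non-line bases")
        prior = build_coefficient_prior(
            ts, y_range=(float(ts.y.min()), float(ts.y.max()))
        )
    notes: list[str] = []
    N, lmin = ts.N, basis.lmin
    feasible_max = N // lmin
    if feasible_max < 1:
        raise DataValidationError(f"series too short: N={N} < lmin={lmin}")
    if M_max is None:
        M_max = min(10, feasible_max)
    if N < 2 * lmin:
        if M_max > 1:
            warnings.warn("fewer than 2*lmin points: only M=1 is feasible")
            notes.append("analysis limited to M=1 (N < 2*lmin)")
        M_max = 1
    elif M_max > feasible_max:
        notes.append(f"M_max trimmed from {M_max} to {feasible_max}")
        M_max = feasible_max

    unknown = isinstance(sigma, str) and sigma == "unknown"
    M_values = list(range(1, M_max + 1))
    sigma_hat = None

    if unknown:
        table = precompute_segment_table(basis, ts, prior, sigma_mode="unit")
        prior = sigma_mod.ensure_sigma_bounds(table, prior)
        table.prior = prior
        log_ev = np.array(
            [sigma_mod.log_evidence_unknown_sigma(table, M, prior).log_evidence
             for M in M_values]
        )
        M_best = select_M(M_values, log_ev)
        if M_best >= 2:
            means, variances = sigma_mod.posterior_boundaries_unknown_sigma(
                table, M_best, prior
            )
        else:
            means, variances = np.empty(0), np.empty(0)
        est = sigma_mod.em_sigma_safe(table, M_best, prior)
        sigma_hat = est.sigma_hat if est is not None else None
    else:
        table = precompute_segment_table(
            basis, ts, prior, sigma_mode="known", sigma=sigma
        )
        log_ev = np.array([log_evidence_known_sigma(table, M) for M in M_values])
        M_best = select_M(M_values, log_ev)
        means, variances = posterior_boundary_moments(table, M_best)

    cuts = _repair_boundaries(means, N, M_best, lmin)
    segments = _segments_from_cuts(cuts, N)
    from .marginal import check_prior_width

    stats = [segment_stats_from_table(table, a, b) for a, b in segments]
    for a, b in segments:
        if table.valid[a, b] and not check_prior_width(table.kernel(a, b), prior):
            msg = (
                f"prior box may be too narrow for segment [{a + 1}, {b + 1}] "
                "(1-based): sqrt(det A) * P(m) is not << 1"
            )
            logger.warning(msg)
            notes.append(msg)
    return PartitionResult(
        M_values=M_values,
        log_evidence=log_ev,
        M_best=M_best,
        boundaries_mean=means,
        boundaries_var=variances,
        boundaries_index=cuts,
        segments=segments,
        segment_stats=stats,
        sigma_mode="unknown" if unknown else "known",
        sigma_hat=sigma_hat,
        warnings_=notes,
    )
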