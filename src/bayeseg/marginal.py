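"""Marginal likelihood of one candidate segment under Gaussian noise.

For known per-point errors the coefficient integral is carried out in closed
form (extended to infinite range), giving the segment's full log marginal.
For an unknown shared noise scale the segment kernel is computed once with
unit errors and the sigma-dependent factors are attached on the fly.

The straight-line basis has a specialized path built from six running sums,
which lets the table of all O(N^2) candidate segments be assembled with
vectorized arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import (
    BasisSet,
    CoefficientPrior,
    DataValidationError,
    DegenerateSegmentError,
    TimeSeries,
    _resolve_sigma,
    design_matrix,
)

__all__ = [
    "LineSuffStats",
    "SegmentKernel",
    "SegmentTable",
    "line_suff_stats",
    "segment_kernel",
    "log_marginal_known_sigma",
    "log_marginal_sigma_kernel",
    "check_prior_width",
    "precompute_segment_table",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_LOG_SQRT_2PI = 0.5 * _LOG_2PI

#: Operational cutoff for the prior-width validity condition
#: sqrt(det A) * P(m) <= PRIOR_WIDTH_CUTOFF.
PRIOR_WIDTH_CUTOFF = 0.1

#: Condition-number guard beyond which a segment's normal matrix is treated
#: as degenerate rather than solved.
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class LineSuffStats:
    """The six weighted sums for the straight-line fast path.

    T1 = sum y^2/(2 s^2), T2 = sum x^2/(2 s^2), T3 = sum 1/(2 s^2),
    T4 = sum y/s^2, T5 = sum x y/s^2, T6 = sum x/s^2, accumulated over the
    segment's points and all replicates.
    """

    T1: float
    T2: float
    T3: float
    T4: float
    T5: float
    T6: float


@dataclass(frozen=True)
class SegmentKernel:
    """Sufficient statistics of one candidate segment.

    ``A`` is the K x K normal matrix, ``m_bar`` the most likely coefficient
    vector, and ``U`` half the weighted residual sum of squares at ``m_bar``.
    """

    i0: int
    i1: int
    A: np.ndarray
    m_bar: np.ndarray
    U: float
    log_det_A: float
    ell: int
    n_replicates: int

    @property
    def K(self) -> int:
        return self.A.shape[0]


def line_suff_stats(ts: TimeSeries, i0: int, i1: int, sigma=None) -> LineSuffStats:
    """Accumulate the six line sums over points i0..i1 and all replicates."""
    if not (0 <= i0 <= i1 < ts.N):
        raise IndexError(f"invalid segment [{i0}, {i1}] for N={ts.N}")
    sig = _resolve_sigma(ts, sigma)[i0 : i1 + 1]
    x = ts.x[i0 : i1 + 1]
    y = ts.y[:, i0 : i1 + 1]
    w = 1.0 / sig**2
    nr = ts.N_r
    return LineSuffStats(
        T1=float(np.sum(y**2 * (0.5 * w)[None, :])),
        T2=float(nr * np.sum(x**2 * 0.5 * w)),
        T3=float(nr * np.sum(0.5 * w)),
        T4=float(np.sum(y * w[None, :])),
        T5=float(np.sum(y * (x * w)[None, :])),
        T6=float(nr * np.sum(x * w)),
    )


def _line_kernel_values(T: LineSuffStats) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form A, m_bar, U for the line basis from the six sums."""
    A = np.array([[2.0 * T.T3, T.T6], [T.T6, 2.0 * T.T2]])
    det = 4.0 * T.T2 * T.T3 - T.T6**2
    if det <= 0 or det < 1e-14 * max(4.0 * T.T2 * T.T3, 1e-300):
        raise DegenerateSegmentError(
            "collinear line fit: 4*T2*T3 - T6^2 is not positive"
        )
    m1 = (2.0 * T.T2 * T.T4 - T.T5 * T.T6) / det
    m2 = (2.0 * T.T3 * T.T5 - T.T4 * T.T6) / det
    U = T.T1 - (T.T2 * T.T4**2 + T.T3 * T.T5**2 - T.T4 * T.T5 * T.T6) / det
    return A, np.array([m1, m2]), float(U)


def segment_kernel(
    basis: BasisSet, ts: TimeSeries, i0: int, i1: int, sigma=None
) -> SegmentKernel:
    """Normal-matrix decomposition (A, m_bar, U) of the segment [i0, i1]."""
    ell = i1 - i0 + 1
    if ell < basis.lmin:
        raise DataValidationError(f"segment [{i0}, {i1}] shorter than lmin={basis.lmin}")
    sig = _resolve_sigma(ts, sigma)
    phi = design_matrix(basis, ts, i0, i1, sig)
    z = (ts.y[:, i0 : i1 + 1] / sig[None, i0 : i1 + 1]).ravel()
    A = phi @ phi.T
    rhs = phi @ z
    evals = np.linalg.eigvalsh(A)
    if evals[0] <= 0 or evals[-1] / evals[0] > CONDITION_LIMIT:
        raise DegenerateSegmentError(
            f"segment [{i0}, {i1}]: normal matrix singular or ill-conditioned"
        )
    # QR-based solve: appreciably more accurate than the normal equations
    # when the segment's x values sit far from the origin
    m_bar, *_ = np.linalg.lstsq(phi.T, z, rcond=None)
    resid = z - phi.T @ m_bar
    U = 0.5 * float(resid @ resid)
    return SegmentKernel(
        i0=i0,
        i1=i1,
        A=A,
        m_bar=m_bar,
        U=U,
        log_det_A=float(np.sum(np.log(evals))),
        ell=ell,
        n_replicates=ts.N_r,
    )


def check_prior_width(kernel: SegmentKernel, prior: CoefficientPrior) -> bool:
    """Validity condition for the infinite-range coefficient integral.

    Returns True when sqrt(det A) times the prior density is at most
    :data:`PRIOR_WIDTH_CUTOFF`; a False value indicates the prior box may be
    too narrow to contain the likelihood's peak region.
    """
    value = 0.5 * kernel.log_det_A + prior.log_volume_inv
    return bool(value <= np.log(PRIOR_WIDTH_CUTOFF))


def log_marginal_known_sigma(
    kernel: SegmentKernel,
    prior: CoefficientPrior,
    ts: TimeSeries,
    sigma=None,
) -> float:
    """Log marginal likelihood of one segment with known per-point errors.

    Computed wholly in log space:
    log P(m) - N_r * sum_j log(sqrt(2 pi) sigma_j) + (K/2) log(2 pi)
    - (1/2) log det A - U.
    """
    if not check_prior_width(kernel, prior):
        logger.warning(
            "prior box may be too narrow for segment [%d, %d]: "
            "sqrt(det A) * P(m) exceeds %.2g",
            kernel.i0,
            kernel.i1,
            PRIOR_WIDTH_CUTOFF,
        )
    sig = _resolve_sigma(ts, sigma)[kernel.i0 : kernel.i1 + 1]
    K = kernel.K
    return float(
        prior.log_volume_inv
        - kernel.n_replicates * np.sum(_LOG_SQRT_2PI + np.log(sig))
        + 0.5 * K * _LOG_2PI
        - 0.5 * kernel.log_det_A
        - kernel.U
    )


def log_marginal_sigma_kernel(
    kernel: SegmentKernel, prior: CoefficientPrior, sigma: float
) -> float:
    """Log marginal of one segment at a trial shared noise scale ``sigma``.

    The kernel must have been built with unit errors; the value is
    log P(m) - (N_r*ell - K) * log(sqrt(2 pi) sigma) - (1/2) log det A
    - U / sigma^2.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ndof = kernel.n_replicates * kernel.ell - kernel.K
    return float(
        prior.log_volume_inv
        - ndof * (_LOG_SQRT_2PI + np.log(sigma))
        - 0.5 * kernel.log_det_A
        - kernel.U / sigma**2
    )


class SegmentTable:
    """Kernels of every admissible contiguous segment, stored as N x N arrays.

    Entry ``[a, b]`` refers to the 0-based inclusive segment from point ``a``
    to point ``b``; entries with fewer than ``lmin`` points are invalid.
    Shared by the known-sigma and unknown-sigma evidence paths: the former
    reads :meth:`log_marginal_known`, the latter :meth:`log_marginal_at_sigma`
    on kernels built with unit errors.
    """

    def __init__(
        self,
        basis: BasisSet,
        ts: TimeSeries,
        prior: CoefficientPrior,
        sigma_mode: str = "known",
        sigma=None,
    ):
        if sigma_mode not in ("known", "unit"):
            raise ValueError("sigma_mode must be 'known' or 'unit'")
        self.basis = basis
        self.ts = ts
        self.prior = prior
        self.sigma_mode = sigma_mode
        N = ts.N
        self.N = N
        self.lmin = basis.lmin
        self.K = basis.K
        self.N_r = ts.N_r
        if sigma_mode == "unit":
            self._sigma = np.ones(N)
        else:
            self._sigma = _resolve_sigma(ts, sigma)

        lengths = np.arange(N)[None, :] - np.arange(N)[:, None] + 1
        self.ell = lengths
        self.valid = lengths >= self.lmin

        if basis.tag == "line" and basis.K == 2:
            self._build_line_table()
        else:
            basis.check_independence(ts.x)
            self._build_generic_table()
        # -N_r * sum_j log(sqrt(2pi) sigma_j), per segment
        c = np.concatenate([[0.0], np.cumsum(_LOG_SQRT_2PI + np.log(self._sigma))])
        self.log_sigma_const = -self.N_r * (c[None, 1:] - c[:-1, None])

    # -- construction -----------------------------------------------------

    def _build_line_table(self) -> None:
        # The six running sums are combined in central-moment form, which is
        # algebraically identical to the raw closed form (with T2 = Sxx/2,
        # T3 = W/2, T6 = Sx: det A = W*Vxx, etc.) but avoids the worst
        # cancellation when x or y sit far from the origin.
        ts, sig = self.ts, self._sigma
        w = 1.0 / sig**2
        x, y = ts.x, ts.y
        nr = self.N_r

        def seg_sums(per_point: np.ndarray) -> np.ndarray:
            # extended precision absorbs the cancellation of differencing
            # long cumulative sums
            c = np.concatenate([[0.0], np.cumsum(per_point.astype(np.longdouble))])
            return c[None, 1:] - c[:-1, None]

        W = seg_sums(nr * w)
        Sx = seg_sums(nr * x * w)
        Sy = seg_sums(np.sum(y, axis=0) * w)
        Sxx = seg_sums(nr * x**2 * w)
        Sxy = seg_sums(np.sum(y, axis=0) * x * w)
        Syy = seg_sums(np.sum(y**2, axis=0) * w)

        with np.errstate(invalid="ignore", divide="ignore"):
            Vxx = (Sxx - Sx**2 / W).astype(float)
            Vxy = (Sxy - Sx * Sy / W).astype(float)
            Vyy = (Syy - Sy**2 / W).astype(float)
        W = W.astype(float)
        Sx = Sx.astype(float)
        Sy = Sy.astype(float)
        Sxx = Sxx.astype(float)
        det = W * Vxx
        degenerate = ~np.isfinite(det) | (det <= 0) | (Vxx < 1e-14 * Sxx)
        ok = self.valid & ~degenerate
        safe_Vxx = np.where(ok, Vxx, 1.0)
        safe_W = np.where(W > 0, W, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m2 = Vxy / safe_Vxx
            m1 = (Sy - m2 * Sx) / safe_W
            U = 0.5 * (Vyy - Vxy**2 / safe_Vxx)
            log_det = np.where(ok, np.log(np.where(ok, det, 1.0)), np.nan)
        self.U = np.where(ok, np.maximum(U, 0.0), np.nan)
        self.log_det_A = log_det
        self.coef = np.stack([m1, m2], axis=-1)
        self.valid = ok

    def _build_generic_table(self) -> None:
        ts, sig = self.ts, self._sigma
        K, N, nr = self.K, self.N, self.N_r
        phi = self.basis.evaluate(ts.x)  # K x N, unweighted
        w = 1.0 / sig**2
        # per-point building blocks, then prefix sums along j
        outer = np.einsum("kj,lj,j->jkl", phi, phi, w) * nr
        ysum = np.sum(ts.y, axis=0)
        rhs_pt = phi * (ysum * w)[None, :]
        zz_pt = np.sum(ts.y**2, axis=0) * w
        cA = np.concatenate([np.zeros((1, K, K)), np.cumsum(outer, axis=0)])
        cr = np.concatenate([np.zeros((K, 1)), np.cumsum(rhs_pt, axis=1)], axis=1)
        cz = np.concatenate([[0.0], np.cumsum(zz_pt)])

        self.U = np.full((N, N), np.nan)
        self.log_det_A = np.full((N, N), np.nan)
        self.coef = np.full((N, N, K), np.nan)
        ok = np.zeros((N, N), dtype=bool)
        for a in range(N):
            for b in range(a + self.lmin - 1, N):
                A = cA[b + 1] - cA[a]
                rhs = cr[:, b + 1] - cr[:, a]
                evals = np.linalg.eigvalsh(A)
                if evals[0] <= 0 or evals[-1] / evals[0] > CONDITION_LIMIT:
                    continue
                m_bar = np.linalg.solve(A, rhs)
                zz = cz[b + 1] - cz[a]
                self.U[a, b] = max(0.5 * (zz - m_bar @ A @ m_bar), 0.0)
                self.log_det_A[a, b] = np.sum(np.log(evals))
                self.coef[a, b] = m_bar
                ok[a, b] = True
        self.valid = self.valid & ok

    # -- queries ----------------------------------------------------------

    def n_entries(self) -> int:
        return int(np.count_nonzero(self.valid))

    def log_marginal_known(self) -> np.ndarray:
        """N x N array of known-sigma log marginals (-inf where invalid)."""
        if self.sigma_mode != "known":
            raise ValueError("table was built with unit sigma")
        out = (
            self.prior.log_volume_inv
            + self.log_sigma_const
            + 0.5 * self.K * _LOG_2PI
            - 0.5 * self.log_det_A
            - self.U
        )
        return np.where(self.valid, out, -np.inf)

    def log_marginal_at_sigma(self, sigma: float) -> np.ndarray:
        """N x N array of log marginals at a shared noise scale ``sigma``."""
        if self.sigma_mode != "unit":
            raise ValueError("table was built with known sigma")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        ndof = self.N_r * self.ell - self.K
        with np.errstate(invalid="ignore"):
            out = (
                self.prior.log_volume_inv
                - ndof * (_LOG_SQRT_2PI + np.log(sigma))
                - 0.5 * self.log_det_A
                - self.U / sigma**2
            )
        return np.where(self.valid, out, -np.inf)

    def kernel(self, i0: int, i1: int) -> SegmentKernel:
        """Reconstruct the :class:`SegmentKernel` of one tabulated segment."""
        if not self.valid[i0, i1]:
            raise DegenerateSegmentError(f"segment [{i0}, {i1}] is not tabulated")
        return segment_kernel(self.basis, self.ts, i0, i1, sigma=self._sigma)


def precompute_segment_table(
    basis: BasisSet,
    ts: TimeSeries,
    prior: CoefficientPrior,
    sigma_mode: str = "known",
    sigma=None,
) -> SegmentTable:
    """Tabulate kernels for all contiguous segments with at least lmin points."""
    if ts.N < basis.lmin:
        raise DataValidationError(
            f"series of length {ts.N} shorter than lmin={basis.lmin}"
        )
    return SegmentTable(basis, ts, prior, sigma_mode=sigma_mode, sigma=sigma)
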