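"""Core data types: time series, basis-function sets, coefficient priors.

A :class:`TimeSeries` holds an ascending grid ``x`` with one or more replicate
observation vectors ``y`` and, optionally, a per-point measurement error
``sigma`` shared across replicates.  A :class:`BasisSet` holds the K functions
whose linear combinations model each contiguous segment; straight lines use
``{1, x}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "DataValidationError",
    "DegenerateSegmentError",
    "PerfectFitError",
    "TimeSeries",
    "BasisSet",
    "CoefficientPrior",
    "make_linear_basis",
    "make_polynomial_basis",
    "design_matrix",
]


class DataValidationError(ValueError):
    """Raised when input data violate the model's structural assumptions."""


class DegenerateSegmentError(RuntimeError):
    """Raised when a segment's normal matrix is singular or ill-conditioned."""


class PerfectFitError(RuntimeError):
    """Raised when residuals vanish and the noise scale cannot be inferred."""


@dataclass
class TimeSeries:
    """An ascending 1D grid with replicate observations.

    Parameters
    ----------
    x : array of shape (N,)
        Strictly ascending abscissa (time in hours, or dilution factor).
    y : array of shape (N_r, N) or (N,)
        Replicate observation vectors; a 1D array is treated as one replicate.
    sigma : array of shape (N,), optional
        Per-point measurement error, strictly positive, shared by replicates.
    """

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.ndim != 1:
            raise DataValidationError("x must be one-dimensional")
        if self.y.shape[1] != self.x.size:
            if self.y.shape[0] == self.x.size:
                self.y = self.y.T
            else:
                raise DataValidationError(
                    f"y shape {self.y.shape} incompatible with {self.x.size} x values"
                )
        if self.x.size < 2:
            raise DataValidationError("need at least two data points")
        if not np.all(np.isfinite(self.x)):
            raise DataValidationError("x contains non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise DataValidationError("y contains non-finite values")
        dx = np.diff(self.x)
        if np.any(dx <= 0):
            bad = list(np.nonzero(dx <= 0)[0] + 1)
            raise DataValidationError(
                f"x must be strictly ascending; violation at row(s) {bad}"
            )
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.x.shape:
                raise DataValidationError("sigma must match x in length")
            if not np.all(np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
                raise DataValidationError("sigma must be finite and strictly positive")

    @property
    def N(self) -> int:
        return self.x.size

    @property
    def N_r(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class BasisSet:
    """K real-valued basis functions of x with a minimum segment length.

    ``tag == "line"`` marks the ``{1, x}`` pair, which enables the closed-form
    sufficient-statistics fast path.
    """

    funcs: tuple[Callable[[np.ndarray], np.ndarray], ...]
    names: tuple[str, ...]
    lmin: int
    tag: str = "custom"

    def __post_init__(self) -> None:
        if len(self.funcs) != len(self.names):
            raise ValueError("funcs and names must have equal length")
        if self.lmin < self.K:
            raise ValueError(f"lmin={self.lmin} must be >= K={self.K}")

    @property
    def K(self) -> int:
        return len(self.funcs)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions on ``x``; returns a K x len(x) matrix."""
        x = np.asarray(x, dtype=float)
        out = np.empty((self.K, x.size))
        for k, f in enumerate(self.funcs):
            out[k] = np.broadcast_to(np.asarray(f(x), dtype=float), x.shape)
        return out

    def check_independence(self, x: np.ndarray, rtol: float = 1e-10) -> None:
        """Verify numerical linear independence on the grid ``x``.

        The smallest singular value of the full-grid design matrix must exceed
        ``rtol`` times the largest; otherwise the basis is rejected.
        """
        x = np.asarray(x, dtype=float)
        if np.unique(x).size < self.K:
            raise DataValidationError(
                f"need at least K={self.K} distinct x values to resolve the basis"
            )
        sv = np.linalg.svd(self.evaluate(x), compute_uv=False)
        if sv[-1] <= rtol * sv[0]:
            raise DataValidationError(
                "basis functions are numerically collinear on this x grid"
            )


def make_linear_basis(lmin: int = 3) -> BasisSet:
    """The straight-line basis {1, x} with lmin defaulting to 3."""
    return BasisSet(
        funcs=(lambda x: np.ones_like(x), lambda x: x),
        names=("intercept", "slope"),
        lmin=lmin,
        tag="line",
    )


def make_polynomial_basis(degree: int, lmin: int | None = None) -> BasisSet:
    """Monomial basis 1, x, ..., x**degree.

    ``lmin`` defaults to K+1 so that the residual variance stays informative;
    a user-supplied value below K is rejected.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    K = degree + 1
    if lmin is None:
        lmin = K + 1
    funcs = tuple((lambda p: (lambda x: x**p))(p) for p in range(K))
    names = tuple("1" if p == 0 else f"x^{p}" for p in range(K))
    tag = "line" if degree == 1 else "custom"
    return BasisSet(funcs=funcs, names=names, lmin=lmin, tag=tag)


@dataclass(frozen=True)
class CoefficientPrior:
    """Bounded uniform prior over the K coefficients (and optionally sigma)."""

    lo: np.ndarray
    hi: np.ndarray
    sigma_lo: float | None = None
    sigma_hi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))
        if self.lo.shape != self.hi.shape or self.lo.ndim != 1:
            raise ValueError("lo and hi must be 1D arrays of equal length")
        if np.any(self.hi <= self.lo):
            raise ValueError("each upper bound must exceed its lower bound")
        if (self.sigma_lo is None) != (self.sigma_hi is None):
            raise ValueError("sigma bounds must be given together")
        if self.sigma_lo is not None:
            if self.sigma_lo <= 0 or self.sigma_hi <= self.sigma_lo:
                raise ValueError("require 0 < sigma_lo < sigma_hi")

    @property
    def K(self) -> int:
        return self.lo.size

    @property
    def log_volume_inv(self) -> float:
        """Log of the constant prior density inside the box."""
        return float(-np.sum(np.log(self.hi - self.lo)))

    def with_sigma_bounds(self, sigma_lo: float, sigma_hi: float) -> "CoefficientPrior":
        return CoefficientPrior(self.lo, self.hi, sigma_lo=sigma_lo, sigma_hi=sigma_hi)


def _resolve_sigma(ts: TimeSeries, sigma) -> np.ndarray:
    """Normalize a sigma argument to a strictly positive (N,) array."""
    if sigma is None:
        if ts.sigma is not None:
            return ts.sigma
        return np.ones(ts.N)
    arr = np.asarray(sigma, dtype=float)
    if arr.ndim == 0:
        arr = np.full(ts.N, float(arr))
    if arr.shape != (ts.N,):
        raise DataValidationError("sigma must be scalar or length-N")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DataValidationError("sigma must be finite and strictly positive")
    return arr


def design_matrix(
    basis: BasisSet,
    ts: TimeSeries,
    i0: int,
    i1: int,
    sigma=None,
) -> np.ndarray:
    """Error-weighted design matrix of the segment [i0, i1] (inclusive).

    Entry (k, j) is phi_k(x_j) / sigma_j.  With N_r replicates the x block is
    tiled N_r times along the columns, replicate-major, to match the flattened
    observation vector ``ts.y[:, i0:i1+1].ravel()``.
    """
    if not (0 <= i0 <= i1 < ts.N):
        raise IndexError(f"invalid segment [{i0}, {i1}] for N={ts.N}")
    if i1 - i0 + 1 < basis.lmin:
        raise DataValidationError(
            f"segment [{i0}, {i1}] shorter than lmin={basis.lmin}"
        )
    sig = _resolve_sigma(ts, sigma)[i0 : i1 + 1]
    phi = basis.evaluate(ts.x[i0 : i1 + 1]) / sig[None, :]
    return np.tile(phi, (1, ts.N_r))
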