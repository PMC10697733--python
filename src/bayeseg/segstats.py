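"""Per-segment fit summaries and coefficient-prior construction.

For the line basis each segment is summarized by the gradient, intercept and
R^2 of its maximum-likelihood line; for other bases the coefficient vector
and R^2 are reported without slope/intercept fields.  The prior box over the
two line coefficients can be built from three user-input forms: an explicit
box, a gradient range, or the maximal y range of the experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CoefficientPrior, DataValidationError, TimeSeries

__all__ = [
    "SegmentStats",
    "segment_stats",
    "segment_stats_from_table",
    "select_segment",
    "build_coefficient_prior",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentStats:
    """Best-fit summary of one segment (0-based inclusive indices)."""

    start: int
    end: int
    npoints: int
    r_squared: float
    gradient: float | None = None
    intercept: float | None = None
    coefficients: tuple[float, ...] | None = None
    degenerate: bool = False


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> tuple[float, bool]:
    """Pooled-replicate R^2: TSS about the grand mean of the segment."""
    rss = float(np.sum((y - fitted[None, :]) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        exact = rss <= 1e-20 * max(float(np.sum(y**2)), 1.0)
        return (1.0 if exact else 0.0), True
    return max(0.0, min(1.0, 1.0 - rss / tss)), False


def segment_stats(kernel, ts: TimeSeries) -> SegmentStats:
    """Summary statistics from a :class:`~bayeseg.marginal.SegmentKernel`."""
    x = ts.x[kernel.i0 : kernel.i1 + 1]
    y = ts.y[:, kernel.i0 : kernel.i1 + 1]
    if kernel.K == 2:
        intercept, gradient = float(kernel.m_bar[0]), float(kernel.m_bar[1])
        fitted = intercept + gradient * x
        r2, degen = _r_squared(y, fitted)
        return SegmentStats(
            start=kernel.i0,
            end=kernel.i1,
            npoints=kernel.ell,
            r_squared=r2,
            gradient=gradient,
            intercept=intercept,
            coefficients=tuple(float(c) for c in kernel.m_bar),
            degenerate=degen,
        )
    raise ValueError(
        "segment_stats requires the line basis; use segment_stats_from_table "
        "for other bases"
    )


def segment_stats_from_table(table, i0: int, i1: int) -> SegmentStats:
    """Summary statistics for a tabulated segment."""
    ts = table.ts
    x = ts.x[i0 : i1 + 1]
    y = ts.y[:, i0 : i1 + 1]
    npoints = i1 - i0 + 1
    if not table.valid[i0, i1]:
        return SegmentStats(
            start=i0, end=i1, npoints=npoints, r_squared=0.0, degenerate=True
        )
    coef = table.coef[i0, i1]
    phi = table.basis.evaluate(x)
    fitted = coef @ phi
    r2, degen = _r_squared(y, fitted)
    gradient = intercept = None
    if table.basis.tag == "line" and table.K == 2:
        intercept, gradient = float(coef[0]), float(coef[1])
    return SegmentStats(
        start=i0,
        end=i1,
        npoints=npoints,
        r_squared=r2,
        gradient=gradient,
        intercept=intercept,
        coefficients=tuple(float(c) for c in coef),
        degenerate=degen,
    )


def select_segment(stats: list[SegmentStats], criterion="gradient") -> SegmentStats:
    """Pick a segment by criterion: 'gradient', 'r2', or an integer index.

    Ties go to the earliest segment.
    """
    if not stats:
        raise ValueError("empty segment list")
    if isinstance(criterion, int):
        return stats[criterion]
    if criterion in ("gradient", "highest-gradient"):
        key = [s.gradient for s in stats]
        if any(g is None for g in key):
            raise ValueError("gradient selection requires the line basis")
    elif criterion in ("r2", "highest-r2"):
        key = [s.r_squared for s in stats]
    elif criterion == "first":
        return stats[0]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = 0
    for i, v in enumerate(key):
        if v > key[best]:
            best = i
    return stats[best]


def build_coefficient_prior(
    ts: TimeSeries,
    box: tuple[float, float, float, float] | None = None,
    gradient_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> CoefficientPrior:
    """Prior box for the line coefficients (m1 intercept, m2 gradient).

    Exactly one of the three forms must be given:

    * ``box`` -- (m1_lo, m1_hi, m2_lo, m2_hi), passed through verbatim.
    * ``gradient_range`` -- (m2_lo, m2_hi); the intercept range is derived as
      m1_lo = min(-m2_hi*x_max, m2_lo*x_min),
      m1_hi = max(-m2_lo*x_max, m2_hi*x_min).
    * ``y_range`` -- (y_lo, y_hi); the gradient range is [-g, g] with
      g = (y_hi - y_lo)/min(diff(x)), then the intercept rule above.

    The derived intercept range is widened, with a warning, if it would
    exclude the full-series least-squares intercept.
    """
    given = [v is not None for v in (box, gradient_range, y_range)]
    if sum(given) != 1:
        raise ValueError("give exactly one of box, gradient_range, y_range")
    if box is not None:
        m1lo, m1hi, m2lo, m2hi = map(float, box)
        if m1hi <= m1lo or m2hi <= m2lo:
            raise ValueError("inverted prior ranges")
        return CoefficientPrior(np.array([m1lo, m2lo]), np.array([m1hi, m2hi]))

    if y_range is not None:
        ylo, yhi = map(float, y_range)
        if yhi <= ylo:
            raise ValueError("inverted y range")
        dx = np.diff(ts.x)
        dx_min = float(dx.min())
        if dx_min <= 0:
            raise DataValidationError("duplicate x values: zero minimal spacing")
        gmax = (yhi - ylo) / dx_min
        m2lo, m2hi = -gmax, gmax
    else:
        m2lo, m2hi = map(float, gradient_range)
        if m2hi <= m2lo:
            raise ValueError("inverted gradient range")

    x_min, x_max = float(ts.x[0]), float(ts.x[-1])
    m1lo = min(-m2hi * x_max, m2lo * x_min)
    m1hi = max(-m2lo * x_max, m2hi * x_min)

    # keep the box wide enough to contain the full-series LS intercept
    X = np.column_stack([np.ones(ts.N), ts.x])
    coef, *_ = np.linalg.lstsq(
        np.tile(X, (ts.N_r, 1)), ts.y.ravel(), rcond=None
    )
    b0 = float(coef[0])
    width = m1hi - m1lo if m1hi > m1lo else max(abs(b0), 1.0)
    if not (m1lo < b0 < m1hi):
        logger.warning(
            "derived intercept range [%g, %g] excludes the least-squares "
            "intercept %g; widening", m1lo, m1hi, b0,
        )
        m1lo = min(m1lo, b0 - 0.05 * width)
        m1hi = max(m1hi, b0 + 0.05 * width)
    if m1hi <= m1lo:
        m1lo, m1hi = b0 - 1.0, b0 + 1.0
    return CoefficientPrior(np.array([m1lo, m2lo]), np.array([m1hi, m2hi]))
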