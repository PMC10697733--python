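"""Assembly of the JSON report shared by the CLI subcommands."""

from __future__ import annotations

from typing import Any

import numpy as np

from . import __version__
from .engine import PartitionResult
from .segstats import SegmentStats


def _segment_payload(s: SegmentStats) -> dict[str, Any]:
    return {
        "start_1based": s.start + 1,
        "end_1based": s.end + 1,
        "start_0based": s.start,
        "end_0based": s.end,
        "npoints": s.npoints,
        "gradient": s.gradient,
        "intercept": s.intercept,
        "r_squared": s.r_squared,
        "coefficients": s.coefficients,
        "degenerate": s.degenerate,
    }


def partition_payload(res: PartitionResult) -> dict[str, Any]:
    """JSON-ready summary of a partition result (1-based boundary indices)."""
    return {
        "M_values": res.M_values,
        "log_evidence": [
            float(v) if np.isfinite(v) else None for v in res.log_evidence
        ],
        "M_best": res.M_best,
        "boundaries_mean_1based": res.boundaries_mean,
        "boundaries_var": res.boundaries_var,
        "boundaries_index_1based": res.boundaries_index,
        "segments_1based": res.segments_1based,
        "segments_0based": res.segments,
        "segments": [_segment_payload(s) for s in res.segment_stats],
        "sigma_mode": res.sigma_mode,
        "sigma_hat": res.sigma_hat,
        "warnings": res.warnings_,
    }


def full_report(res: PartitionResult, config: dict[str, Any],
                extra: dict[str, Any] | None = None) -> dict[str, Any]:
    payload = {
        "version": __version__,
        "config": config,
        "partition": partition_payload(res),
    }
    if extra:
        payload.update(extra)
    return payload
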