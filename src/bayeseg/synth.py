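"""Synthetic benchmark: continuous piecewise-linear truths plus Gaussian noise.

Each truth has M segments of 10-50 points at unit spacing.  Segment slopes
are sampled uniformly in angle on [-arctan(20), arctan(20)] so that gradients
stay in [-20, 20], with adjacent segments separated by more than a minimum
angle gap.  Noisy replicates are y = f(x) + eps, eps ~ Normal(0, sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import TimeSeries

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "sample_piecewise_function",
    "add_noise_replicates",
    "generate_benchmark_suite",
    "DEFAULT_SIGMAS",
    "DEFAULT_THETA0S",
]

THETA_MAX = float(np.arctan(20.0))
REJECTION_CAP = 10_000

#: Noise levels of the full benchmark grid (anchored at the published 0.25
#: and 8; the intermediate values are configurable defaults).
DEFAULT_SIGMAS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
#: Minimum adjacent-angle gaps of the grid, in degrees (10 is the published
#: anchor).
DEFAULT_THETA0S = (5.0, 10.0, 20.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    M: int
    theta0: float = 10.0  # degrees
    sigma: float = 0.25
    n_replicates: int = 3
    points_min: int = 10
    points_max: int = 50
    dx: float = 1.0
    gradient_max: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.M:
            raise ValueError("M must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.points_min < 2 or self.points_max < self.points_min:
            raise ValueError("invalid points-per-segment range")


@dataclass(frozen=True)
class SyntheticDataset:
    """A noisy piecewise-linear dataset with its ground truth."""

    ts: TimeSeries
    truth_boundaries: np.ndarray  # 1-based index of the last point per segment
    truth_gradients: np.ndarray  # tan(theta) per segment
    truth_values: np.ndarray  # noiseless f(x)
    spec: SyntheticSpec

    @property
    def M(self) -> int:
        return self.truth_gradients.size


def _sample_angles(M: int, theta0_rad: float, rng: np.random.Generator,
                   theta_max: float) -> np.ndarray:
    """Sequential rejection: each angle must differ from its predecessor."""
    angles = np.empty(M)
    angles[0] = rng.uniform(-theta_max, theta_max)
    for i in range(1, M):
        for _ in range(REJECTION_CAP):
            cand = rng.uniform(-theta_max, theta_max)
            if abs(cand - angles[i - 1]) > theta0_rad:
                angles[i] = cand
                break
        else:
            raise ValueError(
                f"could not satisfy the angle-gap constraint theta0="
                f"{np.degrees(theta0_rad):.1f} deg within {REJECTION_CAP} draws"
            )
    return angles


def sample_piecewise_function(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the noiseless truth; the returned dataset's replicates equal it."""
    rng = np.random.default_rng(spec.seed)
    theta_max = float(np.arctan(spec.gradient_max))
    lengths = rng.integers(spec.points_min, spec.points_max + 1, size=spec.M)
    angles = _sample_angles(spec.M, np.radians(spec.theta0), rng, theta_max)
    gradients = np.tan(angles)

    N = int(lengths.sum())
    x = np.arange(N, dtype=float) * spec.dx
    f = np.empty(N)
    boundaries = np.cumsum(lengths)[:-1]  # 1-based last-point indices
    start = 0
    value = 0.0  # f at the first point of the current segment
    for i, (ell, g) in enumerate(zip(lengths, gradients)):
        idx = np.arange(start, start + ell)
        f[idx] = value + g * (x[idx] - x[start])
        # next segment continues from the break midway to its first point
        value = f[start + ell - 1] + gradients[min(i + 1, spec.M - 1)] * spec.dx
        start += ell

    ts = TimeSeries(x=x, y=np.tile(f, (1, 1)))
    return SyntheticDataset(
        ts=ts,
        truth_boundaries=boundaries.astype(int),
        truth_gradients=gradients,
        truth_values=f,
        spec=spec,
    )


def add_noise_replicates(
    dataset: SyntheticDataset,
    sigma: float | None = None,
    n_replicates: int | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Attach Gaussian-noise replicates to a dataset's truth."""
    spec = dataset.spec
    sigma = spec.sigma if sigma is None else float(sigma)
    n_rep = spec.n_replicates if n_replicates is None else int(n_replicates)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    f = dataset.truth_values
    y = f[None, :] + rng.normal(0.0, sigma, size=(n_rep, f.size)) if sigma > 0 \
        else np.tile(f, (n_rep, 1))
    ts = TimeSeries(x=dataset.ts.x, y=y)
    return replace(
        dataset,
        ts=ts,
        spec=replace(spec, sigma=sigma, n_replicates=n_rep),
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Truth plus noisy replicates in one call."""
    return add_noise_replicates(sample_piecewise_function(spec))


def generate_benchmark_suite(
    seed: int,
    n_functions: int = 200,
    theta0s=DEFAULT_THETA0S,
    sigmas=DEFAULT_SIGMAS,
    M_range: tuple[int, int] = (1, 10),
    n_replicates: int = 3,
):
    """Yield the full benchmark grid: functions x theta0 values x noise levels.

    Each (function id, theta0) pair fixes one truth whose segment count is
    drawn uniformly from ``M_range``; every noise level is then applied to
    that truth with an independent child seed.  The default full grid is
    200 x 3 x 6 = 3600 datasets.
    """
    root = np.random.SeedSequence(seed)
    for fid in range(n_functions):
        for t_idx, theta0 in enumerate(theta0s):
            fn_ss, noise_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(fid, t_idx)
            ).spawn(2)
            fn_rng = np.random.default_rng(fn_ss)
            M = int(fn_rng.integers(M_range[0], M_range[1] + 1))
            fn_seed = int(fn_ss.generate_state(1)[0])
            truth = sample_piecewise_function(
                SyntheticSpec(M=M, theta0=float(theta0), sigma=0.0,
                              n_replicates=n_replicates, seed=fn_seed)
            )
            noise_seeds = noise_ss.generate_state(len(sigmas))
            for s_idx, sig in enumerate(sigmas):
                yield (fid, float(theta0), float(sig)), add_noise_replicates(
                    truth, sigma=float(sig), n_replicates=n_replicates,
                    seed=int(noise_seeds[s_idx]),
                )


def suite_manifest(datasets) -> list[dict]:
    """Rows (dataset id, M, theta0, sigma, seed) describing a suite."""
    rows = []
    for i, (tag, ds) in enumerate(datasets):
        fid, theta0, sig = tag
        rows.append(
            {
                "dataset": i,
                "function_id": fid,
                "M": ds.M,
                "theta0": theta0,
                "sigma": sig,
                "seed": ds.spec.seed,
            }
        )
    return rows
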