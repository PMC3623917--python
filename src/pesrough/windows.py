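"""Multi-scale window planning and extraction.

The analysis probes the energy landscape one time scale at a time: at scale
tau, a window is n = 2^m frames taken every s = tau/delta frames, so the
window spans (n-1)*tau of simulated time.  Many such windows are placed
evenly over the available trajectories and their per-window statistics are
aggregated per scale.

Placement is deterministic (no RNG): with A_t admissible start frames in
trajectory t, the window budget is split across trajectories by
largest-remainder proportional allocation on A_t, and within a trajectory
W windows start at round(i * A / W) for i = 0..W-1 (duplicates after
rounding dropped).  Windows may overlap — at fine scales even coverage
requires it — but never span a trajectory boundary.  A seeded random
placement mode exists for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, ParameterError, SizeError
from .series import EnergySeries, TrajectorySet


@dataclass(frozen=True)
class TimescaleGrid:
    """Ordered set of analysis time scales on a base sampling grid.

    Each scale tau must be an integer multiple of the base interval delta;
    scales must strictly increase.
    """

    scales: tuple[float, ...]
    base_interval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))
        if self.base_interval <= 0:
            raise ParameterError("base_interval must be > 0")
        if not self.scales:
            raise ParameterError("need at least one scale")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ParameterError("scales must strictly increase")
        for s in self.scales:
            self.stride(s)

    def stride(self, tau: float) -> int:
        """Integer stride s = tau/delta; errors if tau is off-grid."""
        ratio = tau / self.base_interval
        s = int(round(ratio))
        if s < 1 or abs(ratio - s) > 1e-9 * max(1.0, ratio):
            raise ParameterError(
                f"scale {tau} is not a positive integer multiple of "
                f"base_interval {self.base_interval}"
            )
        return s

    @classmethod
    def decades(cls, base_interval: float, n_decades: int, start: int = 0):
        """Logarithmic decade grid: strides 10^start .. 10^(start+n_decades-1)."""
        scales = [base_interval * 10**k for k in range(start, start + n_decades)]
        return cls(tuple(scales), base_interval)


@dataclass(frozen=True)
class WindowSpec:
    """One window: n frames starting at start_index, every stride frames."""

    trajectory_id: str
    start_index: int
    stride: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SizeError("window length n must be >= 2")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.start_index < 0:
            raise ParameterError("start_index must be >= 0")

    @property
    def last_index(self) -> int:
        return self.start_index + (self.n - 1) * self.stride


def admissible_starts(length: int, stride: int, n: int) -> int:
    """Number of admissible start frames: max(0, L - (n-1) s)."""
    return max(0, length - (n - 1) * stride)


def _allocate(budgets: list[int], total: int) -> list[int]:
    """Largest-remainder proportional allocation of ``total`` across capacities."""
    grand = sum(budgets)
    if grand <= total:
        return list(budgets)
    # exact integer arithmetic: quota_t = cap_t * total / grand
    alloc = [c * total // grand for c in budgets]
    remainder = [c * total % grand for c in budgets]
    # deterministic tie-break: larger remainder first, then earlier trajectory
    order = sorted(range(len(budgets)), key=lambda i: (-remainder[i], i))
    short = total - sum(alloc)
    for idx in order:
        if short == 0:
            break
        if alloc[idx] < budgets[idx]:
            alloc[idx] += 1
            short -= 1
    # if capping prevented some assignments, sweep again
    for idx in order:
        if short == 0:
            break
        take = min(budgets[idx] - alloc[idx], short)
        alloc[idx] += take
        short -= take
    return alloc


def plan_windows(
    trajectories: TrajectorySet,
    tau: float,
    m: int,
    max_windows: int = 1000,
    placement: str = "even",
    seed: int = 0,
) -> list[WindowSpec]:
    """Plan up to ``max_windows`` windows of n = 2^m points at scale tau.

    Raises
    ------
    CapacityError
        If no trajectory admits even one window at (tau, m).
    """
    if m < 1:
        raise ParameterError("window exponent m must give n = 2^m >= 2")
    n = 2**m
    delta = trajectories.sampling_interval
    stride = TimescaleGrid((tau,), delta).stride(tau)
    caps = [admissible_starts(len(s), stride, n) for s in trajectories]
    if sum(caps) == 0:
        raise CapacityError(
            f"no trajectory admits a window of n={n} at scale tau={tau} "
            f"(span {(n - 1) * stride} frames)"
        )
    if max_windows < 1:
        raise ParameterError("max_windows must be >= 1")
    alloc = _allocate(caps, max_windows)

    plans: list[WindowSpec] = []
    rng = np.random.default_rng(seed) if placement == "random" else None
    for series, cap, w in zip(trajectories, caps, alloc):
        if w == 0:
            continue
        if placement == "even":
            starts = np.unique(np.round(np.arange(w) * cap / w).astype(np.int64))
        elif placement == "random":
            starts = np.sort(rng.choice(cap, size=w, replace=False))
        else:
            raise ParameterError(f"unknown placement mode {placement!r}")
        plans.extend(
            WindowSpec(series.trajectory_id, int(st), stride, n) for st in starts
        )
    return plans


def extract(series: EnergySeries, w: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pull the (e_p, e_pw) subsequences of a window as fresh copies."""
    if w.last_index >= len(series):
        raise IndexError(
            f"window [{w.start_index}:{w.last_index}] exceeds series "
            f"length {len(series)}"
        )
    idx = w.start_index + w.stride * np.arange(w.n)
    return series.e_p[idx].copy(), series.e_pw[idx].copy()


def plan_to_tsv(plans: list[WindowSpec], path) -> None:
    """Export a window plan for audit (trajectory_id, start_index, stride, n)."""
    with open(path, "w") as fh:
        fh.write("trajectory_id\tstart_index\tstride\tn\n")
        for w in plans:
            fh.write(f"{w.trajectory_id}\t{w.start_index}\t{w.stride}\t{w.n}\n")
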