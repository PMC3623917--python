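"""Containers for energy time series.

An :class:`EnergySeries` holds the two potential-energy components analysed
throughout the package — the protein self energy ``e_p`` and the
protein-water interaction energy ``e_pw``, both in kcal/mol — sampled on a
uniform time grid.  Their sum, the total energy of the solvated-protein
potential-energy surface, is always derived on demand (``e_tot``) and never
stored, so that the variance-decomposition identity

    Var(E_tot) = Var(E_p) + Var(E_p-w) + 2 Cov(E_p, E_p-w)

remains a testable statement about the data rather than an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SizeError


@dataclass
class EnergySeries:
    """Uniform-grid time series of the two energy components for one trajectory.

    Parameters
    ----------
    trajectory_id:
        Free-form label identifying the trajectory.
    sampling_interval:
        Grid spacing delta between consecutive frames (abstract time units).
    e_p, e_pw:
        Protein self energy and protein-water interaction energy per frame,
        kcal/mol.  Must be equal-length, finite, and hold at least 2 frames.
    """

    trajectory_id: str
    sampling_interval: float
    e_p: np.ndarray
    e_pw: np.ndarray

    def __post_init__(self) -> None:
        self.e_p = np.asarray(self.e_p, dtype=np.float64)
        self.e_pw = np.asarray(self.e_pw, dtype=np.float64)
        if self.sampling_interval <= 0:
            raise ParameterError("sampling_interval must be > 0")
        if self.e_p.ndim != 1 or self.e_pw.ndim != 1:
            raise SizeError("energy series must be one-dimensional")
        if len(self.e_p) != len(self.e_pw):
            raise SizeError(
                f"e_p and e_pw lengths differ: {len(self.e_p)} != {len(self.e_pw)}"
            )
        if len(self.e_p) < 2:
            raise SizeError("an energy series needs at least 2 frames")
        if not (np.isfinite(self.e_p).all() and np.isfinite(self.e_pw).all()):
            raise ParameterError("energy series contain non-finite values")

    def __len__(self) -> int:
        return len(self.e_p)

    @property
    def e_tot(self) -> np.ndarray:
        """Total energy E_p + E_p-w, computed on demand."""
        return self.e_p + self.e_pw

    @property
    def times(self) -> np.ndarray:
        """Frame times t_i = i * delta."""
        return np.arange(len(self)) * self.sampling_interval


@dataclass
class TrajectorySet:
    """A collection of :class:`EnergySeries` sharing one sampling interval.

    Member lengths may differ (the study design this mirrors mixed long,
    sparsely saved trajectories with short, densely saved ones — but each
    set analysed together shares a grid spacing).
    """

    series: list[EnergySeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.series:
            raise SizeError("TrajectorySet needs at least one series")
        d0 = self.series[0].sampling_interval
        for s in self.series[1:]:
            if s.sampling_interval != d0:
                raise ParameterError(
                    "all series in a TrajectorySet must share sampling_interval"
                )

    @property
    def sampling_interval(self) -> float:
        return self.series[0].sampling_interval

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, i):
        return self.series[i]
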