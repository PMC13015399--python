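"""Time-series container shared by the ProSeD simulator and the ODE engine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "average_trajectories"]


@dataclass
class Trajectory:
    """Frequency tensors over time for one trial (or one ODE solution).

    ``freqs[t, g, p]`` is the population fraction of genotype ``g`` with
    phenotype ``p`` at record ``t``; every slice sums to 1.  ``dilutions``
    holds the serial-dilution index (ODE output uses the record index) and
    ``times`` the corresponding continuous time ``t = dilution * dt``.
    """

    times: np.ndarray              # (T,)
    freqs: np.ndarray              # (T, G, P)
    mean_fitness: np.ndarray       # (T,)
    dilutions: np.ndarray = None   # (T,) int
    trial: int | str = 0
    seed: int | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mean_fitness = np.asarray(self.mean_fitness, dtype=float)
        if self.dilutions is None:
            self.dilutions = np.arange(len(self.times))
        self.dilutions = np.asarray(self.dilutions)

    @property
    def n_records(self) -> int:
        return self.freqs.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.freqs.shape[1], self.freqs.shape[2]

    def validate(self, atol: float = 1e-12) -> None:
        sums = self.freqs.sum(axis=(1, 2))
        if not np.allclose(sums, 1.0, atol=atol, rtol=0):
            raise ValueError(
                f"frequency tensors drift off the simplex (max |sum-1| = "
                f"{np.abs(sums - 1).max():.3e})")
        if self.freqs.min() < -atol or self.freqs.max() > 1 + atol:
            raise ValueError("frequencies outside [0, 1]")


def average_trajectories(trajs: list[Trajectory]):
    """Ensemble mean and standard error across equally-sampled trials.

    Returns ``(times, mean_freqs, se_freqs)`` where the standard error is
    over trials (ddof=1); with a single trial the SE is zero.
    """
    if not trajs:
        raise ValueError("no trajectories to average")
    times = trajs[0].times
    stack = np.stack([t.freqs for t in trajs])  # (trials, T, G, P)
    for t in trajs[1:]:
        if not np.array_equal(t.times, times):
            raise ValueError("trajectories are not sampled at matched times")
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        se = np.zeros_like(mean)
    return times, mean, se
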