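"""ProSeD: agent-based Probabilistic Serial Dilution simulation.

A discrete-time, overlapping-generation simulator for finite populations
evolving under a probabilistic genotype-phenotype map.  Each step of
duration ``dt``:

1. every individual of phenotype ``p`` spawns one offspring with
   probability ``dt * X(p)`` (parents persist);
2. each offspring's genotype is drawn from the parent's replication-
   mutation row ``mu[g, :]``;
3. each offspring's phenotype is drawn from ``phi[h, k, :]`` — new
   genotype ``h``, parental phenotype ``k``;
4. every individual spontaneously mutates with probability
   ``dt * R(p)``; the new genotype comes from ``m[g, :]`` and the
   phenotype is re-drawn through ``phi`` of the new genotype;
5. every individual switches phenotype with probability ``dt * S(p)``,
   the target drawn from ``sigma[g, k, :]``;
6. the pooled population is diluted back to exactly ``N`` individuals by
   uniform sampling without replacement (multivariate hypergeometric) —
   the numerical analogue of pipetting an aliquot of broth.

Death occurs only through dilution.  The within-step event order
(reproduce -> spontaneous mutation -> SPS -> dilute) is fixed for
reproducibility; all per-event probabilities are O(dt), so the order is
immaterial in the small-``dt`` limit the deterministic theory describes.

Randomness comes from a counter-based Philox generator; trial ``k`` of a
run uses the stream ``SeedSequence(base_seed, spawn_key=(k,))`` so trials
are mutually independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PrGPModel
from .trajectory import Trajectory, average_trajectories

__all__ = ["PopulationState", "prosed_step", "run_prosed",
           "detect_equilibration", "default_dt"]


@dataclass
class PopulationState:
    """Integer counts ``n_g(p)`` of every genotype-phenotype pair."""

    counts: np.ndarray   # (G, P) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a G x P matrix")
        if self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        return self.counts / self.total


def default_dt(model: PrGPModel) -> float:
    """Step size keeping per-step reproduction probabilities below 0.5."""
    xmax = float(model.fitness.max())
    if xmax <= 0:
        return 1.0
    return 1.0 / (2.0 * xmax)


def _check_dt(model: PrGPModel, dt: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, rate in (("X", model.fitness), ("R", model.spont_rate),
                       ("S", model.sps_rate)):
        if dt * float(rate.max(initial=0.0)) > 1.0 + 1e-12:
            raise ValueError(
                f"dt * max({name}) = {dt * rate.max():.3g} exceeds 1")


def prosed_step(state: PopulationState, model: PrGPModel, dt: float,
                rng: np.random.Generator) -> PopulationState:
    """Advance the population by one dilution cycle of duration ``dt``."""
    _check_dt(model, dt)
    counts = state.counts
    N = state.total
    if N < 1:
        raise ValueError("empty population")
    G, P = model.shape
    X, mu, phi = model.fitness, model.repl_mutation, model.phenotype_noise
    R, m = model.spont_rate, model.spont_mutation
    S, sigma = model.sps_rate, model.sps_matrix

    pool = counts.copy()

    # 1-3: reproduction with genotype mutation and phenotype noise at birth.
    if np.any(X > 0):
        births = rng.binomial(counts, np.minimum(dt * X, 1.0)[None, :])
        pending = np.zeros((G, P), dtype=np.int64)  # (new genotype, parent k)
        for g in range(G):
            for k in range(P):
                b = int(births[g, k])
                if b:
                    pending[:, k] += rng.multinomial(b, mu[g])
        for h in range(G):
            for k in range(P):
                b = int(pending[h, k])
                if b:
                    pool[h] += rng.multinomial(b, phi[h, k])

    # 4: spontaneous mutation (parents and offspring alike); the phenotype
    # is re-drawn through phi of the new genotype.
    if np.any(R > 0):
        muts = rng.binomial(pool, np.minimum(dt * R, 1.0)[None, :])
        pool -= muts
        for g in range(G):
            for k in range(P):
                b = int(muts[g, k])
                if b:
                    targets = rng.multinomial(b, m[g])
                    for h in range(G):
                        if targets[h]:
                            pool[h] += rng.multinomial(int(targets[h]),
                                                       phi[h, k])

    # 5: SPS — lifetime phenotype switching, decoupled from replication.
    if np.any(S > 0):
        switch = rng.binomial(pool, np.minimum(dt * S, 1.0)[None, :])
        pool -= switch
        for g in range(G):
            for k in range(P):
                b = int(switch[g, k])
                if b:
                    pool[g] += rng.multinomial(b, sigma[g, k])

    # 6: dilution to exactly N (uniform, without replacement).
    total = int(pool.sum())
    if total > N:
        kept = rng.multivariate_hypergeometric(pool.ravel(), N)
        pool = np.asarray(kept, dtype=np.int64).reshape(G, P)
    return PopulationState(counts=pool)


def _trial_rng(base_seed: int, trial: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(trial,))
    return np.random.Generator(np.random.Philox(ss))


def run_prosed(model: PrGPModel,
               init: PopulationState | np.ndarray,
               n_dilutions: int,
               dt: float | None = None,
               n_trials: int = 1,
               base_seed: int = 0) -> list[Trajectory]:
    """Run independent ProSeD trials and record every dilution.

    ``init`` is either a :class:`PopulationState` (shared by all trials)
    or a frequency tensor, multinomially sampled to counts per trial.
    Each trial uses an independent, reproducible Philox substream derived
    from ``(base_seed, trial)``.  Trajectories contain ``n_dilutions + 1``
    records (the initial state plus one per dilution) with continuous
    time ``t = dilution * dt``.
    """
    if n_dilutions < 1:
        raise ValueError("n_dilutions must be >= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if dt is None:
        dt = default_dt(model)
    _check_dt(model, dt)
    G, P = model.shape

    from_freqs = not isinstance(init, PopulationState)
    if from_freqs:
        f0 = np.asarray(init, dtype=float)
        if f0.shape != (G, P):
            raise ValueError(f"init shape {f0.shape} != model shape {(G, P)}")
        if abs(f0.sum() - 1.0) > 1e-9 or f0.min() < 0:
            raise ValueError("init frequencies must lie on the simplex")
        if model.pop_size is None:
            raise ValueError("model.pop_size required to sample counts "
                             "from frequencies")
        N = int(model.pop_size)
    else:
        if init.counts.shape != (G, P):
            raise ValueError("init counts shape does not match the model")
        N = init.total
        if model.pop_size is not None and N != model.pop_size:
            raise ValueError(
                f"init total {N} != model.pop_size {model.pop_size}")

    trajectories = []
    for trial in range(n_trials):
        rng = _trial_rng(base_seed, trial)
        if from_freqs:
            counts = rng.multinomial(N, f0.ravel()).reshape(G, P)
            state = PopulationState(counts=counts)
        else:
            state = PopulationState(counts=init.counts.copy())
        freqs = np.empty((n_dilutions + 1, G, P))
        freqs[0] = state.frequencies()
        for d in range(1, n_dilutions + 1):
            state = prosed_step(state, model, dt, rng)
            freqs[d] = state.frequencies()
        times = np.arange(n_dilutions + 1) * dt
        xbar = np.einsum("tgp,p->t", freqs, model.fitness)
        trajectories.append(Trajectory(
            times=times, freqs=freqs, mean_fitness=xbar,
            dilutions=np.arange(n_dilutions + 1), trial=trial,
            seed=base_seed, dt=dt))
    return trajectories


def detect_equilibration(traj: Trajectory | np.ndarray,
                         reference: np.ndarray,
                         tol: float) -> int | None:
    """First dilution index after which the trajectory stays within
    ``tol`` (sup-norm) of ``reference`` for all later recorded times.

    Returns ``None`` if the trajectory never settles inside the band.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    freqs = traj.freqs if isinstance(traj, Trajectory) else np.asarray(traj)
    reference = np.asarray(reference, dtype=float)
    dist = np.abs(freqs - reference[None]).max(
        axis=tuple(range(1, freqs.ndim)))
    inside = dist < tol
    if not inside[-1]:
        return None
    # last index that is outside, +1; 0 if never outside
    outside = np.nonzero(~inside)[0]
    return int(outside[-1] + 1) if outside.size else 0
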