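"""Probabilistic genotype-phenotype landscape specification.

A :class:`PrGPModel` bundles everything needed to evolve a haploid asexual
population whose genotypes map *probabilistically* onto phenotypes:

* a Malthusian fitness ``X(p)`` per phenotype,
* per-replication genotype mutation probabilities ``mu[g, h]``,
* the phenotype-noise-at-birth tensor ``phi[g, k, p]`` — the probability
  that an offspring of genotype ``g`` born to a parent of phenotype ``k``
  is assigned phenotype ``p``,
* spontaneous (lifetime) mutation rates ``R(p)`` and target probabilities
  ``m[g, h]``,
* stochastic phenotype switching (SPS) rates ``S(p)`` and target
  probabilities ``sigma[g, k, p]``.

The same object drives the agent-based ProSeD simulator (finite population
``pop_size``) and the deterministic infinite-population integrator.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PrGPModel",
    "validate_model",
    "build_two_by_two",
    "build_bridge",
    "shift_fitness",
]

_ATOL = 1e-12


def _offdiag_uniform(n: int) -> np.ndarray:
    """Row-stochastic matrix, uniform over off-diagonal targets (zero diag).

    For ``n == 1`` the off-diagonal simplex is empty and the single row is
    all-zero; callers must pair this with a zero rate.
    """
    if n == 1:
        return np.zeros((1, 1))
    out = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class PrGPModel:
    """Full probabilistic genotype -> phenotype -> fitness specification."""

    genotypes: list[str]
    phenotypes: list[str]
    fitness: np.ndarray            # (P,)   X(p), per unit time, >= 0
    repl_mutation: np.ndarray      # (G,G)  mu[g,h], rows sum to 1 (incl. self)
    phenotype_noise: np.ndarray    # (G,P,P) phi[g,k,p], sum over p = 1
    spont_rate: np.ndarray         # (P,)   R(p)
    spont_mutation: np.ndarray     # (G,G)  m[g,h], zero diag, rows sum to 1
    sps_rate: np.ndarray           # (P,)   S(p)
    sps_matrix: np.ndarray         # (G,P,P) sigma[g,k,p], zero diag in (k,p)
    pop_size: int | None = None    # N (simulator only; None = infinite)
    time_scale: float = 1.0        # dilution-step -> model-time conversion

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        self.repl_mutation = np.asarray(self.repl_mutation, dtype=float)
        self.phenotype_noise = np.asarray(self.phenotype_noise, dtype=float)
        self.spont_rate = np.asarray(self.spont_rate, dtype=float)
        self.spont_mutation = np.asarray(self.spont_mutation, dtype=float)
        self.sps_rate = np.asarray(self.sps_rate, dtype=float)
        self.sps_matrix = np.asarray(self.sps_matrix, dtype=float)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genotypes, self.n_phenotypes)

    def copy(self) -> "PrGPModel":
        return copy.deepcopy(self)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        """Plain-Python dict using the config-file key names."""
        d = {
            "genotypes": list(self.genotypes),
            "phenotypes": list(self.phenotypes),
            "fitness": self.fitness.tolist(),
            "mu": self.repl_mutation.tolist(),
            "phi": self.phenotype_noise.tolist(),
            "R": self.spont_rate.tolist(),
            "m": self.spont_mutation.tolist(),
            "S": self.sps_rate.tolist(),
            "sigma": self.sps_matrix.tolist(),
            "N": self.pop_size,
            "time_scale": self.time_scale,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PrGPModel":
        known = {"genotypes", "phenotypes", "fitness", "mu", "phi", "R", "m",
                 "S", "sigma", "N", "time_scale"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        required = {"genotypes", "phenotypes", "fitness", "mu", "phi"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"missing model keys: {sorted(missing)}")
        genotypes = [str(g) for g in d["genotypes"]]
        phenotypes = [str(p) for p in d["phenotypes"]]
        G, P = len(genotypes), len(phenotypes)
        model = cls(
            genotypes=genotypes,
            phenotypes=phenotypes,
            fitness=np.asarray(d["fitness"], dtype=float),
            repl_mutation=np.asarray(d["mu"], dtype=float),
            phenotype_noise=np.asarray(d["phi"], dtype=float),
            spont_rate=np.asarray(d.get("R", np.zeros(P)), dtype=float),
            spont_mutation=np.asarray(d.get("m", _offdiag_uniform(G)),
                                      dtype=float),
            sps_rate=np.asarray(d.get("S", np.zeros(P)), dtype=float),
            sps_matrix=np.asarray(
                d.get("sigma",
                      np.broadcast_to(_offdiag_uniform(P), (G, P, P)).copy()),
                dtype=float),
            pop_size=(None if d.get("N") is None else int(d["N"])),
            time_scale=float(d.get("time_scale", 1.0)),
        )
        violations = validate_model(model)
        if violations:
            raise ValueError("invalid model: " + "; ".join(violations))
        return model

    def hash(self) -> str:
        """Stable content hash (stamped into run metadata sidecars)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PrGPModel):
            return NotImplemented
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if a.shape != b.shape or not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


def validate_model(model: PrGPModel, atol: float = _ATOL) -> list[str]:
    """Check every structural and probabilistic invariant of the model.

    Returns an empty list iff the model is valid.  Dimension mismatches are
    reported first (probability checks on misshapen tensors are meaningless);
    each probability violation names the offending index.
    """
    v: list[str] = []
    G, P = model.shape
    if G < 1 or P < 1:
        return [f"model must have G>=1 and P>=1, got G={G}, P={P}"]

    structural = []
    if model.fitness.shape != (P,):
        structural.append(f"fitness shape {model.fitness.shape} != ({P},)")
    if model.repl_mutation.shape != (G, G):
        structural.append(
            f"repl_mutation shape {model.repl_mutation.shape} != ({G}, {G})")
    if model.phenotype_noise.shape != (G, P, P):
        structural.append(
            f"phenotype_noise shape {model.phenotype_noise.shape} "
            f"!= ({G}, {P}, {P})")
    if model.spont_rate.shape != (P,):
        structural.append(f"spont_rate shape {model.spont_rate.shape} != ({P},)")
    if model.spont_mutation.shape != (G, G):
        structural.append(
            f"spont_mutation shape {model.spont_mutation.shape} != ({G}, {G})")
    if model.sps_rate.shape != (P,):
        structural.append(f"sps_rate shape {model.sps_rate.shape} != ({P},)")
    if model.sps_matrix.shape != (G, P, P):
        structural.append(
            f"sps_matrix shape {model.sps_matrix.shape} != ({G}, {P}, {P})")
    if structural:
        return structural

    arrays = {
        "fitness": model.fitness, "repl_mutation": model.repl_mutation,
        "phenotype_noise": model.phenotype_noise,
        "spont_rate": model.spont_rate, "spont_mutation": model.spont_mutation,
        "sps_rate": model.sps_rate, "sps_matrix": model.sps_matrix,
    }
    for name, arr in arrays.items():
        if not np.all(np.isfinite(arr)):
            v.append(f"{name} contains non-finite entries")
        elif np.any(arr < -atol):
            idx = np.unravel_index(int(np.argmin(arr)), arr.shape)
            v.append(f"{name}{list(idx)} = {arr[idx]} is negative")
    if v:
        return v

    for g in range(G):
        s = model.repl_mutation[g].sum()
        if abs(s - 1.0) > atol:
            v.append(f"repl_mutation row g={g} sums to {s}, expected 1")
    for g in range(G):
        for k in range(P):
            s = model.phenotype_noise[g, k].sum()
            if abs(s - 1.0) > atol:
                v.append(
                    f"phenotype_noise row (g={g}, k={k}) sums to {s}, "
                    "expected 1")
    # Spontaneous-mutation targets: zero diagonal, rows sum to 1 over h != g.
    # An all-zero row is tolerated only while every R(p) is zero (process off).
    spont_active = bool(np.any(model.spont_rate > 0))
    for g in range(G):
        if abs(model.spont_mutation[g, g]) > atol:
            v.append(f"spont_mutation self-transition m[{g},{g}] = "
                     f"{model.spont_mutation[g, g]} must be 0")
        s = model.spont_mutation[g].sum()
        if abs(s - 1.0) > atol and (spont_active or s > atol):
            v.append(f"spont_mutation row g={g} sums to {s}, expected 1")
    # SPS targets: zero diagonal, each (g,k) row sums to 1 over p != k.
    for g in range(G):
        for k in range(P):
            if abs(model.sps_matrix[g, k, k]) > atol:
                v.append(f"sps_matrix self-transition sigma[{g},{k},{k}] = "
                         f"{model.sps_matrix[g, k, k]} must be 0")
            s = model.sps_matrix[g, k].sum()
            if abs(s - 1.0) > atol and (model.sps_rate[k] > 0 or s > atol):
                v.append(
                    f"sps_matrix row (g={g}, k={k}) sums to {s}, expected 1")
    if model.pop_size is not None and model.pop_size < 1:
        v.append(f"pop_size = {model.pop_size} must be a positive integer")
    return v


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value} must lie in [0, 1]")


def build_two_by_two(pi0: float, pi1: float, mu: float,
                     X0: float, X1: float, N: int | None = None) -> PrGPModel:
    """Two-genotype / two-phenotype model with parent-independent noise.

    ``pi_g`` is the probability that genotype ``g`` maps onto phenotype 0
    (the fitter one by the ``X0 >= X1`` convention); genotype mutation is
    symmetric with per-replication probability ``mu``.  Spontaneous mutation
    and SPS are off.
    """
    _check_prob("pi0", pi0)
    _check_prob("pi1", pi1)
    _check_prob("mu", mu)
    if X0 < 0 or X1 < 0:
        raise ValueError("fitnesses must be non-negative")
    phi = np.empty((2, 2, 2))
    phi[0, :, 0] = pi0
    phi[0, :, 1] = 1.0 - pi0
    phi[1, :, 0] = pi1
    phi[1, :, 1] = 1.0 - pi1
    return PrGPModel(
        genotypes=["0", "1"],
        phenotypes=["0", "1"],
        fitness=np.array([X0, X1]),
        repl_mutation=np.array([[1.0 - mu, mu], [mu, 1.0 - mu]]),
        phenotype_noise=phi,
        spont_rate=np.zeros(2),
        spont_mutation=_offdiag_uniform(2),
        sps_rate=np.zeros(2),
        sps_matrix=np.broadcast_to(_offdiag_uniform(2), (2, 2, 2)).copy(),
        pop_size=N,
    )


def build_bridge(pi: float, gamma: float, mu: float, X0: float,
                 N: int | None = None) -> PrGPModel:
    """Three-genotype / two-phenotype fitness-valley model.

    Genotypes 0 and 2 map deterministically onto the fit phenotype 0; the
    intermediate genotype 1 maps with low probability ``pi`` onto the
    high-fitness "bridge" phenotype and otherwise onto the "valley"
    phenotype of fitness ``gamma * X0``.  Mutation is nearest-neighbour on
    the genotype chain 0 - 1 - 2: genotypes 0 and 2 send probability ``mu``
    to genotype 1; genotype 1 sends ``mu/2`` to each neighbour.
    """
    _check_prob("pi", pi)
    _check_prob("mu", mu)
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma = {gamma} must lie in (0, 1]")
    if X0 < 0:
        raise ValueError("X0 must be non-negative")
    phi = np.empty((3, 2, 2))
    phi[0, :, 0] = 1.0
    phi[0, :, 1] = 0.0
    phi[1, :, 0] = pi
    phi[1, :, 1] = 1.0 - pi
    phi[2, :, 0] = 1.0
    phi[2, :, 1] = 0.0
    mu_mat = np.array([
        [1.0 - mu, mu, 0.0],
        [mu / 2.0, 1.0 - mu, mu / 2.0],
        [0.0, mu, 1.0 - mu],
    ])
    return PrGPModel(
        genotypes=["0", "1", "2"],
        phenotypes=["0", "1"],
        fitness=np.array([X0, gamma * X0]),
        repl_mutation=mu_mat,
        phenotype_noise=phi,
        spont_rate=np.zeros(2),
        spont_mutation=_offdiag_uniform(3),
        sps_rate=np.zeros(2),
        sps_matrix=np.broadcast_to(_offdiag_uniform(2), (3, 2, 2)).copy(),
        pop_size=N,
    )


def shift_fitness(model: PrGPModel, A: float) -> PrGPModel:
    """Copy of ``model`` with every phenotype fitness shifted by ``A``.

    Under a deterministic genotype-phenotype map this leaves the
    infinite-population frequency dynamics untouched (only relative fitness
    matters); under a probabilistic map it does not — replication-coupled
    phenotype noise scales with absolute fitness.
    """
    shifted = model.fitness + A
    if np.any(shifted < 0):
        raise ValueError(
            f"shift by {A} produces negative fitness (min {shifted.min()})")
    out = model.copy()
    out.fitness = shifted
    return out
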