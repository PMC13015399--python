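"""Deterministic (infinite-population) integrator of the replicator-
mutator dynamics with phenotypic uncertainty.

The state is the frequency tensor ``f[g, p]`` on the simplex.  The time
derivative is the sum of five terms — selection against the mean fitness,
mutation upon replication, spontaneous (lifetime) mutation, phenotype noise
at birth, and stochastic phenotype switching — each of which conserves
total frequency, so the right-hand side sums to zero identically.  The
finite-population genetic-drift noise is *not* integrated here; it is
realized only through the agent-based ProSeD sampling in
:mod:`propgen.simulate`.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import PrGPModel
from .trajectory import Trajectory

__all__ = ["propgen_rhs", "propgen_rhs_terms", "mean_fitness", "integrate",
           "fixed_point"]

_SIMPLEX_ATOL = 1e-8


def _check_simplex(f: np.ndarray, atol: float = _SIMPLEX_ATOL) -> None:
    s = f.sum()
    if abs(s - 1.0) > atol:
        raise ValueError(f"state off the simplex: sum = {s}")
    if f.min() < -atol:
        raise ValueError(f"negative frequency: min = {f.min()}")


def mean_fitness(f: np.ndarray, model: PrGPModel) -> float:
    """Population mean Malthusian fitness  Xbar = sum_gp f[g,p] X(p)."""
    f = np.asarray(f, dtype=float)
    return float(f.sum(axis=0) @ model.fitness)


def propgen_rhs_terms(f: np.ndarray, model: PrGPModel) -> dict[str, np.ndarray]:
    """The five deterministic terms of df/dt, separately, as (G, P) arrays.

    Keys: ``selection``, ``repl_mutation``, ``spontaneous``, ``birth_noise``,
    ``sps``.  Each term individually sums to zero over (g, p).
    """
    f = np.asarray(f, dtype=float)
    X = model.fitness
    mu = model.repl_mutation
    phi = model.phenotype_noise
    R = model.spont_rate
    m = model.spont_mutation
    S = model.sps_rate
    sigma = model.sps_matrix
    G, P = model.shape

    Xbar = mean_fitness(f, model)
    selection = f * (X[None, :] - Xbar)

    # Mutation upon replication: sum_{h != g} sum_k phi[g,k,p] X(k)
    #   (f[h,k] mu[h,g] - f[g,k] mu[g,h])
    mu_diag = np.diag(mu)
    inflow = mu.T @ f - mu_diag[:, None] * f          # (g, k)
    outflow = f * (mu.sum(axis=1) - mu_diag)[:, None]  # (g, k)
    repl = np.einsum("gkp,k,gk->gp", phi, X, inflow - outflow)

    # Spontaneous mutation: inflow redraws the phenotype through phi of the
    # new genotype; outflow leaves at rate R(p) (m has zero diagonal).
    if np.any(R > 0):
        A = m.T @ (f * R[None, :])                     # (g, k)
        spont = (np.einsum("gkp,gk->gp", phi, A)
                 - f * R[None, :] * m.sum(axis=1)[:, None])
    else:
        spont = np.zeros((G, P))

    # Phenotype noise at birth (within-genotype, replication-coupled):
    # sum_{k != p} [X(k) f[g,k] phi[g,k,p] - X(p) f[g,p] phi[g,p,k]]
    phi_diag = np.einsum("gpp->gp", phi)
    birth_in = np.einsum("gkp,k,gk->gp", phi, X, f) - phi_diag * X[None, :] * f
    birth_out = X[None, :] * f * (1.0 - phi_diag)
    birth = birth_in - birth_out

    # SPS (lifetime, fitness-decoupled): sigma has zero diagonal in (k, p).
    if np.any(S > 0):
        sps = (np.einsum("gkp,k,gk->gp", sigma, S, f)
               - S[None, :] * f * sigma.sum(axis=2))
    else:
        sps = np.zeros((G, P))

    return {"selection": selection, "repl_mutation": repl,
            "spontaneous": spont, "birth_noise": birth, "sps": sps}


def propgen_rhs(f: np.ndarray, model: PrGPModel) -> np.ndarray:
    """Deterministic time derivative of the frequency tensor ``f``.

    Raises if ``f`` is off the simplex beyond 1e-8.  The returned tensor
    sums to zero (frequency conservation).
    """
    f = np.asarray(f, dtype=float)
    if f.shape != model.shape:
        raise ValueError(f"state shape {f.shape} != model shape {model.shape}")
    _check_simplex(f)
    terms = propgen_rhs_terms(f, model)
    return sum(terms.values())


def _rhs_unchecked(f: np.ndarray, model: PrGPModel) -> np.ndarray:
    return sum(propgen_rhs_terms(f, model).values())


def integrate(model: PrGPModel, f0: np.ndarray, t_max: float,
              record_every: float | None = None,
              t_eval: np.ndarray | None = None,
              rtol: float = 1e-10, atol: float = 1e-13) -> Trajectory:
    """Integrate the deterministic dynamics from ``f0`` to ``t_max``.

    Uses an adaptive 8th-order Runge-Kutta scheme (DOP853); recorded states
    are renormalized onto the simplex (the raw drift is asserted to be
    tiny).  ``record_every`` sets a uniform output grid; alternatively pass
    explicit ``t_eval`` times.
    """
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != model.shape:
        raise ValueError(f"f0 shape {f0.shape} != model shape {model.shape}")
    _check_simplex(f0)
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    G, P = model.shape
    if t_eval is None:
        if record_every is None:
            record_every = t_max / 200.0
        n = int(np.floor(t_max / record_every + 1e-9))
        t_eval = np.linspace(0.0, n * record_every, n + 1)
        if t_eval[-1] < t_max - 1e-12:
            t_eval = np.append(t_eval, t_max)
    t_eval = np.asarray(t_eval, dtype=float)

    def fun(t, y):
        # Evaluate on the normalized state and relax the sum toward 1:
        # identical to the raw rhs on the simplex, but accumulated solver
        # error in the conserved sum decays instead of compounding.
        s = y.sum()
        g = _rhs_unchecked((y / s).reshape(G, P), model).ravel()
        return g - (s - 1.0) * y

    # Cap the step at one unit of the fastest process: the DOP853 dense
    # output (used for the t_eval grid) degrades on very long steps even
    # when the endpoint error controller is satisfied.
    rate = max(float(model.fitness.max()),
               float(model.spont_rate.max(initial=0.0)),
               float(model.sps_rate.max(initial=0.0)), 1e-12)
    sol = solve_ivp(fun, (0.0, float(t_max)), f0.ravel(), method="DOP853",
                    rtol=rtol, atol=atol, t_eval=t_eval,
                    max_step=max(0.5 / rate, float(t_max) / 2000.0))
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed: {sol.message}; last good t = "
            f"{sol.t[-1] if len(sol.t) else 0.0}")
    ys = sol.y.T.reshape(-1, G, P)
    sums = ys.sum(axis=(1, 2))
    max_drift_rate = np.abs(sums - 1.0).max() / max(float(t_max), 1.0)
    if max_drift_rate > 1e-9:
        raise RuntimeError(
            f"simplex drift {max_drift_rate:.3e} per unit time exceeds 1e-9")
    ys = ys / sums[:, None, None]
    ys = np.clip(ys, 0.0, None)
    ys /= ys.sum(axis=(1, 2))[:, None, None]
    xbar = np.einsum("tgp,p->t", ys, model.fitness)
    return Trajectory(times=sol.t, freqs=ys, mean_fitness=xbar, trial="ode",
                      dt=None)


def fixed_point(model: PrGPModel, f0: np.ndarray | None = None,
                pre_integrate: float | None = None,
                tol: float = 1e-13) -> np.ndarray:
    """Numeric equilibrium reached from ``f0`` (uniform by default).

    Integrates the dynamics until the residual is small — so the solve
    lands in the basin of the *stable* equilibrium, not one of the saddle
    fixed points — then polishes with a hybrid root solve in which the
    redundant rhs component (conservation) is replaced by ``sum(f) - 1``.
    """
    G, P = model.shape
    if f0 is None:
        f0 = np.full((G, P), 1.0 / (G * P))
    f0 = np.asarray(f0, dtype=float).copy()
    rate = max(float(model.fitness.max()), float(model.spont_rate.max(
        initial=0.0)), float(model.sps_rate.max(initial=0.0)), 1e-12)
    t_chunk = 20.0 / rate if pre_integrate is None else pre_integrate
    if t_chunk > 0:
        for _ in range(12):
            f0 = integrate(model, f0, t_chunk,
                           t_eval=np.array([0.0, t_chunk]),
                           rtol=1e-10).freqs[-1]
            if np.abs(_rhs_unchecked(f0, model)).max() < 1e-9 * rate:
                break
            t_chunk *= 2.0

    def fun(y):
        r = _rhs_unchecked(y.reshape(G, P), model).ravel()
        out = np.empty_like(r)
        out[:-1] = r[:-1]
        out[-1] = y.sum() - 1.0
        return out

    sol = root(fun, f0.ravel(), method="hybr", tol=tol)
    feq = sol.x.reshape(G, P)
    resid = np.abs(_rhs_unchecked(feq, model)).max()
    if (not sol.success and resid > 1e-10) or resid > 1e-9:
        raise RuntimeError(
            f"fixed-point solve failed (residual {resid:.3e}): {sol.message}")
    feq = np.clip(feq, 0.0, None)
    return feq / feq.sum()
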