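"""Bacterial persister resuscitation dynamics.

Dormant persisters (P) wake at a time-varying stochastic-phenotype-
switching rate ``S(t) = alpha * exp(beta t)`` and partition into cells
that fail replication (F), damaged-but-replicating cells (D), or healthy
cells (H) with probabilities ``sigma_PD + sigma_PF + sigma_PH = 1``.
Damaged cells replicate at rate ``X_D``; each of their offspring is
healthy with probability ``phi_DH`` (phenotype noise at birth, coupled to
replication) and damaged otherwise.  Healthy cells replicate at ``X_H``.
No bottleneck is imposed, so the system is written for absolute
abundances ``n = (n_P, n_D, n_F, n_H)`` with no mean-fitness term:

    dn_P/dt = -S(t) n_P
    dn_D/dt = X_D (1 - phi_DH) n_D + S(t) sigma_PD n_P
    dn_F/dt = S(t) sigma_PF n_P
    dn_H/dt = X_H n_H + X_D phi_DH n_D + S(t) sigma_PH n_P

This system admits an exact closed form in terms of lower-incomplete-
gamma differences, implemented here for any real shape parameter
(including q <= 0, where the classical gamma(s, x) diverges at the origin
but the difference over [c, c e^{beta t}] with c > 0 is finite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.integrate import quad, solve_ivp

__all__ = ["PersisterParams", "PersisterDerived", "PersisterSolution",
           "persister_rhs", "persister_closed_form", "persister_integrate",
           "normalize_trajectories", "gammainc_diff"]

STATE_NAMES = ("P", "D", "F", "H")


@dataclass(frozen=True)
class PersisterParams:
    alpha: float                 # resuscitation-rate amplitude, > 0
    beta: float                  # resuscitation-rate exponent, > 0
    sigma_PD: float              # P -> D switching probability
    sigma_PF: float              # P -> F switching probability
    sigma_PH: float              # P -> H switching probability
    X_D: float                   # damaged-cell fitness, >= 0
    X_H: float                   # healthy-cell fitness, > 0
    phi_DH: float                # P(offspring of D is H), in [0, 1]
    n0: tuple = (1.0, 0.0, 0.0, 0.0)  # initial (n_P, n_D, n_F, n_H)

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        s = self.sigma_PD + self.sigma_PF + self.sigma_PH
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"switching probabilities sum to {s}, expected 1")
        if min(self.sigma_PD, self.sigma_PF, self.sigma_PH) < 0:
            raise ValueError("switching probabilities must be non-negative")
        if self.X_D < 0 or self.X_H <= 0:
            raise ValueError("require X_D >= 0 and X_H > 0")
        if not 0.0 <= self.phi_DH <= 1.0:
            raise ValueError("phi_DH must lie in [0, 1]")
        if min(self.n0) < 0:
            raise ValueError("initial abundances must be non-negative")

    @property
    def derived(self) -> "PersisterDerived":
        a = self.X_D * (1.0 - self.phi_DH)
        c = self.alpha / self.beta
        k = (self.X_D * self.phi_DH / (self.X_H - a)
             if self.X_H != a else np.inf)
        return PersisterDerived(
            a=a, c=c,
            q_D=1.0 - a / self.beta,
            q_H=1.0 - self.X_H / self.beta,
            k=k,
            B=self.sigma_PH + k * self.sigma_PD if np.isfinite(k) else np.inf,
        )

    def rate(self, t):
        """Resuscitation rate S(t) = alpha * exp(beta t)."""
        return self.alpha * np.exp(self.beta * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class PersisterDerived:
    a: float     # X_D (1 - phi_DH), damaged-cell self-renewal rate
    c: float     # alpha / beta
    q_D: float   # 1 - a / beta
    q_H: float   # 1 - X_H / beta
    k: float     # X_D phi_DH / (X_H - a)
    B: float     # sigma_PH + k sigma_PD


@dataclass
class PersisterSolution:
    times: np.ndarray        # (T,)
    abundances: np.ndarray   # (T, 4) in (P, D, F, H) order
    params: PersisterParams


def persister_rhs(t: float, n: np.ndarray,
                  params: PersisterParams) -> np.ndarray:
    """Time derivative of (n_P, n_D, n_F, n_H)."""
    n = np.asarray(n, dtype=float)
    if n.min() < -1e-12:
        raise ValueError(f"negative abundance: {n}")
    nP, nD, nF, nH = n
    S = params.alpha * np.exp(params.beta * t)
    a = params.X_D * (1.0 - params.phi_DH)
    return np.array([
        -S * nP,
        a * nD + S * params.sigma_PD * nP,
        S * params.sigma_PF * nP,
        params.X_H * nH + params.X_D * params.phi_DH * nD
        + S * params.sigma_PH * nP,
    ])


def gammainc_diff(q: float, x1: float, x2: float) -> float:
    """Lower-incomplete-gamma difference  gamma(q, x2) - gamma(q, x1)
    = integral of u^(q-1) e^(-u) du over [x1, x2], for any real q.

    Requires 0 < x1 <= x2 so the integral converges for q <= 0 as well.
    For q > 0 the regularized scipy routine is used; for q <= 0 the
    definite integral is evaluated by adaptive quadrature with a
    log-domain integrand (the integrand is monotone decreasing there).
    """
    if x1 <= 0:
        raise ValueError("x1 must be positive")
    if x2 < x1:
        return -gammainc_diff(q, x2, x1)
    if x2 == x1:
        return 0.0
    if q > 0:
        return float(special.gamma(q)
                     * (special.gammainc(q, x2) - special.gammainc(q, x1)))

    def integrand(u):
        return np.exp((q - 1.0) * np.log(u) - u)

    # Beyond u ~ 760 the integrand underflows; cap the interval there.
    hi = min(x2, max(x1, 760.0))
    if hi <= x1:
        return 0.0
    val, _ = quad(integrand, x1, hi, epsabs=1e-300, epsrel=1e-11, limit=200)
    return float(val)


def _gamma_term(q: float, c: float, beta: float, t: np.ndarray) -> np.ndarray:
    """e^c c^(-q) [gamma(q, c e^{beta t}) - gamma(q, c)] for a time grid."""
    t = np.asarray(t, dtype=float)
    x2 = c * np.exp(beta * t)
    out = np.empty_like(t)
    for i, x in np.ndenumerate(x2):
        out[i] = gammainc_diff(q, c, float(x))
    return np.exp(c) * c ** (-q) * out


def persister_closed_form(t_grid: np.ndarray,
                          params: PersisterParams) -> PersisterSolution:
    """Exact abundance trajectories on ``t_grid``.

    The removable singularity at ``X_H = a`` (where the shorthand ``k``
    blows up) is evaluated through the analytic limit — the resonant
    variation-of-parameters integral — rather than by nudging parameters.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    p = params
    d = p.derived
    nP0, nD0, nF0, nH0 = p.n0
    c, beta = d.c, p.beta

    nP = nP0 * np.exp(-c * (np.exp(beta * t) - 1.0))
    nF = nF0 + p.sigma_PF * (nP0 - nP)

    gD = _gamma_term(d.q_D, c, beta, t)
    nD = np.exp(d.a * t) * (nD0 + p.alpha * p.sigma_PD * nP0 / beta * gD)

    scale = max(p.X_H, abs(d.a), beta)
    if abs(p.X_H - d.a) > 1e-9 * scale:
        gH = _gamma_term(d.q_H, c, beta, t)
        nH = (np.exp(p.X_H * t)
              * (nH0 + d.k * nD0 + p.alpha * d.B * nP0 / beta * gH)
              - d.k * nD)
    else:
        # X_H == a: nH = e^{X_H t} [nH0 + int_0^t e^{-X_H s}
        #   (X_D phi_DH nD(s) + S(s) sigma_PH nP(s)) ds]
        nH = np.empty_like(t)
        for i, ti in np.ndenumerate(t):
            def integrand(s):
                nPs = nP0 * np.exp(-c * (np.exp(beta * s) - 1.0))
                gDs = (np.exp(c) * c ** (-d.q_D)
                       * gammainc_diff(d.q_D, c, c * np.exp(beta * s)))
                nDs = np.exp(d.a * s) * (nD0 + p.alpha * p.sigma_PD
                                         * nP0 / beta * gDs)
                Ss = p.alpha * np.exp(beta * s)
                return np.exp(-p.X_H * s) * (p.X_D * p.phi_DH * nDs
                                             + Ss * p.sigma_PH * nPs)
            val, _ = quad(integrand, 0.0, float(ti), epsrel=1e-11, limit=200)
            nH[i] = np.exp(p.X_H * ti) * (nH0 + val)

    return PersisterSolution(times=t,
                             abundances=np.stack([nP, nD, nF, nH], axis=1),
                             params=p)


def persister_integrate(t_grid: np.ndarray, params: PersisterParams,
                        rtol: float = 1e-11,
                        atol: float = 1e-12) -> PersisterSolution:
    """Adaptive ODE integration oracle for the closed form."""
    t = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(lambda s, n: persister_rhs(s, np.maximum(n, 0.0), params),
                    (0.0, float(t[-1])), np.array(params.n0, dtype=float),
                    method="DOP853", rtol=rtol, atol=atol, t_eval=t)
    if not sol.success:
        raise RuntimeError(f"persister ODE integration failed: {sol.message}")
    return PersisterSolution(times=t, abundances=sol.y.T, params=params)


def normalize_trajectories(sol: PersisterSolution) -> np.ndarray:
    """Instantaneous phenotype fractions n_i(t) / sum_j n_j(t)."""
    total = sol.abundances.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("total abundance must stay positive")
    return sol.abundances / total[:, None]
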