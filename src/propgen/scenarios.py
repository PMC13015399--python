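"""Catalog of reference scenarios and a random-model generator.

Each scenario packages a fully parameterized model, an initial state,
recommended run sizes, and machine-checkable qualitative predicates (the
phenomena the scenario exists to exhibit: buoying, bridge acceleration,
absolute-fitness dependence, transient mean-fitness decrease, persister
partitioning).  Parameter values that the underlying study setups leave
open are filled with package defaults and marked ``defaulted`` in the
scenario metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bridge as bridge_mod
from . import equilibrium as eq_mod
from . import ode as ode_mod
from . import persister as pers_mod
from . import simulate as sim_mod
from .model import PrGPModel, build_bridge, build_two_by_two, shift_fitness
from .trajectory import average_trajectories

__all__ = ["Scenario", "make_scenario", "run_scenario", "random_model",
           "SCENARIO_NAMES"]

# Defaults for quantities the reference setups do not pin down.
DEFAULT_X0 = 0.1
DEFAULT_X1 = 0.05
DEFAULT_MU = 0.05
DEFAULT_N = 10_000

SCENARIO_NAMES = ("buoy", "phase", "bridge", "absolute_fitness",
                  "mean_fitness_decrease", "persister")


@dataclass
class Scenario:
    name: str
    kind: str                    # "population" | "phase" | "persister"
    model: PrGPModel | None = None
    persister: pers_mod.PersisterParams | None = None
    init: np.ndarray | None = None       # frequency tensor
    dt: float | None = None
    n_dilutions: int = 0
    n_trials: int = 1
    t_max: float = 0.0
    metadata: dict = field(default_factory=dict)
    predicates: list = field(default_factory=list)  # (description, fn)

    def check(self, results: dict) -> list[str]:
        """Evaluate every predicate; returns descriptions of failures."""
        return [desc for desc, fn in self.predicates if not fn(results)]


def make_scenario(name: str, **variant) -> Scenario:
    """Build a catalog scenario; unknown names raise with the catalog list.

    Variants: ``buoy(one_minus_pi1=...)``, ``phase(pi0=...)``,
    ``bridge(pi=...)``, ``absolute_fitness(deterministic=..., A=...)``.
    """
    builders = {
        "buoy": _buoy, "phase": _phase, "bridge": _bridge,
        "absolute_fitness": _absolute_fitness,
        "mean_fitness_decrease": _mean_fitness_decrease,
        "persister": _persister,
    }
    if name not in builders:
        raise ValueError(
            f"unknown scenario {name!r}; catalog: {', '.join(SCENARIO_NAMES)}")
    return builders[name](**variant)


def _buoy(one_minus_pi1: float = 0.5) -> Scenario:
    """Two-genotype buoy competition: pi0 = 0.4, sweeping 1 - pi1."""
    if one_minus_pi1 not in (0.5, 0.4, 0.3, 0.2, 0.1):
        raise ValueError("one_minus_pi1 must be in {0.5, 0.4, 0.3, 0.2, 0.1}")
    pi0, pi1 = 0.4, 1.0 - one_minus_pi1
    model = build_two_by_two(pi0, pi1, DEFAULT_MU, DEFAULT_X0, DEFAULT_X1,
                             N=DEFAULT_N)
    exact = eq_mod.equilibrium_2x2(pi0, pi1, DEFAULT_MU, DEFAULT_X0,
                                   DEFAULT_X1)
    preds = [
        ("ODE settles within the 0.02 equilibration band of the exact "
         "equilibrium over the 250-dilution horizon",
         lambda r: np.abs(r["ode"].freqs[-1].ravel()
                          - r["equilibrium"].feq).max() < 0.02),
    ]
    if one_minus_pi1 >= 0.2:
        preds.append((
            "red pair f1(1) outranks blue pair f0(0) at equilibrium",
            lambda r: r["equilibrium"].feq[3] > r["equilibrium"].feq[0]))
    else:
        preds.append((
            "blue and red equilibrium frequencies within 0.05",
            lambda r: abs(r["equilibrium"].feq[3]
                          - r["equilibrium"].feq[0]) < 0.05))
    return Scenario(
        name=f"buoy[1-pi1={one_minus_pi1}]", kind="population", model=model,
        init=np.full((2, 2), 0.25), dt=1.0, n_dilutions=250, n_trials=10,
        t_max=250.0,
        metadata={"pi0": pi0, "pi1": pi1, "mu": DEFAULT_MU,
                  "X0": DEFAULT_X0, "X1": DEFAULT_X1, "N": DEFAULT_N,
                  "defaulted": ["X0", "X1", "mu", "dt", "N"],
                  "equilibrium": exact},
        predicates=preds)


def _phase(pi0: float = 0.4) -> Scenario:
    model = build_two_by_two(pi0, 0.5, DEFAULT_MU, DEFAULT_X0, DEFAULT_X1,
                             N=DEFAULT_N)
    preds = [("at most 12 ordering sectors",
              lambda r: eq_mod.count_sectors(r["phase"]) <= 12)]
    if pi0 in (0.4, 0.6):
        preds.append(("exactly 11 ordering sectors",
                      lambda r: eq_mod.count_sectors(r["phase"]) == 11))
    return Scenario(
        name=f"phase[pi0={pi0}]", kind="phase", model=model,
        metadata={"pi0": pi0, "X0": DEFAULT_X0, "X1": DEFAULT_X1,
                  "n_grid": 201, "defaulted": ["X0", "X1"]},
        predicates=preds)


def _bridge(pi: float = 0.05, gamma: float = 0.5,
            mu: float = 0.1) -> Scenario:
    """Valley crossing from a population confined to the starting node.

    X0 = 1 makes simulated time directly comparable to the dimensionless
    time constant; dt = 0.05 keeps per-step reproduction probabilities
    small so the discrete simulator sits close to the continuum limit.
    """
    params = bridge_mod.BridgeParams(pi=pi, gamma=gamma, mu=mu)
    model = build_bridge(pi, gamma, mu, X0=1.0, N=DEFAULT_N)
    init = np.zeros((3, 2))
    init[0, 0] = 1.0
    tau = bridge_mod.tau_theory(params)
    t_max = 3.0 * tau if np.isfinite(tau) else 1500.0
    dt = 0.05
    preds = [
        ("ODE-empirical tau within 2% of the exact time constant",
         lambda r: abs(r["tau_ode"] - r["tau_theory"])
         <= 0.02 * r["tau_theory"]),
    ]
    return Scenario(
        name=f"bridge[pi={pi}]", kind="population", model=model, init=init,
        dt=dt, n_dilutions=int(np.ceil(t_max / dt)), n_trials=100,
        t_max=t_max,
        metadata={"params": params, "X0": 1.0, "N": DEFAULT_N,
                  "tau_theory": tau,
                  "defaulted": ["mu", "gamma", "X0", "dt", "N"]},
        predicates=preds)


def _absolute_fitness(deterministic: bool = False, A: float = 0.1) -> Scenario:
    """Global fitness shift: inert for a deterministic map, not otherwise."""
    if deterministic:
        model = build_two_by_two(1.0, 0.0, 0.0, DEFAULT_X0, DEFAULT_X1,
                                 N=DEFAULT_N)
        init = np.array([[0.1, 0.0], [0.0, 0.9]])
    else:
        model = build_two_by_two(0.8, 0.2, 0.0, DEFAULT_X0, DEFAULT_X1,
                                 N=DEFAULT_N)
        init = np.full((2, 2), 0.25)
    # dt keeps dt * max(X + A) = 0.01: the shift-invariance statement is a
    # continuum-limit property, so per-step growth must be small.
    dt = 0.01 / (DEFAULT_X0 + A)

    def _pred(r):
        diff = np.abs(r["ode"].freqs - r["ode_shifted"].freqs).max()
        return diff < 1e-10 if deterministic else diff > 1e-3

    label = "deterministic" if deterministic else "probabilistic"
    return Scenario(
        name=f"absolute_fitness[{label}]", kind="population", model=model,
        init=init, dt=dt, n_dilutions=int(np.ceil(100.0 / dt)), n_trials=50,
        t_max=100.0,
        metadata={"A": A, "deterministic": deterministic,
                  "shifted_model": shift_fitness(model, A),
                  "defaulted": ["X0", "X1", "A", "phi", "dt", "N"]},
        predicates=[
            (f"{label} map: shift by A "
             + ("leaves ODE trajectories unchanged (< 1e-10)"
                if deterministic else "alters ODE trajectories (> 1e-3)"),
             _pred),
        ])


def _mean_fitness_decrease() -> Scenario:
    """Mutation-free 2x2 setting whose mean fitness transiently drops."""
    model = build_two_by_two(0.1, 0.8, 0.0, 0.09, 0.02, N=DEFAULT_N)
    init = np.array([[0.4, 0.1], [0.05, 0.45]])

    def _non_monotone(r):
        xbar = r["ode"].mean_fitness
        return (xbar[1] < xbar[0]) and (xbar[-1] > xbar.min()) \
            and (xbar.argmin() not in (0, len(xbar) - 1))

    return Scenario(
        name="mean_fitness_decrease", kind="population", model=model,
        init=init, dt=1.0, n_dilutions=500, n_trials=10, t_max=500.0,
        metadata={"X0": 0.09, "X1": 0.02, "pi0": 0.1, "pi1": 0.8,
                  "f0": init.copy(), "defaulted": ["t_max"]},
        predicates=[
            ("mean fitness decreases at t=0 then recovers (non-monotone)",
             _non_monotone),
        ])


def _persister() -> Scenario:
    """Reference persister parameterization (partitioning shapes)."""
    params = pers_mod.PersisterParams(
        alpha=1.0, beta=0.5, sigma_PD=0.2, sigma_PF=0.3, sigma_PH=0.5,
        X_D=0.3, X_H=1.0, phi_DH=0.4, n0=(1.0, 0.0, 0.0, 0.0))

    def _transient(r):
        frac = r["fractions"]
        ok = True
        for idx in (1, 2):    # D and F fractions rise, peak, then fall
            x = frac[:, idx]
            imax = int(x.argmax())
            ok &= 0 < imax < len(x) - 1 and x[-1] < 0.5 * x[imax]
        return ok and frac[-1, 3] > 0.9

    return Scenario(
        name="persister", kind="persister", persister=params, t_max=10.0,
        metadata={"params": params,
                  "defaulted": ["alpha", "beta", "sigma", "X_D", "X_H",
                                "phi_DH"]},
        predicates=[
            ("closed form matches ODE integration to 1e-6 relative",
             lambda r: r["closed_vs_ode_relerr"] < 1e-6),
            ("damaged and failed fractions are transient; healthy "
             "fraction dominates at late times", _transient),
        ])


def run_scenario(sc: Scenario, engine: str = "ode", base_seed: int = 0,
                 n_trials: int | None = None,
                 n_dilutions: int | None = None) -> dict:
    """Execute a scenario and return the objects its predicates consume.

    ``engine`` is ``"ode"``, ``"prosed"`` or ``"both"`` for population
    scenarios and ignored otherwise.
    """
    results: dict = {"scenario": sc}
    if sc.kind == "phase":
        results["phase"] = eq_mod.phase_diagram(
            sc.metadata["pi0"], sc.metadata["X0"], sc.metadata["X1"],
            n_grid=sc.metadata["n_grid"])
        return results
    if sc.kind == "persister":
        t = np.linspace(0.0, sc.t_max, 201)
        closed = pers_mod.persister_closed_form(t, sc.persister)
        odesol = pers_mod.persister_integrate(t, sc.persister)
        scale = np.abs(odesol.abundances).max(axis=0)
        relerr = np.abs(closed.abundances - odesol.abundances) / scale[None]
        results.update({
            "closed": closed, "ode": odesol,
            "closed_vs_ode_relerr": float(relerr.max()),
            "fractions": pers_mod.normalize_trajectories(closed),
        })
        return results

    # population scenario
    n_dil = n_dilutions if n_dilutions is not None else sc.n_dilutions
    n_tri = n_trials if n_trials is not None else sc.n_trials
    t_eval = np.arange(n_dil + 1) * sc.dt
    if engine in ("ode", "both"):
        results["ode"] = ode_mod.integrate(sc.model, sc.init, t_eval[-1],
                                           t_eval=t_eval)
        if "shifted_model" in sc.metadata:
            results["ode_shifted"] = ode_mod.integrate(
                sc.metadata["shifted_model"], sc.init, t_eval[-1],
                t_eval=t_eval)
        if "params" in sc.metadata and isinstance(
                sc.metadata["params"], bridge_mod.BridgeParams):
            params = sc.metadata["params"]
            fe = bridge_mod.node_frequencies(results["ode"])[:, 3]
            tau, _, _ = bridge_mod.tau_empirical(results["ode"].times, fe,
                                                 params=params)
            results["tau_ode"] = tau
            results["tau_theory"] = bridge_mod.tau_theory(params)
    if engine in ("prosed", "both"):
        trajs = sim_mod.run_prosed(sc.model, sc.init, n_dil, dt=sc.dt,
                                   n_trials=n_tri, base_seed=base_seed)
        results["prosed"] = trajs
        results["prosed_mean"] = average_trajectories(trajs)
    if "equilibrium" in sc.metadata:
        results["equilibrium"] = sc.metadata["equilibrium"]
    return results


def random_model(G: int, P: int, seed: int, *,
                 phenotype_noise: bool = True, repl_mutation: bool = True,
                 spontaneous: bool = False, sps: bool = False,
                 fitness_range: tuple = (0.01, 0.2),
                 rate_range: tuple = (0.0, 0.05),
                 N: int | None = None) -> PrGPModel:
    """Random valid model for property tests; deterministic in ``seed``.

    Probability rows are symmetric-Dirichlet draws; with a flag off the
    corresponding process is disabled (identity mutation, deterministic
    one-hot phenotype map per genotype, zero rates).
    """
    if G < 1 or P < 1:
        raise ValueError("G and P must be >= 1")
    rng = np.random.default_rng(seed)
    fitness = rng.uniform(*fitness_range, size=P)

    if repl_mutation and G > 1:
        mu = rng.dirichlet(np.ones(G), size=G)
    else:
        mu = np.eye(G)

    if phenotype_noise and P > 1:
        phi = rng.dirichlet(np.ones(P), size=(G, P))
    else:
        phi = np.zeros((G, P, P))
        targets = rng.integers(0, P, size=G)
        for g in range(G):
            phi[g, :, targets[g]] = 1.0

    if G > 1:
        m = rng.dirichlet(np.ones(G - 1), size=G) if spontaneous \
            else np.full((G, G - 1), 1.0 / (G - 1))
        m_full = np.zeros((G, G))
        for g in range(G):
            m_full[g, np.arange(G) != g] = m[g]
    else:
        m_full = np.zeros((1, 1))
    R = rng.uniform(*rate_range, size=P) if spontaneous and G > 1 \
        else np.zeros(P)

    if P > 1:
        sig = rng.dirichlet(np.ones(P - 1), size=(G, P)) if sps \
            else np.full((G, P, P - 1), 1.0 / (P - 1))
        sigma = np.zeros((G, P, P))
        for k in range(P):
            sigma[:, k, np.arange(P) != k] = sig[:, k]
    else:
        sigma = np.zeros((G, 1, 1))
    S = rng.uniform(*rate_range, size=P) if sps and P > 1 else np.zeros(P)

    return PrGPModel(
        genotypes=[str(g) for g in range(G)],
        phenotypes=[str(p) for p in range(P)],
        fitness=fitness, repl_mutation=mu, phenotype_noise=phi,
        spont_rate=R, spont_mutation=m_full, sps_rate=S, sps_matrix=sigma,
        pop_size=N)
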