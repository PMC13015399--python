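"""Exact equilibrium of the two-genotype / two-phenotype model and the
coexistence phase diagrams of genotype-phenotype pair orderings.

With parent-independent phenotype noise (``pi_g`` = probability genotype
``g`` maps onto the fitter phenotype 0) and symmetric replication mutation
``mu``, the equilibrium factorizes as ``f_g(p) = F_g * phi_g(p)`` where the
genotype masses ``F_g`` solve a 2x2 eigenproblem with per-genotype mean
birth rates ``alpha_g = pi_g X(0) + (1 - pi_g) X(1)``.  The equilibrium
mean fitness is the dominant root of

    Xbar^2 - beta Xbar + alpha_0 alpha_1 (1 - 2 mu) = 0,
    beta = (1 - mu)(alpha_0 + alpha_1),

and the closed-form frequency vector follows.  A low-fitness,
low-probability pair can nonetheless rank high at equilibrium when the
fit pair of the *same genotype* acts as a phenotypic buoy — a population
source coupled to it through noisy phenotype assignment at birth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Equilibrium2x2", "PhaseDiagram", "equilibrium_2x2",
    "equilibrium_2x2_eigen", "ordering_label", "phase_diagram",
    "count_sectors", "boundary_curves", "PAIR_NAMES",
]

#: The four genotype-phenotype pairs in frequency-vector order.
PAIR_NAMES = ("f0(0)", "f0(1)", "f1(0)", "f1(1)")

_PERMS = list(itertools.permutations(range(4)))


@dataclass(frozen=True)
class Equilibrium2x2:
    """Exact equilibrium of the 2x2 model."""

    feq: np.ndarray        # (4,) = (f0(0), f0(1), f1(0), f1(1))
    Xbar_eq: float
    params: tuple          # (pi0, pi1, mu, X0, X1)
    alpha0: float
    alpha1: float
    beta: float

    @property
    def feq_tensor(self) -> np.ndarray:
        return self.feq.reshape(2, 2)


@dataclass
class PhaseDiagram:
    """Ordering labels of the 2x2 equilibrium on a (pi1, mu) lattice."""

    pi1_grid: np.ndarray       # (n,)
    mu_grid: np.ndarray        # (n,)
    pi0: float
    X0: float
    X1: float
    labels: np.ndarray         # (n, n) int permutation index, [i_mu, i_pi1]
    min_gap: np.ndarray        # (n, n) smallest pairwise frequency gap
    boundary: np.ndarray       # (n, n) bool, gap below tie tolerance
    tie_tol: float


def _params_check(pi0, pi1, mu, X0, X1):
    for name, val in (("pi0", pi0), ("pi1", pi1), ("mu", mu)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} = {val} must lie in [0, 1]")
    if X0 <= 0 and X1 <= 0:
        raise ValueError("degenerate fitnesses: need X0 > 0")
    if X1 > X0:
        raise ValueError("convention requires X0 >= X1 (phenotype 0 fitter)")


def _xbar_eq(alpha0, alpha1, mu):
    beta = (1.0 - mu) * (alpha0 + alpha1)
    disc = beta * beta - 4.0 * alpha0 * alpha1 * (1.0 - 2.0 * mu)
    return beta, (beta + np.sqrt(np.maximum(disc, 0.0))) / 2.0


def equilibrium_2x2(pi0: float, pi1: float, mu: float,
                    X0: float, X1: float) -> Equilibrium2x2:
    """Closed-form equilibrium frequencies and mean fitness.

    The genotype masses are taken proportional to
    ``(mu * alpha1, Xbar_eq - (1 - mu) * alpha0)`` — the dominant
    eigenvector written without dividing by ``Xbar_eq`` — and the pair
    frequencies are ``F_g`` split by the mapping probabilities ``pi_g``.
    """
    _params_check(pi0, pi1, mu, X0, X1)
    alpha0 = pi0 * X0 + (1.0 - pi0) * X1
    alpha1 = pi1 * X0 + (1.0 - pi1) * X1
    beta, xbar = _xbar_eq(alpha0, alpha1, mu)
    w0 = mu * alpha1
    w1 = xbar - (1.0 - mu) * alpha0
    s = w0 + w1
    if s <= 0 or xbar <= 0:
        # mu = 0 with one genotype strictly dominant: all mass on the
        # genotype with the larger mean birth rate.
        F0 = 1.0 if alpha0 >= alpha1 else 0.0
        F1 = 1.0 - F0
    else:
        F0, F1 = w0 / s, w1 / s
    feq = np.array([F0 * pi0, F0 * (1.0 - pi0), F1 * pi1, F1 * (1.0 - pi1)])
    return Equilibrium2x2(feq=feq, Xbar_eq=float(xbar),
                          params=(pi0, pi1, mu, X0, X1),
                          alpha0=float(alpha0), alpha1=float(alpha1),
                          beta=float(beta))


def equilibrium_2x2_eigen(pi0: float, pi1: float, mu: float,
                          X0: float, X1: float) -> Equilibrium2x2:
    """Independent route: dominant eigenvector of the full 4x4 birth matrix.

    At equilibrium ``Xbar f = B f`` with
    ``B[(g,p),(h,k)] = phi_g(p) X(k) mu[h,g]``; the equilibrium vector is
    the Perron eigenvector of ``B`` and ``Xbar_eq`` its eigenvalue.  Used
    as a cross-check of the rank-deficiency closed form.
    """
    _params_check(pi0, pi1, mu, X0, X1)
    phi = np.array([[pi0, 1.0 - pi0], [pi1, 1.0 - pi1]])  # phi[g, p]
    X = np.array([X0, X1])
    mu_mat = np.array([[1.0 - mu, mu], [mu, 1.0 - mu]])
    B = np.zeros((4, 4))
    for g in range(2):
        for p in range(2):
            for h in range(2):
                for k in range(2):
                    B[2 * g + p, 2 * h + k] = phi[g, p] * X[k] * mu_mat[h, g]
    vals, vecs = np.linalg.eig(B)
    i = int(np.argmax(vals.real))
    v = np.abs(vecs[:, i].real)
    feq = v / v.sum()
    alpha0 = pi0 * X0 + (1.0 - pi0) * X1
    alpha1 = pi1 * X0 + (1.0 - pi1) * X1
    return Equilibrium2x2(feq=feq, Xbar_eq=float(vals.real[i]),
                          params=(pi0, pi1, mu, X0, X1),
                          alpha0=float(alpha0), alpha1=float(alpha1),
                          beta=float((1.0 - mu) * (alpha0 + alpha1)))


def ordering_label(feq: np.ndarray, tie_tol: float = 1e-9):
    """Descending-order permutation of the four pair frequencies.

    Returns ``(perm, boundary)`` where ``perm`` is a tuple of pair indices
    in decreasing frequency and ``boundary`` is True when any pairwise gap
    is below ``tie_tol`` (relative to the largest frequency).
    """
    feq = np.asarray(feq, dtype=float)
    order = tuple(int(i) for i in np.argsort(-feq, kind="stable"))
    gaps = [abs(feq[i] - feq[j])
            for i, j in itertools.combinations(range(4), 2)]
    boundary = min(gaps) < tie_tol * max(feq.max(), 1e-300)
    return order, boundary


def _feq_grid(pi0, pi1, mu, X0, X1):
    """Vectorized closed form over broadcastable pi1/mu arrays."""
    alpha0 = pi0 * X0 + (1.0 - pi0) * X1
    alpha1 = pi1 * X0 + (1.0 - pi1) * X1
    beta = (1.0 - mu) * (alpha0 + alpha1)
    disc = beta * beta - 4.0 * alpha0 * alpha1 * (1.0 - 2.0 * mu)
    xbar = (beta + np.sqrt(np.maximum(disc, 0.0))) / 2.0
    w0 = mu * alpha1
    w1 = xbar - (1.0 - mu) * alpha0
    s = w0 + w1
    F0 = np.where(s > 0, w0 / np.where(s > 0, s, 1.0), alpha0 >= alpha1)
    F1 = 1.0 - F0
    return np.stack([F0 * pi0, F0 * (1.0 - pi0), F1 * pi1, F1 * (1.0 - pi1)],
                    axis=-1)


def phase_diagram(pi0: float, X0: float = 0.1, X1: float = 0.05,
                  n_grid: int = 201, tie_tol: float = 1e-9) -> PhaseDiagram:
    """Evaluate the equilibrium ordering on an open (pi1, mu) lattice.

    Endpoints are offset by half a cell so the degenerate edges of the
    unit square are excluded.  Cells are labeled by the index of the
    descending-order permutation; near-ties are flagged as boundary cells.
    """
    if n_grid < 51:
        raise ValueError("n_grid must be at least 51")
    h = 0.5 / n_grid
    axis = np.linspace(h, 1.0 - h, n_grid)
    pi1 = axis[None, :]
    mu = axis[:, None]
    feq = _feq_grid(pi0, pi1, mu, X0, X1)      # (n, n, 4)

    order = np.argsort(-feq, axis=-1, kind="stable")
    perm_index = {p: i for i, p in enumerate(_PERMS)}
    keys = (order[..., 0] * 64 + order[..., 1] * 16
            + order[..., 2] * 4 + order[..., 3])
    key_to_idx = np.full(4 * 64, -1, dtype=int)
    for p, i in perm_index.items():
        key_to_idx[p[0] * 64 + p[1] * 16 + p[2] * 4 + p[3]] = i
    labels = key_to_idx[keys]

    diffs = np.abs(feq[..., :, None] - feq[..., None, :])
    iu = np.triu_indices(4, k=1)
    min_gap = diffs[..., iu[0], iu[1]].min(axis=-1)
    boundary = min_gap < tie_tol * np.maximum(feq.max(axis=-1), 1e-300)

    return PhaseDiagram(pi1_grid=axis, mu_grid=axis, pi0=pi0, X0=X0, X1=X1,
                        labels=labels, min_gap=min_gap, boundary=boundary,
                        tie_tol=tie_tol)


def count_sectors(pd: PhaseDiagram) -> int:
    """Number of distinct ordering permutations among non-boundary cells."""
    return int(np.unique(pd.labels[~pd.boundary]).size)


def permutation_of_label(label: int) -> tuple[int, ...]:
    return _PERMS[label]


def boundary_curves(pi0: float, X0: float = 0.1, X1: float = 0.05,
                    n_slices: int = 201, tol: float = 1e-10) -> dict:
    """The six pairwise-equality curves ``feq_i = feq_j`` in (pi1, mu).

    For each unordered pair of frequency-vector components, scans vertical
    slices (fixed pi1) for sign changes of ``feq_i - feq_j`` in mu and
    brackets each root with Brent's method.  Returns a dict mapping the
    component pair to an array of (pi1, mu) curve points; a pair whose
    difference never changes sign contributes an empty array (a valid
    outcome — that boundary does not cross the open square).
    """
    h = 0.5 / n_slices
    slice_vals = np.linspace(h, 1.0 - h, n_slices)
    scan = np.linspace(1e-6, 1.0 - 1e-6, 401)
    curves: dict[tuple[int, int], np.ndarray] = {}
    for i, j in itertools.combinations(range(4), 2):

        def diff(pi1, mu):
            d = _feq_grid(pi0, pi1, mu, X0, X1)
            return d[..., i] - d[..., j]

        pts = []
        # roots in mu at fixed pi1, then in pi1 at fixed mu — covers both
        # nearly-horizontal and nearly-vertical boundary orientations.
        for pi1 in slice_vals:
            sign = np.sign(diff(pi1, scan))
            for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
                mu_star = brentq(lambda mu: float(diff(pi1, mu)),
                                 scan[k], scan[k + 1], xtol=tol)
                pts.append((pi1, mu_star))
        for mu in slice_vals:
            sign = np.sign(diff(scan, mu))
            for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
                pi1_star = brentq(lambda pi1: float(diff(pi1, mu)),
                                  scan[k], scan[k + 1], xtol=tol)
                pts.append((pi1_star, mu))
        curves[(i, j)] = np.array(pts).reshape(-1, 2)
    return curves
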