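"""Exact 2x2 equilibrium, orderings, phase diagrams, boundary curves."""

import itertools

import numpy as np
import pytest

from propgen.equilibrium import (boundary_curves, count_sectors,
                                 equilibrium_2x2, equilibrium_2x2_eigen,
                                 ordering_label, phase_diagram, _feq_grid)
from propgen.model import build_two_by_two
from propgen.ode import fixed_point, integrate, propgen_rhs

from conftest import random_2x2_params


class TestClosedForm:
    def test_deterministic_map_to_fit_phenotype(self):
        eq = equilibrium_2x2(1.0, 1.0, 0.05, 0.1, 0.05)
        assert eq.feq[1] == eq.feq[3] == 0.0
        assert eq.Xbar_eq == pytest.approx(0.1)

    def test_three_routes_agree(self, rng):
        """Closed form == 4x4 Perron eigenvector == numeric ODE fixed point
        over a random parameter sweep."""
        for params in random_2x2_params(rng, 60):
            eq = equilibrium_2x2(*params)
            eige = equilibrium_2x2_eigen(*params)
            fp = fixed_point(build_two_by_two(*params))
            assert np.abs(eq.feq - eige.feq).max() < 1e-10
            assert abs(eq.Xbar_eq - eige.Xbar_eq) < 1e-10
            assert np.abs(eq.feq - fp.ravel()).max() < 1e-8

    def test_matches_long_time_integration(self):
        eq = equilibrium_2x2(0.4, 0.9, 0.05, 0.1, 0.05)
        model = build_two_by_two(0.4, 0.9, 0.05, 0.1, 0.05)
        traj = integrate(model, np.full((2, 2), 0.25), 3000.0,
                         record_every=500.0)
        assert np.abs(traj.freqs[-1].ravel() - eq.feq).max() < 1e-8
        # the buoyed pair (g=1, p=0) dominates at pi1 = 0.9
        assert eq.feq.argmax() == 2

    def test_residual_in_general_rhs(self, rng):
        for params in random_2x2_params(rng, 20):
            eq = equilibrium_2x2(*params)
            model = build_two_by_two(*params)
            assert np.abs(propgen_rhs(eq.feq_tensor, model)).max() < 1e-10

    def test_buoy_sweep_red_outranks_blue(self):
        """Low-probability, low-fitness pair f1(1) persists above f0(0)
        across the buoy sweep, even when its mapping probability is lower."""
        for one_minus_pi1 in (0.5, 0.4, 0.3, 0.2):
            eq = equilibrium_2x2(0.4, 1.0 - one_minus_pi1, 0.05, 0.1, 0.05)
            assert eq.feq[3] > eq.feq[0], one_minus_pi1

    def test_buoy_ranking_above_half(self, rng):
        """The buoy pair f1(0) ranks first whenever pi1 > 0.5 in the
        sweep configuration."""
        for pi1 in np.linspace(0.55, 0.95, 9):
            eq = equilibrium_2x2(0.4, pi1, 0.05, 0.1, 0.05)
            assert eq.feq.argmax() == 2

    def test_mu_zero_degenerate_limit(self):
        eq = equilibrium_2x2(0.9, 0.1, 0.0, 0.1, 0.05)
        # genotype 0 has the larger mean birth rate; all mass on it
        assert eq.feq[2] == eq.feq[3] == 0.0
        assert eq.feq[0] == pytest.approx(0.9)

    def test_convention_violation_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_2x2(0.4, 0.5, 0.05, 0.05, 0.1)  # X1 > X0
        with pytest.raises(ValueError):
            equilibrium_2x2(0.4, 0.5, 0.05, 0.0, 0.0)


class TestOrdering:
    def test_identity_ordering(self):
        order, boundary = ordering_label(np.array([0.4, 0.3, 0.2, 0.1]))
        assert order == (0, 1, 2, 3) and not boundary

    def test_tie_flag(self):
        order, boundary = ordering_label(np.array([0.3, 0.3, 0.2, 0.2]),
                                         tie_tol=1e-6)
        assert boundary

    def test_equilibrium_ordering_at_strong_buoy(self):
        eq = equilibrium_2x2(0.4, 0.9, 0.01, 0.1, 0.05)
        order, boundary = ordering_label(eq.feq)
        assert order[0] == 2 and not boundary


class TestPhaseDiagram:
    def test_eleven_sectors_at_reference_pi0(self):
        for pi0 in (0.4, 0.6):
            pd = phase_diagram(pi0, 0.1, 0.05, n_grid=201)
            assert count_sectors(pd) == 11

    @pytest.mark.parametrize("ratio", [1.5, 2.0, 4.0])
    def test_sector_count_robust_to_fitness_ratio(self, ratio):
        pd = phase_diagram(0.4, 0.1, 0.1 / ratio, n_grid=101)
        assert count_sectors(pd) == 11

    def test_at_most_twelve_orderings(self):
        """pi0 != 0.5 pins the f0(0) vs f0(1) order, halving 24 -> 12."""
        pd = phase_diagram(0.3, 0.1, 0.05, n_grid=101)
        assert count_sectors(pd) <= 12
        labels = pd.labels[~pd.boundary]
        from propgen.equilibrium import _PERMS
        for lab in np.unique(labels):
            perm = _PERMS[lab]
            # pair 1 (= f0(1)) always precedes pair 0 when pi0 < 0.5
            assert perm.index(1) < perm.index(0)

    def test_genotype_exchange_symmetry(self):
        """Relabeling the two genotypes permutes the equilibrium exactly:
        feq(pi0, pi1) equals the block-swapped feq(pi1, pi0)."""
        for pi0, pi1, mu in [(0.3, 0.8, 0.2), (0.5, 0.61, 0.32),
                             (0.9, 0.15, 0.05)]:
            a = equilibrium_2x2(pi0, pi1, mu, 0.1, 0.05).feq
            b = equilibrium_2x2(pi1, pi0, mu, 0.1, 0.05).feq
            assert np.abs(a - b[[2, 3, 0, 1]]).max() < 1e-12

    def test_degenerate_equal_fitness_single_sector(self):
        """X0 == X1 removes selection between phenotypes: the genotype
        split is uniform and orderings follow mapping probabilities only;
        brute-force over the grid."""
        pd = phase_diagram(0.4, 0.1, 0.1, n_grid=101)
        labels = np.unique(pd.labels[~pd.boundary])
        h = 0.5 / 101
        axis = np.linspace(h, 1 - h, 101)
        feq = _feq_grid(0.4, axis[None, :], axis[:, None], 0.1, 0.1)
        brute = np.argsort(-feq, axis=-1, kind="stable")
        # orderings depend on pi1 only (mu drops out): each grid column
        # must be a single ordering
        assert (brute == brute[:1]).all()
        assert labels.size <= 4

    def test_min_grid_enforced(self):
        with pytest.raises(ValueError):
            phase_diagram(0.4, 0.1, 0.05, n_grid=50)


class TestBoundaryCurves:
    def test_six_pairwise_relations(self):
        curves = boundary_curves(0.4, 0.1, 0.05, n_slices=31)
        assert len(curves) == 6
        assert set(curves) == set(itertools.combinations(range(4), 2))

    def test_equality_on_curve_points(self):
        curves = boundary_curves(0.4, 0.1, 0.05, n_slices=31)
        for (i, j), pts in curves.items():
            for pi1, mu in pts:
                feq = _feq_grid(0.4, pi1, np.asarray(mu), 0.1, 0.05)
                assert abs(feq[i] - feq[j]) < 1e-9

    def test_absent_curves_have_constant_sign(self):
        """A pair with no returned curve never changes order anywhere on
        the open square."""
        curves = boundary_curves(0.4, 0.1, 0.05, n_slices=31)
        h = 0.5 / 201
        axis = np.linspace(h, 1 - h, 201)
        feq = _feq_grid(0.4, axis[None, :], axis[:, None], 0.1, 0.05)
        for (i, j), pts in curves.items():
            d = feq[..., i] - feq[..., j]
            if len(pts) == 0:
                assert d.min() > 0 or d.max() < 0
            else:
                assert d.min() < 0 < d.max()

    def test_curves_overlay_label_switches(self):
        """Every label change between adjacent grid cells lies within one
        cell of some boundary curve."""
        n = 101
        pd = phase_diagram(0.4, 0.1, 0.05, n_grid=n)
        curves = boundary_curves(0.4, 0.1, 0.05, n_slices=n)
        pts = np.concatenate([c for c in curves.values() if len(c)])
        cell = 1.0 / n
        edges = []
        for axis in (0, 1):
            d = np.diff(pd.labels, axis=axis)
            idx = np.argwhere(d != 0)
            for i, j in idx:
                mu = pd.mu_grid[i] + (0.5 * cell if axis == 0 else 0.0)
                pi1 = pd.pi1_grid[j] + (0.5 * cell if axis == 1 else 0.0)
                edges.append((pi1, mu))
        edges = np.asarray(edges)
        # subsample for speed; every sampled switch must be near a curve
        for pi1, mu in edges[:: max(1, len(edges) // 400)]:
            dist = np.hypot(pts[:, 0] - pi1, pts[:, 1] - mu).min()
            assert dist < 1.5 * cell
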