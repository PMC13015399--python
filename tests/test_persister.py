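"""Persister resuscitation: closed form vs ODE, flux bookkeeping, shapes."""

import numpy as np
import pytest
from scipy.integrate import quad

from propgen.persister import (PersisterParams, gammainc_diff,
                               normalize_trajectories, persister_closed_form,
                               persister_integrate, persister_rhs)

REF = PersisterParams(alpha=1.0, beta=0.5, sigma_PD=0.2, sigma_PF=0.3,
                      sigma_PH=0.5, X_D=0.3, X_H=1.0, phi_DH=0.4,
                      n0=(1.0, 0.0, 0.0, 0.0))


def random_params(rng):
    sigma = rng.dirichlet(np.ones(3))
    X_D = rng.uniform(0.0, 1.0)
    X_H = rng.uniform(0.2, 2.0)
    return PersisterParams(
        alpha=rng.uniform(0.2, 2.0), beta=rng.uniform(0.1, 2.0),
        sigma_PD=sigma[0], sigma_PF=sigma[1], sigma_PH=sigma[2],
        X_D=X_D, X_H=X_H, phi_DH=rng.uniform(0.0, 1.0),
        n0=(1.0, rng.uniform(0, 0.2), 0.0, rng.uniform(0, 0.2)))


class TestRhs:
    def test_direct_substitution_at_start(self):
        d = persister_rhs(0.0, np.array([1.0, 0.0, 0.0, 0.0]), REF)
        assert np.allclose(d, [-1.0, 0.2, 0.3, 0.5])

    def test_exhausted_source(self):
        d = persister_rhs(2.0, np.array([0.0, 1.0, 0.0, 1.0]), REF)
        assert d[0] == 0.0 and d[2] == 0.0
        assert d[1] == pytest.approx(0.3 * 0.6)           # a * nD
        assert d[3] == pytest.approx(1.0 + 0.3 * 0.4)     # X_H nH + XD phi nD

    def test_monotone_compartments(self, rng):
        for _ in range(20):
            n = rng.uniform(0.0, 2.0, size=4)
            t = rng.uniform(0.0, 5.0)
            d = persister_rhs(t, n, REF)
            assert d[0] <= 0.0 and d[2] >= 0.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            persister_rhs(0.0, np.array([-0.1, 0.0, 0.0, 0.0]), REF)

    def test_finite_difference_of_closed_form(self):
        """The closed form differentiates back onto the rhs to O(h^2)."""
        h = 1e-5
        for t0 in (0.5, 2.0, 5.0):
            ts = np.array([t0 - h, t0, t0 + h])
            sol = persister_closed_form(ts, REF)
            fd = (sol.abundances[2] - sol.abundances[0]) / (2 * h)
            rhs = persister_rhs(t0, sol.abundances[1], REF)
            assert np.abs(fd - rhs).max() < 1e-6


class TestClosedForm:
    def test_initial_condition_exact(self):
        p = PersisterParams(alpha=0.7, beta=0.9, sigma_PD=0.25, sigma_PF=0.25,
                            sigma_PH=0.5, X_D=0.4, X_H=1.2, phi_DH=0.3,
                            n0=(2.0, 0.5, 0.25, 1.0))
        sol = persister_closed_form(np.array([0.0]), p)
        assert np.allclose(sol.abundances[0], p.n0, atol=1e-14)

    def test_failed_compartment_saturates(self):
        sol = persister_closed_form(np.array([0.0, 50.0]), REF)
        assert sol.abundances[-1, 2] == pytest.approx(
            REF.n0[2] + REF.sigma_PF * REF.n0[0], abs=1e-12)
        assert sol.abundances[-1, 0] == pytest.approx(0.0, abs=1e-200)

    def test_matches_ode_reference_parameterization(self):
        t = np.linspace(0.0, 10.0, 101)
        closed = persister_closed_form(t, REF)
        ode = persister_integrate(t, REF)
        scale = np.abs(ode.abundances).max(axis=0)
        rel = np.abs(closed.abundances - ode.abundances) / scale[None]
        assert rel.max() < 1e-6

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_ode_random_parameters(self, seed):
        rng = np.random.default_rng(1000 + seed)
        p = random_params(rng)
        t = np.linspace(0.0, 8.0, 61)
        closed = persister_closed_form(t, p)
        ode = persister_integrate(t, p)
        scale = np.abs(ode.abundances).max(axis=0)
        rel = np.abs(closed.abundances - ode.abundances) / scale[None]
        assert rel.max() < 1e-6

    def test_removable_singularity_xh_equals_a(self):
        p = PersisterParams(alpha=1.0, beta=0.5, sigma_PD=0.2, sigma_PF=0.3,
                            sigma_PH=0.5, X_D=0.5, X_H=0.3, phi_DH=0.4)
        assert p.derived.a == pytest.approx(p.X_H)
        t = np.linspace(0.0, 8.0, 41)
        closed = persister_closed_form(t, p)
        ode = persister_integrate(t, p)
        scale = np.abs(ode.abundances).max(axis=0)
        assert (np.abs(closed.abundances - ode.abundances)
                / scale[None]).max() < 1e-6

    def test_switching_flux_conservation(self):
        """Everything the dormant pool loses arrives in F, D and H in the
        sigma proportions: integrating S(t) n_P equals n_P(0) - n_P(t),
        and the F gain is exactly the sigma_PF share."""
        t_end = 4.0
        flux, _ = quad(lambda s: REF.rate(s)
                       * persister_closed_form(np.array([s]),
                                               REF).abundances[0, 0],
                       0.0, t_end, limit=200)
        sol = persister_closed_form(np.array([0.0, t_end]), REF)
        lost = sol.abundances[0, 0] - sol.abundances[1, 0]
        assert flux == pytest.approx(lost, rel=1e-8)
        gained_F = sol.abundances[1, 2] - sol.abundances[0, 2]
        assert gained_F == pytest.approx(REF.sigma_PF * lost, rel=1e-10)

    def test_strictly_decreasing_P_nondecreasing_F(self):
        t = np.linspace(0.0, 10.0, 201)
        sol = persister_closed_form(t, REF)
        assert (np.diff(sol.abundances[:, 0]) < 0).all()
        assert (np.diff(sol.abundances[:, 2]) >= 0).all()

    def test_beta_nonpositive_unsupported(self):
        with pytest.raises(ValueError):
            PersisterParams(alpha=1.0, beta=0.0, sigma_PD=0.2, sigma_PF=0.3,
                            sigma_PH=0.5, X_D=0.3, X_H=1.0, phi_DH=0.4)


class TestNormalized:
    def test_fractions_sum_to_one(self):
        t = np.linspace(0.0, 10.0, 101)
        frac = normalize_trajectories(persister_closed_form(t, REF))
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_transient_partitioning_shapes(self):
        """Damaged and failed fractions rise, peak, and vanish while the
        healthy fraction takes over."""
        t = np.linspace(0.0, 10.0, 201)
        frac = normalize_trajectories(persister_closed_form(t, REF))
        for idx in (1, 2):  # D, F
            x = frac[:, idx]
            peak = int(x.argmax())
            assert 0 < peak < len(x) - 1
            assert x[-1] < 0.1 * x[peak]
        assert frac[-1, 3] > 0.99

    def test_healthy_takeover_when_fitter(self, rng):
        for seed in range(5):
            p = random_params(np.random.default_rng(7000 + seed))
            if p.X_H <= p.derived.a + 0.05:
                continue
            t = np.linspace(0.0, 60.0, 31)
            frac = normalize_trajectories(persister_closed_form(t, p))
            assert frac[-1, 3] > 0.95

    def test_birth_noise_not_interchangeable_with_switching(self):
        """Replication-coupled damaged->healthy conversion (phi_DH) cannot
        be mimicked by re-routing the one-shot dormancy switch: zeroing
        phi_DH and handing its long-run share to sigma_PH changes the
        dynamics qualitatively (D never decays relative to its own growth,
        and the D trajectory differs)."""
        alt = PersisterParams(alpha=1.0, beta=0.5, sigma_PD=0.2,
                              sigma_PF=0.3, sigma_PH=0.5, X_D=0.3, X_H=1.0,
                              phi_DH=0.0)
        t = np.linspace(0.0, 10.0, 101)
        a = persister_closed_form(t, REF).abundances
        b = persister_closed_form(t, alt).abundances
        assert np.abs(a[:, 1] - b[:, 1]).max() > 0.05
        # without phi_DH the damaged pool grows at full X_D forever
        assert (np.diff(b[-20:, 1]) > 0).all()


class TestGammaIncDiff:
    def test_positive_q_matches_quadrature(self, rng):
        for _ in range(10):
            q = rng.uniform(0.1, 3.0)
            x1 = rng.uniform(0.1, 2.0)
            x2 = x1 + rng.uniform(0.1, 5.0)
            ref, _ = quad(lambda u: u ** (q - 1) * np.exp(-u), x1, x2)
            assert gammainc_diff(q, x1, x2) == pytest.approx(ref, rel=1e-9)

    def test_nonpositive_q_finite_and_ordered(self):
        v = gammainc_diff(-1.5, 0.5, 4.0)
        assert np.isfinite(v) and v > 0
        assert gammainc_diff(-1.5, 4.0, 0.5) == pytest.approx(-v)
        assert gammainc_diff(-1.5, 0.5, 0.5) == 0.0

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            gammainc_diff(0.5, 0.0, 1.0)
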