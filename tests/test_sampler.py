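"""Gibbs-sampler building blocks validated against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invwishart

from recmt.model import ModelSpec, PhenotypeTable
from recmt.pedigree import toposort_pedigree
from recmt.sampler import (
    GibbsSampler,
    Priors,
    conditional_moments,
    run_gibbs,
    sample_G,
    sample_missing,
)
from recmt.simdata import SimulationConfig, simulate_dataset, simulate_pedigree
from .conftest import random_spd


class TestConditionalMoments:
    def test_diagonal_R_gives_marginals(self, rng):
        R = np.diag([2.0, 3.0, 4.0])
        mu = np.array([1.0, -1.0, 0.5])
        y = np.array([1.7, np.nan, np.nan])
        mask = np.array([True, False, False])
        mean, cov = conditional_moments(y, mask, mu, R)
        assert np.allclose(mean, mu[1:])
        assert np.allclose(cov, R[1:, 1:])

    def test_bivariate_closed_form(self):
        R = np.array([[2.0, 0.8], [0.8, 1.5]])
        mu = np.array([0.3, -0.2])
        y = np.array([1.0, np.nan])
        mean, cov = conditional_moments(y, np.array([True, False]), mu, R)
        assert mean[0] == pytest.approx(mu[1] + R[0, 1] / R[0, 0] * (y[0] - mu[0]))
        assert cov[0, 0] == pytest.approx(R[1, 1] - R[0, 1] ** 2 / R[0, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_joint_precision_oracle(self, seed):
        """Conditioning via R blocks equals conditioning via the full precision."""
        rng = np.random.default_rng(seed)
        R = random_spd(4, rng)
        mu = rng.standard_normal(4)
        y = rng.standard_normal(4)
        mask = np.zeros(4, dtype=bool)
        mask[rng.choice(4, size=rng.integers(1, 4), replace=False)] = True
        mean, cov = conditional_moments(y, mask, mu, R)
        P = np.linalg.inv(R)
        M, O = np.flatnonzero(~mask), np.flatnonzero(mask)
        cov_o = np.linalg.inv(P[np.ix_(M, M)])
        mean_o = mu[M] - cov_o @ P[np.ix_(M, O)] @ (y[O] - mu[O])
        assert np.allclose(mean, mean_o)
        assert np.allclose(cov, cov_o)

    def test_complete_record_returned_unchanged(self, rng):
        y = np.array([1.0, 2.0])
        out = sample_missing(y, np.array([True, True]), np.zeros(2), np.eye(2), rng)
        assert np.array_equal(out, y)


class TestVarianceConditionals:
    def test_prior_limit_mean(self, rng):
        """With U = 0 the G draw reduces to the prior IW(S0, s + nu0)."""
        from scipy import sparse

        m, s = 2, 4
        prior = Priors(nu0_g=8.0, S0_g=np.eye(m), nu0_r=8.0, S0_r=np.eye(m))
        Ainv = sparse.identity(s, format="csr")
        draws = np.array([
            sample_G(np.zeros((s, m)), Ainv, prior, rng) for _ in range(4000)
        ])
        expect = np.eye(m) / (8 + s - m - 1)
        assert np.allclose(draws.mean(axis=0), expect, atol=0.02)

    def test_univariate_scaled_inv_chi2_moments(self, rng):
        """m = 1 reduces to a scaled inverse chi-square; check mean and variance."""
        from scipy import sparse

        u = np.array([[1.3], [-0.4]])
        prior = Priors(nu0_g=5.0, S0_g=np.eye(1), nu0_r=5.0, S0_r=np.eye(1))
        Ainv = sparse.identity(2, format="csr")
        draws = np.array([
            sample_G(u, Ainv, prior, rng)[0, 0] for _ in range(30000)
        ])
        scale = 1.0 + (u.T @ u).item()
        df = 5.0 + 2
        mean_th = scale / (df - 2)
        var_th = 2 * scale**2 / ((df - 2) ** 2 * (df - 4))
        assert draws.mean() == pytest.approx(mean_th, rel=0.03)
        assert draws.var() == pytest.approx(var_th, rel=0.12)

    def test_draws_reproducible_under_seed(self, small_pedigree):
        cfg = SimulationConfig(n_founders=14, n_generations=3, n_per_generation=12,
                               n_records=30, n_hys=2, n_dam_age=2, seed=7)
        ped, table, _ = simulate_dataset(cfg)
        c1 = run_gibbs(ped, table, n_iter=40, burn_in=10, thin=2, seed=5)
        c2 = run_gibbs(ped, table, n_iter=40, burn_in=10, thin=2, seed=5)
        assert np.array_equal(c1.G, c2.G)
        assert np.array_equal(c1.R, c2.R)

    def test_every_stored_sample_is_spd(self):
        cfg = SimulationConfig(n_founders=20, n_generations=2, n_per_generation=20,
                               n_records=30, seed=2)
        ped, table, _ = simulate_dataset(cfg)
        chain = run_gibbs(ped, table, n_iter=120, burn_in=20, thin=2, seed=3)
        for k in range(len(chain)):
            np.linalg.cholesky(chain.G[k])
            np.linalg.cholesky(chain.R[k])


def _mme_solution(ped, table, G, R):
    """Dense mixed-model-equations solve (independent of the sampler)."""
    from recmt.model import build_design

    d = build_design(table)
    m = len(table.spec.traits)
    n, s = table.n, ped.size
    Rinv = np.linalg.inv(R)
    Ginv = np.linalg.inv(G)
    Ainv = ped.relationship_inverse().toarray()
    rows = ped.index_of(table.ids)
    # stacked record-major y and design
    p = d.p_total
    Xs = np.zeros((n * m, p))
    Zs = np.zeros((n * m, s * m))
    for r in range(n):
        for t in range(m):
            Xs[r * m + t, d.coef_slice(t)] = d.trait_matrix(t)[r]
            Zs[r * m + t, rows[r] * m + t] = 1.0
    Rbig = np.kron(np.eye(n), Rinv)
    y = table.y.reshape(-1)
    C = np.block([
        [Xs.T @ Rbig @ Xs, Xs.T @ Rbig @ Zs],
        [Zs.T @ Rbig @ Xs, Zs.T @ Rbig @ Zs + np.kron(Ainv, Ginv)],
    ])
    rhs = np.concatenate([Xs.T @ Rbig @ y, Zs.T @ Rbig @ y])
    sol = np.linalg.solve(C, rhs)
    post_cov = np.linalg.inv(C)
    return sol[:p], sol[p:].reshape(s, m), post_cov


class TestLocationSampling:
    def test_scalar_shrinkage_for_single_founder(self):
        """One founder, one record, m = 1: E[u | y] = g/(g+r) (y - xb)."""
        ped = toposort_pedigree([(1, 0, 0)])
        spec = ModelSpec(traits=("t",), intercept=False)
        y0, g, r = 2.4, 1.5, 0.9
        table = PhenotypeTable(pd.DataFrame({"id": [1], "t": [y0]}), spec)
        smp = GibbsSampler(ped, table, seed=0, G0=np.array([[g]]),
                           R0=np.array([[r]]))
        draws = []
        for _ in range(20000):
            smp.step_u()
            draws.append(smp.u[0, 0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(g / (g + r) * y0, abs=0.02)
        assert draws.var() == pytest.approx(1.0 / (1 / g + 1 / r), rel=0.05)

    def test_long_run_mean_matches_mme_solution(self):
        """Posterior mean of (b, u) with fixed (G, R) is the MME solution."""
        cfg = SimulationConfig(n_founders=6, n_generations=1, n_per_generation=6,
                               n_records=10, seed=11,
                               traits=("x", "y"),
                               G_true=np.array([[1.0, 0.3], [0.3, 0.8]]),
                               R_true=np.array([[1.5, -0.2], [-0.2, 1.2]]),
                               trait_means=np.zeros(2),
                               n_hys=2, n_dam_age=2, age_traits=("y",),
                               missingness=[])
        ped, table, truth = simulate_dataset(cfg)
        assert table.mask.all()  # no missing data in this check
        chain = run_gibbs(ped, table, n_iter=12000, burn_in=2000, thin=1,
                          seed=4, update_g=False, update_r=False,
                          G0=truth["G"], R0=truth["R"])
        b_hat, u_hat, post_cov = _mme_solution(ped, table, truth["G"], truth["R"])
        p = b_hat.size
        sd = np.sqrt(np.diag(post_cov))
        # Monte-Carlo error allowance: single-site u sampling autocorrelates
        tol_b = 6 * sd[:p] / np.sqrt(1000)
        tol_u = 6 * sd[p:].reshape(u_hat.shape) / np.sqrt(1000)
        assert np.all(np.abs(chain.b_mean - b_hat) < tol_b + 1e-3)
        assert np.all(np.abs(chain.u_mean - u_hat) < tol_u + 1e-3)


class TestJointDistribution:
    def test_successive_conditional_simulation_recovers_prior(self):
        """Geweke-style check: the Gibbs transitions leave the prior invariant.

        Alternating (simulate data | parameters) with one parameter sweep must
        keep (G, R) marginally distributed as their inverse-Wishart prior;
        compare the chain's first and second moments of G[0,0], R[0,0] with
        the analytic prior moments.
        """
        m = 2
        spec = ModelSpec(traits=("a", "b"), intercept=False)
        ped = simulate_pedigree(
            SimulationConfig(n_founders=10, n_generations=2, n_per_generation=10,
                             n_records=5, seed=5))
        s = ped.size
        rec = np.arange(s - 20, s)
        rng = np.random.default_rng(99)
        prior = Priors(nu0_g=8.0, S0_g=np.eye(m), nu0_r=8.0, S0_r=np.eye(m))
        G0 = invwishart.rvs(8, np.eye(m), random_state=rng)
        R0 = invwishart.rvs(8, np.eye(m), random_state=rng)
        df = pd.DataFrame({"id": [ped.labels[i] for i in rec],
                           "a": 0.0, "b": 0.0})
        table = PhenotypeTable(df, spec)
        smp = GibbsSampler(ped, table, priors=prior, seed=7, G0=G0, R0=R0)
        La = np.linalg.cholesky(ped.relationship_matrix())
        smp.u = La @ rng.standard_normal((s, m)) @ np.linalg.cholesky(smp.G).T
        N = 6000
        g00 = np.empty(N)
        r00 = np.empty(N)
        for it in range(N):
            e = rng.standard_normal((rec.size, m)) @ np.linalg.cholesky(smp.R).T
            smp.y_aug = smp.u[rec] + e
            smp.step_u()
            smp.step_G()
            smp.step_R()
            g00[it] = smp.G[0, 0]
            r00[it] = smp.R[0, 0]
        mean_th = 1.0 / (8 - m - 1)
        sd_th = np.sqrt(2.0 / ((8 - m - 1) ** 2 * (8 - m - 3)))
        for x in (g00, r00):
            batches = x.reshape(60, 100).mean(axis=1)
            mcse = batches.std(ddof=1) / np.sqrt(60)
            assert abs(x.mean() - mean_th) < 4 * mcse + 0.01
            assert x.std() == pytest.approx(sd_th, rel=0.25)


class TestRecoverySmall:
    def test_univariate_h2_matches_independent_scalar_sampler(self):
        """m = 1, family pedigree: h2 posterior matches a plain scalar Gibbs coding.

        Full sib families make g and r separable. The reference sampler is an
        independent scalar implementation of the same animal model (dense
        A^{-1}, single-site u updates, scaled-inverse-chi-square variances).
        """
        from recmt.pedigree import build_A

        g_true, r_true = 2.0, 3.0
        n_fam, fam_size = 40, 6
        recs = []
        k = 2 * n_fam
        for f in range(n_fam):
            recs += [(f"s{f}", 0, 0), (f"d{f}", 0, 0)]
        for f in range(n_fam):
            for o in range(fam_size):
                recs.append((f"o{f}_{o}", f"s{f}", f"d{f}"))
        ped = toposort_pedigree(recs)
        s = ped.size
        rng = np.random.default_rng(8)
        A = build_A(ped)
        u_true = np.linalg.cholesky(A) @ rng.normal(0, np.sqrt(g_true), s)
        y_all = u_true + rng.normal(0, np.sqrt(r_true), s)
        spec = ModelSpec(traits=("t",), intercept=True)
        table = PhenotypeTable(
            pd.DataFrame({"id": list(ped.labels), "t": y_all}), spec)
        chain = run_gibbs(ped, table, n_iter=6000, burn_in=1500, thin=1, seed=3)
        gd, rd = chain.G[:, 0, 0], chain.R[:, 0, 0]
        h2_pkg = gd / (gd + rd)

        # independent scalar implementation, same priors (nu0 = 3, S0 = 0.01)
        nu0, s0 = 3.0, 0.01
        rng2 = np.random.default_rng(31)
        Ainv = np.linalg.inv(A)
        rows = ped.index_of(table.ids)
        y = np.empty(s)
        y[rows] = table.y[:, 0]
        uu = np.zeros(s)
        g, r, b = 1.0, 1.0, y.mean()
        h2_ref = []
        for it in range(6000):
            for i in range(s):
                prec = Ainv[i, i] / g + 1.0 / r
                num = (y[i] - b) / r - (Ainv[i] @ uu - Ainv[i, i] * uu[i]) / g
                uu[i] = num / prec + rng2.normal(0, np.sqrt(1.0 / prec))
            b = (y - uu).mean() + rng2.normal(0, np.sqrt(r / s))
            g = (s0 + uu @ Ainv @ uu) / rng2.chisquare(nu0 + s)
            e = y - b - uu
            r = (s0 + e @ e) / rng2.chisquare(nu0 + s)
            if it >= 1500:
                h2_ref.append(g / (g + r))
        h2_ref = np.array(h2_ref)
        assert h2_pkg.mean() == pytest.approx(h2_ref.mean(), abs=0.04)
        assert h2_pkg.std() == pytest.approx(h2_ref.std(), rel=0.35)
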