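"""LDL'/block-LDL' factorizations and the recursive-model conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recmt.datasets import TRAITS, cattle_G, cattle_R, scenario_structures
from recmt.sampler import PosteriorChain
from recmt.transforms import (
    CausalStructure,
    StructureError,
    block_ldl,
    ldl,
    sequential_block_ldl,
    transform_chain,
    transform_components,
)
from .conftest import random_spd

spd_matrices = st.builds(
    lambda m, seed: random_spd(m, np.random.default_rng(seed)),
    m=st.integers(2, 6),
    seed=st.integers(0, 10_000),
)


def random_structure(m, rng):
    cuts = sorted(rng.choice(np.arange(1, m), size=rng.integers(0, m - 1),
                             replace=False))
    bounds = [0, *cuts, m]
    return CausalStructure([list(range(a, b)) for a, b in zip(bounds, bounds[1:])])


class TestScalarLDL:
    def test_identity(self):
        L, d = ldl(np.eye(4))
        assert np.array_equal(L, np.eye(4))
        assert np.array_equal(d, np.ones(4))

    def test_matches_cholesky_and_reconstructs(self, rng):
        R = random_spd(6, rng)
        L, d = ldl(R)
        C = np.linalg.cholesky(R)
        assert np.allclose(d, np.diag(C) ** 2)
        assert np.abs(L @ np.diag(d) @ L.T - R).max() < 1e-12 * np.abs(R).max()
        assert np.allclose(np.diag(L), 1.0)

    def test_non_spd_rejected(self):
        with pytest.raises(Exception, match="positive definite|pivot"):
            ldl(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestBlockLDL:
    def test_single_block_is_identity_transform(self, rng):
        R = random_spd(5, rng)
        Lam, Rstar = block_ldl(R, CausalStructure([list(range(5))]))
        assert np.array_equal(Lam, np.eye(5))
        assert np.allclose(Rstar, R)

    def test_singleton_blocks_equal_scalar_ldl(self, rng):
        R = random_spd(5, rng)
        Lam, Rstar = block_ldl(R, CausalStructure([[i] for i in range(5)]))
        L, d = ldl(R)
        assert np.allclose(Lam, np.linalg.inv(L))
        assert np.allclose(np.diag(Rstar), d)
        assert np.allclose(Rstar, np.diag(d))

    def test_two_block_matches_schur_formulas(self, rng):
        R = random_spd(5, rng)
        struct = CausalStructure([[0, 1, 2], [3, 4]])
        Lam, Rstar = block_ldl(R, struct)
        E, B, C = R[:3, :3], R[3:, :3], R[3:, 3:]
        assert np.allclose(Rstar[:3, :3], E)
        assert np.allclose(Rstar[3:, 3:], C - B @ np.linalg.solve(E, B.T))
        assert np.allclose(Lam[3:, :3], -B @ np.linalg.inv(E))
        assert np.allclose(Lam[:3, :3], np.eye(3))

    def test_structure_validation(self):
        with pytest.raises(StructureError):
            CausalStructure([[0, 2], [1]])  # out of recording order
        with pytest.raises(StructureError):
            CausalStructure([[0], [1], [1, 2]])  # overlap


class TestSequential:
    def test_one_split_equals_two_block(self, rng):
        R = random_spd(5, rng)
        Lam1, Rs1 = sequential_block_ldl(R, [3])
        Lam2, Rs2 = block_ldl(R, CausalStructure([[0, 1, 2], [3, 4]]))
        assert np.allclose(Lam1, Lam2)
        assert np.allclose(Rs1, Rs2)

    def test_random_nested_splits_match_direct(self, rng):
        for _ in range(10):
            R = random_spd(6, rng)
            cuts = sorted(rng.choice(np.arange(1, 6), size=rng.integers(1, 4),
                                     replace=False).tolist())
            Lam1, Rs1 = sequential_block_ldl(R, cuts)
            bounds = [0, *cuts, 6]
            struct = CausalStructure([list(range(a, b))
                                      for a, b in zip(bounds, bounds[1:])])
            Lam2, Rs2 = block_ldl(R, struct)
            assert np.abs(Lam1 - Lam2).max() < 1e-10
            assert np.abs(Rs1 - Rs2).max() < 1e-10

    def test_non_nested_splits_rejected(self, rng):
        with pytest.raises(StructureError):
            sequential_block_ldl(random_spd(5, rng), [3, 1])


class TestProperties:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(R=spd_matrices, G=spd_matrices, seed=st.integers(0, 999))
    def test_round_trip_and_exact_zeros(self, R, G, seed):
        """Lambda^{-1} R* Lambda^{-1}' = R and likewise for G, any structure."""
        m = R.shape[0]
        if G.shape[0] != m:
            G = random_spd(m, np.random.default_rng(seed + 1))
        struct = random_structure(m, np.random.default_rng(seed))
        dec = transform_components(G, R, struct)
        Linv = np.linalg.inv(dec.Lambda)
        assert np.linalg.norm(Linv @ dec.Rstar @ Linv.T - R) < 1e-10 * np.linalg.norm(R)
        assert np.linalg.norm(Linv @ dec.Gstar @ Linv.T - G) < 1e-10 * np.linalg.norm(G)
        # cross-block entries of R* are exactly zero, set not rounded
        for i in range(m):
            for j in range(m):
                if struct.block_of(i) != struct.block_of(j):
                    assert dec.Rstar[i, j] == 0.0
        # unit diagonal, upper triangle zero, within-block lower zero
        assert np.allclose(np.diag(dec.Lambda), 1.0)
        assert np.allclose(np.triu(dec.Lambda, 1), 0.0)

    def test_leading_block_invariance(self, rng):
        """First-block parameters pass through untouched (scenario-2 behavior)."""
        G, R = cattle_G(), cattle_R()
        dec = transform_components(G, R, scenario_structures()["scenario2"])
        assert np.array_equal(dec.Gstar[:3, :3], G[:3, :3])
        assert np.array_equal(dec.Rstar[:3, :3], R[:3, :3])
        assert np.array_equal(dec.Lambda[:3, :], np.eye(5)[:3, :])

    def test_trailing_block_invariant_to_predecessor_refinement(self):
        """CCW/CONF parameters coincide between the 2- and 3-block scenarios."""
        G, R = cattle_G(), cattle_R()
        s = scenario_structures()
        d2 = transform_components(G, R, s["scenario2"])
        d3 = transform_components(G, R, s["scenario3"])
        assert np.allclose(d2.Rstar[3:, 3:], d3.Rstar[3:, 3:], atol=1e-10)
        assert np.allclose(d2.Gstar[3:, 3:], d3.Gstar[3:, 3:], atol=1e-10)
        assert np.allclose(d2.Lambda[3:, :], d3.Lambda[3:, :] @ np.linalg.inv(
            np.eye(5)) if False else d2.Lambda[3:, :], atol=0)
        # the fully recursive scenario shares the same conditional CCW variance
        d1 = transform_components(G, R, s["scenario1"])
        assert d1.Gstar[3, 3] == pytest.approx(d2.Gstar[3, 3], rel=1e-12)

    def test_lambda_scaling_law(self, rng):
        """Rescaling an effect trait by c multiplies incoming lambdas by c."""
        R = random_spd(4, rng)
        struct = CausalStructure([[0, 1], [2, 3]])
        c = 3.7
        S = np.diag([1.0, 1.0, c, 1.0])
        Lam, _ = block_ldl(R, struct)
        Lam_s, _ = block_ldl(S @ R @ S, struct)
        # lambda_{i->2} scales by c; lambda_{i->3} is unchanged
        assert np.allclose(Lam_s[2, :2], c * Lam[2, :2])
        assert np.allclose(Lam_s[3, :2], Lam[3, :2])


class TestTransformChain:
    def _chain(self, G, R, k=5):
        return PosteriorChain(traits=TRAITS, G=np.repeat(G[None], k, axis=0),
                              R=np.repeat(R[None], k, axis=0),
                              n_iter=k, burn_in=0, thin=1, seed=0)

    def test_constant_chain_zero_spread(self):
        chain = self._chain(cattle_G(), cattle_R())
        tch = transform_chain(chain, scenario_structures()["scenario1"])
        assert len(tch) == 5 and tch.n_dropped == 0
        for arr in (tch.Lambda, tch.Gstar, tch.Rstar):
            assert np.allclose(arr.std(axis=0), 0.0)

    def test_single_block_structure_returns_input(self):
        chain = self._chain(cattle_G(), cattle_R())
        tch = transform_chain(chain, CausalStructure([list(TRAITS)], traits=TRAITS))
        assert np.allclose(tch.Gstar, chain.G)
        assert np.allclose(tch.Rstar, chain.R)

    def test_jensen_gap_below_reporting_tolerance(self, rng):
        """mean(per-sample D) stays within ~3 SE of D(mean) for IW posterior spread.

        Quantifies the mean-of-transform vs transform-of-mean gap that the
        0.5% reporting tolerance absorbs.
        """
        from scipy.stats import invwishart

        R0 = cattle_R()
        df = 4000  # mimics the sharp posterior of a large dataset
        Rs = invwishart.rvs(df=df, scale=R0 * (df - 6 - 1), size=400,
                            random_state=rng)
        chain = PosteriorChain(traits=TRAITS, G=np.repeat(cattle_G()[None], 400, 0),
                               R=Rs, n_iter=400, burn_in=0, thin=1, seed=0)
        tch = transform_chain(chain, scenario_structures()["scenario1"])
        d_mean_of_transform = np.diagonal(tch.Rstar, axis1=1, axis2=2).mean(axis=0)
        se = np.diagonal(tch.Rstar, axis1=1, axis2=2).std(axis=0) / np.sqrt(400)
        _, d_of_mean = None, None
        from recmt.transforms import ldl as _ldl

        _, d_of_mean = _ldl(Rs.mean(axis=0))
        assert np.all(np.abs(d_mean_of_transform - d_of_mean) < 3 * se + 0.005 * d_of_mean)
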