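"""Gibbs sampler for the multiple-trait animal model with data augmentation.

The model for individual i is ``y_i = X_i b + u_i + e_i`` with
``u ~ N(0, A (x) G)`` over all pedigree individuals and ``e_i ~ N(0, R)``
per recorded individual. Records may be partially missing; missing traits
are augmented each iteration from their conditional Gaussian given the
observed traits, so the variance updates always see complete m-variate
residuals. One iteration is a fixed systematic scan:

1. augment missing records,
2. sample the fixed effects b jointly, then each u_i single-site,
3. sample G from its inverse-Wishart full conditional (scale U'A^{-1}U + S0,
   degrees of freedom s + nu0, using all s pedigree individuals),
4. sample R from its inverse-Wishart full conditional (scale sum e_i e_i' + S0
   over the n completed records, degrees of freedom n + nu0).

Priors are flat for b and proper weakly informative inverse-Wishart for G and
R by default (nu0 = m + 2, S0 = 0.01 I), overridable. A single seeded
generator drives every draw in fixed order, so chains are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.stats import invwishart

from ._kernels import gibbs_u_sweep
from .model import Design, PhenotypeTable, build_design
from .pedigree import Pedigree

__all__ = [
    "Priors",
    "PosteriorChain",
    "GibbsSampler",
    "run_gibbs",
    "conditional_moments",
    "sample_missing",
    "sample_G",
    "sample_R",
]


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class Priors:
    """Inverse-Wishart hyperparameters for G and R (flat prior on b)."""

    nu0_g: float
    S0_g: np.ndarray
    nu0_r: float
    S0_r: np.ndarray

    @classmethod
    def default(cls, m: int) -> "Priors":
        return cls(nu0_g=m + 2, S0_g=0.01 * np.eye(m),
                   nu0_r=m + 2, S0_r=0.01 * np.eye(m))


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples of (G, R) plus run metadata."""

    traits: tuple
    G: np.ndarray  # (k, m, m)
    R: np.ndarray  # (k, m, m)
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    b_mean: np.ndarray | None = None
    u_mean: np.ndarray | None = None
    coef_names: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return len(self.traits)

    def posterior_mean_G(self) -> np.ndarray:
        return self.G.mean(axis=0)

    def posterior_mean_R(self) -> np.ndarray:
        return self.R.mean(axis=0)


def _pairwise_covariance(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise-complete covariance, floored to be safely positive definite."""
    m = y.shape[1]
    C = np.eye(m)
    means = np.array([y[mask[:, t], t].mean() if mask[:, t].any() else 0.0
                      for t in range(m)])
    for i in range(m):
        for j in range(i + 1):
            both = mask[:, i] & mask[:, j]
            if both.sum() > 2:
                C[i, j] = C[j, i] = np.mean(
                    (y[both, i] - means[i]) * (y[both, j] - means[j]))
    w, V = np.linalg.eigh(C)
    floor = max(1e-6, 1e-4 * w.max())
    return (V * np.maximum(w, floor)) @ V.T


# ---------------------------------------------------------------------------
# conditional-Gaussian augmentation


def conditional_moments(y, mask, mu, R):
    """Moments of the missing traits given the observed ones.

    Returns ``(mean, cov)`` of ``y_M | y_O`` under ``y ~ N(mu, R)``:
    mean ``mu_M + R_MO R_OO^{-1} (y_O - mu_O)``, covariance
    ``R_MM - R_MO R_OO^{-1} R_OM``.
    """
    O = np.flatnonzero(mask)
    M = np.flatnonzero(~mask)
    if M.size == 0:
        return np.empty(0), np.empty((0, 0))
    if O.size == 0:
        raise SamplerError("record with no observed trait reached augmentation")
    ROO = R[np.ix_(O, O)]
    ROM = R[np.ix_(O, M)]
    K = linalg.solve(ROO, ROM, assume_a="pos").T  # (M, O)
    mean = mu[M] + K @ (y[O] - mu[O])
    cov = R[np.ix_(M, M)] - K @ ROM
    return mean, 0.5 * (cov + cov.T)


def sample_missing(y, mask, mu, R, rng) -> np.ndarray:
    """Return a completed copy of one record, drawing ``y_M | y_O``."""
    out = np.array(y, dtype=float)
    M = np.flatnonzero(~mask)
    if M.size == 0:
        return out
    mean, cov = conditional_moments(y, mask, mu, R)
    out[M] = mean + np.linalg.cholesky(cov) @ rng.standard_normal(M.size)
    return out


# ---------------------------------------------------------------------------
# variance-component full conditionals


def sample_G(u: np.ndarray, Ainv: sparse.spmatrix, prior: Priors, rng) -> np.ndarray:
    """Draw G ~ IW(U'A^{-1}U + S0, s + nu0) given all s breeding values."""
    s = u.shape[0]
    S = u.T @ (Ainv @ u) + prior.S0_g
    draw = invwishart.rvs(df=prior.nu0_g + s, scale=0.5 * (S + S.T), random_state=rng)
    return np.atleast_2d(draw)


def sample_R(residuals: np.ndarray, prior: Priors, rng) -> np.ndarray:
    """Draw R ~ IW(sum e_i e_i' + S0, n + nu0) from completed residuals."""
    n, m = residuals.shape
    df = prior.nu0_r + n
    if df <= m + 1 and not np.any(prior.S0_r):
        raise SamplerError("too few records for an improper residual prior")
    S = residuals.T @ residuals + prior.S0_r
    return np.atleast_2d(invwishart.rvs(df=df, scale=0.5 * (S + S.T), random_state=rng))


# ---------------------------------------------------------------------------
# the sampler


class GibbsSampler:
    """Holds the state of one chain and exposes the individual Gibbs steps.

    Most users call :func:`run_gibbs`; the stepwise interface exists so the
    update blocks can be validated separately (and composed into
    simulation-based calibration checks).
    """

    def __init__(
        self,
        pedigree: Pedigree,
        table: PhenotypeTable,
        priors: Priors | None = None,
        seed: int = 0,
        G0: np.ndarray | None = None,
        R0: np.ndarray | None = None,
    ):
        self.pedigree = pedigree
        self.table = table
        self.m = table.spec.m
        self.priors = priors if priors is not None else Priors.default(self.m)
        self.rng = np.random.default_rng(seed)
        self.design: Design = build_design(table)

        rows = pedigree.index_of(table.ids)
        if len(np.unique(rows)) != len(rows):
            raise SamplerError("multiple phenotype records map to one individual")
        self.rec_row = np.full(pedigree.size, -1, dtype=np.int64)
        self.rec_row[rows] = np.arange(table.n)
        self.Ainv = pedigree.relationship_inverse().tocsr()

        # missingness patterns, grouped once
        self._patterns = []
        if table.n:
            uniq, inv = np.unique(table.mask, axis=0, return_inverse=True)
            for k, pat in enumerate(uniq):
                if not pat.all():
                    self._patterns.append((pat.copy(), np.flatnonzero(inv == k)))

        # cross-products for the joint b update, fixed across iterations
        d = self.design
        self._M = [
            [d.trait_matrix(t1).T @ d.trait_matrix(t2) for t2 in range(self.m)]
            for t1 in range(self.m)
        ]

        # state
        y = table.y.copy()
        col_means = np.nanmean(np.where(table.mask, y, np.nan), axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        self.y_aug = np.where(table.mask, y, col_means)
        self.b = np.zeros(d.p_total)
        self.u = np.zeros((pedigree.size, self.m))
        # start at half the empirical (pairwise-complete) phenotypic covariance
        # for both G and R: starting covariances near plausible values shortens
        # the transient compared to a diagonal start
        emp = _pairwise_covariance(y, table.mask)
        self.G = 0.5 * emp if G0 is None else np.array(G0, dtype=float)
        self.R = 0.5 * emp if R0 is None else np.array(R0, dtype=float)

    # -- steps ----------------------------------------------------------

    def step_missing(self) -> None:
        """Data augmentation: redraw all missing traits, grouped by pattern."""
        if not self._patterns:
            return
        mu = self._record_means()
        for pat, rows in self._patterns:
            O = np.flatnonzero(pat)
            M = np.flatnonzero(~pat)
            ROO = self.R[np.ix_(O, O)]
            ROM = self.R[np.ix_(O, M)]
            K = linalg.solve(ROO, ROM, assume_a="pos").T
            cov = self.R[np.ix_(M, M)] - K @ ROM
            Lc = np.linalg.cholesky(0.5 * (cov + cov.T))
            z = self.rng.standard_normal((rows.size, M.size))
            self.y_aug[np.ix_(rows, M)] = (
                mu[np.ix_(rows, M)]
                + (self.y_aug[np.ix_(rows, O)] - mu[np.ix_(rows, O)]) @ K.T
                + z @ Lc.T
            )

    def _record_means(self) -> np.ndarray:
        """n x m matrix of X_i b + u_i for recorded individuals."""
        mu = self.design.predict(self.b)
        rec = np.flatnonzero(self.rec_row >= 0)
        mu[self.rec_row[rec]] += self.u[rec]
        return mu

    def step_fixed(self) -> None:
        """Joint draw of all fixed-effect coefficients."""
        d = self.design
        if d.p_total == 0:
            return
        Rinv = np.linalg.inv(self.R)
        p = d.p_total
        C = np.zeros((p, p))
        rhs = np.zeros(p)
        W = self.y_aug.copy()
        rec = np.flatnonzero(self.rec_row >= 0)
        W[self.rec_row[rec]] -= self.u[rec]
        V = W @ Rinv
        for t1 in range(self.m):
            s1 = d.coef_slice(t1)
            rhs[s1] = d.trait_matrix(t1).T @ V[:, t1]
            for t2 in range(self.m):
                C[s1, d.coef_slice(t2)] = Rinv[t1, t2] * self._M[t1][t2]
        try:
            Lc = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            raise SamplerError(
                "fixed-effect equations are rank deficient after reference coding"
            ) from None
        mu = linalg.cho_solve((Lc, True), rhs)
        z = self.rng.standard_normal(p)
        self.b = mu + linalg.solve_triangular(Lc, z, lower=True, trans="T")

    def step_u(self) -> None:
        """Single-site scan of breeding values for all pedigree individuals."""
        Rinv = np.linalg.inv(self.R)
        Ginv = np.linalg.inv(self.G)
        W = self.y_aug - self.design.predict(self.b)
        z = self.rng.standard_normal((self.pedigree.size, self.m))
        bad = gibbs_u_sweep(
            self.Ainv.indptr, self.Ainv.indices, self.Ainv.data,
            np.ascontiguousarray(Ginv), np.ascontiguousarray(Rinv),
            np.ascontiguousarray(W), self.rec_row, self.u, z,
        )
        if bad >= 0:
            raise SamplerError(
                f"breeding-value precision not SPD at individual index {bad}"
            )

    def step_location(self) -> None:
        self.step_fixed()
        self.step_u()

    def residuals(self) -> np.ndarray:
        """Completed residuals e_i = y_i - X_i b - u_i for the n records."""
        W = self.y_aug - self.design.predict(self.b)
        rec = np.flatnonzero(self.rec_row >= 0)
        W[self.rec_row[rec]] -= self.u[rec]
        return W

    def step_G(self) -> None:
        self.G = _spd_guard(sample_G(self.u, self.Ainv, self.priors, self.rng), "G")

    def step_G_interweave(self) -> None:
        """Non-centered (ancillarity-sufficiency) rescaling move for G.

        Writing ``u_i = L v_i`` with ``G = L L'`` and ``v ~ N(0, A (x) I)``,
        the likelihood is Gaussian in the free entries of the lower-triangular
        ``L`` given the whitened breeding values v, so ``L`` can be proposed
        from that exact Gaussian and accepted against the (weak) transformed
        inverse-Wishart prior — an independence Metropolis-Hastings step.
        Interweaving this with the centered IW draw moves the sampler along
        the G/R ridge in one jump and removes the slow ridge-diffusion of
        purely centered scans on weakly identified data.
        """
        m = self.m
        L_cur = np.linalg.cholesky(self.G)
        # whitened breeding values; v rows solve L v' = u'
        V = linalg.solve_triangular(L_cur, self.u.T, lower=True).T
        rec = np.flatnonzero(self.rec_row >= 0)
        Vr = V[rec]
        Wr = self.y_aug[self.rec_row[rec]] - self.design.predict(self.b)[self.rec_row[rec]]
        M_uu = Vr.T @ Vr
        M_wu = Wr.T @ Vr
        Rinv = np.linalg.inv(self.R)
        tril = [(t, k) for t in range(m) for k in range(t + 1)]
        d = len(tril)
        P = np.empty((d, d))
        bvec = np.empty(d)
        for a, (t, k) in enumerate(tril):
            bvec[a] = (Rinv[t] @ M_wu)[k]
            for b, (t2, k2) in enumerate(tril):
                P[a, b] = Rinv[t, t2] * M_uu[k, k2]
        try:
            Lp = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            return  # degenerate whitened design; skip the move
        mu = linalg.cho_solve((Lp, True), bvec)
        theta = mu + linalg.solve_triangular(Lp, self.rng.standard_normal(d),
                                             lower=True, trans="T")
        L_new = np.zeros((m, m))
        for a, (t, k) in enumerate(tril):
            L_new[t, k] = theta[a]
        if np.any(np.diag(L_new) <= 0):
            return  # outside the prior's support; reject
        if np.log(self.rng.uniform()) < self._log_prior_chol(L_new) - \
                self._log_prior_chol(L_cur):
            self.G = _spd_guard(L_new @ L_new.T, "G")
            self.u = V @ L_new.T

    def _log_prior_chol(self, L: np.ndarray) -> float:
        """Log inverse-Wishart prior of G = LL' in L coordinates (with Jacobian)."""
        m = self.m
        ld = np.log(np.diag(L))
        try:
            Gi_S = linalg.cho_solve((L, True), self.priors.S0_g)
        except Exception:
            return -np.inf
        nu = self.priors.nu0_g
        jac = np.sum((m - np.arange(m)) * ld)  # |dG/dL| = 2^m prod L_ii^{m-i+1}
        return float(-(nu + m + 1) * ld.sum() - 0.5 * np.trace(Gi_S) + jac)

    def step_R(self) -> None:
        self.R = _spd_guard(sample_R(self.residuals(), self.priors, self.rng), "R")

    def step(self, update_g: bool = True, update_r: bool = True,
             u_sweeps: int = 1, interweave: bool = True) -> None:
        """One full systematic scan: missing -> location -> G (-> interweave) -> R.

        ``u_sweeps`` repeats the breeding-value scan within the iteration;
        extra sweeps relax the u field faster (each sweep is a valid Gibbs
        update), which improves mixing of the G/R partition on small datasets
        at modest cost. ``interweave`` adds the non-centered rescaling move
        for G after the centered draw (see :meth:`step_G_interweave`).
        """
        self.step_missing()
        self.step_fixed()
        for _ in range(max(1, u_sweeps)):
            self.step_u()
        if update_g:
            self.step_G()
            if interweave:
                self.step_G_interweave()
        if update_r:
            self.step_R()


def _spd_guard(M: np.ndarray, name: str) -> np.ndarray:
    M = 0.5 * (M + M.T)
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        M = M + 1e-10 * np.trace(M) / M.shape[0] * np.eye(M.shape[0])
        try:
            np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            raise SamplerError(f"sampled {name} not positive definite") from None
    return M


def run_gibbs(
    pedigree: Pedigree,
    table: PhenotypeTable,
    n_iter: int,
    burn_in: int,
    thin: int = 10,
    seed: int = 0,
    priors: Priors | None = None,
    update_g: bool = True,
    update_r: bool = True,
    G0: np.ndarray | None = None,
    R0: np.ndarray | None = None,
    u_sweeps: int = 1,
    interweave: bool = True,
    progress: int = 0,
) -> PosteriorChain:
    """Run one chain and return thinned post-burn-in (G, R) samples.

    ``update_g``/``update_r`` fix the corresponding matrix at its start value
    (``G0``/``R0``), which turns the sampler into a draw from the location
    conditional — used for validation against the mixed-model equations.
    Running means of b and u over stored iterations are kept on the chain.
    """
    if burn_in >= n_iter:
        raise ValueError("n_iter must exceed burn_in")
    smp = GibbsSampler(pedigree, table, priors=priors, seed=seed, G0=G0, R0=R0)
    m = smp.m
    keep = range(burn_in, n_iter, thin)
    k = len(keep)
    Gs = np.empty((k, m, m))
    Rs = np.empty((k, m, m))
    b_sum = np.zeros_like(smp.b)
    u_sum = np.zeros_like(smp.u)
    stored = 0
    keepset = set(keep)
    for it in range(n_iter):
        try:
            smp.step(update_g=update_g, update_r=update_r, u_sweeps=u_sweeps,
                     interweave=interweave)
        except SamplerError as err:
            raise SamplerError(f"iteration {it}: {err}") from err
        if it in keepset:
            Gs[stored] = smp.G
            Rs[stored] = smp.R
            b_sum += smp.b
            u_sum += smp.u
            stored += 1
        if progress and (it + 1) % progress == 0:
            print(f"iter {it + 1}/{n_iter}  diag(G)={np.round(np.diag(smp.G), 3)}"
                  f"  diag(R)={np.round(np.diag(smp.R), 3)}")
    return PosteriorChain(
        traits=table.spec.traits, G=Gs, R=Rs,
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed,
        b_mean=b_sum / max(stored, 1), u_mean=u_sum / max(stored, 1),
        coef_names=smp.design.coef_names(),
        meta={"n_records": table.n, "n_individuals": pedigree.size,
              "n_dropped": table.n_dropped},
    )
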