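"""LDL' and block-LDL' conversion of multi-trait (G, R) into recursive models.

A standard multiple-trait (SM) animal model and a fully linked recursive
(structural equation) model parameterize the same likelihood. Premultiplying
the SM by a unit-lower-triangular matrix ``Lambda`` gives the recursive form

    Lambda y_i = Lambda X_i b + u*_i + e*_i,

with ``G* = Lambda G Lambda'`` and ``R* = Lambda R Lambda'``. Choosing
``Lambda`` so that ``R*`` is (block-)diagonal — i.e. taking the (block-)LDL'
factorization ``R = L D L'`` with ``Lambda = L^{-1}`` — yields the recursive
model in which all residual links between causally ordered trait blocks are
absorbed into structural coefficients ``lambda_{i->j} = -Lambda[j, i]``.
Applying the transformation to every posterior sample of (G, R) converts a
single SM fit into posterior inference under any such recursive model.

Because ``Lambda y`` is the Gaussian innovation representation, the rows of
``Lambda`` for a block are minus the regression coefficients of that block's
traits on all preceding traits, and the corresponding ``R*`` diagonal block
is the Schur complement (the conditional residual covariance given the
preceding blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "CausalStructure",
    "RecursiveDecomposition",
    "TransformedChain",
    "ldl",
    "block_ldl",
    "sequential_block_ldl",
    "transform_components",
    "transform_chain",
]


class StructureError(ValueError):
    """Invalid causal block structure."""


@dataclass(frozen=True)
class CausalStructure:
    """An ordered partition of traits into causal blocks.

    Earlier blocks causally affect later ones; traits within a block are
    linked only through (residual and genetic) covariance. Blocks must be
    contiguous in the trait recording order: their concatenation is exactly
    the trait list.

    Parameters
    ----------
    blocks : sequence of sequences of str or int
        Ordered blocks, by trait name (if ``traits`` is given) or index.
    traits : sequence of str, optional
        Trait names defining index order.
    """

    blocks: tuple
    traits: tuple | None = None
    index_blocks: tuple = field(init=False)

    def __init__(self, blocks: Sequence[Sequence], traits: Sequence[str] | None = None):
        object.__setattr__(self, "traits", tuple(traits) if traits is not None else None)
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in blocks))
        if self.traits is not None:
            name_to_idx = {t: i for i, t in enumerate(self.traits)}
            idx_blocks = tuple(
                tuple(b if isinstance(b, (int, np.integer)) else name_to_idx[b] for b in blk)
                for blk in self.blocks
            )
        else:
            idx_blocks = tuple(tuple(int(b) for b in blk) for blk in self.blocks)
        flat = [i for blk in idx_blocks for i in blk]
        if flat != list(range(len(flat))):
            raise StructureError(
                "blocks must be disjoint, cover all traits and follow the trait "
                f"recording order; got index blocks {idx_blocks}"
            )
        if any(len(blk) == 0 for blk in idx_blocks):
            raise StructureError("empty block")
        object.__setattr__(self, "index_blocks", idx_blocks)

    @property
    def m(self) -> int:
        return sum(len(b) for b in self.index_blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.index_blocks)

    def block_of(self, i: int) -> int:
        for k, blk in enumerate(self.index_blocks):
            if i in blk:
                return k
        raise IndexError(i)

    def cross_block_pairs(self) -> list[tuple[int, int]]:
        """(cause, effect) trait-index pairs for which a coefficient exists."""
        pairs = []
        for kb, blk in enumerate(self.index_blocks):
            pred = [i for b in self.index_blocks[:kb] for i in b]
            for j in blk:
                pairs += [(i, j) for i in pred]
        return pairs

    def trait_name(self, i: int) -> str:
        return self.traits[i] if self.traits is not None else str(i)


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, rtol=0, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError(f"{name} must be symmetric")
    return M


def ldl(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scalar LDL' factorization ``R = L D L'`` of an SPD matrix.

    Returns
    -------
    L : ndarray
        Unit lower triangular.
    d : ndarray
        The positive diagonal of ``D`` as a 1-D array. Under the fully
        recursive ordering, ``d`` is the vector of recursive-model residual
        variances and ``L^{-1}`` is ``Lambda``.
    """
    R = _check_spd(R, "R")
    try:
        C = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        piv = float(np.linalg.eigvalsh(R).min())
        raise linalg.LinAlgError(
            f"matrix is not positive definite (smallest pivot/eigenvalue {piv:.3g})"
        ) from None
    d = np.diag(C) ** 2
    L = C / np.diag(C)
    return L, d


def _lambda_rows(R: np.ndarray, index_blocks: Sequence[Sequence[int]]) -> np.ndarray:
    """Unit-lower-triangular ``Lambda`` with ``Lambda[blk, pred] = -R[blk,pred] R[pred,pred]^{-1}``."""
    m = R.shape[0]
    tol = 1e-10 * np.trace(R) / m  # scale-aware pivot guard
    Lam = np.eye(m)
    pred: list[int] = []
    for blk in index_blocks:
        if pred:
            P = np.ix_(pred, pred)
            lead = R[P]
            if np.linalg.eigvalsh(lead).min() <= tol:
                raise linalg.LinAlgError(
                    f"leading block {pred} is singular to working precision"
                )
            coefs = np.linalg.solve(lead, R[np.ix_(pred, list(blk))]).T
            Lam[np.ix_(list(blk), pred)] = -coefs
        pred += list(blk)
    return Lam


def block_ldl(
    R: np.ndarray, structure: CausalStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Block-LDL' factorization of ``R`` for an ordered block structure.

    Returns ``(Lambda, R*)`` where ``Lambda = L^{-1}`` is unit lower
    triangular with zeros within diagonal blocks, and ``R* = Lambda R
    Lambda'`` is exactly block diagonal: each diagonal block is the Schur
    complement ``C - B E^{-1} B'`` of the preceding traits. With singleton
    blocks this reduces to the scalar LDL'.
    """
    R = _check_spd(R, "R")
    if structure.m != R.shape[0]:
        raise StructureError(
            f"structure covers {structure.m} traits but R is {R.shape[0]}x{R.shape[0]}"
        )
    Lam = _lambda_rows(R, structure.index_blocks)
    Rfull = Lam @ R @ Lam.T
    # off-diagonal cross-block entries are zero by construction; set exactly
    Rstar = np.zeros_like(Rfull)
    for blk in structure.index_blocks:
        B = np.ix_(list(blk), list(blk))
        Rstar[B] = Rfull[B]
    Rstar = 0.5 * (Rstar + Rstar.T)
    return Lam, Rstar


def sequential_block_ldl(
    R: np.ndarray, splits: Sequence[int], traits: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential two-block LDL' factorizations with nested split points.

    ``splits`` are strictly increasing cut positions: split ``c`` factors the
    current matrix into leading traits ``[:c]`` and trailing traits ``[c:]``,
    and each later split refines the trailing block of the earlier one. The
    product of the per-split ``Lambda`` factors equals the direct multi-block
    factorization over the final partition, because the trailing Schur
    complement of a refined split nests inside the coarser one.

    Returns ``(Lambda, R*)`` over the final partition.
    """
    R = _check_spd(R, "R")
    m = R.shape[0]
    splits = list(splits)
    if any(not 0 < c < m for c in splits) or sorted(set(splits)) != splits:
        raise StructureError(
            f"splits must be strictly increasing cut positions in (0, {m}); got {splits}"
        )
    Lam_total = np.eye(m)
    Rk = R
    for c in splits:
        two_block = CausalStructure([list(range(c)), list(range(c, m))])
        Lam_k, Rk = block_ldl(Rk, two_block)
        Lam_total = Lam_k @ Lam_total
    bounds = [0] + splits + [m]
    final = CausalStructure(
        [list(range(a, b)) for a, b in zip(bounds[:-1], bounds[1:])],
        traits=traits,
    )
    # zero the cross-block fill of the final partition exactly
    Rstar = np.zeros_like(Rk)
    for blk in final.index_blocks:
        B = np.ix_(list(blk), list(blk))
        Rstar[B] = Rk[B]
    return Lam_total, 0.5 * (Rstar + Rstar.T)


@dataclass(frozen=True)
class RecursiveDecomposition:
    """Recursive-model parameters equivalent to one (G, R) pair.

    ``Lambda`` is unit lower triangular with structural coefficients
    ``lambda_{i->j} = -Lambda[j, i]`` for cross-block pairs, ``Rstar`` is
    block diagonal over the causal blocks and ``Gstar = Lambda G Lambda'``.
    """

    structure: CausalStructure
    Lambda: np.ndarray
    Gstar: np.ndarray
    Rstar: np.ndarray

    @property
    def lambdas(self) -> dict[tuple[str, str], float]:
        """Structural coefficients keyed by (cause trait, effect trait)."""
        return {
            (self.structure.trait_name(i), self.structure.trait_name(j)):
                -self.Lambda[j, i]
            for i, j in self.structure.cross_block_pairs()
        }

    @property
    def heritabilities(self) -> np.ndarray:
        """Per-trait h2 under the recursive model, Gstar_tt/(Gstar_tt+Rstar_tt)."""
        g, r = np.diag(self.Gstar), np.diag(self.Rstar)
        return g / (g + r)

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """Map back to the standard-model (G, R)."""
        Linv = np.linalg.inv(self.Lambda)
        return Linv @ self.Gstar @ Linv.T, Linv @ self.Rstar @ Linv.T


def transform_components(
    G: np.ndarray, R: np.ndarray, structure: CausalStructure
) -> RecursiveDecomposition:
    """Convert one (G, R) pair into the recursive model for ``structure``.

    ``Lambda`` and ``R*`` come from the block-LDL' of ``R`` (scalar LDL' when
    all blocks are singletons); ``G* = Lambda G Lambda'``.
    """
    G = _check_spd(G, "G")
    Lam, Rstar = block_ldl(R, structure)
    Gstar = Lam @ G @ Lam.T
    return RecursiveDecomposition(structure=structure, Lambda=Lam,
                                  Gstar=0.5 * (Gstar + Gstar.T), Rstar=Rstar)


@dataclass
class TransformedChain:
    """Per-sample recursive-model parameters for a posterior chain.

    Arrays are stacked over the retained samples; samples whose R failed the
    factorization are dropped and counted in ``n_dropped``.
    """

    structure: CausalStructure
    traits: tuple
    Lambda: np.ndarray  # (k, m, m)
    Gstar: np.ndarray
    Rstar: np.ndarray
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.Lambda.shape[0]

    @property
    def m(self) -> int:
        return len(self.traits)

    def lambda_samples(self) -> dict[tuple[str, str], np.ndarray]:
        """Per-sample structural coefficients keyed by (cause, effect)."""
        return {
            (self.structure.trait_name(i), self.structure.trait_name(j)):
                -self.Lambda[:, j, i]
            for i, j in self.structure.cross_block_pairs()
        }

    def heritability_samples(self) -> np.ndarray:
        """(k, m) per-sample heritabilities under the recursive model."""
        g = np.diagonal(self.Gstar, axis1=1, axis2=2)
        r = np.diagonal(self.Rstar, axis1=1, axis2=2)
        return g / (g + r)


def transform_chain(chain, structure: CausalStructure) -> TransformedChain:
    """Apply :func:`transform_components` to every stored (G, R) sample.

    ``chain`` is any object with ``G``/``R`` arrays of shape (k, m, m) and a
    ``traits`` tuple (a :class:`~recmt.sampler.PosteriorChain`). Matching the
    per-iteration pipeline, each posterior sample is transformed separately;
    summaries of nonlinear functions (correlations, heritabilities, lambdas)
    are then taken over transformed samples.
    """
    import warnings

    k = chain.G.shape[0]
    if k == 0:
        raise ValueError("empty chain")
    m = chain.G.shape[1]
    Lams = np.empty((k, m, m))
    Gs = np.empty((k, m, m))
    Rs = np.empty((k, m, m))
    kept = 0
    dropped = []
    for s in range(k):
        try:
            dec = transform_components(chain.G[s], chain.R[s], structure)
        except (linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
            dropped.append(s)
            continue
        Lams[kept] = dec.Lambda
        Gs[kept] = dec.Gstar
        Rs[kept] = dec.Rstar
        kept += 1
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} non-factorizable samples "
            f"(first at index {dropped[0]})"
        )
    return TransformedChain(
        structure=structure, traits=tuple(chain.traits),
        Lambda=Lams[:kept], Gstar=Gs[:kept], Rstar=Rs[:kept],
        n_dropped=len(dropped),
        meta=dict(getattr(chain, "meta", {})),
    )
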