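"""Posterior summaries and chain diagnostics.

Summaries follow the per-sample-then-average convention: correlations,
heritabilities and structural coefficients are computed for every stored
posterior sample and the mean/SD is taken over those derived samples, which
is what a per-iteration transformation pipeline reports. Formatted tables
put variances on the diagonal, covariances above it and correlations below
it, the layout conventional in animal-breeding papers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "cov_to_corr",
    "heritability",
    "effective_sample_size",
    "summarize_chain",
    "ChainSummary",
    "format_cov_table",
]


def cov_to_corr(M: np.ndarray) -> np.ndarray:
    """Correlation matrix ``rho_ij = M_ij / sqrt(M_ii M_jj)``."""
    M = np.asarray(M, dtype=float)
    d = np.diag(M)
    if np.any(d <= 0):
        raise ValueError("covariance matrix has a non-positive diagonal")
    s = np.sqrt(d)
    return M / np.outer(s, s)


def heritability(G: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Per-trait ``h2_t = G_tt / (G_tt + R_tt)`` (no further variance terms)."""
    g, r = np.diag(np.asarray(G, float)), np.diag(np.asarray(R, float))
    tot = g + r
    if np.any(tot <= 0):
        raise ValueError("zero total variance")
    return g / tot


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial-positive-sequence truncation.

    The integrated autocorrelation time is ``tau = -1 + 2 sum Gamma_k`` with
    ``Gamma_k = rho_{2k} + rho_{2k+1}`` summed while positive; ESS = n / tau,
    capped at n. A constant chain has zero autocorrelation by convention and
    returns n.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return float(n)
    x = x - x.mean()
    if np.allclose(x, 0.0, atol=1e-300):
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    tau = -1.0
    k = 0
    while 2 * k + 1 < n:
        gamma = rho[2 * k] + rho[2 * k + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        k += 1
    tau = max(tau, 1e-12)
    return float(min(n / tau, n))


@dataclass
class ChainSummary:
    """Posterior mean/SD matrices and derived-quantity summaries for one chain."""

    traits: tuple
    kind: str  # "standard" or the structure label of a transformed chain
    G_mean: np.ndarray
    G_sd: np.ndarray
    R_mean: np.ndarray
    R_sd: np.ndarray
    G_corr_mean: np.ndarray
    G_corr_sd: np.ndarray
    R_corr_mean: np.ndarray
    R_corr_sd: np.ndarray
    h2_mean: np.ndarray
    h2_sd: np.ndarray
    lambda_mean: dict = field(default_factory=dict)
    lambda_sd: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)

    def genetic_table(self) -> pd.DataFrame:
        return format_cov_table(self.G_mean, self.G_sd,
                                self.G_corr_mean, self.G_corr_sd, self.traits)

    def residual_table(self, mask_zero: bool = False) -> pd.DataFrame:
        return format_cov_table(self.R_mean, self.R_sd,
                                self.R_corr_mean, self.R_corr_sd, self.traits,
                                mask_zero=mask_zero)

    def to_long(self) -> pd.DataFrame:
        """Tidy (parameter, structure, mean, sd) records at full precision."""
        rows = []
        m = len(self.traits)
        for i in range(m):
            for j in range(i, m):
                rows.append(("G", f"{self.traits[i]}:{self.traits[j]}",
                             self.G_mean[i, j], self.G_sd[i, j]))
                rows.append(("R", f"{self.traits[i]}:{self.traits[j]}",
                             self.R_mean[i, j], self.R_sd[i, j]))
                if i != j:
                    rows.append(("G_corr", f"{self.traits[i]}:{self.traits[j]}",
                                 self.G_corr_mean[i, j], self.G_corr_sd[i, j]))
                    rows.append(("R_corr", f"{self.traits[i]}:{self.traits[j]}",
                                 self.R_corr_mean[i, j], self.R_corr_sd[i, j]))
        for t, h, hs in zip(self.traits, self.h2_mean, self.h2_sd):
            rows.append(("h2", t, h, hs))
        for (a, b), v in self.lambda_mean.items():
            rows.append(("lambda", f"{a}->{b}", v, self.lambda_sd[(a, b)]))
        out = pd.DataFrame(rows, columns=["family", "parameter", "mean", "sd"])
        out.insert(0, "structure", self.kind)
        return out


def format_cov_table(mean, sd, corr_mean, corr_sd, traits,
                     decimals: int = 2, mask_zero: bool = False) -> pd.DataFrame:
    """'mean (sd)' strings: variances diagonal, covariances upper, correlations lower."""
    m = len(traits)
    out = pd.DataFrame("", index=list(traits), columns=list(traits))
    for i in range(m):
        for j in range(m):
            if i <= j:
                v, s = mean[i, j], sd[i, j]
            else:
                v, s = corr_mean[i, j], corr_sd[i, j]
            if mask_zero and i != j and v == 0 and s == 0:
                out.iat[i, j] = "-"
            else:
                out.iat[i, j] = f"{v:.{decimals}f} ({s:.{decimals}f})"
    return out


def _corr_samples(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    denom = d[:, :, None] * d[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, cov / denom, 0.0)
    return rho


def summarize_chain(chain, compute_ess: bool = True) -> ChainSummary:
    """Posterior mean/SD of all parameters of a (possibly transformed) chain.

    Accepts a :class:`~recmt.sampler.PosteriorChain` (attributes ``G``/``R``)
    or a :class:`~recmt.transforms.TransformedChain` (``Gstar``/``Rstar``
    plus structural coefficients). Derived quantities are computed per sample
    and then averaged. ESS is reported for the genetic variances.
    """
    transformed = hasattr(chain, "Gstar")
    G = chain.Gstar if transformed else chain.G
    R = chain.Rstar if transformed else chain.R
    if G.shape[0] == 0:
        raise ValueError("empty chain")
    traits = tuple(chain.traits)
    Gc, Rc = _corr_samples(G), _corr_samples(R)
    gdiag = np.diagonal(G, axis1=1, axis2=2)
    rdiag = np.diagonal(R, axis1=1, axis2=2)
    h2 = gdiag / (gdiag + rdiag)
    lam_mean, lam_sd = {}, {}
    if transformed:
        for key, samples in chain.lambda_samples().items():
            lam_mean[key] = float(samples.mean())
            lam_sd[key] = float(samples.std(ddof=1)) if len(samples) > 1 else 0.0
    ess = {}
    if compute_ess and G.shape[0] >= 100:
        for t in range(len(traits)):
            ess[traits[t]] = effective_sample_size(gdiag[:, t])
    ddof = 1 if G.shape[0] > 1 else 0
    return ChainSummary(
        traits=traits,
        kind=("-".join("(" + ",".join(chain.structure.trait_name(i) for i in blk) + ")"
                       for blk in chain.structure.index_blocks)
              if transformed else "standard"),
        G_mean=G.mean(axis=0), G_sd=G.std(axis=0, ddof=ddof),
        R_mean=R.mean(axis=0), R_sd=R.std(axis=0, ddof=ddof),
        G_corr_mean=Gc.mean(axis=0), G_corr_sd=Gc.std(axis=0, ddof=ddof),
        R_corr_mean=Rc.mean(axis=0), R_corr_sd=Rc.std(axis=0, ddof=ddof),
        h2_mean=h2.mean(axis=0), h2_sd=h2.std(axis=0, ddof=ddof),
        lambda_mean=lam_mean, lambda_sd=lam_sd, ess=ess,
    )
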