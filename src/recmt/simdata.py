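"""Synthetic pedigrees and multi-trait phenotypes for validation studies.

The generator emulates the data structure of a beef-cattle genetic
evaluation at desk scale: a multi-generation pedigree under random mating,
five Gaussian traits with the published genetic and residual covariance
matrices as defaults, a herd-year-season-like factor, sex, dam-age and an
age-at-recording covariate, and pattern-structured missingness (each
individual is observed on one subset of traits, mimicking the recording
routes farm -> weighing -> slaughterhouse).

Breeding values are simulated by pedigree recursion (founder draw plus
Mendelian sampling, ``u_i = (u_s + u_d)/2 + eta_i`` with
``eta_i ~ N(0, d_i G)``), which realizes ``u ~ N(0, A (x) G)`` at O(s) cost
and exactly accounts for parental inbreeding through ``d_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CovariateSpec, FactorSpec, ModelSpec, PhenotypeTable
from .pedigree import Pedigree, mendelian_variances

__all__ = [
    "SimulationConfig",
    "default_missingness",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "apply_missingness",
    "simulate_dataset",
]


def default_missingness() -> list[tuple[tuple[str, ...], float]]:
    """Observed-trait patterns with shares mimicking the cattle recording routes.

    Every individual has a birth weight; later traits depend on whether it
    was weighed at 90/210 days and whether it went to the slaughterhouse.
    Shares are the relative sizes of the largest recorded combinations in the
    cattle data (the remainder, ~32%, is birth weight only).
    """
    return [
        (("BW",), 0.317),
        (("BW", "W90"), 0.151),
        (("BW", "CCW", "CONF"), 0.138),
        (("BW", "W90", "W210"), 0.098),
        (("BW", "W210"), 0.095),
        (("BW", "W90", "CCW", "CONF"), 0.086),
        (("BW", "W210", "CCW", "CONF"), 0.057),
        (("BW", "W90", "W210", "CCW", "CONF"), 0.058),
    ]


def _default_G():
    from .datasets import cattle_G

    return cattle_G()


def _default_R():
    from .datasets import cattle_R

    return cattle_R()


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults produce a pedigree of ~3,000 individuals over four discrete
    generations with ~2,000 phenotyped individuals, the published cattle
    (G, R) as truth, a 25-level herd-year-season factor, sex (2 levels),
    dam age (6 levels), an age covariate for all traits but BW, and the
    pattern-structured missingness of :func:`default_missingness`.
    """

    n_founders: int = 600
    n_generations: int = 4
    n_per_generation: int = 600
    traits: tuple = ("BW", "W90", "W210", "CCW", "CONF")
    G_true: np.ndarray = field(default_factory=_default_G)
    R_true: np.ndarray = field(default_factory=_default_R)
    trait_means: np.ndarray = field(
        default_factory=lambda: np.array([41.12, 134.46, 250.71, 300.29, 11.86])
    )
    n_records: int = 2000
    n_hys: int = 25          # herd-year-season-like contemporary groups
    n_dam_age: int = 6
    age_traits: tuple | None = ("W90", "W210", "CCW", "CONF")
    hys_sd_frac: float = 0.25   # contemporary-group effect SD as fraction of trait SD
    sex_effect_frac: float = 0.15
    age_slope_frac: float = 0.02  # per unit of centered age, as fraction of trait SD
    missingness: list = field(default_factory=default_missingness)
    seed: int = 0

    def __post_init__(self):
        for name, M in (("G_true", self.G_true), ("R_true", self.R_true)):
            M = np.asarray(M, dtype=float)
            if M.shape != (len(self.traits),) * 2 or not np.allclose(M, M.T):
                raise ValueError(f"{name} must be a symmetric m x m matrix")
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                raise ValueError(f"{name} must be positive definite") from None
        probs = [p for _, p in self.missingness]
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1 + 1e-9:
            raise ValueError("missingness probabilities must lie in [0,1], sum <= 1")

    @property
    def m(self) -> int:
        return len(self.traits)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            traits=tuple(self.traits),
            factors=(FactorSpec("hys"), FactorSpec("sex"), FactorSpec("dam_age")),
            covariates=(CovariateSpec("age", tuple(self.age_traits))
                        if self.age_traits else CovariateSpec("age"),),
        )


def simulate_pedigree(config: SimulationConfig, rng=None) -> Pedigree:
    """Discrete-generation pedigree under random mating.

    Founders are unrelated; each later individual draws a sire and a dam
    (distinct individuals) uniformly from the previous generation, so related
    matings — and hence inbreeding — arise by chance.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.n_founders < 2:
        raise ValueError("need at least two founders")
    labels = [f"F{i}" for i in range(1, config.n_founders + 1)]
    sire = [-1] * config.n_founders
    dam = [-1] * config.n_founders
    prev = list(range(config.n_founders))
    nxt = config.n_founders
    for g in range(1, config.n_generations + 1):
        cur = []
        for _ in range(config.n_per_generation):
            s, d = rng.choice(prev, size=2, replace=False)
            labels.append(f"G{g}_{nxt + 1}")
            sire.append(int(s))
            dam.append(int(d))
            cur.append(nxt)
            nxt += 1
        prev = cur
    return Pedigree(labels=tuple(labels), sire=np.array(sire), dam=np.array(dam))


def simulate_breeding_values(
    pedigree: Pedigree, G: np.ndarray, rng
) -> np.ndarray:
    """Draw ``u ~ N(0, A (x) G)`` by pedigree recursion (Mendelian sampling)."""
    m = G.shape[0]
    Lg = np.linalg.cholesky(G)
    d = mendelian_variances(pedigree)
    z = rng.standard_normal((pedigree.size, m))
    u = np.empty((pedigree.size, m))
    si, di = pedigree.sire, pedigree.dam
    for i in range(pedigree.size):
        mean = np.zeros(m)
        if si[i] >= 0:
            mean += 0.5 * u[si[i]]
        if di[i] >= 0:
            mean += 0.5 * u[di[i]]
        u[i] = mean + np.sqrt(d[i]) * (Lg @ z[i])
    return u


def simulate_phenotypes(
    pedigree: Pedigree, config: SimulationConfig, rng=None
) -> tuple[PhenotypeTable, dict]:
    """Forward-simulate complete records ``y_i = X_i b + u_i + e_i``.

    The ``config.n_records`` youngest individuals are phenotyped. Returns the
    (complete, pre-masking) table and a ``truth`` dict with the simulated
    ``u``, fixed-effect frame and true parameter matrices.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    m = config.m
    u = simulate_breeding_values(pedigree, config.G_true, rng)
    n = min(config.n_records, pedigree.size)
    rec = np.arange(pedigree.size - n, pedigree.size)

    sd = np.sqrt(np.diag(config.R_true) + np.diag(config.G_true))
    hys = rng.integers(1, config.n_hys + 1, size=n)
    sex = rng.integers(1, 3, size=n)
    dam_age = rng.integers(1, config.n_dam_age + 1, size=n)
    age = rng.uniform(-15.0, 15.0, size=n)  # days around the trait's target age

    hys_eff = rng.normal(0.0, config.hys_sd_frac, size=(config.n_hys, m)) * sd
    sex_eff = np.outer([-0.5, 0.5], config.sex_effect_frac * sd)
    dam_eff = rng.normal(0.0, 0.5 * config.hys_sd_frac, size=(config.n_dam_age, m)) * sd
    slope = config.age_slope_frac * sd
    age_mask = np.ones(m, dtype=bool)
    if config.age_traits is not None:
        age_mask = np.array([t in config.age_traits for t in config.traits])

    e = rng.standard_normal((n, m)) @ np.linalg.cholesky(config.R_true).T
    y = (
        config.trait_means
        + hys_eff[hys - 1]
        + sex_eff[sex - 1]
        + dam_eff[dam_age - 1]
        + np.outer(age, slope * age_mask)
        + u[rec]
        + e
    )
    df = pd.DataFrame(
        {
            "id": [pedigree.labels[i] for i in rec],
            "hys": hys,
            "sex": sex,
            "dam_age": dam_age,
            "age": age,
        }
    )
    for t, name in enumerate(config.traits):
        df[name] = y[:, t]
    table = PhenotypeTable(df, config.model_spec())
    truth = {
        "u": u, "e": e, "record_indices": rec,
        "G": config.G_true, "R": config.R_true,
        "hys_eff": hys_eff, "sex_eff": sex_eff, "dam_eff": dam_eff,
        "slope": slope * age_mask,
    }
    return table, truth


def apply_missingness(
    table: PhenotypeTable,
    patterns: list[tuple[tuple[str, ...], float]] | None = None,
    seed: int = 0,
    rng=None,
) -> tuple[PhenotypeTable, pd.Series]:
    """Assign each individual one observed-trait pattern and mask the rest.

    ``patterns`` is a list of (observed trait subset, probability); any
    remaining probability mass means "all traits observed". Missingness is
    completely at random given the assignment. Returns the masked table and
    the per-pattern assignment counts.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    patterns = default_missingness() if patterns is None else patterns
    traits = table.spec.traits
    for subset, _ in patterns:
        unknown = set(subset) - set(traits)
        if unknown:
            raise ValueError(f"pattern references unknown traits {unknown}")
        if len(subset) == 0:
            raise ValueError("a pattern must observe at least one trait")
    probs = np.array([p for _, p in patterns], dtype=float)
    rest = 1.0 - probs.sum()
    if rest < -1e-9:
        raise ValueError("pattern probabilities sum above 1")
    subsets = [tuple(s) for s, _ in patterns] + [tuple(traits)]
    probs = np.append(probs, max(rest, 0.0))
    probs = probs / probs.sum()
    choice = rng.choice(len(subsets), size=table.n, p=probs)

    df = table.df.copy()
    for k, subset in enumerate(subsets):
        rows = choice == k
        for t in traits:
            if t not in subset:
                df.loc[rows, t] = np.nan
    masked = PhenotypeTable(df, table.spec)
    labels = ["-".join(s) for s in subsets]
    counts = pd.Series(choice).value_counts().sort_index()
    counts.index = [labels[k] for k in counts.index]
    return masked, counts


def simulate_dataset(config: SimulationConfig):
    """Pedigree + masked phenotypes + truth, all from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    table, truth = simulate_phenotypes(ped, config, rng)
    masked, counts = apply_missingness(table, config.missingness, rng=rng)
    truth["pattern_counts"] = counts
    return ped, masked, truth
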