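"""Model specification, phenotype container and fixed-effect design building.

The fixed part of the model is trait-specific: each factor or covariate
applies to a configurable subset of traits (e.g. an age-at-recording
covariate for every trait except birth weight). Factors are reference-coded
(first level dropped) against a global intercept, which keeps every
per-trait design full column rank under any fixed-effect configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FactorSpec", "CovariateSpec", "ModelSpec", "PhenotypeTable", "Design"]

MISSING = "NA"


@dataclass(frozen=True)
class FactorSpec:
    """A categorical fixed effect. ``traits=None`` means all traits."""

    name: str
    traits: tuple | None = None


@dataclass(frozen=True)
class CovariateSpec:
    """A continuous fixed effect (centered at its sample mean)."""

    name: str
    traits: tuple | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Traits and fixed-effect layout of a multiple-trait animal model."""

    traits: tuple
    factors: tuple = ()
    covariates: tuple = ()
    intercept: bool = True

    def __post_init__(self):
        names = set(self.traits)
        for eff in (*self.factors, *self.covariates):
            if eff.traits is not None and not set(eff.traits) <= names:
                raise ValueError(
                    f"effect {eff.name!r} references unknown traits "
                    f"{set(eff.traits) - names}"
                )

    @property
    def m(self) -> int:
        return len(self.traits)

    def applies_to(self, eff) -> np.ndarray:
        """Boolean mask over traits for a factor/covariate spec."""
        if eff.traits is None:
            return np.ones(self.m, dtype=bool)
        return np.array([t in eff.traits for t in self.traits])

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        traits = tuple(d["traits"])
        factors = tuple(
            FactorSpec(name, tuple(v["traits"]) if isinstance(v, dict) and v.get("traits") else None)
            for name, v in (d.get("factors") or {}).items()
        )
        covariates = tuple(
            CovariateSpec(name, tuple(v["traits"]) if isinstance(v, dict) and v.get("traits") else None)
            for name, v in (d.get("covariates") or {}).items()
        )
        return cls(traits=traits, factors=factors, covariates=covariates,
                   intercept=bool(d.get("intercept", True)))

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "factors": {f.name: ({"traits": list(f.traits)} if f.traits else {})
                        for f in self.factors},
            "covariates": {c.name: ({"traits": list(c.traits)} if c.traits else {})
                           for c in self.covariates},
            "intercept": self.intercept,
        }


class PhenotypeTable:
    """n individuals x m traits with an observed/missing mask.

    Wraps a DataFrame holding an ``id`` column, factor/covariate columns and
    one column per trait (NaN = missing). Rows where every trait is missing
    are dropped at construction (such individuals contribute through the
    pedigree only); the count is kept for reporting.
    """

    def __init__(self, df: pd.DataFrame, spec: ModelSpec):
        missing_cols = [t for t in spec.traits if t not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks trait columns {missing_cols}")
        if "id" not in df.columns:
            raise ValueError("phenotype table needs an 'id' column")
        y = df[list(spec.traits)].to_numpy(dtype=float)
        all_missing = np.isnan(y).all(axis=1)
        self.n_dropped = int(all_missing.sum())
        df = df.loc[~all_missing].reset_index(drop=True)
        self.df = df
        self.spec = spec
        self.y = df[list(spec.traits)].to_numpy(dtype=float)
        self.mask = ~np.isnan(self.y)
        if len(df) and df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate phenotype record for id {dup!r}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def trait_counts(self) -> pd.Series:
        """Number of observed records per trait (the 'N' column of a data summary)."""
        return pd.Series(self.mask.sum(axis=0), index=self.spec.traits, name="N")

    def pattern_counts(self) -> pd.Series:
        """Counts of individuals per observed-trait combination."""
        labels = [
            "-".join(t for t, o in zip(self.spec.traits, row) if o)
            for row in self.mask
        ]
        return pd.Series(labels).value_counts()


@dataclass
class Design:
    """Per-trait fixed-effect design matrices sharing one column pool.

    ``X`` is the full n x p column pool; column ``j`` enters trait ``t``'s
    design iff ``applies[j, t]``. The coefficient vector is laid out
    trait-major: all coefficients for trait 0, then trait 1, ...
    """

    X: np.ndarray
    col_names: list
    applies: np.ndarray  # (p, m) bool
    trait_cols: list = field(init=False)  # per trait, column indices
    offsets: np.ndarray = field(init=False)  # coefficient-vector offsets per trait

    def __post_init__(self):
        m = self.applies.shape[1]
        self.trait_cols = [np.flatnonzero(self.applies[:, t]) for t in range(m)]
        sizes = [len(c) for c in self.trait_cols]
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])
        # materialized per-trait designs: sliced every sampler iteration
        self._Xt = [np.ascontiguousarray(self.X[:, c]) for c in self.trait_cols]

    @property
    def p_total(self) -> int:
        return int(self.offsets[-1])

    def coef_slice(self, t: int) -> slice:
        return slice(int(self.offsets[t]), int(self.offsets[t + 1]))

    def trait_matrix(self, t: int) -> np.ndarray:
        return self._Xt[t]

    def predict(self, b: np.ndarray) -> np.ndarray:
        """n x m matrix of fixed-effect means X_i b."""
        n, m = self.X.shape[0], self.applies.shape[1]
        out = np.zeros((n, m))
        for t in range(m):
            out[:, t] = self.trait_matrix(t) @ b[self.coef_slice(t)]
        return out

    def coef_names(self) -> list:
        names = []
        for t in range(self.applies.shape[1]):
            names += [f"t{t}:{self.col_names[j]}" for j in self.trait_cols[t]]
        return names


def build_design(table: PhenotypeTable) -> Design:
    """Assemble the reference-coded column pool for a phenotype table.

    Each factor contributes dummies for levels 2..k (first observed level is
    the reference); covariates are centered. Raises if a factor column is
    absent or single-level designs collapse to rank deficiency is left to the
    sampler's Cholesky to detect per factor.
    """
    spec, df = table.spec, table.df
    cols, names, applies = [], [], []
    if spec.intercept:
        cols.append(np.ones(table.n))
        names.append("intercept")
        applies.append(np.ones(spec.m, dtype=bool))
    for f in spec.factors:
        if f.name not in df.columns:
            raise ValueError(f"factor column {f.name!r} missing from phenotype table")
        codes, levels = pd.factorize(df[f.name], sort=True)
        for lev in range(1, len(levels)):
            cols.append((codes == lev).astype(float))
            names.append(f"{f.name}[{levels[lev]}]")
            applies.append(spec.applies_to(f))
    for c in spec.covariates:
        if c.name not in df.columns:
            raise ValueError(f"covariate column {c.name!r} missing from phenotype table")
        v = df[c.name].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(c.name)
        applies.append(spec.applies_to(c))
    if cols:
        X = np.column_stack(cols)
        A = np.array(applies)
    else:
        X = np.zeros((table.n, 0))
        A = np.zeros((0, spec.m), dtype=bool)
    return Design(X=X, col_names=names, applies=A)
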