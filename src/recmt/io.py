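"""Plain-text readers/writers and the end-to-end pipeline.

All artifacts are delimited text (CSV) or YAML: a three-column pedigree
file, a phenotype table with "NA" for missing records, chain files holding
one row per stored sample (flattened upper triangles of G and R, columns
named by trait pair), and per-structure summary tables. A JSON manifest
records seeds and counts so any run can be re-executed exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelSpec, PhenotypeTable
from .pedigree import Pedigree, toposort_pedigree
from .sampler import PosteriorChain, Priors, run_gibbs
from .summaries import summarize_chain
from .transforms import CausalStructure, TransformedChain, transform_chain

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_model_spec",
    "read_structures",
    "chain_to_frame",
    "write_chain",
    "read_chain",
    "write_transformed_chain",
    "run_pipeline",
]


def read_pedigree(path, strict: bool = False) -> Pedigree:
    """Read a 3-column (id, sire, dam) text file; 0/NA/empty = unknown parent.

    A parent id that never appears in the individual column is added as a
    founder with a warning, unless ``strict`` is set, in which case the file
    is rejected.
    """
    df = pd.read_csv(path, header=None, names=["id", "sire", "dam"],
                     sep=None, engine="python", dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.iloc[0]["id"].lower() in ("id", "individual", "animal"):
        df = df.iloc[1:].reset_index(drop=True)
    unknown = {"0", "", ".", "NA", "na", None}
    recs = []
    ids = set(df["id"])
    phantom = []
    for _, row in df.iterrows():
        s = None if (pd.isna(row["sire"]) or row["sire"] in unknown) else row["sire"]
        d = None if (pd.isna(row["dam"]) or row["dam"] in unknown) else row["dam"]
        for p in (s, d):
            if p is not None and p not in ids:
                if strict:
                    raise ValueError(
                        f"parent {p!r} never appears as an individual (strict mode)"
                    )
                phantom.append(p)
                ids.add(p)
        recs.append((row["id"], s, d))
    if phantom:
        warnings.warn(f"added {len(phantom)} undeclared parents as founders")
        recs = [(p, None, None) for p in dict.fromkeys(phantom)] + recs
    return toposort_pedigree(recs)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(pedigree.labels):
            s = pedigree.labels[pedigree.sire[i]] if pedigree.sire[i] >= 0 else 0
            d = pedigree.labels[pedigree.dam[i]] if pedigree.dam[i] >= 0 else 0
            fh.write(f"{lab},{s},{d}\n")


def read_phenotypes(path, spec: ModelSpec) -> PhenotypeTable:
    """Read a delimited phenotype file ("NA" = missing) into a table."""
    df = pd.read_csv(path, na_values=["NA"], dtype={"id": str})
    return PhenotypeTable(df, spec)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, index=False, na_rep="NA")


def read_model_spec(source) -> ModelSpec:
    """Model spec from a YAML path or an already-parsed mapping."""
    if isinstance(source, dict):
        return ModelSpec.from_dict(source)
    with open(source) as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))


def read_structures(source, traits) -> dict[str, CausalStructure]:
    """Named causal structures from YAML: ``{name: [[trait, ...], ...]}``."""
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    return {name: CausalStructure(blocks, traits=traits)
            for name, blocks in source.items()}


# -- chain files ------------------------------------------------------------


def _upper_cols(prefix, traits):
    m = len(traits)
    return [f"{prefix}_{traits[i]}_{traits[j]}" for i in range(m) for j in range(i, m)]


def _flatten_upper(M):  # (k, m, m) -> (k, m*(m+1)/2)
    m = M.shape[1]
    iu = np.triu_indices(m)
    return M[:, iu[0], iu[1]]


def _unflatten_upper(F, m):
    iu = np.triu_indices(m)
    out = np.zeros((F.shape[0], m, m))
    out[:, iu[0], iu[1]] = F
    out[:, iu[1], iu[0]] = F
    return out


def chain_to_frame(chain: PosteriorChain) -> pd.DataFrame:
    traits = chain.traits
    df = pd.DataFrame(
        np.hstack([_flatten_upper(chain.G), _flatten_upper(chain.R)]),
        columns=_upper_cols("G", traits) + _upper_cols("R", traits),
    )
    df.insert(0, "sample", np.arange(len(chain)))
    return df


def write_chain(chain: PosteriorChain, path) -> None:
    chain_to_frame(chain).to_csv(path, index=False)


def read_chain(path, traits, n_iter=0, burn_in=0, thin=1, seed=0) -> PosteriorChain:
    df = pd.read_csv(path)
    m = len(traits)
    G = _unflatten_upper(df[_upper_cols("G", traits)].to_numpy(), m)
    R = _unflatten_upper(df[_upper_cols("R", traits)].to_numpy(), m)
    return PosteriorChain(traits=tuple(traits), G=G, R=R,
                          n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)


def write_transformed_chain(tchain: TransformedChain, path) -> None:
    traits = tchain.traits
    df = pd.DataFrame(
        np.hstack([_flatten_upper(tchain.Gstar), _flatten_upper(tchain.Rstar)]),
        columns=_upper_cols("Gstar", traits) + _upper_cols("Rstar", traits),
    )
    for (a, b), v in tchain.lambda_samples().items():
        df[f"lambda_{a}_to_{b}"] = v
    df.insert(0, "sample", np.arange(len(tchain)))
    df.to_csv(path, index=False)


# -- pipeline ---------------------------------------------------------------


def run_pipeline(config, out_dir=None) -> dict:
    """simulate-free end-to-end run: fit, then transform + summarize per structure.

    ``config`` is a mapping (or YAML path) with keys ``pedigree``,
    ``phenotypes``, ``model``, ``sampler`` (iters, burnin, thin, seed, and
    optional prior overrides) and optional ``structures``. Artifacts are
    written under ``out`` (or ``out_dir``): the chain, per-structure
    transformed chains, summary tables (formatted and tidy) and a manifest.
    Returns the artifact paths plus in-memory results.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("out", "."))
    out.mkdir(parents=True, exist_ok=True)

    spec = read_model_spec(config["model"])
    ped = read_pedigree(config["pedigree"], strict=config.get("strict", False))
    table = read_phenotypes(config["phenotypes"], spec)
    smp = dict(config.get("sampler", {}))
    seed = int(smp.get("seed", 0))
    priors = None
    if "prior" in smp:
        m = spec.m
        pr = smp["prior"]
        priors = Priors(
            nu0_g=float(pr.get("nu0_g", m + 2)),
            S0_g=np.asarray(pr.get("S0_g", 0.01)) * np.eye(m)
            if np.isscalar(pr.get("S0_g", 0.01)) else np.asarray(pr["S0_g"]),
            nu0_r=float(pr.get("nu0_r", m + 2)),
            S0_r=np.asarray(pr.get("S0_r", 0.01)) * np.eye(m)
            if np.isscalar(pr.get("S0_r", 0.01)) else np.asarray(pr["S0_r"]),
        )
    chain = run_gibbs(
        ped, table,
        n_iter=int(smp.get("iters", 20000)),
        burn_in=int(smp.get("burnin", 5000)),
        thin=int(smp.get("thin", 10)),
        seed=seed, priors=priors,
        progress=int(smp.get("progress", 0)),
    )
    write_chain(chain, out / "chain_sm.csv")
    summaries = {"standard": summarize_chain(chain)}
    summaries["standard"].genetic_table().to_csv(out / "summary_sm_genetic.csv")
    summaries["standard"].residual_table().to_csv(out / "summary_sm_residual.csv")

    structures = read_structures(config.get("structures", {}), spec.traits)
    tidy = [summaries["standard"].to_long()]
    for name, struct in structures.items():
        tch = transform_chain(chain, struct)
        write_transformed_chain(tch, out / f"chain_{name}.csv")
        s = summarize_chain(tch)
        summaries[name] = s
        s.genetic_table().to_csv(out / f"summary_{name}_genetic.csv")
        s.residual_table(mask_zero=True).to_csv(out / f"summary_{name}_residual.csv")
        tidy.append(s.to_long())
    pd.concat(tidy, ignore_index=True).to_csv(out / "summary_long.csv", index=False)

    import recmt

    manifest = {
        "version": recmt.__version__,
        "seed": seed,
        "sampler": {k: v for k, v in smp.items() if k != "prior"},
        "n_records": int(table.n),
        "n_individuals": int(ped.size),
        "n_dropped_all_missing": int(table.n_dropped),
        "trait_counts": {t: int(c) for t, c in table.trait_counts().items()},
        "structures": {k: [list(map(str, b)) for b in v.blocks]
                       for k, v in structures.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"chain": chain, "summaries": summaries, "out": out}
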