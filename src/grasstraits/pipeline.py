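"""End-to-end comparative analysis: transform, fit, rank, ordinate.

The workflow mirrors a comparative trait study: log/absolute-value
transform of the species-mean trait table; for every trait a four-model
PGLS comparison with ML lambda, summarised as a ranked report; PPCA per
trait subset (all / structural / physiological / niche); the same
four-model comparison applied to PC scores of components explaining at
least the retention threshold (default 20%) of total variance; and a run
manifest for reproducibility.  Species present in some inputs but not
others are dropped by intersection, never silently reindexed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model_select import ModelComparison, build_table, compare_models
from .ppca import PPCAResult, run_ppca
from .traits_derive import TraitTable, prepare_traits
from .treeio import parse_newick, phylo_covariance, prune_to
from .synthetic import FixtureBundle

log = logging.getLogger("grasstraits")

__all__ = ["RunConfig", "run_pipeline", "group_summary"]


@dataclass
class RunConfig:
    tree: Path
    traits: Path
    groups: Path
    niche: Path | None = None
    trait_meta: Path | None = None
    outdir: Path = Path("results/run")
    ppca_mode: str = "correlation"
    pc_threshold: float = 20.0     # percent of total variance a PC must explain
    min_n: int = 10                # abort below this many reconciled species
    seed: int = 0
    count_lambda_in_k: bool = True

    @classmethod
    def from_bundle_dir(cls, bundle: str | Path, outdir: str | Path, **kw) -> "RunConfig":
        bundle = Path(bundle)
        niche = bundle / "niche.tsv"
        meta = bundle / "trait_meta.tsv"
        return cls(
            tree=bundle / "tree.nwk",
            traits=bundle / "traits.tsv",
            groups=bundle / "groups.tsv",
            niche=niche if niche.exists() else None,
            trait_meta=meta if meta.exists() else None,
            outdir=Path(outdir),
            **kw,
        )


def group_summary(data: pd.DataFrame, groups: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Descriptive statistics (mean, s.e.m., n) per level of a binary factor.

    Operates on natural-scale trait values, one row per trait and level.
    """
    if factor not in groups.columns:
        raise KeyError(f"factor {factor!r} not in group table")
    rows = []
    aligned = groups.loc[data.index, factor]
    for level in sorted(aligned.unique()):
        sub = data.loc[aligned == level]
        for trait in data.columns:
            vals = sub[trait].dropna()
            rows.append({
                "trait": trait,
                "level": level,
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def _comparisons_for(data: pd.DataFrame, groups: pd.DataFrame, tree, *,
                     count_lambda_in_k: bool) -> list[ModelComparison]:
    out = []
    for trait in data.columns:
        y = data[trait].dropna()
        if len(y) < len(data):
            log.info("trait %s: %d species dropped for missing values (n=%d)",
                     trait, len(data) - len(y), len(y))
        sub_tree = prune_to(tree, list(y.index)) if len(y) < len(data) else tree
        C = phylo_covariance(sub_tree, list(y.index))
        g = groups.loc[y.index]
        out.append(compare_models(y.to_numpy(), g, C, response=trait,
                                  count_lambda_in_k=count_lambda_in_k))
    return out


def _write_ppca(res: PPCAResult, outdir: Path, tag: str) -> None:
    res.loadings_frame().to_csv(outdir / f"ppca_{tag}_loadings.tsv", sep="\t")
    res.scores_frame().to_csv(outdir / f"ppca_{tag}_scores.tsv", sep="\t")
    pd.DataFrame({
        "eigenvalue": res.eigenvalues,
        "percent_variance": res.percent_variance,
    }, index=[f"PC{i + 1}" for i in range(len(res.eigenvalues))]).to_csv(
        outdir / f"ppca_{tag}_variance.tsv", sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written to disk).

    Emits under ``config.outdir``:
      table_traits.tsv       ranked four-model comparison per trait
      table_trait_pcs.tsv    same for retained trait-PPCA PC scores
      table_niche.tsv        same for niche descriptors (when provided)
      table_niche_pcs.tsv    same for retained niche-PPCA PC scores
      ppca_<subset>_*.tsv    loadings / scores / percent variance
      manifest.json          versions, config hash, species counts
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = parse_newick(Path(config.tree).read_text())
    traits_raw = pd.read_csv(config.traits, sep="\t", index_col=0)
    groups = pd.read_csv(config.groups, sep="\t", index_col=0)
    if groups.index.duplicated().any() or traits_raw.index.duplicated().any():
        raise ValueError("duplicate species labels in input tables")

    species = [s for s in traits_raw.index if s in set(groups.index) and s in set(tree.tip_labels)]
    dropped = sorted((set(traits_raw.index) | set(groups.index)) - set(species))
    if len(species) < config.min_n:
        raise ValueError(f"only {len(species)} species reconcile across inputs (< {config.min_n})")
    if len(dropped):
        log.info("species dropped during reconciliation: %s", dropped)
    traits_raw = traits_raw.loc[species]
    groups = groups.loc[species]
    tree = prune_to(tree, species)

    if config.trait_meta is not None:
        meta = pd.read_csv(config.trait_meta, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame({"class": "structural", "negative": False}, index=traits_raw.columns)
    table = prepare_traits(TraitTable(traits_raw, meta))
    data = table.data
    C = phylo_covariance(tree, species)

    # (a) per-trait four-model comparisons
    comps = _comparisons_for(data, groups, tree, count_lambda_in_k=config.count_lambda_in_k)
    build_table(comps).to_csv(outdir / "table_traits.tsv", sep="\t", index=False)
    _dump_json(comps, outdir / "table_traits.json")

    # (b) PPCA per subset, then the same comparison on retained PC scores
    pc_comps = []
    subsets = {"all": data}
    for cls in sorted(meta["class"].unique()):
        cols = [t for t in data.columns if meta.loc[t, "class"] == cls]
        if len(cols) >= 2:
            subsets[cls] = data[cols]
    for tag, sub in subsets.items():
        res = run_ppca(sub, C, config.ppca_mode, subset=tag)
        _write_ppca(res, outdir, tag)
        scores = res.scores_frame()
        for i in res.retained(config.pc_threshold):
            y = scores.iloc[:, i]
            pc_comps.append(compare_models(
                y.to_numpy(), groups, C,
                response=f"PC{i + 1} of {tag} traits",
                count_lambda_in_k=config.count_lambda_in_k))
    if pc_comps:
        build_table(pc_comps).to_csv(outdir / "table_trait_pcs.tsv", sep="\t", index=False)
        _dump_json(pc_comps, outdir / "table_trait_pcs.json")

    # (c, d) niche descriptors and their PCs on the complete-data subset
    n_niche = None
    if config.niche is not None:
        niche_raw = pd.read_csv(config.niche, sep="\t", index_col=0).loc[species]
        complete = niche_raw.dropna(how="any")
        n_niche = len(complete)
        log.info("niche analysis on n=%d species (%d lack climate data)",
                 n_niche, len(species) - n_niche)
        niche_meta = pd.DataFrame({"class": "niche", "negative": False}, index=niche_raw.columns)
        niche_log = prepare_traits(TraitTable(complete, niche_meta)).data
        niche_tree = prune_to(tree, list(complete.index))
        Cn = phylo_covariance(niche_tree, list(complete.index))
        gn = groups.loc[complete.index]
        niche_comps = _comparisons_for(niche_log, gn, niche_tree,
                                       count_lambda_in_k=config.count_lambda_in_k)
        build_table(niche_comps).to_csv(outdir / "table_niche.tsv", sep="\t", index=False)
        _dump_json(niche_comps, outdir / "table_niche.json")
        res = run_ppca(niche_log, Cn, config.ppca_mode, subset="niche")
        _write_ppca(res, outdir, "niche")
        npc_comps = []
        scores = res.scores_frame()
        for i in res.retained(config.pc_threshold):
            npc_comps.append(compare_models(
                scores.iloc[:, i].to_numpy(), gn, Cn,
                response=f"PC{i + 1} of niche descriptors",
                count_lambda_in_k=config.count_lambda_in_k))
        if npc_comps:
            build_table(npc_comps).to_csv(outdir / "table_niche_pcs.tsv", sep="\t", index=False)
            _dump_json(npc_comps, outdir / "table_niche_pcs.json")

    # hash the analysis-relevant settings only, not the output location
    cfg_repr = json.dumps(
        {k: str(v) for k, v in vars(config).items() if k != "outdir"}, sort_keys=True
    )
    manifest = {
        "grasstraits_version": __version__,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "n_species": len(species),
        "n_traits": int(data.shape[1]),
        "n_niche_species": n_niche,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _dump_json(comps: list[ModelComparison], path: Path) -> None:
    payload = []
    for c in comps:
        row = c.to_row()
        row["fits"] = {m: f.to_dict() for m, f in c.fits.items()}
        payload.append(row)
    path.write_text(json.dumps(payload, indent=1, default=float))
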