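"""Synthetic study generator: trees, group labels, and trait tables.

Emulates the statistical shape of a comparative study of 42 co-occurring
grasses: an ultrametric phylogeny; a phylogenetically clustered binary
factor (photosynthetic type, PT — C3 species confined to few clades) and a
weakly clustered one (life history, AP); unbalanced factorial cells
(4 C3-annuals, 6 C3-perennials, 13 C4-annuals, 19 C4-perennials);
log-normal-scale traits generated as fixed group effects plus
multivariate-normal residuals with covariance sigma^2 C(lambda); and niche
descriptors missing for a subset of species (8 of 42 by default, leaving
n = 34 complete rows).

Every generator is a pure function of (config, seed): the same inputs
give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .pgls import DesignMatrix, build_design
from .treeio import PhyloCovariance, Tree, lambda_transform, parse_newick, phylo_covariance, write_newick

__all__ = [
    "SimConfig",
    "FixtureBundle",
    "simulate_yule_tree",
    "assign_groups",
    "simulate_traits",
    "simulate_study",
    "TRAIT_SPECS",
    "NICHE_SPECS",
]

# cell sizes (C3-annual, C3-perennial, C4-annual, C4-perennial)
DEFAULT_CELLS = {"C3-annual": 4, "C3-perennial": 6, "C4-annual": 13, "C4-perennial": 19}

# The 26 functional traits with their class, whether values are stored as
# negatives, and the generating model for each (best-model structure and a
# plausible lambda on the log scale).  Effect sizes are in residual-sd
# units of the log-scale trait.
# (name, class, negative, model, beta_AP, beta_PT, beta_int, lambda)
TRAIT_SPECS = [
    ("H",       "structural",    False, "AP",    1.0, 0.0, 0.0, 0.0),
    ("LA",      "structural",    False, "AP",    0.8, 0.0, 0.0, 0.2),
    ("LT",      "structural",    False, "AP",    0.7, 0.0, 0.0, 0.0),
    ("SLA",     "structural",    False, "AP",   -1.2, 0.0, 0.0, 0.5),
    ("LDMC",    "structural",    False, "AP",    0.9, 0.0, 0.0, 0.1),
    ("IVD",     "structural",    False, "PT",    0.0, -1.5, 0.0, 0.0),
    ("Dlvb",    "structural",    False, "AP",    0.9, 0.0, 0.0, 0.0),
    ("AL_AS",   "structural",    False, "AP",    0.9, 0.0, 0.0, 0.0),
    ("sts",     "structural",    False, "PT",    0.0, -1.0, 0.0, 0.2),
    ("std",     "structural",    False, "PT",    0.0, 0.6, 0.5, 0.1),
    ("SS",      "structural",    False, "AP",    0.6, 0.0, 0.0, 0.0),
    ("Dsv",     "structural",    False, "AP",    1.0, 0.0, 0.0, 0.0),
    ("SVD",     "structural",    False, "AP",   -0.5, 0.0, -0.5, 0.0),
    ("SD",      "structural",    False, "AP",    1.2, 0.0, 0.0, 0.0),
    ("LC",      "structural",    False, "PT",    0.0, 0.4, 0.0, 0.0),
    ("K_leaf",  "physiological", False, "AP×PT", 0.0, 0.0, 1.5, 0.25),
    ("K_S",     "physiological", False, "AP",   -0.5, 0.0, 0.0, 0.0),
    ("K_L",     "physiological", False, "AP",   -0.4, 0.0, 0.0, 0.5),
    ("Psi_pre", "physiological", True,  "PT",    0.0, -1.3, 0.0, 0.0),
    ("Psi_mid", "physiological", True,  "AP",   -0.4, 0.0, 0.0, 0.0),
    ("Psi_tlp", "physiological", True,  "AP",    1.2, 0.0, 0.0, 0.0),
    ("A",       "physiological", False, "PT",    0.0, 1.0, 0.0, 0.0),
    ("g_s",     "physiological", False, "AP",   -0.9, 0.0, 0.0, 0.35),
    ("g_wmax",  "physiological", False, "AP",    0.7, 0.0, 0.0, 0.55),
    ("WUE_i",   "physiological", False, "PT",    0.0, 1.1, 0.0, 0.45),
    ("d13C",    "physiological", True,  "PT",    0.0, -0.8, 0.0, 0.6),
]

# (name, model, beta_AP, beta_PT, beta_int, lambda)
NICHE_SPECS = [
    ("MAP",           "AP", -0.8, 0.0, 0.0, 0.0),
    ("MAT",           "AP", -0.6, 0.0, 0.0, 0.85),
    ("Ps",            "AP",  0.9, 0.0, 0.0, 0.5),
    ("Ts",            "AP",  1.0, 0.0, 0.0, 0.0),
    ("tree_cover",    "AP", -0.5, 0.0, 0.0, 0.0),
    ("wet_days",      "AP+PT", -0.6, -0.4, 0.0, 0.0),
]


@dataclass
class SimConfig:
    """Study-shaped simulation settings; the defaults ARE the study shape."""

    n_tips: int = 42
    seed: int = 0
    cells: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    sigma2: float = 1.0
    missing_niche: int = 8
    pt_clustering: float = 0.95   # lambda of the latent character behind PT
    baseline: float = 2.0         # log-scale intercept for generated traits

    def __post_init__(self):
        if sum(self.cells.values()) != self.n_tips:
            raise ValueError(
                f"cell sizes {self.cells} sum to {sum(self.cells.values())}, not n_tips={self.n_tips}"
            )


@dataclass
class FixtureBundle:
    tree: Tree
    groups: pd.DataFrame
    traits: pd.DataFrame
    trait_meta: pd.DataFrame
    niche: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(write_newick(self.tree) + "\n")
        self.groups.to_csv(outdir / "groups.tsv", sep="\t")
        self.traits.to_csv(outdir / "traits.tsv", sep="\t")
        self.trait_meta.to_csv(outdir / "trait_meta.tsv", sep="\t")
        self.niche.to_csv(outdir / "niche.tsv", sep="\t")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return outdir

    @classmethod
    def read(cls, indir: str | Path) -> "FixtureBundle":
        indir = Path(indir)
        tree = parse_newick((indir / "tree.nwk").read_text())
        groups = pd.read_csv(indir / "groups.tsv", sep="\t", index_col=0)
        traits = pd.read_csv(indir / "traits.tsv", sep="\t", index_col=0)
        meta = pd.read_csv(indir / "trait_meta.tsv", sep="\t", index_col=0)
        niche = pd.read_csv(indir / "niche.tsv", sep="\t", index_col=0)
        truth = json.loads((indir / "truth.json").read_text())
        return cls(tree, groups, traits, meta, niche, truth)


def simulate_yule_tree(n_tips: int, seed: int) -> Tree:
    """Pure-birth (Yule) ultrametric tree rescaled to root depth 1."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(seed))
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the sampler stops exactly at the n-th birth, leaving two zero-length
    # terminal edges; run the process one further exponential waiting time
    extra = rng.expovariate(n_tips)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # deterministic labels in leaf-iteration order
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:02d}"
    tree = Tree(dtree)
    depth = max(tree.depths().values())
    for node in dtree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    return tree


def _mvn_symmetric(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator,
                   size: int | None = None) -> np.ndarray:
    """Sample MVN via the symmetric (eigen) square root of the covariance."""
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError(f"covariance not PSD (min eigenvalue {evals.min():.3g})")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    if size is None:
        return mean + root @ rng.standard_normal(len(mean))
    return mean + rng.standard_normal((size, len(mean))) @ root


def assign_groups(tree: Tree, config: SimConfig) -> pd.DataFrame:
    """Binary factors with study-like phylogenetic structure.

    PT thresholds a latent Brownian character simulated on the tree with
    lambda = ``pt_clustering`` (the threshold is placed to hit the C3
    count exactly, and clustering strength 0 makes PT independent of the
    tree); AP is a stratified random draw within each PT level to hit the
    configured cell counts, so it is far less clustered — life history
    flips within clades while C3 photosynthesis is clade-restricted.
    """
    rng = np.random.default_rng(int(config.seed))
    taxa = tree.tip_labels
    n = len(taxa)
    n_c3 = config.cells["C3-annual"] + config.cells["C3-perennial"]
    n_c4 = config.cells["C4-annual"] + config.cells["C4-perennial"]
    if n_c3 + n_c4 != n or min(config.cells.values()) < 0:
        raise ValueError(f"infeasible cell counts {config.cells} for {n} tips")
    C = phylo_covariance(tree, taxa)
    Clam = lambda_transform(C, float(config.pt_clustering)).C
    z = _mvn_symmetric(np.zeros(n), Clam, rng)
    c3_idx = set(np.argsort(z)[:n_c3])
    pt = np.array(["C3" if i in c3_idx else "C4" for i in range(n)])

    ap = np.empty(n, dtype=object)
    for level, n_annual in (("C3", config.cells["C3-annual"]), ("C4", config.cells["C4-annual"])):
        members = np.flatnonzero(pt == level)
        annual = rng.choice(members, size=n_annual, replace=False)
        ap[members] = "perennial"
        ap[annual] = "annual"
    return pd.DataFrame({"AP": ap, "PT": pt}, index=pd.Index(taxa, name="species"))


def simulate_traits(
    tree_or_C: Tree | PhyloCovariance,
    X: DesignMatrix | np.ndarray,
    beta: np.ndarray,
    sigma2: float,
    lambda_true: float,
    seed: int,
    n_reps: int | None = None,
) -> np.ndarray:
    """Trait column(s) y = X beta + MVN(0, sigma^2 C(lambda)) residuals."""
    C = tree_or_C if isinstance(tree_or_C, PhyloCovariance) else phylo_covariance(tree_or_C)
    V = lambda_transform(C, float(lambda_true)).C * float(sigma2)
    Xmat = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    mean = Xmat @ np.asarray(beta, float)
    rng = np.random.default_rng(int(seed))
    return _mvn_symmetric(mean, V, rng, size=n_reps)


def simulate_study(config: SimConfig) -> FixtureBundle:
    """A full study-shaped bundle: tree, groups, 26 traits, 6 niche columns.

    Trait values are written on the natural (log-normal) scale — the
    analysis pipeline re-applies the log transform — and traits flagged
    negative (water potentials, d13C) are negated.  ``missing_niche``
    species get blank niche rows.
    """
    tree = simulate_yule_tree(config.n_tips, config.seed)
    groups = assign_groups(tree, config)
    taxa = list(groups.index)
    C = phylo_covariance(tree, taxa)
    designs = {m: build_design(groups, m) for m in ("AP", "PT", "AP+PT", "AP×PT")}

    def betavec(model, b_ap, b_pt, b_int, intercept):
        full = {"intercept": intercept, "AP[perennial]": b_ap, "PT[C4]": b_pt, "AP:PT": b_int}
        return np.array([full[c] for c in designs[model].column_names])

    traits = {}
    meta_rows = []
    truth_traits = {}
    for i, (name, cls, neg, model, b_ap, b_pt, b_int, lam) in enumerate(TRAIT_SPECS):
        sd = np.sqrt(config.sigma2)
        b = betavec(model, b_ap * sd, b_pt * sd, b_int * sd, config.baseline)
        y_log = simulate_traits(C, designs[model], b, config.sigma2, lam,
                                seed=config.seed * 1000 + i)
        natural = np.exp(y_log)
        traits[name] = -natural if neg else natural
        meta_rows.append({"trait": name, "class": cls, "negative": neg})
        truth_traits[name] = {"model": model, "beta": list(np.round(b, 10)), "lambda": lam}

    niche = {}
    truth_niche = {}
    for j, (name, model, b_ap, b_pt, b_int, lam) in enumerate(NICHE_SPECS):
        sd = np.sqrt(config.sigma2)
        b = betavec(model, b_ap * sd, b_pt * sd, b_int * sd, config.baseline)
        y_log = simulate_traits(C, designs[model], b, config.sigma2, lam,
                                seed=config.seed * 1000 + 500 + j)
        niche[name] = np.exp(y_log)
        truth_niche[name] = {"model": model, "beta": list(np.round(b, 10)), "lambda": lam}

    traits_df = pd.DataFrame(traits, index=pd.Index(taxa, name="species"))
    niche_df = pd.DataFrame(niche, index=pd.Index(taxa, name="species"))
    rng = np.random.default_rng(int(config.seed) + 99)
    missing = sorted(rng.choice(len(taxa), size=config.missing_niche, replace=False))
    niche_df.iloc[missing, :] = np.nan
    meta = pd.DataFrame(meta_rows).set_index("trait")

    truth = {
        "seed": config.seed,
        "n_tips": config.n_tips,
        "cells": config.cells,
        "sigma2": config.sigma2,
        "baseline": config.baseline,
        "pt_clustering": config.pt_clustering,
        "missing_niche_species": [taxa[i] for i in missing],
        "traits": truth_traits,
        "niche": truth_niche,
    }
    return FixtureBundle(tree, groups, traits_df, meta, niche_df, truth)
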