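# grasstraits

Phylogenetic comparative analysis of functional-trait tables, built around
the question of how two binary species attributes — life history
(annual/perennial, "AP") and photosynthetic type (C3/C4, "PT") — jointly
explain variation in leaf and stem traits and climatic niche descriptors
across a set of co-occurring grass species.

Species are not independent data points: close relatives covary. The
package therefore fits every comparison with **phylogenetic generalised
least squares (PGLS)**,

    y = Xβ + ε,   ε ~ MVN(0, σ² C(λ)),

where `C` is the Brownian-motion tip covariance matrix derived from a
rooted, branch-length-bearing phylogeny (`C[i,j]` = shared root-to-MRCA
path length) and Pagel's λ ∈ [0, 1] rescales the off-diagonal shared
history (λ = 0: species independent; λ = 1: pure Brownian expectation).
λ is estimated by maximum likelihood for every model.

For each response, four nested factorial models — AP×PT, AP+PT, PT, AP —
are compared with the small-sample Akaike criterion
`AICc = −2 ln L + 2k + 2k(k+1)/(n−k−1)`, turned into model probabilities

    w_i = exp(−ΔAICc_i/2) / Σ_r exp(−ΔAICc_r/2),

and ranked by the evidence ratio `w_min/w_2` (best over second-best
weight, identically `exp(ΔAICc₂/2)`; a ΔAICc gap of 3.22 corresponds to
an evidence ratio of 5). Trait coordination is summarised by
**phylogenetic PCA** (GLS mean, C⁻¹-weighted covariance/correlation,
eigen-decomposition), and PC scores explaining ≥ 20% of variance are fed
back through the same four-model machinery.

The package also derives the underlying hydraulic and stomatal traits
from raw measurements (leaf/stem hydraulic conductance from
pressure-chamber flow, anatomical maximum stomatal conductance from
stomatal density and guard-cell geometry, turgor-loss point from
pressure–volume curves, SLA/LDMC/WUEᵢ and friends), and ships a
synthetic-data module that generates study-shaped datasets — ultrametric
Yule trees, a phylogenetically clustered PT factor, unbalanced factorial
cells (4/6/13/19 over 42 species), λ-structured log-normal traits, and
niche tables with missing species — so the whole chain is testable
without any external data.

## Worked example

```sh
python analysis/01_simulate_study.py        # writes results/bundle/
python analysis/02_trait_model_selection.py # writes results/analysis/
python analysis/03_ppca_summary.py
python analysis/04_recovery_checks.py
```

The second step prints the ranked model-comparison table; its first rows
(seed 3) look like:

```
response  dAICc_AP×PT  dAICc_AP+PT  dAICc_PT  dAICc_AP  evidence_ratio best_model  lambda_best stratum
  K_leaf         0.00         8.72     18.72     18.12           78.42      AP×PT         0.43      >5
 Psi_tlp         0.00         4.48     25.20      9.06            9.38      AP×PT         0.00      >5
 Psi_mid         4.97         2.57     14.44      0.00            3.62         AP         0.00    >2.5
```

Each row is one trait: the four ΔAICc values (best model at 0), the
evidence ratio `w_min/w_2`, the winning model, its ML λ, and the
evidence stratum (dashed-line bands at 5 and 2.5). Here the leaf
hydraulic conductance trait, generated with an interaction effect, is
decisively assigned the AP×PT model, with moderate phylogenetic signal
(λ = 0.43) in the best fit. The calibration step (04) reports, over
study-shaped replicates: λ mean-absolute-error 0.24 at λ_true = 0.5,
additive-model coefficients recovered without bias (means 0.98 and 1.01
for true effects of 1), 100/100 best-model recovery at 1.5-sd effects,
and 0/100 spurious decisive evidence ratios for responses unrelated to
the factors.

The same machinery is scriptable:

```python
from grasstraits import parse_newick, phylo_covariance, compare_models
tree = parse_newick(open("tree.nwk").read())
C = phylo_covariance(tree, list(traits.index))
mc = compare_models(traits["SLA"].to_numpy(), groups, C, response="SLA")
print(mc.best_model, mc.evidence_ratio, mc.lambda_best)
```

or available through the `pcm` CLI (`pcm simulate|derive|fit|ppca|run`).

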