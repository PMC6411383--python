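# Methods

## Model

Each response (a log-transformed species-mean trait, niche descriptor, or
PPCA score) is modelled as

    y = Xβ + ε,   ε ~ MVN(0, σ² C(λ)),

with `C` the Brownian-motion tip covariance of the phylogeny (`C[i,j]` =
root-to-MRCA shared path length, `C[i,i]` = root-to-tip depth) and
Pagel's λ multiplying the off-diagonal entries. The design matrices use
treatment coding with reference levels *annual* (AP) and *C3* (PT), in
the fixed column order (intercept, AP, PT, AP:PT); the four candidate
models are AP×PT (p = 4), AP+PT (p = 3), PT (p = 2), AP (p = 2).

Estimation is maximum likelihood throughout, never REML: AICc
comparisons across models with different fixed effects are only valid
under a common ML likelihood. For fixed λ the GLS solution is closed
form (computed via a Cholesky whitening, so `V` is never inverted
explicitly); σ² is the ML estimator `r'V⁻¹r/n`.

### λ profiling

The profile likelihood in λ can be flat or multimodal, so the optimum is
located on a 21-point grid over [0, 1] and refined by bounded scalar
minimisation (tolerance 1e-6) in the bracketing interval. Two
deterministic conventions:

* likelihood ties within 1e-8 resolve toward the smaller λ — a star
  phylogeny, where λ is unidentifiable, therefore reports exactly 0;
* optima within 1e-4 of a boundary snap to exactly 0 or 1, matching how
  such fits are conventionally reported ("0.00").

### AICc and the parameter count

`k = p + 2` by default: the coefficients, σ², and λ (λ is a fitted
parameter). Whether published analyses count λ is rarely stated, so
`count_lambda_in_k=False` (k = p + 1) is available; because the same
rule applies to all four models, ΔAICc, the Akaike weights and the
evidence ratios are unchanged by this choice — only absolute AICc
values move. For the same reason the base of the log transform is
inert: rescaling y shifts every model's log-likelihood equally.

### Model probabilities and evidence

Weights are computed after Δ-referencing (`ΔAICc_i = AICc_i − min AICc`),
which makes overflow impossible. The evidence ratio is the largest over
the second-largest weight and equals `exp(ΔAICc₂/2)` identically; report
tables flag models with ΔAICc < 3.22 (evidence ratio vs. the best
≈ 5.00) and weights > 0.60, and stratify responses at evidence ratios of
5 and 2.5. Best-model ties closer than 1e-6 ΔAICc resolve by parsimony
(fewer parameters, then the fixed order AP, PT, AP+PT, AP×PT).

## Phylogenetic PCA

The phylogenetic (GLS, ancestral) mean `a = (1'C⁻¹1)⁻¹1'C⁻¹X` replaces
the arithmetic mean, and the evolutionary covariance
`R = (X−1a)'C⁻¹(X−1a)/(n−1)` replaces the sample covariance; `R` is
eigen-decomposed and species scores are `(X−1a)L` in raw trait space
(standardised by the phylogenetic SDs in correlation mode), the
convention under which species scores are plotted directly. Choices the
method leaves open, fixed here as:

* **correlation mode by default** — the trait batteries span
  incommensurate units (cm², MPa, mol m⁻² s⁻¹), so covariance-mode PCs
  would be dominated by whichever trait has the largest numeric spread;
  covariance mode remains available;
* **λ = 1 (pure Brownian C)** in the covariance weighting, the simplest
  reading of the method; a joint-ML λ option exists but is off by
  default;
* PC signs fixed so each loading column's largest-magnitude entry is
  positive; eigenvalues are returned nonincreasing.

Agreement with the reference R implementation of this procedure
(phytools `phyl.pca`) is exact in eigenvalues and species scores up to
per-PC sign; note that implementation reports correlation-style loadings
rather than raw eigenvectors, so loading matrices are not directly
comparable.

Components explaining ≥ 20% of total variance (the pipeline's
`pc_threshold`) are refitted with the same four-model machinery as raw
traits.

## Derived traits

All formula traits are exact arithmetic with explicit unit conventions:
leaf hydraulic conductance `(ΔW₂−ΔW₁)/(area·time·ΔΨ)` with flow masses
converted to mmol of water at 18.015 mg/mmol; stem conductivity
`(ΔW₂−ΔW₁)·length/(time·ΔΨ)` in SI kg m s⁻¹ MPa⁻¹ with the
normalisations `K_S = K_h/A_SV`, `K_L = K_h/A_L` (so
`K_S·A_SV = K_L·A_L = K_h` holds to machine precision); SLA, stem
density, LDMC, A_L/A_S and WUEᵢ = A/g_s as plain ratios.

Anatomical maximum stomatal conductance per surface is
`g = (d/v)·std·a_max / (depth + (π/2)√(a_max/π))`, summed over both
surfaces. The geometry rule is configurable and defaults to pore length
= gl/2, pore depth = gw/2, `a_max = π(pore length/2)²`, with
d = 2.49e-5 m² s⁻¹ and v = 2.24e-2 m³ mol⁻¹ (25 °C); published analyses
vary in these conventions, so all four are config entries rather than
constants.

### Turgor-loss point

PV curves are analysed in the classic 1/Ψ vs (1 − RWC) plane: beyond
turgor loss 1/Ψ is linear (purely osmotic), before it the curve bends
away. The breakpoint is found by a global search over all two-segment
splits with ≥ 3 points per side, minimising total SSE, with an
admissibility gate requiring the dry segment to be convincingly linear
(R² ≥ 0.95). Because the turgid segment is globally curved while the
transition is a local kink, fitting one straight line to the whole
turgid segment biases the intersection badly; the kink abscissa is
therefore located by intersecting the dry line with a *local* line
through the three turgid points nearest the split, and Ψ_tlp is the dry
(osmotic) line evaluated at the kink. On synthetic curves from the
closed-form PV model (osmotic potential at full turgor −1.5 MPa,
apoplastic fraction 0.2, linear turgor decline; analytic TLP
−1.714 MPa) this recovers the TLP to 0.03 MPa noiselessly and with
median error 0.03 MPa under 0.02 MPa Gaussian noise.

### Analysis transform

`prepare_traits` applies the natural log to every analysed column;
traits stored as negative values (Ψ_tlp, Ψ_pre, Ψ_mid, δ¹³C) take
absolute values first and must be strictly negative throughout — mixed
signs are an error naming the offending species. The transform is
invertible on its domain (`exp` recovers |original| exactly).

## Synthetic data

The generator emulates the *statistical shape* of the study the analysis
is designed for:

* **Tree**: pure-birth (Yule) topology, extended by one final
  exponential waiting time past the n-th birth (otherwise two terminal
  branches have zero length and `C` is singular), rescaled to root depth
  1. An empirical supertree extract would differ in topology imbalance
  and branch-length distribution; seeds explore topology sensitivity.
* **Groups**: PT thresholds a latent Brownian character (λ = 0.95 by
  default, threshold placed to hit the C3 count exactly), so C3 species
  are clade-restricted; AP is a stratified random draw within PT levels
  to hit the unbalanced cells 4/6/13/19 — life history flips within
  clades, mirroring the real contrast in clustering between the two
  factors.
* **Traits**: `y = Xβ + MVN(0, σ²C(λ))` on the log scale, sampled
  through the symmetric eigen square root of the covariance;
  exponentiated (and negated for the negative-value traits) to natural
  scale so the pipeline's transform is exercised. Each of the 26 traits
  carries a generating model and effect sizes (in residual-sd units)
  chosen to mirror the qualitative pattern of the study: mostly
  single-factor AP or PT effects of ~0.5–1.5 sd, one strong interaction
  trait (leaf hydraulic conductance), λ mostly ≤ 0.2 with a few traits
  at 0.4–0.6. Six niche columns follow the same recipe and 8 of 42
  species get blank niche rows (n = 34 complete cases).
* Determinism: every generator is a pure function of (config, seed);
  bundles rewrite byte-identically.

What the generator does **not** emulate: measurement error at the
instrument level (traits are generated at the species-mean level the
analysis consumes; measurement-level generators live with the
trait-derivation tests), non-ultrametric branch lengths, correlated
residuals *across* traits, and real-world trait distributions beyond
log-normality. Passing recovery tests therefore demonstrate correctness
of the estimator chain under its own assumptions, not robustness to
their violation.

## Numerical choices

* Near-singular covariance (condition number > 1e12, e.g. zero-length
  terminal branches in supertree extracts): a diagonal jitter of
  1e-10 × mean depth is added before factorisation, with a warning.
* Degenerate fits (residual variance < 1e-12 × var(y), or constant
  response) raise rather than returning infinite likelihoods.
* Taxa ordering everywhere follows the trait-table row order, so data
  vectors and covariance matrices align by construction; species-set
  mismatches across inputs are reconciled by intersection with logging,
  and duplicate labels are hard errors.
* Non-ultrametric trees are accepted with a warning (PGLS is defined
  for any valid C); no rescaling is applied.

## Problem sizes

Simulation-based checks run at the study's own scale: 42 tips with the
4/6/13/19 cells for recovery and calibration (200 replicates for
λ/coefficient recovery, 100 each for model recovery and null
calibration), 100–200 tips for λ-consistency checks, 5 000–20 000
replicates for Monte-Carlo covariance checks on 3-tip trees. The full
suite runs in well under a minute on one core.

## Known limitations

* λ at n = 42 is intrinsically noisy (MAE ≈ 0.24 at λ = 0.5); per-trait
  λ values should be read as regularisers of the GLS fit, not precise
  signal estimates.
* The PPCA refit treats PC scores as data, ignoring their estimation
  uncertainty — as the source methodology does.
* The turgor-loss point gate (dry-segment R² ≥ 0.95) assumes curves are
  dried well past the TLP; curves truncated near the TLP fail rather
  than extrapolate.
* No measurement-error (within-species) variance in PGLS; species means
  are taken as known.
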