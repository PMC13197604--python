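# Methods

This note documents the models implemented in `dodder`, the choices made
where the design was genuinely open, and what the synthetic-data validation
does and does not establish.

## Fluorescence yields

Raw PAM values are taken as the instrument reports them (relative units);
no recalibration is attempted. The three derived parameters are pure
arithmetic: F_v/F_m = (F_m − F_o)/F_m, Φ_PSII = 1 − F_s/F′_m,
Φ_NPQ = F_s/F′_m − F_s/F_m. All are dimensionless and, for physically
sensible inputs (0 ≤ F_o ≤ F_m, 0 ≤ F_s ≤ F′_m ≤ F_m), lie in [0, 1].
Records violating these orderings are *flagged*, never silently dropped:
outlier handling is the statistics module's job, and keeping the rows
preserves the audit trail. Yields are stored at full floating precision
and rounded only for display.

## Pigment summaries

Concentrations are nmol g⁻¹ fresh weight; an absent HPLC peak is 0.
Total carotenoids sum exactly seven constituents (V, A, Z, N, L, α-car,
β-car); lutein epoxide is tracked as its own field and excluded from the
total, because it is a distinct member of a second xanthophyll cycle and
folding it into lutein would hide exactly the signal the correlation
analyses target. Carotenoids are normalized by total carotenoids, not by
chlorophyll, since chlorophyll approaches zero in the holoparasite and a
per-chlorophyll ratio degenerates there; the chl a:b ratio is reported as
missing (not infinity) when chl b = 0.

Neoxanthin presence per taxon uses an any-detection rule across all stages
and replicates. The detection threshold defaults to 0 (any positive
quantified peak) and is configurable because instrument detection limits
vary; the scoring is monotone in the threshold by construction. Taxa in
the tree without pigment samples are scored *missing* and their state is
inferred by the phylogenetic model.

## Group statistics

Outliers are screened by Cook's distance on a one-way cell-means model
(one mean per species × stage cell), computed per response variable. The
cutoff is the absolute value 4 by default, with the common 4/n rule
available (`rule="4overN"`). The cell-means design was chosen because the
screening is applied separately to each yield parameter and the
stage-by-taxon cell is the finest stratum the downstream tests use.
Observations alone in their cell have leverage 1 and are exempt (their
Cook's distance is degenerate); a perfect fit short-circuits to "no
removals" to avoid 0/0 artifacts.

Omnibus comparisons use tie-corrected Kruskal–Wallis (scipy's
implementation behind the module surface) — chosen over ANOVA for
non-normal, unbalanced data — followed by two-sided Dunn tests on mean
midranks (implemented here; the z statistic uses the pooled tie
correction) and Benjamini–Hochberg adjustment (statsmodels). For display,
a greedy first-fit letter assignment marks groups whose adjusted p exceeds
α as sharing a letter; greedy assignment can differ from the minimal
letter cover, which is acceptable for a display-only artifact.

## Penalized-likelihood dating

The chronogram module maximizes
Σ_i [B_i log(r_i τ_i n) − r_i τ_i n] − λ·Φ(r) over branch rates r_i and
node ages, where B_i = (input branch length) × n are Poisson pseudo-counts
at n = `nsites` (default 1000), τ_i is branch duration, and the roughness
penalty Φ sums squared rate differences over parent–child branch pairs
plus the variance of root-adjacent rates (the correlated-rates variant).
Root age is fixed at 1 — only relative times are identifiable without
calibrations. Ages are parameterized as logit-fractions of the parent age
so the topology's ordering constraints hold by construction; rates are
log-parameterized. Optimization is joint L-BFGS-B from a UPGMA-like
initialization (ages proportional to mean remaining path length, one
global clock rate); the objective trace is recorded and is monotone
non-decreasing over accepted iterates. λ defaults to 1; as λ → ∞ the rate
vector collapses to a clock (verified to CV < 1e-3 at λ = 1e8).
Zero-length terminal branches are allowed (their B_i = 0 term contributes
only −r_i τ_i n).

## MCMC machinery

One root seed per run; per-chain generators are spawned from a
`SeedSequence`, so runs are exactly reproducible from (seed, data,
schedule) and chains are independent. No thinning — every generation is
recorded. ESS uses the initial-positive-sequence truncation of the
autocorrelation sum, capped at n (anti-correlated chains); constant
columns report n with a degeneracy warning. Convergence of replicate
chains is declared when split-R̂ < 1.01 for every continuous column and
per-chain model-indicator frequencies agree within 0.05; the R̂ threshold
is a configuration default, chosen conservatively. The ESS floor for the
discrete-trait analysis defaults to 650 (minimum over continuous
parameters of the combined run); falling short is recorded as a warning in
the run metadata rather than an error, since the sampled values remain
valid, just noisier.

## Reversible-jump Dollo test

Two-state CTMC (0 = absent, 1 = present) on branch durations of the
chronogram; transition probabilities in closed form. The irreversible
model fixes q_gain = 0; the reversible model frees it. Each free rate has
an exponential prior with mean = expected_transitions / tree_length
("n expected changes over the tree", default n = 1); the model prior is
0.5/0.5 (configurable — the uniform choice follows common reversible-jump
defaults). The root state is fixed to "present", which makes the model
comparison fair: a hypothetical ancestor that lacked the trait could never
lose it.

One move per generation: with probability 0.5 an indicator flip, realized
as an independence birth/death proposal drawing q_gain from its prior —
the proposal density cancels the prior density, so the acceptance ratio
reduces to likelihood ratio × model-prior odds (Jacobian 1); otherwise a
multiplicative sliding-window update (window 2.0 on the log scale, set for
adequate prior-regime mixing) of one free rate. Likelihoods come from
Felsenstein pruning with missing tips entered as partial likelihood
(1, 1). Each generation one *joint* ancestral reconstruction is drawn by
backward sampling from the stored pruning partials (root first, then
children conditional on parents); joint sampling was chosen over marginal
per-node sampling so that each generation's reconstruction is internally
coherent, and sampling during the run makes node posteriors model-averaged
automatically. States of data-missing tips are sampled alongside interior
nodes. Reported nodes are resolved as named MRCAs of tip sets at run time,
robust to tip order.

The sampler was validated against two independent oracles: brute-force
enumeration of interior states (log-likelihood agreement < 1e-10 on
trees ≤ 5 tips) and direct quadrature of the two marginal likelihoods over
the rate priors (posterior model probability agreement ± 0.03).

A caveat established during validation: with the root fixed present,
typical tip patterns simulated under the *reversible* model are often
explained equally well by pure loss, so the true posterior probability of
reversibility — confirmed by quadrature, not a sampler artifact — frequently
stays near 0.5 unless the realized history left presences nested inside
absent clades. Detecting regains requires the right pattern, not merely a
reversible-process origin; the packaged presence pattern (nested regains
within subg. *Grammica*) is of the detectable kind and yields
P(reversible) ≈ 0.99.

Prior sensitivity is assessed by re-running at expected transitions
n ∈ {1, 2, 5, 10} and flagging whether the maximum-a-posteriori
reconstruction changes.

## Brownian-motion correlation

For one ontogenetic stage, species-level tip values are replicate means on
the raw scale (median and log-mean are available; the aggregation choice
is a configuration flag because raw replicate-to-tip reduction is
underdetermined). Taxa missing either trait are dropped, as are explicit
exclusions (the hybrid *C. sandwichiana*, whose reticulate history blurs
the tree, and the outgroup, whose tissues are not homologous). The
likelihood is the matrix-normal form of the 2n-dimensional Gaussian with
covariance R ⊗ C; because tree and data are fixed within a run, a single
Cholesky of C reduces each evaluation to closed-form scalars, making the
50 000-generation default cheap. Priors: r ~ Uniform(−1, 1) (symmetric
about 0, which is what justifies prior odds 1 in the sign Bayes factor);
σ² ~ Exponential with mean the empirical tip variance; root means ~ Normal
centred on the tip means with 10 × the tip standard deviation. Each
generation applies 11 moves drawn uniformly from four kinds: scaling of
σ²_x, scaling of σ²_y, sliding r with reflection at ±1, and a joint slide
of the two root means.

BF⁺ = f/(1 − f) with f the post-burn-in fraction of r > 0 samples, pooled
over chains; the negative-correlation factor is its reciprocal. Saturated
fractions (f ∈ {0, 1} with m samples) are reported as the half-sample
bound (m − 0.5)/0.5 with a saturation flag rather than as infinity.
Natural logarithms throughout; tiers on |2 ln BF⁺|: n.s. ≤ 2,
* in (2, 6], *** above 6 (values ≥ 10 exceed the top published band and
map to the top tier). Stages retaining fewer than 3 taxa yield a
not-estimable row; stages with exactly 3 carry a caution flag.

## Synthetic data

The generator reproduces the *statistical structure* the analyses assume,
not any real measurements:

- **Fixture chronogram** — 16 tips (14 phenotyped *Cuscuta*, the unsampled
  *C. africana*, outgroup *Ipomoea nil*), backbone
  (outgroup, (Monogynella, ((Cuscuta, Pachystigma), Grammica))), root age 1.
  Within-*Grammica* resolution groups species by section; the remaining
  arbitrary choices and all node ages are invented package constants —
  explicitly **not** an estimate of the real tree.
- **Measurements** — species × 6 stages × 3 replicates by default
  (matching the 3–5 individuals of the study design). Stage-level yield
  targets follow the U-shaped ontogenetic profile (high in seedling/young
  stem, low in old stem, recovering in seed) with additive Gaussian noise
  (sd 0.02), then are inverted to raw F quadruples that reproduce the
  yields exactly; pigments are stage/clade-scaled truncated-normal draws
  (CV 0.15; lognormal optional), β-carotene follows the inverse stage
  pattern, the holoparasite gets zero chlorophyll and contributes no
  fluorescence rows, and neoxanthin follows the planted presence pattern
  (positive only in seedling/young-stem samples of "present" taxa).
- **Binary traits** — exact forward Gillespie simulation along branches,
  returning true node states and realized event counts (defaults
  q_gain = 1, q_loss = 2 per unit tree time: loss-biased, as befits a
  parasite lineage shedding photosynthesis genes).
- **Continuous pairs** — root-to-tip bivariate Gaussian increments with
  per-branch covariance R × duration.

What passing tests therefore show: the estimators recover what they model,
the samplers target their exact posteriors, and the pipeline is internally
consistent end to end. What they cannot show: anything about instrument
artifacts, HPLC quantification error, real replicate structure, or the
true *Cuscuta* branch lengths — in particular, deep-node ancestral
posteriors depend on branch lengths and transfer to the real system only
qualitatively. The simulated measurement tables also contain no planted
phylogenetic correlation between pigments and yields, so per-stage
correlation outputs on fully synthetic inputs hover around noise level by
design (the known-truth Brownian simulations are the quantitative check).

## Problem sizes

Library defaults follow the full study design (4 × 5000 generations,
burn-in 1000 for the discrete trait; 2 × 50 000, burn-in 1000 for the
correlations). The test suite scales replicate-heavy validations down —
recovery studies use single chains of 3000–6000 generations, and the
calibration study uses 10 000 three-group null datasets — sizes chosen so
the whole suite runs in a few minutes while keeping Monte-Carlo error well
inside the asserted tolerances. The acceptance script uses the full
designs for the headline runs and the scaled sizes for the auxiliary
scans; all sizes are printed alongside each reported value.

## Known limitations

- Binary-trait model: two states, homogeneous rates, no covarion or
  branch-specific variation; event counts along branches (stochastic
  mapping) are not produced.
- Correlation model: strict Brownian motion (no Ornstein–Uhlenbeck pull,
  no rate shifts), two traits, no within-species measurement-error term;
  Bayes-factor magnitudes depend on the σ² and root priors even where the
  posterior of r is robust.
- Dating: no fossil calibrations, single penalty variant; branch-length-
  sensitive downstream quantities inherit its uncertainty, which is why
  the package treats them as qualitative on synthetic trees.
- The fluorescence module applies no correction for measurements taken at
  differing measuring-light intensities (the outgroup-leaf case); raw
  yields are assumed comparable.
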