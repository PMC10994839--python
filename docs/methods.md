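# Methods

`stressmix` quantifies how bacterial growth responds to all combinations of a
panel of chemical stressors, and whether those responses interact beyond
independent action. This note records the models, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Growth metric

Each well contributes one optical-density (OD600) time series, read hourly
over a 0–72 h window. A cubic smoothing spline is fitted to each series, with
the smoothing parameter chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); an interpolating spline on
hourly data would chase plate-reader noise, while GCV adapts the roughness
penalty per well. The fitness endpoint is the area under the fitted curve
(AUC) over the window, computed as the exact integral of the piecewise
polynomial with any sub-zero excursions of the fit clipped out (each cubic
piece's minimum is checked analytically; pieces that dip below zero are split
at their real roots and only the positive part integrated). AUC deliberately
collapses lag, rate and capacity into one number: a stressor can move any of
them.

Requirements and edge cases: at least 4 time points (an interpolating cubic
is used at exactly 4, since GCV smoothing needs 5); strictly increasing
times; negative readings are clamped to zero with a warning. Optional
per-well baseline correction (subtracting the minimum of the first three
readings) exists behind a flag but is off by default — raw absorbance is the
primary path, and both paths are supported because blank handling in plate
assays varies.

Relative growth for a culture × mixture is

    G = mean(treatment AUCs) / mean(control AUCs),

with the replicate-level AUC lists retained for resampling. Controls are a
per-culture pool (45 control conditions × 4 replicates at the study-shaped
defaults); treatments are not paired to specific control wells. A zero mean
control AUC raises an error and flags the culture rather than producing
infinities.

## Interaction model

The null model for a mixture is multiplicative (Bliss-type independence on
the relative-growth scale): the expected G of mixture A is the product of
the single-chemical G's. Additive nulls are meaningless for relative
fitness — two 70% reductions would "predict" a 140% reduction; the
multiplicative null predicts 0.3 × 0.3 = 0.09, a 91% reduction.

Two coefficients are computed on the subset lattice:

- **Net interaction** N_A = G_A / Π_{a∈A} G_a — the overall deviation from
  independent action, regardless of which subsets cause it.
- **Emergent interaction** I_A — the residual attributable specifically to
  the full set A, obtained by iterating over subset sizes: pair coefficients
  first, then triples (dividing out pair terms), and so on. For |A| = 2 the
  two definitions coincide.

The recursion has a closed form by inclusion–exclusion,
log I_A = Σ_{∅≠S⊆A} (−1)^{|A|−|S|} log G_S, implemented separately as
`mobius_log_interaction` and used as an independent oracle: the test suite
checks agreement to 1e-10 in log space on random lattices up to 8 chemicals.
A partial-order variant divides G_A by singleton effects plus all emergent
terms up to a chosen order m; m = 1 reduces to the net coefficient and
m = |A| − 1 to the emergent one. This is the device behind the
"how many interaction orders suffice" table: a mixture whose residual stops
being significant at order m needs no terms beyond m-way.

Numerical decisions: all interaction arithmetic is carried in log space
(products of up to 255 ratios otherwise underflow) and exponentiated at the
end; G values below a floor of 1e-4 are floored before the log transform and
the affected mixtures flagged — zero-growth wells would otherwise make every
containing coefficient undefined, and flagging beats silently dropping.
Incomplete lattices fail loudly naming the missing subset; nothing is
imputed.

## Significance and classification

A two-stage percentile bootstrap (default 10,000 reps, 95% CIs, all
substreams derived from one master seed by hashing the culture/mixture/kind
key, so adding one analysis never perturbs another):

1. **Response gate.** Treatment and control replicate AUC lists are
   resampled with replacement at their own sizes and G recomputed per rep.
   A CI containing 1 means the mixture produced no detectable response; its
   interaction category is `no_response` and no interaction test is run.
2. **Interaction test.** Every replicate list entering the coefficient's
   formula is resampled per rep, with the shared control pool resampled once
   per rep and reused in every G term of that rep (all G's divide by the
   same controls; independent per-term control resampling would overstate
   independence — the choice is an assumption and is recorded here). All
   lower-order coefficients are recomputed from the resampled data; the
   percentile CI of the target coefficient decides the call.

Classification is direction-aware: if the null predicts reduced growth, a
significant coefficient above 1 dampens the predicted harm (antagonistic)
and below 1 deepens it (synergistic); if the null predicts increased growth
the mapping flips; a CI containing 1 with a passing gate is multiplicative.
The degenerate case of a null prediction exactly 1 is classified as
synergistic (any significant deviation amplifies |G − 1|) and logged.

Percentile intervals are used because they are the minimal reading of
"bootstrap 95% confidence intervals"; no BCa correction, and no
multiple-testing adjustment by default (a Benjamini–Hochberg switch exists
but is off, matching the unadjusted-p convention of the analysis this
reproduces).

**Known calibration limitation.** With 4 replicates the percentile bootstrap
is anticonservative: the plug-in variance of a mean of n = 4 is (n−1)/n of
the unbiased estimate, and the interval implicitly uses normal-range
quantiles where a 3-df t would be needed. A direct resampling oracle puts
the response gate's two-sided error near 0.17 and net-coefficient CI
coverage near 0.88 rather than the nominal 0.95. This is a property of the
procedure at this replicate count, not of the implementation; the test suite
asserts agreement between the pipeline and the oracle rather than the
unattainable nominal level. Measured through the full pipeline at the
study-shaped conditions, the fraction of mixtures called interacting on
purely multiplicative plates is ≈0.09.

## Result summaries

- Response-sign table: each culture × mixture is negative (gate CI entirely
  below 1), positive (entirely above) or none; proportions by mixture
  complexity plus an OLS trend of the negative proportion on complexity.
- Complexity regression: OLS of per-mixture mean G on complexity and an
  indicator for a focal chemical (e.g. the antibiotic that splits responses
  into two modes), pooled across cultures or per culture; mixture means are
  used, unweighted, as the minimal reading of "linear regression". Constant
  input is reported as zero coefficients with a degeneracy flag.
- Persistence lattice: nodes are mixtures with their category; directed
  edges join significantly interacting mixtures exactly one chemical apart
  (Hasse-diagram edges restricted to antagonistic/synergistic endpoints).
- Order-sufficiency table: counts of net-significant mixtures still
  significant as the partial-order null absorbs 2-way, 3-way, … terms;
  counts are non-increasing in the order for a fixed seed because the same
  seed discipline is reused.
- Cross-culture consistency: among mixtures of ≥3 chemicals where ≥2
  cultures show a significant emergent interaction, the fraction where all
  such cultures agree in type.

## Phylogenetic signal

Strain fingerprints are the ordered vector of G over the full mixture
enumeration; fingerprint dissimilarity is Euclidean, clustered hierarchically
(average linkage by default; complete and Ward available — the linkage used
by the original analysis is not stated). Association between phenotypic and
patristic distance matrices uses a one-sided Mantel test with Kendall's τ on
the vectorized upper triangles, permuting rows and columns of the second
matrix jointly; default 9,999 permutations, p = (1 + #{τ* ≥ τ}) / (n+1).

Per-chemical scalar responses are tested with:

- **Pagel's λ** — maximum likelihood under Brownian motion with the
  off-diagonal (shared-history) entries of the tree covariance scaled by
  λ ∈ [0, 1]; root state and rate are profiled out analytically, λ found by
  bounded scalar search (tolerance 1e-8) with explicit boundary checks; the
  p-value is a likelihood-ratio test against λ = 0 (χ², 1 df). Estimates at
  the bounds are reported as boundary values; some reference
  implementations allow λ slightly above 1, so boundary fits can differ
  from theirs while having equal or higher likelihood within [0, 1].
- **Blomberg's K** — the ratio of observed MSE0/MSE (tip variance about the
  phylogenetically corrected mean over the GLS error under the tree
  covariance) to its Brownian expectation on the same tree; K = 1 matches
  Brownian motion. The p-value shuffles tip labels (default 1,000 shuffles)
  and counts shuffles whose GLS error is at most the observed one, with
  add-one smoothing.

Before the λ test, traits are passed through a rank-based inverse-normal
transform (average ranks, Φ⁻¹((r − 0.5)/n)): λ's likelihood assumes normal
tips and relative-growth responses are typically left-skewed. Rank-INT is
parameter-free, deterministic and monotone; it is not necessarily the
transform the original analysis used, so λ values on real data may differ
for that reason.

Both statistics were cross-validated against `phytools::phylosig` in R on
fixed fixtures; K agrees to 1e-10 and the λ likelihood machinery reproduces
phytools' maximum to 1e-6 (fixture values frozen into the test suite).

## Synthetic experiments

The generator defines ground truth on the scale the analysis measures:
log G_A = Σ_{a∈A} log g_a + Σ_{k⊆A} log ι_k for planted singleton effects g
and interaction terms ι. Wells are logistic growth curves
K/(1 + ((K−N0)/N0)e^{−rt}); for a treatment with target G, capacity and rate
are jointly scaled by a factor found by a one-dimensional root solve so that
the closed-form logistic AUC over the window equals G times the control AUC.
Planting effects on rate or capacity alone would make the true G depend on
the integration window; calibrating on the AUC ratio makes the planted
values exactly the quantities the pipeline estimates (the noiseless pipeline
recovers them to ~1e-7 relative; the contract tested is 1e-3). Targets below
the reachable AUC ratio (bounded away from zero because the inoculum is
fixed) raise an error.

Noise is additive Gaussian on OD, truncated at zero, default SD 0.01 OD — a
realistic plate-reader magnitude; no quantitative noise model was published
for the emulated study, so this is a free parameter of the generator, not an
estimate. Per-well noise streams are spawned from the master seed, so runs
are reproducible and streams non-overlapping.

The study-shaped preset (`paperlike_preset`) has 8 chemicals (two
antibiotics, two fungicides, two herbicides, a molluscicide, an
insecticide), 12 cultures with fixed per-culture growth parameters and
antibiotic susceptibilities (constants of the preset; the seed only drives
noise), 4 replicates, 45 control conditions × 4 replicates and hourly
readings over 72 h — 1,200 wells per culture, 255 mixtures. One
antibiotic-like chemical is strongly harmful (g ≈ 0.3), producing the
bimodal split of responses between mixtures with and without it; a pairwise
antagonism (ι = 2 against a harmful null) is planted between the antibiotic
and one fungicide. `demo_preset` is a 3-chemical, 5-culture miniature for
walk-throughs and CLI tests.

What the generator does **not** emulate: contamination events, plate edge
effects, systematic drift within a plate, non-logistic growth (diauxie,
death phases), dose–response structure (single concentration only), and
co-culture dynamics (a mixed community would appear only as another
"culture" with its own response profile). Passing tests on synthetic data
therefore demonstrate correctness of the estimators under the model's
assumptions, not robustness to these real-data features.

Brownian trait simulation for the signal tests draws tips from a
multivariate normal with the λ-scaled tree covariance; random test trees are
binary with exponential(1) branch lengths.

## Problem sizes in the checks

The acceptance script and test suite scale simulations to run on one CPU in
minutes, as this package's own choice of problem size: 200 random lattices
for the oracle-equivalence check; 100 (tests) / 50 (script) simulated
experiments for planted-effect recovery at noise SD 0.005 with bootstrap
2,000; 20/15 datasets on a 4-chemical panel for the multiplicative
calibration; 500 simulations each for Mantel and K null calibration
(199 permutations/shuffles) and for λ/K recovery on a 64-tip tree.
Bootstrap defaults (10,000 reps) apply to real analyses via the CLI.

## Known limitations

- Percentile-bootstrap anticonservatism at 4 replicates (quantified above).
- The contamination heuristic is a flag, not a validated detector; real
  exclusion lists should come from inspection.
- λ on real data depends on the normalizing transform chosen.
- Emergent-interaction bootstraps resample every subset term independently;
  replicate AUCs shared between different coefficients of the same lattice
  make the per-lattice family of tests dependent, and no family-wise
  correction is applied by default.
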