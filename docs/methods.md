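# Methods

This note documents the statistical models, defaults and design choices
behind `cometa`, and what the synthetic-data tests do and do not establish
about real data.

## Effect-size meta-analysis (`meta_de`)

Per gene and study, the effect is the small-sample-corrected standardized
mean difference (Hedges g): d = J (x̄₁ − x̄₀)/s_pooled with
J = 1 − 3/(4n − 9), n = n₁ + n₂, and sampling variance
var(d) = n/(n₁n₂) + d²/(2n).  Genes with zero pooled standard deviation in
a study are excluded from that study (they can still be tested if enough
other studies measured them).  Between-study variance uses the
DerSimonian–Laird moment estimator with fixed-effect weights w = 1/var:
Q = Σw(d − d̄_w)², τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)).  The combined
effect uses w* = 1/(var + τ²): μ̂ = Σw*d/Σw*, se = (Σw*)^(−1/2), z = μ̂/se,
and a two-sided normal p; the normal reference is the standard choice for
this estimator (a permutation reference would be an extension).
Benjamini–Hochberg FDR is applied across all tested genes (the
implementation delegates to `statsmodels.multipletests`; a property test
checks it against the literal step-up definition).

Defaults: `min_studies` equals the number of input studies, i.e. only
complete-case genes are tested; it can be lowered to 2 when platforms
differ in gene coverage.  Direction convention: positive μ̂ = upregulated
in cases, everywhere.

**Calibration caveat (measured, not assumed).** Under a fully null
simulation the DL random-effects p-values are mildly *conservative*: the
τ² clamp at zero is active for roughly a third of null genes and inflates
the standard error, leaving ~3% of null genes below p = 0.05 instead of
5%.  A Kolmogorov–Smirnov test against uniformity detects this at 2000
genes (the fixed-effect combination of the same effects is uniform).  The
estimator is never anticonservative here, and the null false-call rate at
q < 0.05 stays below 1%.

## Directional comparison (`comorbidity`)

DE status is sign(μ̂) where q < 0.05 (threshold configurable).  For a pair,
the background is the set of genes tested in *both* meta-analyses; each of
the four directional intersections is tested with the hypergeometric upper
tail P(X ≥ k) — the one-tailed Fisher exact test.  FDR correction is
applied jointly across the 4 × n_pairs tests of a comparison batch (the
conservative reading; per-pair scope is available).  Labels: SDDC iff
qA, qB < α and qC, qD ≥ α; ODDC for the converse; "mixed" when both
direction classes contain a significant intersection; "none" otherwise.

The profile correlation uses all jointly tested genes, not only
significant ones — with ~10% of genes deregulated this yields moderate r
values (≈ 0.3 for a pair sharing half its DE genes), which is the regime
such analyses report in practice.

Exact-test discreteness: with DE sets of ~100 genes over a 2000-gene
background the overlap count takes few enough values that the null
p-values are visibly superuniform (mean ≈ 0.56); they are valid but not
exactly uniform, which a sensitive uniformity test will flag.

## Enrichment (`enrichment`)

Preranked GSEA ranks genes by meta-analysis z (descending, ties broken by
gene id).  The running sum gains |score|^w / Σ_members|score|^w at member
positions (default weight w = 1) and loses 1/(N − m) elsewhere; ES is the
signed maximum deviation, computed in closed form at the positions just
before and after each hit (O(m) per set rather than O(N)).  Exact ties
between the positive and negative extremum resolve to the positive side
(within 1e-9, absorbing float rounding).  The null permutes set-membership
labels — the only valid option for preranked input — with one shared null
per set size; NES = ES / mean(|null ES| of the same sign);
p = (1 + #{same-sign nulls ≥ |ES|}) / (1 + #same-sign nulls); FDR within
each sign class.  Set-size filter defaults to 5–500 members after
restriction to the ranked universe; n_perm defaults to 1000 (the
permutation p floor of 1/(#same-sign+1) must clear the post-FDR threshold,
which ~500 same-sign permutations do for collections of tens of sets).

Overrepresentation (ORA) shares its p-value core with the comorbidity
Fisher test — a single implementation, asserted identical by test.

The drug analysis computes cosine similarity between the disease z-vector
and each perturbation signature over their shared genes (positive =
mimics, negative = reverses), ranks drugs by it, and applies the same
preranked enrichment machinery to drug sets; significant positive-NES
sets are labeled "mimics", negative "reverses".

## Clustering (`clustering`)

Continuous disease profiles use correlation distance 1 − r of μ̂ vectors
over shared genes.  Discrete {−1, 0, +1} status matrices offer: `hamming`
(mismatch fraction over all genes), `matching` (mismatch fraction over
genes where at least one profile is nonzero — insensitive to the shared
"unchanged" majority), and `manhattan` (sum of absolute status
differences).  The two conventions for "Hamming" on ternary status vectors
(all positions vs active positions) are both provided under distinct names.

PAM is BUILD (greedy 1-by-1 medoid addition) followed by best-improvement
SWAP descent; every accepted swap strictly decreases the summed distance
to medoids.  Because the single-swap neighborhood can stall in a local
optimum on unlucky instances (observed: n = 8, k = 4 with cost 3.761
against a global 3.735), the descent restarts from a fixed set of
deterministic alternative initializations (lexicographic and seeded
pseudo-random medoid sets, part of the algorithm, not user randomness) and
keeps the cheapest local optimum; on random small instances this matches
exhaustive medoid search.  All tie-breaks (assignment, swap choice, best
k) are lexicographic, so results are deterministic.  Silhouette is
s(i) = (b − a)/max(a, b) with s = 0 for singletons; k is chosen by maximal
average silhouette (ties to the smallest k), and the full per-k table is
returned so weak structure stays visible.  Hierarchical clustering uses
scipy's agglomerative linkage (average by default) on the discrete
distances, with a Newick export and a report of which columns join a
reference column first.

## Preprocessing (`preprocess`)

* **Quantile normalization** maps each column's stable rank order onto the
  across-column mean of sorted values.  No tie-averaging: tied values
  receive distinct adjacent reference values in row order, which keeps the
  defining property (all columns share the sorted vector exactly) and
  idempotence for every input, at the cost of arbitrarily (but
  deterministically) ordering ties.
* **Count stabilization** replaces a shrinkage-based variance-stabilizing
  transform with median-of-ratios size factors (genes with any zero count
  excluded from factor estimation) followed by log2(count/sf + 1): library
  size is removed and the scale is continuous log2, which is what the
  downstream standardized effects need; per-gene shrinkage would only
  matter at very low counts.
* **Probe collapsing** keeps the max-variance probe per gene; equal
  variances break to the lexicographically smallest probe id.
* **Outlier removal** works per group (cases and controls separately,
  so unbalanced designs cannot cause removals): while the group's mean
  pairwise Pearson correlation is below 0.9, the sample with the lowest
  mean correlation is dropped; a group never shrinks below 2 samples.
  All correlations are computed on the post-normalization log2 scale.
* **Control augmentation** draws pool controls until the merged study shows
  no significant case/control difference in sex (Fisher exact on the 2×2
  table — exact at small n), age or PMI (Welch t-tests) at p > 0.05, then
  re-normalizes and batch-adjusts with sample origin as batch; if no
  balanced draw exists the best-balanced one is used with a warning.
* **Batch adjustment** is per-gene location-scale standardization of each
  batch to the gene's pooled mean and sd.  Empirical-Bayes shrinkage
  (ComBat-style) is a refinement point; the testable contract — batch no
  longer dominates the top variance axis, pooled means preserved — holds
  either way.
* **Redundancy removal**: studies are ranked by mean inter-sample
  correlation (proxy for a fuller multi-metric quality index); walking down
  that order, a sample is dropped when its patient already appears in a
  higher-quality study, so each patient survives exactly once.
* Order of operations in the pipeline: normalize → outlier-filter →
  (optional) augment → de-duplicate → meta-analyze.  The alternative
  (augment before outlier filtering) is defensible; the chosen order is
  recorded in the run manifest.

## Synthetic data (`synthetic_data`)

The generator emulates the structure of multi-study case-control
compendia on a latent log2 scale: per-gene baselines N(8, 4²) (N(6, 2²)
for counts, keeping Poisson rates in a realistic range), unit within-group
noise (so planted effects are in standardized units), per-study per-gene
batch offsets N(0, 0.3²), and for each DE gene g in study s a case-mean
shift θ_gs = θ_g + η_gs with η_gs ~ N(0, τ²) — exactly the random-effects
structure the meta-analysis estimates.  Counts are Poisson draws with
rate 2^latent.  Outlier samples get noise sd 8 instead of 1, which drops
their inter-sample correlation to ~0.2 against ~0.94 for well-behaved
samples — detectably below the 0.9 threshold.  Patient sharing copies a
sample's latent profile (plus sd-0.1 noise) into the next study under the
same patient id.  Covariates (age, sex, PMI) are generated but carry no
expression effect by default.  One explicit RNG per generator call; no
global state.

Default conditions (4 studies × 20/20 samples, 2000 genes, 10% DE, τ =
0.2) are the study conditions used throughout the tests.  Effect
magnitudes are |N(1.0, 0.6)| — mean ≈ 1.0 with a right-skewed spread
(many weak effects, a few strong ones), chosen once for recovery power:
with the stated sample sizes the estimation error of μ̂ per gene is
≈ 0.027 in variance, so a spread this wide is what makes planted-truth
recovery (r > 0.9) a meaningful target.

What the generator does *not* emulate: probe-level array artifacts,
realistic RNA-seq library composition, gene–gene correlation beyond the
shared baseline, covariate-driven expression, or annotation noise.
Passing tests therefore demonstrate the statistics recover *this* planted
structure, not that real compendia meet the model's assumptions.

## Pipeline (`pipeline`, CLI)

`run_all` derives one sub-seed per stage from a master seed, writes every
stage's artifacts as plain TSV/GMT under its own subdirectory, and records
parameters, seeds and SHA-256 checksums in `manifest.json`; reruns with
the same config are bit-identical.  The shipped demo configuration
(index disease + same-direction, opposite-direction and independent
comparators at default conditions) runs in ~5 s on one CPU.  Test and
acceptance problem sizes (2000 genes, 20-seed replicates, 1000
permutations) were chosen so the whole suite completes in a few minutes.

## Known limitations

* DL conservatism under homogeneity (see above) — a REML or
  Knapp–Hartung variant would sharpen small-k calibration.
* Location-scale batch adjustment does not pool information across genes.
* The GSEA null is gene-label permutation only; no phenotype permutation.
* `augment_controls` balance testing is marginal (per covariate), not
  joint.
* PAM multi-start is heuristic; global optimality is only verified
  empirically on small instances.
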