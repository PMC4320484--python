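# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## Quantitation model

Spectral-count proteomics is treated as compositional: the normalized
spectral abundance factor NSAF_k = (PSM_k/L_k) / Σ_i (PSM_i/L_i) divides
each protein's counts by its length (longer proteins yield more peptide-
spectrum matches at equal molarity) and renormalizes per sample, so NSAF is
a relative abundance and each sample column sums to 1 (enforced to 1e-12).
Two printed filters gate quantitation: a minimum abundance of 0.001 applied
to the per-protein **maximum** across samples — a mean-based rule would
discard stage-specific proteins that are absent under one condition and
strongly present under another, which are exactly the interesting ones in a
starvation/recovery design — and a presence rule (all replicates at ≥ 1
timepoint, or detections at ≥ 5 distinct timepoints; the looser "any 5
samples" reading is available via `FilterParams(alt_mode="any_samples")`).
Detection means a strictly positive stored value; NaN means "missing, to
impute" and never counts as detected. Metabolites use sample-centric
normalization (divide by total area) with a full-replicate-set clause or
strictly more than 18 detections. Physiology is divided by its mean at the
first sampling time, per-variable opt-out for ratio-type variables (the
quantum-yield variable is exempt by default).

## Sequential KNN imputation

Incomplete features are processed in order of ascending missing count (ties
by input order). Each is matched to its K nearest complete features by
Euclidean distance over its observed sample positions — scaled by
√(n_observed/n_used), which is identically 1 here because candidates are
complete — filled with the unweighted neighbour mean, and then joins the
complete set so it can serve later features. K defaults to 10 and must not
exceed the number of initially complete features (the pipeline clamps K
downward with a logged warning; the library function raises). Observed
entries are never altered; the procedure is deterministic; imputation runs
after presence filtering and before log transform/scaling, per block.
Under 10% missing-completely-at-random on correlated blocks, the scheme
beats per-feature mean imputation in squared error (tested); it assumes
MCAR and will be biased under intensity-dependent (censoring-type)
missingness, which is out of scope.

## Univariate testing

Proteins: Kruskal-Wallis on log₂(x + c), c = half the smallest positive
value when the matrix contains zeros (0 otherwise). The log base is
irrelevant to a rank test; the pseudocount only handles stored zeros.
Metabolites and physiology: one-way ANOVA, then all pairwise Tukey HSD
comparisons. Pairwise significance is decided by comparing the
Tukey-Kramer statistic q_ij = |m_i − m_j| / √(MSE/2·(1/n_i+1/n_j)) to the
studentized-range critical value q_{1−α;k,df}, which is mathematically
equivalent to thresholding the Tukey p-value at α but ~1000× cheaper at
screening scale (the survival function costs ~10 ms per evaluation; exact
pairwise p-values for a single feature are exposed as `tukey_pairwise_p`).
Compact letters are assembled by insert-and-absorb so that two groups share
a letter iff their comparison is not significant. Benjamini-Hochberg
adjustment is applied across features within each block, not pooled —
blocks differ in measurement technology and null behaviour. Features with
zero variance are flagged degenerate with p = 1.

Calibration, recomputed by `scripts/acceptance.py` on fresh null data each
run: at the 6×4 design the Kruskal-Wallis chi-square approximation is
conservative (empirical rate ≈ 0.027–0.03 at nominal 0.05 — with n = 4 per
group the permutation distribution of H is coarse), the Tukey familywise
rate sits at ≈ 0.05, and the raw lag-1 Granger test at T = 50 sits at
≈ 0.05.

## Latent-variable core

One numerical core serves three entry points. Sparse PLS (regression mode)
iterates, per component, u ∝ select_keepX(Xᵀ Y v) and v ∝ Yᵀ X u with unit
norms, where select_keepX keeps the keepX largest-|·| weights (ties broken
by feature order) and zeroes the rest; v is initialized from the leading
right singular vector of XᵀY; convergence is max elementwise change < 1e-6
(cap 500 iterations; non-convergence is flagged, not fatal). Scores are
t = Xu; X and Y are both deflated with t, which makes successive X-scores
orthogonal (asserted to 1e-8). PLS-DA is the same core against a centred
scaled one-hot class matrix with keepX = p; PCA is a plain SVD. Scaling
uses the n−1 SD denominator; constant features are dropped with a warning.
Every component's sign is fixed by making its largest-|weight| entry
positive, so fitted models are bit-for-bit reproducible. Defaults ncomp = 3
and keepX = 50 are declared configuration values, not tuned quantities.

The relevance network uses sim(i,j) = Σ_h cor(x_i,t_h)·cor(y_j,t_h) with
the X-scores for both variable sets — the standard construction for
regression-mode sparse PLS, and exactly the plain Pearson correlation when
Y lies in the span of a fully retained X (tested). Values are clipped to
[−1,1] with clip events logged. Edges below the cutoff are absent, not
zero-weighted; per-edge provenance (spls-similarity vs pairwise-correlation)
is kept through merges.

## Granger screening

For ordered pair (x, y) at lag ℓ: restricted model y_t ~ 1 + y_{t−1..t−ℓ},
unrestricted adds x_{t−1..t−ℓ}; F = [(RSS₀−RSS₁)/ℓ]/[RSS₁/(T−3ℓ−1)] on
(ℓ, T−3ℓ−1) df. Series are replicate means per timepoint, standardized; no
differencing or detrending is applied by default. Singular designs (e.g.
x ≡ y) and constant series are flagged degenerate with p = 1 and excluded
from the BH family, which otherwise spans all ordered pairs tested in one
run. With the 6-point design the unrestricted regression has 2 residual
degrees of freedom — legal but severely underpowered, so the module warns
for T < 10 rather than refusing; the powered setting (T = 50 series from
the generator) is where planted β = 0.9 pairs are recovered in full.

## Profiles and biclustering

Per-feature profiles are replicate means per timepoint scaled to percent of
the feature's own maximum (so every feature peaks at 100; idempotent and
invariant to positive rescaling). Bin aggregation restricts to features
passing the significance threshold, maps each to its first (most specific)
functional bin, and reports mean ± SD per timepoint with member counts
(< 2 members flagged). Biclustering is agglomerative with Euclidean
distance and complete linkage on both axes — the simplest determinate
choice; both are config-exposed — with SciPy's deterministic leaf ordering
and Newick export of both dendrograms.

## The synthetic-data generator

The generator emulates the study conditions, not just array shapes: 6
sampling times (0, 5, 24, 72, 77, 96 h) × 4 biological replicates; 500
proteins, 50 metabolites, 5 physiological variables; expected sequencing
depth 20,000 PSM per sample (so a typical protein carries ~40 counts);
protein lengths uniform on 100–1500 residues; between-feature baselines
lognormal (σ = 0.8); replicate noise lognormal (σ = 0.2).

Planted structure, all recorded in a truth object:

* **Responders** (10% of proteins, alternating induced/repressed) follow a
  starvation-response profile — at baseline at 0 h, at effect_size
  (default 4-fold, within the range of reported starvation fold changes)
  during starvation, relaxing through early recovery back to baseline.
  Responders are drawn from the quantifiable pool (above the ~35th
  percentile of baseline abundance and expected counts): a repressed
  responder whose control abundance already sits at the detection limit
  falls below the printed abundance/presence filters and is unrecoverable
  by construction, which would defeat the generator's purpose of giving
  every stage a recoverable answer.
* **Correlated blocks**: three latent factors (smooth cosine time shapes
  plus replicate noise, standardized) each drive 10 proteins and 5
  metabolites with within-block pairwise correlation `factor_loading`
  (member-to-factor correlation √factor_loading), members loading with
  alternating sign — under starvation some pools rise while others fall,
  and sign balance also prevents a synchronized block from dominating the
  per-sample totals that both NSAF and sample-centric normalization divide
  by. Block log-amplitude is 1.5 (~4.5-fold swings) and member proteins are
  drawn from the upper half of expected counts, because correlation
  structure is simply not observable in features measured with ~10 PSM
  (Poisson log-noise ≥ 0.3). The factor residual is the member's replicate
  noise, not an extra layer. Physiology variables are noisy affine images
  of the factors.
* **Spectral counts** are Poisson around depth·L_k·a_ks / Σ_j L_j·a_js —
  the simplest law under which NSAF is an unbiased plug-in for the latent
  relative abundance a (verified by Monte-Carlo against the closed form).
  Expectations below `dropout_threshold` (default 1 count) are recorded as
  0; thresholded-expectation dropout keeps presence-filter tests exactly
  predictable, at the cost of not modelling stochastic peptide sampling
  near the limit.
* **Causal series**: white-noise drivers x and targets
  y(t) = β·x(t−1) + ε(t) (β = 0.9, ε ~ N(0, 0.1²), T = 50) plus
  independent null series, generated separately from the 6-point tables
  because lag-1 regression at T = 6 has no power by design.
* **Missingness** is MCAR only — matching what sequential KNN assumes —
  with exactly round(rate·cells) blanks and never a fully blanked feature
  or sample (uniform rejection sampling with a constructive row/column-
  cover fallback).

One seed sequence drives all stages; identical seed and parameters give
bit-identical tables and truth.

**What the generator does not emulate**, hence what passing tests do not
show about real data: peptide-level sampling and shared-peptide inference,
intensity-dependent (MNAR) missingness, batch and run-order effects,
retention-time drift, heteroscedastic physiological error, and biological
covariance structure beyond low-rank factors plus archetypal time profiles.
Recovery rates measured here (≥ 80–100% for planted responders, blocks,
causal pairs and sample conditions under the default conditions) are
upper bounds on what equally sized real experiments could yield.

## Pipeline and provenance

Stage order is fixed: quantify → impute → univariate → latent → network →
causality → profiles. Every intermediate table is written as TSV; the run
log (JSON, sorted keys, no timestamps) records the seed, the full config,
survivor counts per filter and all warnings, so a config plus seed
reproduces every byte. A failing stage writes a FAILED marker naming the
stage and offending entity and aborts. The Granger stage screens the
`granger_max_features` most significant features (default 30; 870 ordered
pairs) — screening all ~500² ordered pairs of a full proteome at T = 6
would multiply runtime for tests that cannot be powered anyway.

## Problem sizes

Defaults were chosen so the full synthetic run (500 proteins, 50
metabolites, 5 physiology variables, 24 samples) completes in seconds, and
the calibration simulations (2,000 Granger pairs, 5,000 Kruskal-Wallis
features, 2,000 Tukey features) in well under a minute each on one CPU.

## Known limitations

* The Kruskal-Wallis chi-square p-value is conservative at n = 4 per group;
  an exact/permutation variant is not implemented.
* Granger screening is pairwise and unconditional; common drivers produce
  spurious directed edges, and T = 6 results are reported with a warning
  but should be treated as exploratory.
* sPLS tuning (ncomp, keepX) by cross-validation is out of scope; the
  similarity cutoff is a declared config value, with no claim that any
  particular threshold is "significant" in a formal sense (a permutation
  option would be the principled extension).
* Only regression-mode sPLS and MCAR imputation are provided; canonical
  mode, multi-block variants and MNAR-aware imputation are non-goals.
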