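# Methods

This note documents the statistical model behind `mirnorm`, the default
parameters and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Quantities and scales

qPCR reports the threshold cycle Ct; one cycle ≈ a factor of 2 in template
abundance, so Ct is a (negated) log2 scale. All internal modelling is
therefore done on log2 values, and relative quantities assume perfect
amplification efficiency:

- `RQ_ij = 2^(−ΔCt_ij)`, `ΔCt_ij = Ct_ij − Ct_spike,j` (spike mode), or
  ΔCt against a single panel-wide reference detector (min-Ct mode).
- `NF_j = (Π_{r∈refs} RQ_rj)^(1/k)`; `NRQ_ij = RQ_ij / NF_j`.
- `ARQ_ij = (log10 RQ_ij − mean_i) / sd_i` with row mean and sample SD
  (ddof = 1) of log10 RQ.

Efficiency-corrected models are out of scope; if per-assay efficiencies
matter, they must be folded into the Ct values upstream.

## Quality control

- **Censoring** is strict: cells with `Ct > threshold` (default 35 cycles)
  become missing with reason `above_threshold`; a value exactly at the
  threshold is kept. The threshold is platform-dependent and configurable.
- **Low-Ct flagging** (default floor 10 cycles) removes the signature of
  non-exponential amplification curves that cross the fluorescence
  threshold spuriously. The floor value is this package's
  operationalization of a visual-inspection step; user exclusion masks
  cover cases a rule cannot.
- **Detection filter**: a detector is kept iff its present count is at
  least `ceil(fraction · n_g)` in every group (default fraction 2/3).
  "Every group" rather than "any" because a candidate normalizer must be
  stably detected across the whole design; `ceil` because the rule is a
  lower bound. Flagging precedes filtering.
- **Imputation**: k-NN (default k = 10, capped at m−1) on log2 values via
  scikit-learn's `KNNImputer`: nan-Euclidean distance over jointly observed
  samples, inverse-distance-weighted mean of the neighbours' log2 values.
  Log2 space is used because Euclidean distance there corresponds to Ct
  distance, which is physically meaningful. Imputation is meant for an
  exiguous number of technically missing cells — the detection filter, not
  the imputer, handles biologically absent miRNAs.

## Stability algorithms

**geNorm.** `V(j,k) = SD(log2(RQ_j/RQ_k))` over samples (sample SD,
ddof = 1); `M_j = mean_k≠j V(j,k)`. The detector with the highest M is
removed and M recomputed until two remain. The score entering the SSS is
the *stepwise* M — each detector's M in the round of its elimination, the
canonical geNorm output — with the single-pass full-set M available via
`stepwise_m=False`. Ties on M remove the lexicographically larger id
first, making elimination deterministic. The companion series
`V(n, n+1) = SD(log2(NF_n/NF_{n+1}))` (NF_n = geometric mean of the top-n
candidates) supports choosing the number of references, which remains
user-defined (default 3).

**Model-based stability value (ρ).** Within each group g the model is
`y_igj = detector_i + sample_gj + ε_igj` on y = log2 RQ, with
heterogeneous noise variance σ²_ig. From the two-way centered residuals
`r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_·g·` and `u_ig = Σ_j r²_igj/(n_g−1)`,
the intragroup variance is the moment estimator

    σ̂²_ig = max(0, (I/(I−2)) · (u_ig − Σ_i' u_i'g / (I(I−1)))),

which is exactly unbiased under the model (the `I/(I−2)` factor undoes the
leakage of the other detectors' variances into the centered residuals);
truncation at 0 is the conventional fix for a moment estimator and its
small upward bias is quantified by the Monte-Carlo calibration test. With
G ≥ 2 groups, the detector-centered group difference d̂_ig is shrunk by
its reliability `γ̂²_i/(γ̂²_i + σ̂²_ig/n_g)` — detectors whose apparent
group difference is within noise are not punished for it — and

    ρ_i = (1/G) Σ_g ( |d̃_ig| + sqrt( γ̂²_i(σ̂²_ig/n_g)/(γ̂²_i + σ̂²_ig/n_g) + σ̂²_ig/n_g ) ).

With one group, ρ_i = σ̂_i. Lower ρ = smaller systematic error. Bit-level
agreement with the original Normfinder script is not claimed; the
estimator is validated against its stated model properties (unbiasedness,
shift sensitivity, single-group reduction).

**CV score.** Shares `X_ij = RQ_ij / Σ_{i∈real} RQ_ij`;
`CV_i = SD(X_i·)/mean(X_i·)` (ddof = 1). The column total is a surrogate
of the total miRNA recovered for that sample, so the score is invariant to
per-sample input differences by construction. Pseudo-detectors are scored
against the real-detector totals but never contribute to them.

**SSS.** `SSS_i = sqrt(M_i² + ρ_i² + CV_i²)`, ranked ascending with
detector-id tie-break. The three scores are combined on their raw scales
by default, because the defining formula carries no standardization; an
optional mode min-max rescales each score to [0, 1] first for users
concerned about scale mismatch between methods. All three scores — hence
the SSS and the ranking — are invariant to per-sample multiplicative
scaling (geNorm: ratios cancel; the model: the sample effect absorbs the
factor; CV score: shares).

**Selection.** References are picked by walking ranks upward, skipping
pseudo-detectors and any detector whose miRNA family is already
represented (family members share sequence similarity, hence likely
functional overlap). Families come from a user-supplied annotation table;
unannotated detectors form singleton families.

**Cross-platform combination.** Restricted to detectors present in every
platform's table; each platform's SSS is min-max rescaled to [0, 1] over
that shared set and the combined score is the arithmetic mean, ranked
ascending. Min-max + mean was chosen because the platforms' raw score
scales are not commensurable and the combination should weight platforms
equally; any monotone per-platform transform with equal weights would
serve the same purpose.

## Evaluation

CVs for evaluation are computed on the *linear* scale (SD/mean per
detector row). ECDFs of the CV vectors are evaluated on a 100-point grid
spanning the pooled CV range; a normalization scheme "dominates" raw when
its ECDF is ≥ raw's at every grid point, which turns the visual
left-shifted-curve comparison into a testable predicate.

PCA treats detectors as observations (points), samples as variables;
components come from the SVD of the column-centered matrix
(scikit-learn's exact solver) with a deterministic sign convention (each
loading vector's largest-magnitude entry is non-negative). For autoscaled
input PC1–PC2 are informative; for unscaled log10 input PC1 carries
expression level, so PC2–PC3 are used. The separation statistic —
mean distance to own centroid of the top set divided by that of the bottom
set in the chosen component plane — is this package's numeric
operationalization of "stable candidates cluster at the funnel's narrow
end"; no canonical definition exists, so the statistic is deliberately the
simplest scale-free contrast of within-set spread.

## Synthetic-data generator

The generator emulates, on the Ct scale, the variability sources of serum
panels: per-detector baselines uniform over 20–32 cycles (the usable
abundance window between very abundant and near-threshold); class noise —
stable SD 0.05, variable SD 0.5 log2 units (≈ ±3% vs ±40% per sample);
a 1-log2-unit (2-fold) group shift for differential detectors;
a per-sample scaling factor s_j ~ N(0, 1 log2 unit) on every endogenous
detector, representing inter-individual total-miRNA concentration and
input differences; a spike-in with only technical noise (SD 0.05);
censoring above 35 cycles. Defaults: 5 stable + 15 variable + 10
differential detectors, 2 groups × 8 samples — a small discovery-phase
panel. Noise is Normal on the log2/Ct scale because multiplicative biology
is additive there.

The spike-in is added at a fixed concentration, so by default it does
*not* carry s_j: spike normalization removes extraction/RT effects it
shares (none are simulated separately by default) but cannot remove the
sample-concentration component — which is precisely why an endogenous NF
stage exists, and what makes the CV-reduction and PCA-funnel analyses
informative on these data. `spike_shares_scaling=True` models a
co-extracted spike that absorbs s_j too; the scale-invariant stability
scores behave identically under either choice.

Not emulated: hemolysis contamination, batch structure, replicate wells,
platform-specific chemistry differences, non-Normal outlier tails, and
correlated biological co-regulation between miRNAs. Passing tests on these
data therefore demonstrate the estimators' statistical behaviour under the
declared noise model, not robustness to every pre-analytical pathology of
real serum studies.

## Numerical conventions and degenerate inputs

- Sample SDs use ddof = 1 throughout.
- Variance estimates are truncated at 0; shrinkage factors with a zero
  denominator are defined as 0.
- Geometric means are computed as `2^(mean(log2 ·))` except the reference
  NF, which uses `(Π RQ)^(1/k)` so a single reference reproduces its RQ
  exactly.
- Ties: geNorm elimination removes the lexicographically larger id; the
  min-Ct reference and SSS ranks prefer the lexicographically smaller id.
- The detection-count threshold uses `ceil(fraction·n − 1e−9)` to protect
  exact thirds from floating-point representation.
- Constant rows are excluded (with a warning) from autoscaling; an
  all-constant matrix, an empty detection-filter result, or a detector
  with no jointly observed samples for imputation raise data errors rather
  than producing silent output.
- Determinism: one configured seed drives all simulation draws through
  named `SeedSequence` substreams; identical config + seed yields
  byte-identical output tables.

## Problem sizes used in the shipped analyses

The acceptance harness runs 20 simulation seeds of the default 30-detector
× 16-sample design, 50 random matrices (≤ 10 × ≤ 12) for the geNorm
brute-force cross-check, 20 random matrices for scale invariance, and
2000 Monte-Carlo replicates (10 detectors × 8 or 16 samples) for the
variance-estimator calibration — sizes at which the Monte-Carlo error of
each check is comfortably below its acceptance margin.

## Known limitations

- Amplification efficiency is fixed at 2; no efficiency-corrected NRQ.
- The min-Ct reference is a single panel-wide detector (minimum *mean* Ct
  among fully observed detectors), not a per-sample minimum: a per-sample
  reference would destroy cross-sample comparability of the RQs.
- BestKeeper-style and rank-correlation-based selection methods are not
  implemented.
- Batch-effect correction is out of scope; the annotation carries an
  optional batch column for documentation only.
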