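# Methods

This note documents the models, numerical choices and limitations behind
`retroclock`, in the order the pipeline runs.

## Probe–locus annotation

Array manifests give one genomic coordinate per probe — the interrogated
cytosine. A probe belongs to the retroelement CpG universe when that
coordinate is contained in an annotated retroelement locus,
`start ≤ pos ≤ end` on the same chromosome, with all coordinates 1-based
inclusive internally (BED input is converted at the I/O boundary, and
only there). Three deliberate simplifications:

* **Point, not interval.** The CpG dinucleotide spans 2 bp, but loci span
  hundreds to thousands; point containment is unambiguous and matches how
  manifests are published.
* **Strand is ignored.** CpG methylation is measured symmetrically on
  both strands, and no strand rule is defensible at locus scale.
* **Multi-locus probes keep all hits** but enter any clock design matrix
  exactly once; in class summaries they count once per repeat class and
  once in the distinct-probe total.

Chromosome naming ("chr1" vs "1") is never reconciled silently: if the
probe and locus chromosome sets are disjoint but agree after stripping
the prefix, annotation raises unless aliasing is explicitly enabled.
Repeat classes live in a closed vocabulary {HERV, LINE, LTR, SINE, DNA,
Unknown}; RepeatMasker-style compound labels ("LINE/L1") resolve by their
top-level class and anything unrecognized becomes Unknown rather than
failing, since annotation sources vary.

The interval index (one interval tree per chromosome) is verified against
a brute-force all-pairs scan on randomized instances; the scan, not the
index, is the definition.

## Clock training

The clock solves the elastic-net problem

    (1/2n) Σ (y_i − b0 − x_i'b)² + λ[α‖b‖₁ + ((1−α)/2)‖b‖₂²]

with features standardized internally (population sd; constant features
are left with zero coefficients) and coefficients returned on the beta
scale. Choices where the design was open:

* **Mixing parameter α = 0.5** by default. The clock literature uses
  "elastic net" with α anywhere in (0, 1]; 0.5 is the common middle
  ground and is exposed in `TrainingConfig`. For the λ_max formula α is
  clamped at 10⁻³ as α → 0 (the formula diverges; pure ridge has no
  finite all-zero threshold).
* **λ path**: 100 log-spaced values from λ_max down to λ_max·10⁻³.
* **Cross-validation**: 10 folds, error = mean squared error on the
  response scale. Folds are stratified on the response (sorted, then fold
  labels permuted within consecutive blocks), which reduces fold-to-fold
  imbalance in age distribution. Selection is the CV minimum
  (`lambda_min`) by default; the one-SE rule is available.
* **Solver**: coordinate descent (scikit-learn's `enet_path`, the same
  algorithm family as glmnet), warm-started along the path. Default
  stopping tolerance is 1e-4 with at most 1000 sweeps — at desk scale
  (hundreds of samples × thousands of probes) a tighter tolerance
  multiplies runtime roughly tenfold while leaving the selected support
  and held-out accuracy unchanged. Solver correctness is verified
  separately: on small problems run at tolerance 1e-12, the returned
  solution satisfies the KKT subgradient conditions to well below 1e-6
  and beats random coefficient perturbations in objective value. The KKT
  checker (`kkt_violation`) is part of the public API.
* **Constant response** returns an intercept-only model with a warning
  rather than an error.

Train/test splitting assigns `round(0.8·n)` samples to training via a
seeded permutation. With donor grouping, whole donors are packed
greedily, in seeded random order, into the training side until it reaches
the target share — no donor ever straddles the split, at the price of an
achieved share that can miss the target by up to one donor. Splitting
fails only when a valid non-empty two-sided grouped split is impossible
(fewer than two donors).

Missing betas are mean-imputed from **training** means only — the same
means the shipped model applies at prediction time, keeping the linear
predictor unbiased at the training centroid and train/deploy behavior
identical. Samples missing more than 20% of the probe universe
(configurable) are excluded with a warning. Features are raw beta values;
no M-value transform (mainstream clock construction operates on the beta
scale).

## Age transforms

Human clocks regress on age directly. Cross-species clocks use relative
age `ln(age + offset)` with a 2-year offset; natural log is used (the
base only rescales coefficients — predictions are base-invariant because
the inverse uses the same base). The inverse `exp(y) − offset` is exact;
round-trip error is at float precision (< 1e-12 relative). Predictions
are always reported in years.

## Evaluation, acceleration, contrasts

Accuracy is Pearson's *r* and the **median** absolute error in years —
"MAE" in the epigenetic-clock sense, which is the median, not the mean.
*r* requires at least three pairs and non-degenerate variance; otherwise
it is reported as NaN while the median error is still computed.

Age acceleration defaults to the plain difference predicted − observed
(exactly interpretable per sample); the residual method regresses
predicted on chronological age within the supplied cohort and returns
residuals (these sum to zero, and agree with the difference method when
the regression is the identity line). Residual acceleration is
cohort-relative and is the right choice when comparing groups measured on
a common regression baseline.

Group contrasts are Student's t-tests, two-sided, with 95% confidence
intervals: pooled-variance two-sample t for two-group designs (Welch
optional), one-sample t on within-donor differences for paired designs.
Donors missing a timepoint are an error naming them, not a silent drop.
A paired design with zero variance in the differences is handled
degenerately (t = 0, p = 1 for no change; p = 0 for a constant nonzero
change).

Clock-CpG comparisons use UpSet semantics: for every non-empty
combination of clocks, the count of CpGs belonging to exactly that
combination. These counts partition the union by construction and are
tested against direct membership-vector enumeration.

## Enrichment

Each feature set is intersected with the stated probe universe before
testing. The 2×2 table (a = query∩feature, b, c, d) is tested one-sided
for enrichment via the exact upper hypergeometric tail P(X ≥ a)
(two-sided Fisher optional); fold enrichment is
(a/|query|)/(|feature|/|universe|) and the odds ratio is ad/bc (infinite
when bc = 0). BH adjustment is applied within each feature database
(TFBS, chromatin states and histone panels are distinct hypothesis
families tested and reported separately). Two universes are exposed —
the full platform manifest or the retroelement CpG universe — because
the enrichment baseline is a modelling choice, not a fact; the platform
universe is the default.

## Reliability

Technical replicates are modelled one-way random-effects:
y_ij = μ + u_i + e_ij with u_i ~ N(0, σ²_b), e_ij ~ N(0, σ²_w), and
ICC = σ²_b/(σ²_b + σ²_w). Two-way ICC forms need a rater/batch factor
that technical replicates lack. REML (via a random-intercept mixed
model) is primary; the one-way ANOVA moment estimator ICC(1,1), with the
mean-group-size correction k₀ = (N − Σk²/N)/(a−1) for unbalanced designs,
is the cross-check and automatic fallback on mixed-model failure.
Negative variance estimates are truncated at zero and flagged. The exact
degenerate case σ²_w = 0 (replicates identical within every subject) is
short-circuited to ICC = 1 rather than fitted.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the pipeline assumes,
with every truth table recorded so the generator is its own oracle:

* **Methylation cohorts**: ages uniform over 12–100 years; causal probes
  follow logit(β) = a_j + b_j·(driver − mean) + ε with b_j = ±0.02 logit
  units/year against noise sd 0.5 (per-probe signal-to-noise ≈ 1 over the
  age span), baselines a_j ~ N(0, 1.5); non-causal probes are
  age-independent. Defaults: 600 samples × 3000 probes, 150 causal. The
  logit scale guarantees β ∈ (0, 1) by construction.
* **Multi-species cohorts**: each species' lifespan scale is drawn
  log-uniformly over [0.1, 1] of the maximum age and the causal driver is
  relative age ln(age + 2) at ±0.5 logit units per log-year — the
  log-offset transform is the correct model, so these cohorts exercise
  it. Donor/tissue/species block shifts (sd 0.1/0.1/0.2 logit units) add
  the nesting structure grouped splitting must respect.
* **Replicates**: subject means N(μ, σ²_b = 9), replicates N(mean,
  σ²_w = 1), 30 subjects × 2 by default (true ICC 0.9).
* **Expression cohorts**: negative-binomial counts (size 10), log-mean
  linear in age (±0.02 log-fold/year) for 40 of 1000 loci, log-normal
  library sizes (median 10⁶, sd 0.3 on the log), 160 samples.

These cohorts deliberately omit type I/II probe chemistry differences,
batch and plate effects, cell-composition confounding and realistic
probe-probe correlation. A passing recovery test therefore shows the
pipeline is correct and well-calibrated under its own assumptions — it
does not certify accuracy on real arrays, where preprocessing and
confounding dominate.

Problem sizes in the test suite and the acceptance script (600×3000
recovery cohort, 400×1500 multi-species cohort, 200 ICC simulations,
2×2 tables with margins ≤ 50, ≥ 10,000 randomized annotation probes) are
chosen so the full verification run completes in a few minutes on a
single CPU while keeping every recovery threshold non-trivial.

## Known limitations

* Raw IDAT preprocessing, normalization and probe QC are out of scope;
  the package consumes finished beta matrices.
* RNA-seq quantification of retroelement expression is out of scope; the
  expression clock consumes a locus × sample count matrix.
* Published clocks (Horvath, Hannum, PhenoAge, GrimAge, PC-clocks,
  DunedinPACE) are not recomputed; clock-CpG intersections operate on
  user-supplied CpG lists.
* The grouped splitter is greedy, not an exact partitioner: with few,
  large donors the achieved training share can deviate from the target by
  up to one donor.
* ICC confidence intervals are not provided (a percentile bootstrap can
  be layered on by resampling subjects).
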