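# Methods

This note documents the models and procedures varprox implements, the
defaults it ships, the numerical choices behind them, and what the synthetic
data does and does not establish.

## Proxy labels from allele frequency

The core assumption is population-genetic: purifying selection keeps
deleterious alleles rare, so allele frequency carries information about
deleteriousness. varprox operationalizes this as binary proxy labels over
frequency strata:

* **excluded** — AF > 0.5. Such records are ambiguous about which allele is
  derived; exclusion is applied *before* stratification, so an excluded
  record can never enter a stratum.
* **singleton** — AC = 1 (observed on a single haplotype).
* **rare** — MAF < 0.001 and AC > 1.
* **frequent** — MAF ≥ 0.001 (boundary inclusive). The 0.1% cutoff is the
  conventional conservative frequency bound for dominant disease alleles.

MAF is always computed on demand as min(AF, 1 − AF) and never stored.
Proxy labels are noisy by construction — many rare variants are neutral —
but highly regularized linear models tolerate substantial mislabeling, and
the label direction (enrichment of deleterious variants at low frequency) is
what the model learns.

## Leakage control by spectrum matching

Frequency strata differ in substitution composition (recurrent mutation at
hypermutable sites pushes transitions, C→T above all, to higher
frequencies). A classifier could exploit this composition difference without
any biological signal. When a balanced pair is assembled, the
proxy-deleterious pool is therefore subsampled to match the proxy-benign
spectrum:

* **Classes.** 12 ordered ref→alt SNV classes — deliberately without strand
  collapsing or CpG context, since only the composition of the training
  table matters to the matcher — plus InDel classes (insertion/deletion ×
  length 1..50, longer pooled at 50; lengths beyond 50 are irrelevant
  because the clinical benchmark caps InDels at 50 bp).
* **Apportionment.** Largest-remainder apportionment of the sample size by
  target proportions, ties broken by lexicographic class order; this makes
  the per-class counts exact to the integer and the whole draw reproducible.
  The L1 distance between sample and target proportions is bounded by
  (number of occupied classes)/n.
* **Universes.** SNVs and InDels are matched and balanced independently,
  since stratum sizes and spectra are reported separately per type.
* Every proxy-deleterious source is matched when matching is enabled;
  unbalanced ("-all") pairs skip matching to retain the full pool and
  instead carry per-record weights w_c = n_max/n_c so each label class
  contributes equal summed weight.

## Feature pipeline

Imputation (median/mode computed on the training matrix, or a literal
per-column default), one-hot binarization of categoricals (indicator
vocabulary frozen at fit; unseen scoring-time levels map to all-zero
indicators with a warning — the non-crashing choice), feature crosses
(elementwise products, computed after imputation and *before* normalization
so sign semantics are preserved), group exclusion, and z-normalization.

* Each column carries one of five group tags: conservation/constraint,
  epigenetic/regulatory, sequence-based, variant density, other. A cross
  inherits the tags of both parents, so excluding a group also removes every
  cross touching it. Variant-density features are the second leakage
  channel: local variant density is correlated with the frequency-derived
  labels themselves, which is why every pair can be trained with and without
  that group.
* Standardization uses the population (divide-by-n) standard deviation;
  only internal consistency matters, and constant columns map to all-zero.
  Statistics are frozen on the training matrix and reused at scoring time.
* The shipped cross list is a small configurable default; the exact
  production cross list of a full annotation stack is configuration, not
  code.

## Iterative logistic regression

The trainer minimizes the weighted penalized negative log-likelihood

    L(w, b) = Σᵢ sᵢ [log(1 + e^{zᵢ}) − yᵢ zᵢ] + ‖w‖²/(2C),  zᵢ = xᵢ·w + b

with C = 1 and an unpenalized intercept (conventional; keeps class balance
out of the penalty). Optimization is scipy's L-BFGS-B from zero
initialization with a per-iteration callback, so snapshot k is exactly the
parameter state after k optimizer iterations — one optimizer run yields the
whole trace. Convergence tolerances are set effectively to zero so the
optimizer cannot stop before the requested iteration count; if it
nevertheless converges early, the converged state is repeated. The objective
is non-increasing across snapshots (asserted to 1e-6 per step).

Early stopping is the model's regularizer in practice: the snapshot used for
scoring maximizes the unweighted mean over validation sets of
(AUROC + AUPRC)/2 (sets differ by orders of magnitude in size, hence
unweighted; the 1:1 combination of the two metrics is a documented,
configurable choice), ties to the smallest iteration. Without validation
sets the default is iteration 13. Standing-variation pairs train 20
iterations; pairs including the human-derived cohort train 50, since larger
combined sets move the optimum later.

Because inputs are standardized, coefficients are directly comparable and
reported as importances: the top 30 by |coefficient| with per-group
|coefficient| sums, ties resolved in manifest order.

## PHRED scaling

Raw scores are ranked against a reference score set (descending
deleteriousness) and reported as −10·log₁₀(rank/N). Ties take the average
rank; a query absent from the reference takes the rank it would displace.
Ranks are capped at N, so the scale has floor 0 and its maximum is attained
by the top reference score. Rank fraction 0.01 ⇔ PHRED 20, 0.001 ⇔ 30. The
average-rank tie convention is a documented choice; min-rank would differ
only within tied blocks.

## Evaluation

AUROC is computed by the Mann–Whitney rank formula (ties counted half),
which equals trapezoidal ROC integration; AUPRC is step-wise average
precision (no trapezoidal PR interpolation — standard and conservative),
with ties broken by stable input order. Consequence-stratified evaluation
reports both metrics per VEP-style label and aggregated over the fixed
coding/noncoding partition, skipping (and flagging) single-class strata.
The binned analysis samples up to 100,000 variants per unit-wide PHRED bin
over (0, 50] after excluding AF = 0 records and reports mean AF and
singleton fraction per bin; singletons are defined by AC = 1 (an AF-based
definition would denote fixed alleles, contradicting the singleton concept).
When a bin's population is below the cap the result is deterministic and
seed-independent.

## Benchmarks

* **Clinical.** Whitelist-only retention: {Pathogenic, Likely pathogenic,
  Pathogenic/Likely pathogenic} → 1, {Benign, Likely benign, Benign/Likely
  benign} → 0; everything else (uncertain, conflicting, ...) is dropped by
  not being whitelisted. SNVs and InDels with net length ≤ 50 bp (inclusive),
  mitochondrial records dropped, assembly filtered when an assembly column
  is present. Inputs are assumed coordinate-harmonized; liftOver is out of
  scope.
* **Reporter assay (MPRA).** Per cell type, a variant is *regulatory* when
  both element activities are significant (A_logP > 3 and B_logP > 3,
  strict), the allele skew is significant (Skew_logP > 4, strict) and the
  effect size |skewStat| ≥ 1 (inclusive); the variant-level call needs ≥ 3
  of 5 cell types. *Neutral* needs stronger activity (A_logP, B_logP > 4),
  no significant skew (Skew_logP < 2, strict), |skewStat| ≤ 0.15
  (inclusive) in ≥ 4 of 5 cell types, and no splice or (non-)coding exonic
  consequence — read literally as the coding partition plus SPLICE_SITE,
  CANONICAL_SPLICE and NONCODING_CHANGE. Criteria are evaluated per
  experiment; a variant qualifying for both labels (possible across
  duplicate measurements of shared variants) is removed from both sets and
  counted.

## Synthetic data: what it emulates, and what it does not

The generator produces the structure the method assumes, with a hidden
ground truth emitted as a sidecar so no pipeline stage can read it
accidentally:

* **SFS.** Allele counts follow a truncated power law P(AC = i) ∝ i^−α on
  1..AN/2 (truncation makes the alternate allele always minor, so the
  AF > 0.5 exclusion is never triggered by construction). The default
  α = 1.75 reproduces the hallmark composition of a large sequenced cohort —
  ~51% singletons and a frequent stratum of a few percent; a neutral 1/i law
  would invert those proportions and make balanced frequent-vs-rare pairs
  infeasible. A coalescent simulation would add nothing here: only the rank
  structure of AC matters to the method under test.
* **Selection.** Latent-deleterious sites (fraction 0.3) draw AC with
  exponent α × 1.45 ≈ 2.5, concentrating them at AC = 1. The resulting
  contamination is realistic in kind: most rare variants remain neutral,
  and proxy labels are noisy.
* **Spectra.** Substitution class is drawn conditional on the realized
  frequency class; defaults give C→T = 40.1% (frequent) vs 29.8%
  (singleton), with transitions generally enriched among frequent variants.
  This drives the leakage demonstration: a substitution-class-only
  classifier reaches AUROC ≈ 0.62 on an unmatched frequent-vs-singleton
  pair and ≈ 0.50 after matching.
* **Annotations.** Five signal columns with effects (1.5, 1.2, 1.0, −0.8,
  −1.2) on noise sd 1.0, fifteen pure-noise decoys, one categorical column
  with truth-dependent level frequencies, and one variant-density column
  equal to 1.5 × (frequency-class code) + noise — a pure leakage channel.
  Cells go missing completely at random at rate 0.05.
* **Validation labels.** Balanced draws from latent-deleterious and neutral
  sites; with probability 0.05 a label is replaced by a fair coin (so at
  noise q, ranking by the truth yields AUROC 1 − q/2 + q²/4... = 0.75 at
  q = 0.5, which the tests verify).

What passing tests on this generator shows: the set-construction, matching,
featurization, training, tuning, scaling and evaluation machinery is
correct, deterministic under seeds, and recovers planted effects through
proxy labels (held-out AUROC ≈ 0.93 at 100,000 sites). What it does not
show: performance on real cohorts. The generator has no linkage, no
demography, no mutation-rate maps, no CpG context, independent annotation
noise, and missingness that is not informative — real annotation stacks
violate all of these.

## Problem sizes

The shipped analyses run at desk scale by design: the end-to-end recovery
uses 100,000 sites (training pair ≈ 2,300 records), the leakage
demonstration 900,000 sites (pair ≈ 20,600), parameter recovery 50,000
rows, and the orchestrated example run 40,000 sites. Counts-based planning
(stratum shares, balanced subsample sizes) works directly from published
per-stratum totals without touching variant tables.

## Known limitations

* The feature schema ships a small default cross list; reproducing a full
  production annotation stack (1000+ columns) is configuration the user
  supplies.
* Multi-allelic sites are decomposed into one record per alternate allele —
  a convention, since cohort pipelines differ; the decomposition conserves
  the per-site alternate allele count.
* Unbalanced training relies on class weights equalizing summed weight per
  label; other weighting schemes (e.g. effective-sample-size corrections)
  are not implemented.
* PHRED scaling is relative to whatever reference score set is supplied;
  scores from different references are not comparable.
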