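# Methods

## The problem

Exhaustive SNP-level search for high-order epistasis in a genome-wide
case-control study is combinatorially hopeless: an 8th-order interaction scan
over 500 000 SNPs would have to examine C(500000, 8) ≈ 9.69 × 10⁴⁰ SNP
combinations.  This package implements a gene-based two-stage multifactor
dimensionality reduction (MDR) strategy that first compresses each gene into
a single binary attribute and then searches interactions among those
attributes, so a 2-way gene-level result built from 4 + 4 chosen SNPs still
represents an 8th-order SNP-level interaction.

## Generalized MDR engine

MDR partitions samples by their multi-locus genotype cell, pools cells into
*high-risk* and *low-risk* classes, and evaluates the resulting
one-dimensional classifier.  To adjust for covariates we use the
residual-score form of generalized MDR for binary traits:

* Fit the null logistic model logit P(yᵢ = 1) = β₀ + βᵀxᵢ of phenotype on
  covariates only (intercept-only when there are none) and set
  sᵢ = yᵢ − p̂ᵢ.
* A genotype cell is **high risk** iff Σᵢ∈cell sᵢ > 0 (strict).  With no
  covariates this is algebraically identical to the classic MDR rule
  "cell case/control ratio exceeds the overall case/control ratio"
  (n_case·N_ctrl > n_ctrl·N_case), which the test suite verifies against an
  exact-integer implementation.
* The classifier predicts case for samples in high-risk cells; its quality
  measure is balanced accuracy BA = (sensitivity + specificity)/2.

Cross-validation uses case/control-stratified k folds (default k = 10) from
a seeded shuffle, so BA is defined in every fold; this needs at least k
samples of each class.  Per fold, labels are fit on the training split
(score sums over training samples only; the score itself always comes from
the full-data null model) and evaluated on the held-out fold; test-fold
cells never seen in training default to low risk.

For a set of candidate attributes the exhaustive search enumerates all
combinations of the requested orders.  Each fold's *winner* is the
combination with the highest **training** BA — test data never influences
within-fold model choice.  A combination's cross-validation consistency
(CVC) is the number of folds it wins; the best combination maximizes
(CVC, mean test BA) with a final lexicographic tie-break.

### Numerical choices and tie-breaking

Every tie is resolved deterministically:

* Cell score sums within 10⁻⁹ of zero (including exact case/control balance)
  are treated as ties and labeled **low** — conservative, and robust to the
  ~10⁻¹³ float noise of summed logistic residuals.  True nonzero margins in
  the no-covariate case are ≥ 1/n, orders of magnitude above the tolerance.
* Training-BA ties within a fold: the smaller order wins, then the
  lexicographically smallest attribute tuple (realized by enumerating
  combinations in ascending order/lexicographic sequence with strict `>`
  comparisons).
* Final (CVC, mean test BA) ties: lexicographic order of the sorted
  attribute tuple.
* Unobserved and empty cells predict control (low).

The search is two-pass: fold winners are found streaming with O(k) memory,
then only the ≤ k distinct winners are fully cross-validated — the final
best model is by construction a fold winner, so this is exact, and memory no
longer scales with the number of combinations.

## Two-stage pipeline

**Stage 1 (within-gene).**  SNPs are assigned to the nearest gene whose
interval lies within 100 kb (interval-boundary distance; BED intervals are
0-based half-open, SNP positions 1-based, all distance math in the half-open
convention; exact ties go to the lexicographically smallest symbol, making
assignment independent of gene-file line order).  Unannotated SNPs are
excluded.  Per gene, the search covers orders 1..min(4, #SNPs); the winning
combination is refit on **all** samples and its high/low cell labeling
becomes the binary gene predictor.  Refitting on all samples uses the
complete data and keeps the predictor deterministic; the CV statistics (CVC,
mean test BA) are carried from the search untouched.

**Filtering.**  Predictors with CVC < 5 and/or mean test BA < 0.5 are
excluded (strict comparisons, so boundary values are retained).

**Stage 2 (between-gene).**  All C(G, 2) pairs of retained predictors (each
a 2-level attribute) are cross-validated and ranked by mean test BA
descending; CVC (fold-winner counts among all pairs) is reported alongside.
Stage 2 draws its own fold plan from the master seed, independent of
stage 1, so its results do not depend on gene iteration order; orders > 2
are supported but pairwise is the validated default.

**SNP-level traceback.**  For a ranked pair, one MDR model is fit on the
concatenation of the two genes' chosen SNPs; the pool size is the SNP-level
interaction order (1 + 4 → 5, 4 + 4 → 8), capped at 8.  Because the gene
predictors dichotomize away within-gene detail, the traceback BA usually
exceeds the gene-level BA; the signed difference is reported per interaction
as `traceback_delta` rather than being folded into any statistic.

**Network summary.**  The top-500 ranked pairs (configurable) form an
undirected graph: nodes are genes, edge weight is gene-level mean test BA,
node degree identifies hub genes.  Canonical outputs are edge/node TSVs and
GraphML; plotting is best-effort.

## Quality control

SNPs are removed when (in controls) the 1-df chi-square goodness-of-fit test
of Hardy-Weinberg proportions has p < 5.7 × 10⁻⁷, when MAF < 5 % (over all
samples by default; configurable to cases or controls, since conventions
differ), or when the missing-call proportion exceeds 5 %.  The chi-square
test (not the exact test) is deterministic, fast, and adequate at such an
extreme threshold; monomorphic sites are defined to pass (p = 1, flagged).
Missing genotypes are tolerated only on the raw PLINK read path so the
missingness filter can be computed; analysis entry points require complete
data, and a SNP passing thresholds but retaining missing calls is dropped
with a warning.  A two-control-cohort heterogeneity filter is not
implemented; stratified control designs should be handled upstream.

## Synthetic data generator

The generator emulates the structure of a SNP-array case-control study:

* genotypes are independent draws from binomial(2, MAF) — Hardy-Weinberg
  proportions — with MAFs sampled uniformly from a configurable range
  (presets use [0.1, 0.5] so generated data pass default QC untouched);
* genes are BED intervals holding 1..n SNPs;
* covariates: sex ~ Bernoulli(0.5), age ~ Normal(45, 12²);
* disease risk: logit P(y=1) = logit(π₀) + β_sex·sex + β_age·z(age) +
  Σ_c [logit(T_c(g)) − logit(π₀)], where each penetrance component c has a
  table T_c over the genotype cells of its SNP tuple.  Components compose on
  the logit scale so several components and covariates combine without
  leaving [0, 1]; a single full-coverage component with no covariate effects
  reproduces its table exactly.
* case/control quotas are met by drawing unascertained batches until both
  quotas fill (error after a bounded number of draws when the model's
  prevalence is effectively 0 or 1); everything is reproducible from one
  seed.

The canonical pure-epistasis preset plants a **parity/XOR** component on two
single-SNP genes at MAF 0.5: P(case) = 0.8 when g₁ + g₂ is odd, 0.2
otherwise.  At MAF 0.5 each locus is *exactly* marginally null (conditioning
on either genotype leaves the other's parity at probability ½) while the
joint 9-cell table carries the full signal.  Why can the pipeline still find
it, given that each gene predictor is fit marginally?  Because the scores
sum to zero, the three genotype-cell score sums of a single-SNP gene cannot
all share a sign — the fitted predictor is never constant, and *every*
non-constant split of {0, 1, 2} is at least partially informative about
parity.  The between-gene stage then sees a 2 × 2 table that retains enough
of the XOR pattern to separate the causal pair (pairwise test BA ≈ 0.6–0.8)
from null pairs (≈ 0.5).  The preset's effect size (0.8/0.2, n = 2000) was
calibrated once on pilot simulations and frozen.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: linkage disequilibrium between SNPs (real
within-gene SNPs are correlated, which both helps and confounds combination
selection), population stratification, genotyping error and missingness
patterns, imputation uncertainty, and genes with hundreds of SNPs (where the
4th-order search is the dominant compute cost).  Multi-SNP causal genes
whose signal is purely cross-gene are also genuinely harder than the
single-SNP preset: the zero-sum argument above weakens as the number of
cells grows, and the method can miss such interactions — a structural
property of summarize-then-search approaches, surfaced rather than hidden.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `max_within_order` | 4 | largest within-gene SNP combination |
| `between_order` | 2 | gene-predictor combination size |
| `k` | 10 | CV folds (stratified) |
| `cvc_min` / `ba_min` | 5 / 0.5 | predictor retention thresholds (inclusive) |
| `window` | 100 000 bp | SNP-to-gene assignment distance |
| `traceback_max_order` | 8 | cap on pooled SNP-level model order |
| `top_n_network` | 500 | ranked interactions kept in the network |
| QC | MAF ≥ 0.05, missing ≤ 0.05, HWE p ≥ 5.7e-7 | SNP filters |

## Problem sizes used by the test suite and acceptance script

Chosen as the smallest designs at which each property is statistically
meaningful: exhaustive-search oracle agreement on 10 fixtures of ≤ 8 SNPs ×
≤ 200 samples; classic-MDR reduction on 100 random tables; null calibration
on 25 seeds of the `null` scenario (1000 samples, 20 genes × 5 SNPs); power
on 50 seeds of `pure_epistasis_2gene` (2000 samples, 6 genes); determinism
on the `mixed` scenario (1000 samples, 12 genes).  The whole suite runs in
well under a minute on one core.

## Known limitations

* Gene predictors are fit marginally, so purely cross-gene epistasis among
  multi-SNP genes can be missed (see above); the globally best SNP-level
  model is not guaranteed.
* The within-gene exhaustive search is O(Σ_m C(p, m)·k·n) per gene; genes
  with hundreds of SNPs at order 4 are expensive (no heuristic pruning is
  attempted).
* Binary traits only; PLINK binary/VCF formats, imputation and PCA are out
  of scope (principal components enter as ordinary covariate columns).
* No significance machinery for the final models: reported statistics are
  CVC and balanced accuracy, as is conventional for MDR-family methods.
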