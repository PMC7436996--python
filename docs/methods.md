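# Methods

## Scope and model

`reprospec` implements a tissue-specificity screen for bulk RNA-seq count
matrices. The observation model throughout is the negative binomial with
mean μ and dispersion φ, Var = μ + φμ² — the standard model for biological
replicate variability in RNA-seq. The screen itself is a decision
procedure, not a likelihood fit: differential expression supplies an FDR
per (gene, reproductive tissue, non-reproductive tissue) comparison, and
the candidate decision combines that FDR with two TPM abundance filters.

## Normalization

* **CPM** divides counts by the effective library size (column sum ×
  scaling factor) × 10⁶. Log values use log₂(CPM + 0.5); the 0.5
  pseudocount is a common small-count stabilizer (the choice is exposed).
* **TPM** divides counts by gene length in kb before the within-sample
  rescaling, so columns of any non-empty sample sum to 10⁶.
* **TMM** factors follow Robinson–Oshlack: log-ratios M and average
  abundances A against a reference sample (the one whose upper-quartile
  CPM is closest to the panel mean), doubly trimmed at 30% (M) and 5% (A)
  by rank, averaged with inverse delta-method variance weights, and
  rescaled to geometric mean one. The implementation reproduces
  `edgeR::calcNormFactors(method="TMM")` to 1e-6 on a test fixture.

## Batch correction (RUVr variant)

First-pass residuals are OLS residuals of log₂(CPM + 0.5) on the
tissue-indicator design — identical to per-(gene, group) mean subtraction.
In the large-count regime these are equivalent to NB deviance residuals,
and they are closed-form; the deviance-residual variant was considered and
not implemented because the OLS residuals already recover planted batch
factors at |corr| > 0.99 under the generator's conditions.

W is the matrix of the first k right-singular vectors of the residual
matrix (samples as the factored dimension). Because residual rows lie in
the orthocomplement of the design space, regressing expression on W
recovers only nuisance loadings α, and the corrected expression is
log-expr − αWᵀ. Corrected CPM-scale values are 2^corrected − 0.5 clipped
at zero. `k` defaults to 1 (one study-of-origin axis); it is
config-settable, and k = 0 reproduces the uncorrected pipeline bit for
bit. A side effect of correcting in log space is that genes with zero
counts can acquire small positive corrected CPM ("phantom expression",
bounded by the pseudocount times the correction factor); at the default
conditions this costs well under 1% sensitivity and is the main reason a
planted specific gene can fail the non-reproductive TPM ceiling.

Downstream, the factors are applied by adjusting counts with the fitted
nuisance term before testing ("covariate" mode, the default) — an
approximation chosen so the exact test remains applicable; testing the
corrected CPM directly ("corrected_counts" mode) is also exposed. TPM
summaries are computed from the corrected expression by default
(raw mode available), since the screen's published description computes
average expression from batch-corrected values; the wording there
conflates TPM and CPM, so both interpretations are computable and the
default is a documented choice, not an assertion of intent.

## Differential expression

The test is the classic conditional exact test for two NB groups:

1. Counts are rescaled to the geometric-mean effective library
   ("quantile-free mean-library rescaling"). This slightly distorts the
   NB variance of individual samples when libraries are very uneven; the
   measured consequence is a mild anti-conservativeness (null
   P(p < 0.05) ≈ 0.05–0.06 at 2.7× library-size spread).
2. Conditional on the total T of the two (rounded) group sums, the split
   is exactly beta-binomial(T, n_A/φ, n_B/φ). The pmf is evaluated with
   cumulative log products rather than `betaln` differences, which stays
   accurate for the enormous shape parameters of the small-φ regime; as
   φ → 0 it converges to the conditional binomial (verified to < 1e-6 by
   enumeration on totals ≤ 30).
3. The two-sided p-value sums the probabilities of all splits no more
   likely than the one observed. Outcomes within 1e-6 in log probability
   are treated as tied; the tolerance must exceed the O(φ) perturbation
   of exact binomial ties and only ever makes p (negligibly) larger. The
   enumerated mass is renormalized so the all-inclusive case is exactly 1.

Dispersions: the common φ maximizes the summed NB conditional
log-likelihood on equalized counts over a 161-point log-spaced grid
(≈ 8% spacing, 1e-4…30, with a numerically-zero leading point); tagwise
φ_g maximizes the gene's own conditional likelihood plus `prior_weight`
(default 10) times the genewise-average likelihood — weighted-likelihood
empirical Bayes shrinkage. All-zero genes get the common value and a flag.

Fold changes use per-sample group means with a prior count of 0.125 to
avoid infinities, signed so positive = higher in the reproductive group.
BH adjustment is applied within each pairwise comparison (a global mode
exists behind a flag); per-comparison adjustment matches the screen's
per-comparison FDR semantics.

Exact numerical parity with any existing package is a non-goal; the DE
stage is validated by statistical properties (type-I calibration, the
binomial limit, label-swap antisymmetry, power on planted 50× changes).

## The specificity cascade

"Maximum expression" of the non-reproductive panel is operationalized as
the comparison with **minimal log₂ fold change** (reproductive over
non-reproductive), with lexicographic tie-breaks; with batch effects off,
this agrees with the mean-TPM argmax for ≥ 99% of genes with an
unambiguous maximum, and provenance records both the selected tissue and
all filter outcomes. All three thresholds compare inclusively
(≤ 0.05 FDR, ≤ 1.0 / 2.0 TPM ceiling, ≥ 10.0 / 8.0 TPM floor for
human / mouse). Zero entries in the candidate matrix always carry at
least one recorded failed condition ("not tested" if the gene was absent
from a comparison).

## Classification, orthologs, stratification

Candidates are assigned to disjoint tissue categories from the roles of
the datasets they pass in, with precedence: testis-side ∧ epididymis →
`testis_and_epididymis`; epididymis alone → `epididymis_only`; whole
testis → `testis_only`; Sertoli without testis/germ → `sertoli_only`;
germ cells without whole testis → `germ_cell_only` (stage-exclusive vs
multi-stage sub-label; a gene seen in two germ-cell stages is labelled
`multi_stage` explicitly); anything else → `mixed_other`, so the partition
is total. "Identified in a dataset" means passing the screen with that
dataset's replicates as the reproductive group, and lists from several
datasets of the same tissue combine by union.

Ortholog sources are consolidated by unioning target-symbol sets per
stable gene id (precedence between disagreeing spellings is not guessed).
Multiplicity bins are 0 / 1-same-symbol / 1-different-symbol / 2–3 /
4–10 / >10; human–mouse "same symbol" comparison is case-insensitive
because the species differ by capitalization convention (an exact-match
mode exists). Novelty against prior-study lists matches the candidate's
own symbol or any consolidated ortholog symbol after cross-species
conversion, and is monotone in prior-list growth. Mouse-model status is a
three-level vocabulary (none / model / model with infertility phenotype).
The stratification is a tree — total → has/lacks ortholog → novel/known →
no-model/model → congruent priority set — whose counts sum level to
parent by construction, with epididymis-involved sub-counts carried per
stratum.

## Synthetic data generator

The generator emulates an aggregated multi-tissue panel. Defaults (the
test conditions): 2000 genes; two reproductive targets (testis,
epididymis) and four somatic tissues (brain, liver, kidney, muscle), five
replicates each split 3/2 across two batches so batch is not confounded
with tissue; library sizes log-uniform on [3×10⁵, 8×10⁵]; gene lengths
uniform on [500, 5000] bp; φ log-normal with median 0.05 and log-SD 0.7
(typical bulk RNA-seq tagwise dispersions).

Expression is specified on the TPM scale per tissue. Planted classes:
ubiquitous (55%, log-normal around 20 TPM with 0.25 log₂ tissue jitter),
strictly specific per reproductive tissue (15% combined, target-tissue
TPM log-uniform on [30, 300] — at least three times the 10-TPM floor —
and 0.02 TPM elsewhere), leaky (5%, one somatic tissue planted just above
the 1-TPM ceiling), low-expression reproductive (5%, target TPM on
[2, 9], below the floor) and silent (20%). Ubiquitous abundances are
rescaled so each tissue's TPM column totals 10⁶ exactly, making the
planted values realized TPM expectations rather than relative weights.

The batch model is rank one: batch scores standardized over the sample
panel times gene loadings β_g ~ N(0, batch_log₂_sd²), applied as
2^(β_g z_b). Standardizing the scores makes the effects pure contrasts
(zero per-gene expected offset — so planted TPM bands survive batching)
and makes `batch_log2_sd` (default 0.5) exactly the per-gene log₂ SD of
the batch term. This is precisely the structure RUVr estimates; real
multi-study batch effects are not exactly rank one, so RUV recovery
results on this generator are a best case.

What the generator does **not** emulate: isoform structure, GC/length
biases beyond the fixed per-gene length, correlated genes, count outliers
and sample swaps, and more-than-rank-one batch structure. Passing tests
therefore demonstrate correctness of the decision logic and calibration
under the stated model, not performance on any particular public corpus.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 2000 genes × 30
samples (10 seeds for recovery metrics, 1 seed of 2000 null genes for
calibration), sizes at which every statistic of interest has small enough
Monte-Carlo error to check against its band. Degenerate inputs are
defined rather than left to chance: all-zero comparisons give p = 1 and
log₂FC = 0; singleton groups report SD 0 with a flag; constant matrices
make PCA return zero scores with a degeneracy flag; a zero residual
matrix makes factor estimation raise rather than return noise.

## Known limitations

* The exact test's library equalization is approximate; with extreme
  library-size spread the null calibration drifts anti-conservative.
* Covariate-mode DE adjusts counts by the fitted nuisance term rather
  than putting W in a GLM design; the GLM/quasi-likelihood path is out of
  scope.
* RUVg/RUVs variants (control genes, replicate sets) are not implemented.
* Candidate counts from the original multi-hundred-sample corpora are not
  reproducible at this scale and are not a target of the test suite.
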