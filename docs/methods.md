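# Methods

## Overview

The package implements a single-sample gene-set classifier for tumors driven
by a constitutively active estrogen receptor alpha (mutant or translocated
ERα). The workflow has four stages: (1) derive candidate genes by
differential expression between active-driver and comparator sample groups,
(2) reduce candidates to a signature via pathway overrepresentation,
(3) score individual samples by the mean within-sample percentile rank of
signature genes, and (4) select an operating cutoff on a training ROC curve
and classify. A synthetic-cohort generator provides labeled data with the
effect structure the analysis assumes, so every stage is testable without
external downloads.

## Signature derivation

Two comparisons are run on the estrogen-deprived (−E2) arm of a training
cohort: active vs inactive and active vs control. For each gene,

* the location test is a **two-sided Welch t-test on log2(x + 1)** values.
  The choice of test is a package decision: Welch's unequal-variance t on
  the log scale is the minimal defensible two-sample test for continuous
  abundance data, and the downstream filters (below) are insensitive to the
  specific location test at the planted effect sizes the generator produces.
* the **fold change** is the ratio of linear group means with a stabilizer,
  (mean_a + ε)/(mean_b + ε), ε = 0.01, so near-zero comparator means cannot
  produce unbounded ratios.
* multiple testing is controlled by **Benjamini–Hochberg** across all tested
  genes (delegated to `statsmodels.stats.multitest`).
* a **low-expression prefilter** excludes genes whose linear mean is below
  1 (TPM-like units) in *both* groups before testing; configurable
  (`min_mean=0` disables it).

Candidates must pass **fold change > 4 AND q < 0.05, both strict**, in the
upregulated direction, in *both* comparisons (set intersection). Candidates
are then tested for overrepresentation in a gene-set collection with the
**hypergeometric upper tail** P(X ≥ k) — overrepresentation only, matching
the one-sided question being asked — with BH correction across sets. The
universe is the set of genes tested for DE, keeping the null aligned with
the tested pool. The signature is the intersection of the candidates with
the union of the selected top pathways; by default the estrogen-response
(early + late, treated as a single program) and EMT sets. Per-gene
membership records which program(s) contain the gene (`estrogen_response`,
`emt`, or `both`).

The published 24-gene MOTERA definition (19 estrogen-response, 2 EMT, 3
both) ships as a packaged JSON fixture (`load_motera()`), so scoring with
the canonical signature never requires rerunning the derivation. The early
and late estrogen-response sets are merged into one program label; the
packaged definition records all three source sets.

## Scoring

Within each sample, every gene receives a fractional average-rank
percentile, rank/N ∈ (0, 1], ascending, with ties given the mean of their
rank positions. The signature score is the mean percentile of the signature
genes **ranked against all genes in the supplied matrix** (not just the
signature), which is what makes the score measure relative elevation of the
signature. Consequences of this definition:

* the all-genes signature has the closed-form score (N + 1)/(2N) regardless
  of values;
* a k-gene signature score is bounded in [(k+1)/(2N), (2N−k+1)/(2N)];
* scores are invariant under strictly increasing per-sample transforms,
  so linear TPM and log2(TPM + c) matrices give identical scores for any
  pseudocount c > 0.

Signature genes missing from a matrix are dropped and recorded — never
imputed — mirroring how the signature is applied to datasets in which a
couple of genes were not quantified. Scoring refuses to proceed below 50%
signature coverage.

## Evaluation

* **AUC** is the Mann–Whitney statistic: the probability that a randomly
  chosen positive outscores a randomly chosen negative, ties counted 1/2.
  It is computed in rank form and equals the exhaustive pairwise statistic
  (property-tested).
* **ROC curves** use thresholds at midpoints between consecutive distinct
  scores with ±∞ sentinels; a sample is predicted positive when
  score ≥ threshold. When all scores are identical the lone score is kept
  as the finite threshold so a cutoff can still be returned (with a
  warning).
* The **95% CI of the AUC** uses the DeLong placement-variance estimator
  with a normal approximation, clipped to [0, 1]; it is cross-checked
  against a seeded percentile bootstrap in the tests.
* The **cutoff** maximizes Youden's J = sens + spec − 1; ties break toward
  higher specificity, then the lower threshold. Youden's index is the
  standard single-number "best threshold" criterion for ROC analysis and is
  the package's choice where the upstream analysis protocol names only "ROC
  curve analysis".
* **Confusion metrics** follow the standard definitions: accuracy =
  (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). A
  metric whose denominator is empty (single-class truth) is reported as
  absent (`None`), never as 0.

## Synthetic cohorts

`generate_cohort` draws per-gene baselines 2^Normal(μ, σ) (defaults μ = 4,
σ = 2 on log2 scale — a broad, realistic dynamic range for TPM data),
shared across samples, then applies multiplicative effects:

* samples of class `active` or `mutant_tumor`: program genes × `planted_fc`
  (default 6) in **both** E2 arms — constitutive activity;
* samples of class `control` or `wt_tumor` under +E2: program genes ×
  `e2_fc` (default 6) — normal E2 induction;
* `inactive` samples and −E2 control/WT samples: baseline only;
* every entry gets independent 2^Normal(0, `noise_sd`) noise
  (default `noise_sd` = 0.25 log2 units).

The default design mirrors the training layout: 4 active-fusion, 3
inactive-fusion, 3 control groups, 3 replicates each, both E2 arms
(60 samples), 2000 genes with planted programs of 30 + 30 + 20 genes
(estrogen-response early/late and EMT). `pdx_like_config` produces the
validation layout: 11 mutant and 9 WT tumor lines. Truth labels
(`class ∈ {active, mutant_tumor}`) are stored in the sample table, never
inferred from names. A separate `sample_seed` lets callers draw held-out
samples from the same world (identical planted genes and baselines, new
noise), which is how train/validate splits are constructed.

`generate_gene_sets` builds the three Hallmark-style sets containing the
planted program genes plus 50 random non-program decoy members each
(emulating the breadth of curated pathway sets), optional extra all-decoy
sets, and the full gene pool as universe.

**What the generator does not emulate:** count-level sampling noise and
overdispersion of a sequencer, correlated co-expression structure outside
the planted programs, batch effects, library-size artifacts, tumor purity /
stromal contamination, or fusion-junction reads. A green synthetic test
therefore establishes that the pipeline's statistics and decision rules are
implemented correctly and recover planted structure at the stated effect
size and noise level — not that the signature generalizes to any particular
real dataset. Replicate-variance defaults (`noise_sd` = 0.25) are package
choices of a realistic magnitude for cell-line RNA-seq, not values taken
from data.

## Numerical and policy choices

* **log2 pseudocount: 1.0.** Avoids −∞ at zero TPM and is the dominant
  convention; provably irrelevant to scores (rank invariance) and only
  mildly compressive for the Welch test at TPM-scale values.
* **ER⁺ inclusion filter:** strictly greater than the threshold
  (default 1 FPKM).
* **Strictness of candidate filters:** fold change exactly 4 or q exactly
  0.05 are excluded.
* **Degenerate inputs:** all-equal expression vectors produce the uniform
  percentile (N+1)/(2N) with a warning; zero-variance genes in the Welch
  test get p = 1 when group means agree (no evidence) and p = 0 otherwise;
  degenerate ROC curves (J = 0 everywhere) return the tie-break threshold
  with a warning.
* **Evaluation arm:** classification metrics are computed on the −E2 arm by
  default (`evaluate_e2="minus_E2"`), because E2-responsive wild-type /
  control samples legitimately express the program under +E2 and are not
  false positives of the biology the signature targets; the E2-arm contrast
  itself is exposed (and tested) as the expected behavior that WT scores
  rise with E2 while constitutively active samples are unaffected.
* **Pooled active group:** DE compares the pooled active samples against the
  pooled comparator group (not per-line tests).

## Known limitations

* The DE model is a two-group Welch test on transformed abundances; there is
  no count-based dispersion modeling, batch correction, or covariate
  adjustment.
* Overrepresentation uses the hypergeometric test only; no ranked (GSEA-style)
  enrichment.
* The classifier is binary (active vs not) with a single score cutoff; no
  multi-class or probabilistic calibration.
* The packaged 24-gene signature is a fixed gene list; applying it to a new
  dataset requires that gene identifiers match (HGNC symbols) and that at
  least half the genes are quantified.
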