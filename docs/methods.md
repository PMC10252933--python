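# Methods

## The screening model

The substrate is a cell-line × gene matrix of gene-effect scores from a
genome-wide knockout (CRISPR) or knockdown (RNAi) screen, on the standard
scale where 0 is the non-essential anchor and −1 the median of
common-essential genes. For each lineage the screen contrasts the
lineage's lines against **all** remaining lines in the matrix (one vs
rest, not a matched subset) with a two-sample t-test, and ranks genes by
the signed statistic, most negative first. Selection is by rank on the
signed t, not by p-value: directionality is preserved without a
one-/two-sided choice, and no multiple-testing correction is applied to
the screen itself because the output is a fixed-size top-k list (k = 5 by
default), not a significance call.

The pooled-variance (Student) form is the default because it is the
conventional definition of the portal-style "T-statistic score" this
screen reproduces; Welch with Satterthwaite degrees of freedom is
available via `pooled=False` for heteroscedastic panels. Reported
p-values are always two-sided.

Numerical conventions: missing values are dropped per group per gene;
genes with fewer than `min_group` (default 2 — real panels contain
lineages with as few as four lines) present values in either group are
skipped; ties in t are broken by gene label so output is deterministic;
both groups constant and equal yields t = 0, p = 1 with a warning rather
than NaN. The screen is vectorized across genes; the scalar
`two_sample_t` entry point shares the same formulas and is cross-checked
against `scipy.stats.ttest_ind` in the tests.

### Dependency calls

Dependency-probability matrices are thresholded as *dependent ⇔
probability > 0.5* (strict, so exactly 0.5 is not dependent). Some
published descriptions of this screen family state the inequality in the
opposite direction; that reading contradicts both the score anchors
(more-negative score = more essential = higher dependency probability)
and the usual portal convention, so this package deliberately implements
the internally consistent direction and documents the choice here.

## Synthetic data generator

The generator emulates a DepMap-like release so every stage is testable
without downloads. Defaults define the reference study conditions:
1000 genes × 200 lines, five lineages of 20 lines (the remainder pooled
as `other`), 10% common-essential genes, five implanted lineage-specific
dependencies per lineage, implant and common-essential mean effect −1.0,
Gaussian score noise with sd 0.3.

- **Scores** are Gaussian around the class mean: non-essential 0
  everywhere, common-essential −1 everywhere, implants −1 inside their
  lineage and 0 outside. No published noise model exists for these
  matrices; independent Gaussian noise is the simplest choice that makes
  power calculations transparent. sd 0.3 makes a 20-line implant a ~14
  standard-error effect — clearly detectable but not degenerate.
- **Dependency probabilities** are a deterministic logistic map of the
  score, p = 1/(1 + exp(10·(e + 0.5))): the simplest monotone map that
  crosses 0.5 midway between the two scale anchors and saturates near
  them (0.993 at e = −1, 0.007 at 0).
- **Expression** is log2(TPM+1) of a lognormal TPM baseline (log-mean
  1.0, log-sd 1.0); implanted genes are multiplied by a configurable
  linear fold (`expr_fold_implant`) within their lineage, tying
  dependency to relative overexpression. Setting the fold to 1 restores
  the no-association null, which the tests exercise.
- **RNAi replicate**: per gene, `r·crispr + sqrt(1−r²)·N(0, noise_sd)`
  with r the gene's reliability — 0.9 for the high prediction-accuracy
  group, 0.0 for the low group by default, assigned i.i.d. 50/50. The
  accuracy grouping is treated as an external annotation (as it is in
  real data), not something estimated here.
- **Clinical cohorts** are lognormal with a target fold-change median:
  normal median 10 (arbitrary linear-scale anchor; the FC is
  scale-invariant), log-sd 0.5 — a moderate biological spread that keeps
  the median of a 200-sample arm within a few percent of its target.
  A `zero_normal` flag emulates transcripts below detection in normal
  tissue (FC undefined-infinite).
- **Survival cohorts**: standard-Gaussian expression, exponential event
  times with hazard 0.1·HR^[above median], and per-subject exponential
  censoring with rate chosen so P(censored) equals `censor_rate`
  (default 0.3) exactly under the subject's own hazard.

One global seed drives fixed per-component substreams
(`SeedSequence([seed, key])`), so outputs are bit-reproducible and
regenerating one component never shifts another.

What the generator does **not** emulate: copy-number and screen-quality
artifacts, batch effects, correlated gene modules, heavy-tailed score
noise, real lineage-size imbalance, and covariate-dependent censoring.
Passing tests therefore demonstrate correctness and calibration of the
statistics under clean conditions, not robustness to every pathology of
real screens.

## Downstream analyses

**Expression profile.** Breadth is the fraction of lines with
log2(TPM+1) strictly above a cutoff; the two conventional cutoffs are 1
and 2 on that scale (i.e. TPM > 1 and TPM > 3). Published phrasing that
names "a log2(TPM+2) threshold" is read as the cutoff value 2 on the
same log2(TPM+1) scale — two different transforms per gene would be
incoherent as a cutoff — and both cutoffs are plain parameters in any
case. The relative-expression index is median(lineage)/median(panel),
computed on the stored log scale by default with a `linear_scale` option,
and flagged undefined when the panel median is 0. Ties at a breadth
cutoff count as not expressed.

**Tumor vs normal.** Mann–Whitney U with U = #(tumor > normal) + ½·ties.
`auto` mode enumerates the exact permutation null when n₁+n₂ ≤ 16 and the
pooled sample is tie-free, otherwise uses the tie-corrected normal
approximation with continuity correction (both variants exposed, since
portal implementations differ). The fold-change median is a plain linear
ratio; direction (up/down/flat) comes from the FC, significance (default
α = 0.01) from the test. BH correction across genes is available but off
by default to match per-gene reporting.

**RNAi concordance.** A screen hit receives KD score 1 iff its
one-vs-rest difference on the RNAi matrix is *negative* (t < 0) and
significant at p < 0.0005 — the sign gate plus a two-sided p, with a
one-sided option since portal sidedness conventions vary. Genes absent
from the RNAi panel produce explicit missing records. Under the global
null the sign gate makes the pass probability ≈ α/2 per gene, which the
calibration test verifies.

**Enrichment.** Fisher's exact test (two-sided by minimum-likelihood
summation, the common convention) on the 2×2 table of study/background ×
in/out of category; fold enrichment = observed / (study_size ·
category_frequency); Benjamini–Hochberg across all tested categories
("FDR" reported without a named procedure in this literature is taken as
BH). The background universe defaults to all genes in the annotation
table; categories with fewer than 2 background genes are skipped as
degenerate. Motif-class summaries report, per class, the share of study
genes carrying it and the share of all class-carrying genes the study
covers.

**Survival.** Median split of expression (ties to the low group;
quantile cutoffs available) — deliberately not an optimized cutoff scan,
which inflates type-I error. The log-rank statistic aggregates
O − E over distinct event times with the hypergeometric variance at ties,
and the hazard ratio is the Mantel–Haenszel one-step exp((O−E)/V): fully
specified, hand-checkable against a risk-set table, and cross-checked
against `lifelines` in the tests. Groups with zero events yield flagged
results without an HR. The one-step estimate is mildly attenuated for
large true HRs; at HR = 2 it recovers the target comfortably within the
tested band.

## Problem sizes used in validation

The acceptance tests and `scripts/acceptance.py` use the reference
conditions above: 100 seeds for implanted-target recovery, ≥ 2·10⁶
gene-tests for null calibration, 20 seeds for the concordance split and
fold-change recovery (n = 200 per arm), 2000 cohorts (n = 200) for
survival type-I calibration and 100 cohorts (n = 500) for HR recovery.
These sizes give Monte-Carlo standard errors several times smaller than
the tolerances being checked while keeping the whole suite fast on one
CPU.

## Known limitations

- The screen assumes the gene-effect matrix is already normalized across
  screens/batches; it performs no copy-number or quality correction.
- One-vs-rest contrasts inherit whatever composition the panel has: a
  lineage highly similar to another (e.g. two blood lineages) dilutes its
  own signal through the "rest" group.
- The exact Mann–Whitney path requires tie-free samples; tied small
  samples fall back to the corrected normal approximation.
- The one-step HR is not a fitted proportional-hazards model and carries
  no covariate adjustment.
- Enrichment treats annotations as flat sets (no ontology-graph
  propagation).
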