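"""Synthetic DepMap-like datasets with known ground truth.

Every generator is deterministic given the config seed.  One global seed
drives per-component substreams via ``numpy.random.SeedSequence([seed, key])``
with fixed component keys, so regenerating one output never perturbs another.

Scale conventions mirror the knockout-screen gene-effect scale: a score of
0 is the non-essential anchor and -1 the median of common-essential genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AnnotationTable,
    ClinicalCohort,
    DependencyProbabilityMatrix,
    ExpressionMatrix,
    GeneEffectMatrix,
    LineageAnnotation,
    SurvivalCohort,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_screen_dataset",
    "simulate_rnai_replicate",
    "simulate_clinical_cohort",
    "simulate_survival_cohort",
    "simulate_annotation",
    "LOGISTIC_MIDPOINT",
    "LOGISTIC_STEEPNESS",
]

# score -> probability-of-dependency logistic map: p = 1/(1 + exp(s*(e - m))).
# m = -0.5 puts p = 0.5 halfway between the non-essential (0) and
# common-essential (-1) anchors; s = 10 keeps the anchors near 0 and 1.
LOGISTIC_MIDPOINT = -0.5
LOGISTIC_STEEPNESS = 10.0

# substream keys (arbitrary fixed integers, one per generated component)
_KEY_CLASSES = 11
_KEY_SCORES = 12
_KEY_EXPRESSION = 13
_KEY_ACCURACY = 14
_KEY_RNAI = 15
_KEY_ANNOTATION = 16


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic screen.

    Defaults describe a 1000-gene, 200-line panel with five lineages of 20
    lines each (the remaining lines form an ``other`` pool), five implanted
    lineage-specific dependencies per lineage at full common-essential depth
    (-1.0) and Gaussian score noise of 0.3.
    """

    n_genes: int = 1000
    n_lines: int = 200
    lineages: tuple = (("L1", 20), ("L2", 20), ("L3", 20), ("L4", 20), ("L5", 20))
    frac_common_essential: float = 0.1
    n_implants_per_lineage: int = 5
    effect_common: float = -1.0
    effect_implant: float = -1.0
    noise_sd: float = 0.3
    expr_fold_implant: float = 4.0
    rnai_reliability_high: float = 0.9
    rnai_reliability_low: float = 0.0
    frac_high_accuracy: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if sum(size for _, size in self.lineages) > self.n_lines:
            raise ValueError("lineage sizes exceed n_lines")
        if not 0 <= self.frac_common_essential <= 1:
            raise ValueError("frac_common_essential must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_implants = self.n_implants_per_lineage * len(self.lineages)
        n_common = int(round(self.frac_common_essential * self.n_genes))
        if n_implants + n_common > self.n_genes:
            raise ValueError("more implanted + common-essential genes than genes")
        for r in (self.rnai_reliability_high, self.rnai_reliability_low):
            if not 0 <= r <= 1:
                raise ValueError("rnai reliabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-gene implanted class and RNAi prediction-accuracy group."""

    gene_class: dict[str, str]  # 'nonessential' | 'common_essential' | 'lineage_specific'
    gene_lineage: dict[str, str | None]  # lineage for lineage-specific genes
    accuracy_group: dict[str, str]  # 'high' | 'low'

    def implanted_genes(self, lineage: str | None = None) -> list[str]:
        return [
            g
            for g, cls in self.gene_class.items()
            if cls == "lineage_specific"
            and (lineage is None or self.gene_lineage[g] == lineage)
        ]

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.gene_class)
        return pd.DataFrame(
            {
                "gene": genes,
                "gene_class": [self.gene_class[g] for g in genes],
                "lineage": [self.gene_lineage[g] or "" for g in genes],
                "accuracy_group": [self.accuracy_group[g] for g in genes],
            }
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d} ({i})" for i in range(1, n + 1)]


def _line_ids(n: int) -> list[str]:
    return [f"ACH-{i:06d}" for i in range(1, n + 1)]


def simulate_screen_dataset(config: SyntheticConfig):
    """Generate one synthetic screen: gene effects, dependency probabilities,
    expression, lineage annotation and the ground-truth manifest.

    Scores are Gaussian(class mean, noise_sd): non-essential genes center at
    0 everywhere, common-essential genes at ``effect_common`` everywhere, and
    implanted lineage-specific genes at ``effect_implant`` inside their
    lineage and 0 outside.  Probabilities follow the fixed logistic map of
    the score.  Expression is log2(TPM+1) of a lognormal TPM baseline
    (log-mean 1.0, log-sd 1.0); implanted genes are multiplied by
    ``expr_fold_implant`` (linear scale) within their lineage.
    """
    cfg = config
    genes = _gene_ids(cfg.n_genes)
    lines = _line_ids(cfg.n_lines)

    # lineage assignment: declared lineages first, remainder pooled as 'other'
    mapping: dict[str, str] = {}
    idx = 0
    for label, size in cfg.lineages:
        for _ in range(size):
            mapping[lines[idx]] = label
            idx += 1
    for j in range(idx, cfg.n_lines):
        mapping[lines[j]] = "other"
    ann = LineageAnnotation(mapping)

    # gene class assignment
    rng = _rng(cfg.seed, _KEY_CLASSES)
    n_common = int(round(cfg.frac_common_essential * cfg.n_genes))
    n_implants = cfg.n_implants_per_lineage * len(cfg.lineages)
    perm = rng.permutation(cfg.n_genes)
    common_idx = perm[:n_common]
    implant_idx = perm[n_common : n_common + n_implants]

    gene_class = {g: "nonessential" for g in genes}
    gene_lineage: dict[str, str | None] = {g: None for g in genes}
    for i in common_idx:
        gene_class[genes[i]] = "common_essential"
    for k, i in enumerate(implant_idx):
        label = cfg.lineages[k // cfg.n_implants_per_lineage][0]
        gene_class[genes[i]] = "lineage_specific"
        gene_lineage[genes[i]] = label

    rng_acc = _rng(cfg.seed, _KEY_ACCURACY)
    groups = np.where(
        rng_acc.random(cfg.n_genes) < cfg.frac_high_accuracy, "high", "low"
    )
    accuracy = {g: str(grp) for g, grp in zip(genes, groups)}
    truth = GroundTruth(gene_class, gene_lineage, accuracy)

    # mean matrix
    mean = np.zeros((cfg.n_lines, cfg.n_genes))
    mean[:, common_idx] = cfg.effect_common
    line_lineage = np.array([mapping[l] for l in lines])
    for k, i in enumerate(implant_idx):
        label = cfg.lineages[k // cfg.n_implants_per_lineage][0]
        mean[line_lineage == label, i] = cfg.effect_implant

    rng_scores = _rng(cfg.seed, _KEY_SCORES)
    scores = mean + rng_scores.normal(0.0, cfg.noise_sd, size=mean.shape)
    effects = GeneEffectMatrix(
        pd.DataFrame(scores, index=lines, columns=genes), platform="crispr"
    )

    prob = 1.0 / (1.0 + np.exp(LOGISTIC_STEEPNESS * (scores - LOGISTIC_MIDPOINT)))
    probs = DependencyProbabilityMatrix(pd.DataFrame(prob, index=lines, columns=genes))

    rng_expr = _rng(cfg.seed, _KEY_EXPRESSION)
    tpm = rng_expr.lognormal(mean=1.0, sigma=1.0, size=mean.shape)
    for k, i in enumerate(implant_idx):
        label = cfg.lineages[k // cfg.n_implants_per_lineage][0]
        tpm[line_lineage == label, i] *= cfg.expr_fold_implant
    expr = ExpressionMatrix(
        pd.DataFrame(np.log2(tpm + 1.0), index=lines, columns=genes)
    )

    return effects, probs, expr, ann, truth


def simulate_rnai_replicate(
    crispr: GeneEffectMatrix, truth: GroundTruth, config: SyntheticConfig
) -> GeneEffectMatrix:
    """Noisy knockdown replicate of a knockout screen.

    Per gene, ``rnai = r * crispr + sqrt(1 - r^2) * N(0, noise_sd)`` where r
    is the gene's reliability: ``rnai_reliability_high`` for the high
    prediction-accuracy group, ``rnai_reliability_low`` for the low group.
    """
    genes = crispr.gene_ids
    missing = [g for g in genes if g not in truth.accuracy_group]
    if missing:
        raise ValueError(f"ground truth lacks accuracy groups for {missing[:5]}")
    r = np.array(
        [
            config.rnai_reliability_high
            if truth.accuracy_group[g] == "high"
            else config.rnai_reliability_low
            for g in genes
        ]
    )
    rng = _rng(config.seed, _KEY_RNAI)
    X = crispr.data.to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=X.shape)
    vals = r[None, :] * X + np.sqrt(1.0 - r[None, :] ** 2) * noise
    return GeneEffectMatrix(
        pd.DataFrame(vals, index=crispr.line_ids, columns=genes), platform="rnai"
    )


def simulate_clinical_cohort(
    gene: str,
    fc_median_target: float,
    n_tumor: int = 200,
    n_normal: int = 200,
    log_sd: float = 0.5,
    seed: int = 0,
    base_median: float = 10.0,
    zero_normal: bool = False,
) -> ClinicalCohort:
    """Lognormal tumor/normal expression cohorts with a target fold-change
    median.

    Normal samples are lognormal with median ``base_median`` and log-scale
    sd ``log_sd``; tumor samples share the sd with the median multiplied by
    ``fc_median_target``.  ``zero_normal=True`` emulates a transcript below
    detection in normal tissue (all normal values 0, fold change undefined).
    """
    if n_tumor <= 0 or n_normal <= 0:
        raise ValueError("cohort sizes must be positive")
    if not zero_normal and fc_median_target <= 0:
        raise ValueError("fc_median_target must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    mu = math.log(base_median)
    normal = (
        np.zeros(n_normal)
        if zero_normal
        else rng.lognormal(mean=mu, sigma=log_sd, size=n_normal)
    )
    tumor_mu = mu + (math.log(fc_median_target) if not zero_normal else 0.0)
    tumor = rng.lognormal(mean=tumor_mu, sigma=log_sd, size=n_tumor)
    return ClinicalCohort(gene=gene, tumor_values=tumor, normal_values=normal)


def simulate_survival_cohort(
    hr_target: float,
    n: int = 200,
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.1,
    gene: str = "",
) -> SurvivalCohort:
    """Exponential survival with a target hazard ratio between expression
    halves.

    Expression is standard Gaussian; event hazard is ``baseline_hazard``
    below the median split and ``baseline_hazard * hr_target`` above it.
    Censoring is independent exponential with the per-subject rate tuned so
    each subject is censored with probability ``censor_rate``.
    """
    if hr_target <= 0:
        raise ValueError("hr_target must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if n < 10:
        raise ValueError("need at least 10 patients for a median split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    expr = rng.normal(0.0, 1.0, size=n)
    high = expr > np.median(expr)
    hazard = baseline_hazard * np.where(high, hr_target, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate == 0:
        return SurvivalCohort(time=t_event, event=np.ones(n, int), expression=expr, gene=gene)
    c_hazard = hazard * censor_rate / (1.0 - censor_rate)
    t_censor = rng.exponential(1.0 / c_hazard)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return SurvivalCohort(time=time, event=event, expression=expr, gene=gene)


def simulate_annotation(
    truth: GroundTruth,
    enriched_category: str = "dna_binding",
    frac_background_in_category: float = 0.1,
    frac_implanted_in_category: float = 0.6,
    n_null_categories: int = 5,
    seed: int = 0,
) -> AnnotationTable:
    """Synthetic gene-category annotation with one category enriched among
    implanted genes (synthetic stand-in for GO/motif-class resources).

    The background universe is every simulated gene.  ``enriched_category``
    covers ``frac_background_in_category`` of non-implanted genes but
    ``frac_implanted_in_category`` of implanted genes; null categories cover
    uniform random tenths of the background.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _KEY_ANNOTATION]))
    genes = list(truth.gene_class)
    implanted = set(truth.implanted_genes())
    categories: dict[str, set[str]] = {}

    def add(gene, cat):
        categories.setdefault(gene, set()).add(cat)

    for g in genes:
        p = frac_implanted_in_category if g in implanted else frac_background_in_category
        if rng.random() < p:
            add(g, enriched_category)
        for k in range(n_null_categories):
            if rng.random() < 0.1:
                add(g, f"null_category_{k + 1}")
    return AnnotationTable(categories, set(genes))
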