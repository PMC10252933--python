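"""Category overrepresentation by Fisher's exact test with fold enrichment
and Benjamini-Hochberg FDR, plus DNA-binding motif-class representation
summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable

__all__ = [
    "EnrichmentRecord",
    "MotifClassSummary",
    "fisher_exact_2x2",
    "bh_fdr",
    "category_enrichment",
    "motif_class_representation",
]


@dataclass
class EnrichmentRecord:
    """One category's overrepresentation test."""

    category: str
    n_study: int
    n_study_total: int
    n_bg: int
    n_bg_total: int
    expected: float
    fold_enrichment: float
    p_raw: float
    fdr: float


@dataclass
class MotifClassSummary:
    """Representation of one DNA-binding motif class among study genes."""

    motif_class: str
    n_in_class: int
    pct_of_study: float  # study genes in class / study genes, as %
    pct_of_class_genome_wide: float  # study genes in class / all genes in class, as %


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness by minimum-likelihood summation: all tables with the
    margins fixed whose hypergeometric probability does not exceed the
    observed table's (within a small relative tie tolerance) contribute.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_enrichment(
    study,
    annotation: AnnotationTable,
    min_background: int = 2,
) -> list[EnrichmentRecord]:
    """Fisher-exact overrepresentation of annotation categories in a study
    gene set against the annotation's background universe.

    Study genes outside the background are reported via a warning and
    dropped.  Categories with fewer than ``min_background`` background
    genes are skipped (degenerate tables).  ``fold_enrichment`` is the
    observed study count over the count expected from the background
    frequency; FDR is Benjamini-Hochberg across all tested categories.
    """
    study = set(study)
    stray = study - annotation.background
    if stray:
        warnings.warn(
            f"{len(stray)} study genes outside the background universe dropped: "
            f"{sorted(stray)[:5]}"
        )
        study -= stray
    if not study:
        raise ValueError("empty study set after background filtering")
    n_study_total = len(study)
    n_bg_total = len(annotation.background)
    records = []
    for cat in sorted(annotation.all_categories):
        members = annotation.genes_in_category(cat)
        n_bg = len(members)
        if n_bg < min_background:
            continue
        n_hit = len(study & members)
        expected = n_study_total * n_bg / n_bg_total
        # margins: study vs rest, in-category vs out
        p = fisher_exact_2x2(
            n_hit,
            n_study_total - n_hit,
            n_bg - n_hit,
            (n_bg_total - n_study_total) - (n_bg - n_hit),
        )
        records.append(
            EnrichmentRecord(
                category=cat,
                n_study=n_hit,
                n_study_total=n_study_total,
                n_bg=n_bg,
                n_bg_total=n_bg_total,
                expected=expected,
                fold_enrichment=n_hit / expected if expected > 0 else float("nan"),
                p_raw=p,
                fdr=float("nan"),
            )
        )
    if records:
        adj = bh_fdr([r.p_raw for r in records])
        for rec, q in zip(records, adj):
            rec.fdr = float(q)
    return records


def motif_class_representation(
    study, motif_annotation: AnnotationTable
) -> list[MotifClassSummary]:
    """Per motif class: how many study genes carry it, what share of the
    study set that is, and what share of all genome genes carrying the
    class the study genes represent."""
    study = set(study)
    n_study = len(study)
    out = []
    for cls in sorted(motif_annotation.all_categories):
        members = motif_annotation.genes_in_category(cls)
        hit = len(study & members)
        out.append(
            MotifClassSummary(
                motif_class=cls,
                n_in_class=hit,
                pct_of_study=100.0 * hit / n_study if n_study else 0.0,
                pct_of_class_genome_wide=100.0 * hit / len(members) if members else 0.0,
            )
        )
    return out


def classes_hit(summaries) -> int:
    """Number of distinct motif classes with at least one study gene."""
    return sum(1 for s in summaries if s.n_in_class > 0)
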