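"""Cross-platform validation of screen hits on a knockdown (RNAi) panel.

A gene called for a lineage on the knockout screen gets a binary "KD score"
on the RNAi matrix: 1 iff the one-vs-rest gene-effect difference is negative
and significant at p < 0.0005 (the portal's confidence threshold), else 0.
Scores are summarized by the gene's external prediction-accuracy group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneEffectMatrix, LineageAnnotation
from .screen import two_sample_t

__all__ = [
    "ConcordanceRecord",
    "ConcordanceSummary",
    "rnai_kd_score",
    "concordance_summary",
]


@dataclass
class ConcordanceRecord:
    """Per (gene, lineage) RNAi validation result."""

    gene: str
    lineage: str
    rnai_t: float
    rnai_p: float
    kd_score: int
    accuracy_group: str  # 'high' | 'low' | 'unknown'
    missing: bool  # gene absent from the RNAi panel


@dataclass
class ConcordanceSummary:
    """Per accuracy group: genes scored, genes passing, passing fraction."""

    group: str
    n_genes: int
    n_passing: int
    fraction: float


def rnai_kd_score(
    rnai: GeneEffectMatrix,
    ann: LineageAnnotation,
    gene: str,
    lineage: str,
    alpha: float = 0.0005,
    accuracy_group: str = "unknown",
    one_sided: bool = False,
) -> ConcordanceRecord:
    """Binary knockdown-validation score for one (gene, lineage).

    Reuses the screen's two-sample t on the RNAi matrix.  The score is 1
    iff the difference is negative (t < 0) and the two-sided p is below
    ``alpha``; ``one_sided=True`` halves the p before the comparison.
    Genes absent from the RNAi panel (the knockout and knockdown panels
    differ) yield an explicit missing record, never a silent drop.
    """
    if gene not in rnai.data.columns:
        return ConcordanceRecord(
            gene=gene,
            lineage=lineage,
            rnai_t=float("nan"),
            rnai_p=float("nan"),
            kd_score=0,
            accuracy_group=accuracy_group,
            missing=True,
        )
    col = rnai.column(gene)
    in_lines = [l for l in ann.lines_in(lineage) if l in rnai.data.index]
    in_vals = col.loc[in_lines].to_numpy()
    out_vals = col.drop(index=in_lines).to_numpy()
    t, p = two_sample_t(in_vals, out_vals, pooled=True)
    p_eff = p / 2.0 if one_sided and t < 0 else p
    score = int(t < 0 and p_eff < alpha)
    return ConcordanceRecord(
        gene=gene,
        lineage=lineage,
        rnai_t=t,
        rnai_p=p,
        kd_score=score,
        accuracy_group=accuracy_group,
        missing=False,
    )


def concordance_summary(records) -> list[ConcordanceSummary]:
    """Counts and passing fractions per prediction-accuracy group.

    Missing records are excluded from denominators.  Deterministic and
    independent of record order (groups reported sorted).
    """
    tallies: dict[str, list[int]] = {}
    for rec in records:
        if rec.missing:
            continue
        n, k = tallies.setdefault(rec.accuracy_group, [0, 0])
        tallies[rec.accuracy_group] = [n + 1, k + rec.kd_score]
    return [
        ConcordanceSummary(
            group=grp,
            n_genes=n,
            n_passing=k,
            fraction=(k / n if n else 0.0),
        )
        for grp, (n, k) in sorted(tallies.items())
    ]
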