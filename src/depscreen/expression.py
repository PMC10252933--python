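"""Expression breadth across a cell-line panel and the relative-expression
index (median in the focal lineage over median in all lines)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, LineageAnnotation

__all__ = ["ExpressionSummary", "expression_breadth", "relative_expression_index", "summarize_expression"]


@dataclass
class ExpressionSummary:
    """Breadth at the two standard log2(TPM+1) cutoffs plus the relative
    expression index for a focal lineage."""

    gene: str
    breadth_t1: float
    breadth_t2: float
    rel_index: float  # NaN when the overall median is 0
    rel_index_defined: bool
    focal_lineage: str


def expression_breadth(expr: ExpressionMatrix, gene: str, threshold: float) -> float:
    """Fraction of lines (with present values) whose expression strictly
    exceeds ``threshold`` on the stored log2(TPM+1) scale.

    Values exactly at the cutoff count as not expressed.
    """
    vals = expr.column(gene).to_numpy()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"gene {gene!r} has no present expression values")
    return float(np.mean(vals > threshold))


def relative_expression_index(
    expr: ExpressionMatrix,
    ann: LineageAnnotation,
    gene: str,
    lineage: str,
    linear_scale: bool = False,
) -> tuple[float, bool]:
    """Median expression in the focal lineage divided by the median over all
    lines.

    Computed on the matrix's stored log2(TPM+1) scale by default;
    ``linear_scale=True`` converts back to TPM before taking medians.
    Returns ``(index, defined)``; the index is NaN and ``defined`` False
    when the overall median is 0.
    """
    lineage_lines = [l for l in ann.lines_in(lineage) if l in expr.data.index]
    if not lineage_lines:
        raise ValueError(f"lineage {lineage!r} has no lines in the matrix")
    col = expr.column(gene)
    all_vals = col.to_numpy()
    in_vals = col.loc[lineage_lines].to_numpy()
    all_vals = all_vals[~np.isnan(all_vals)]
    in_vals = in_vals[~np.isnan(in_vals)]
    if in_vals.size == 0 or all_vals.size == 0:
        raise ValueError(f"gene {gene!r} has no present values for the index")
    if linear_scale:
        in_vals = 2.0**in_vals - 1.0
        all_vals = 2.0**all_vals - 1.0
    denom = float(np.median(all_vals))
    if denom == 0:
        return float("nan"), False
    return float(np.median(in_vals)) / denom, True


def summarize_expression(
    expr: ExpressionMatrix,
    ann: LineageAnnotation,
    gene: str,
    lineage: str,
    thresholds: tuple[float, float] = (1.0, 2.0),
    linear_scale: bool = False,
) -> ExpressionSummary:
    """Breadth at both cutoffs plus the relative-expression index."""
    b1 = expression_breadth(expr, gene, thresholds[0])
    b2 = expression_breadth(expr, gene, thresholds[1])
    idx, defined = relative_expression_index(expr, ann, gene, lineage, linear_scale)
    return ExpressionSummary(
        gene=gene,
        breadth_t1=b1,
        breadth_t2=b2,
        rel_index=idx,
        rel_index_defined=defined,
        focal_lineage=lineage,
    )
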