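"""One-vs-rest differential dependency screening.

For each lineage, every gene's effect scores in that lineage's cell lines
are contrasted against the scores in all remaining lines with a two-sample
t-test.  The genes with the most negative t-statistics are the lineage's
top dependency targets; by default the top five are reported.

The screen is vectorized across genes (missing values dropped per group)
so genome-scale matrices and Monte-Carlo calibration runs are cheap; the
per-pair :func:`two_sample_t` entry point shares the same formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DependencyProbabilityMatrix, GeneEffectMatrix, LineageAnnotation

__all__ = [
    "ScreenRecord",
    "TargetSet",
    "two_sample_t",
    "screen_lineage",
    "screen_all",
    "call_dependency",
]


@dataclass
class ScreenRecord:
    """Per (gene, lineage) one-vs-rest test result."""

    gene: str
    lineage: str
    t_statistic: float
    p_value: float
    mean_in: float
    mean_out: float
    n_in: int
    n_out: int
    rank: int


@dataclass
class TargetSet:
    """Ordered top-k screen records per lineage (ascending t-statistic)."""

    per_lineage: dict[str, list[ScreenRecord]]

    def lineages(self) -> list[str]:
        return sorted(self.per_lineage)

    def genes(self, lineage: str) -> list[str]:
        return [r.gene for r in self.per_lineage[lineage]]

    def all_records(self) -> list[ScreenRecord]:
        out: list[ScreenRecord] = []
        for lin in self.lineages():
            out.extend(self.per_lineage[lin])
        return out


def _t_arrays(in_vals: np.ndarray, out_vals: np.ndarray, pooled: bool):
    """Vectorized two-sample t over gene columns with NaN handling.

    ``in_vals``/``out_vals`` are (lines x genes) arrays; returns per-gene
    (t, p, mean_in, mean_out, n_in, n_out, valid).  Genes where both groups
    are constant and equal get t = 0, p = 1 by convention.
    """
    n1 = np.sum(~np.isnan(in_vals), axis=0).astype(float)
    n2 = np.sum(~np.isnan(out_vals), axis=0).astype(float)
    valid = (n1 >= 2) & (n2 >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(in_vals, axis=0)
        m2 = np.nanmean(out_vals, axis=0)
        v1 = np.nanvar(in_vals, axis=0, ddof=1)
        v2 = np.nanvar(out_vals, axis=0, ddof=1)
        if pooled:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            se2_1 = v1 / n1
            se2_2 = v2 / n2
            se = np.sqrt(se2_1 + se2_2)
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        diff = m1 - m2
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate: zero variance in both groups
    degen = valid & (se == 0)
    equal = degen & (diff == 0)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    unequal = degen & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(unequal, np.sign(diff) * np.inf, t)
    p = np.where(unequal, 0.0, p)
    return t, p, m1, m2, n1.astype(int), n2.astype(int), valid


def two_sample_t(group_a, group_b, pooled: bool = True) -> tuple[float, float]:
    """Two-sample t-test of group_a vs group_b (two-sided).

    ``pooled=True`` (default) is Student's equal-variance statistic with
    n_a + n_b - 2 degrees of freedom — the definition behind the screen's
    T-statistic score; ``pooled=False`` is Welch with Satterthwaite df.

    Returns ``(t, p)``.  Both groups constant and equal returns ``(0, 1)``
    with a warning; groups of fewer than two values raise ``ValueError``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two present values")
    t, p, m1, m2, _, _, _ = _t_arrays(a[:, None], b[:, None], pooled)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and m1[0] == m2[0]:
        warnings.warn("both groups constant and equal; t = 0, p = 1 by convention")
    return float(t[0]), float(p[0])


def _screen_arrays(
    values: np.ndarray,
    in_mask: np.ndarray,
    pooled: bool = True,
):
    """Split a (lines x genes) array by a boolean line mask and run the
    vectorized one-vs-rest t-test."""
    in_vals = np.where(in_mask[:, None], values, np.nan)
    out_vals = np.where(~in_mask[:, None], values, np.nan)
    return _t_arrays(in_vals, out_vals, pooled)


def screen_lineage(
    effects: GeneEffectMatrix,
    ann: LineageAnnotation,
    lineage: str,
    k: int | None = 5,
    min_group: int = 2,
    pooled: bool = True,
) -> list[ScreenRecord]:
    """Rank all genes for one lineage by ascending one-vs-rest t-statistic.

    Genes with fewer than ``min_group`` present values in either group are
    skipped.  Ties in t are broken by gene label; ranks are 1-based over all
    screened genes.  Returns the first ``k`` records (all when ``k=None``).
    """
    if lineage not in ann:
        raise ValueError(f"lineage {lineage!r} not present in annotation")
    lines = effects.line_ids
    in_mask = np.array([ann.mapping.get(l) == lineage for l in lines])
    if in_mask.sum() < min_group or (~in_mask).sum() < min_group:
        raise ValueError(
            f"lineage {lineage!r} needs >= {min_group} lines inside and outside"
        )
    values = effects.data.to_numpy()
    t, p, m1, m2, n1, n2, valid = _screen_arrays(values, in_mask, pooled)
    valid &= (n1 >= min_group) & (n2 >= min_group) & np.isfinite(t)
    genes = np.array(effects.gene_ids, dtype=object)
    if not valid.any():
        warnings.warn(f"all genes skipped for lineage {lineage!r}")
        return []
    idx = np.flatnonzero(valid)
    order = sorted(idx, key=lambda i: (t[i], genes[i]))
    records = [
        ScreenRecord(
            gene=str(genes[i]),
            lineage=lineage,
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            mean_in=float(m1[i]),
            mean_out=float(m2[i]),
            n_in=int(n1[i]),
            n_out=int(n2[i]),
            rank=r + 1,
        )
        for r, i in enumerate(order)
    ]
    return records if k is None else records[:k]


def screen_all(
    effects: GeneEffectMatrix,
    ann: LineageAnnotation,
    k: int | None = 5,
    min_group: int = 2,
    pooled: bool = True,
    lineages: list[str] | None = None,
) -> TargetSet:
    """Independent one-vs-rest screen of every lineage (or a given subset).

    Lineages failing the group-size preconditions are reported via a
    warning and omitted from the result.
    """
    per_lineage: dict[str, list[ScreenRecord]] = {}
    for lineage in lineages if lineages is not None else ann.lineages:
        try:
            per_lineage[lineage] = screen_lineage(
                effects, ann, lineage, k=k, min_group=min_group, pooled=pooled
            )
        except ValueError as exc:
            warnings.warn(f"skipping lineage {lineage!r}: {exc}")
    return TargetSet(per_lineage)


def call_dependency(
    prob: DependencyProbabilityMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """Binary dependency calls from a probability matrix.

    A line is called dependent on a gene iff its probability of dependency
    strictly exceeds ``threshold`` (higher probability = more dependent;
    exactly at the threshold is not dependent).  Missing stays missing.
    Returns a lines-by-genes DataFrame of {0.0, 1.0, NaN}.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    vals = prob.data.to_numpy()
    calls = np.where(np.isnan(vals), np.nan, (vals > threshold).astype(float))
    return pd.DataFrame(calls, index=prob.line_ids, columns=prob.gene_ids)
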