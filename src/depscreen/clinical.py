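"""Tumor-vs-normal differential expression: Mann-Whitney U test and the
fold-change median (median tumor expression over median normal expression,
linear scale)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ClinicalCohort

__all__ = ["DERecord", "mann_whitney_u", "fold_change_median", "de_screen"]

# sample-size bound below which the exact permutation null is enumerated
_EXACT_LIMIT = 16


@dataclass
class DERecord:
    """Per-gene tumor-vs-normal comparison."""

    gene: str
    u_statistic: float
    p_value: float
    fc_median: float  # inf when normal median is 0 and tumor median > 0
    fc_defined: bool
    direction: str  # 'up' | 'down' | 'flat'
    significant: bool


def mann_whitney_u(
    a, b, mode: str = "auto", continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of a vs b.

    U counts pairs with a_i > b_j plus half the ties.  ``mode='exact'``
    enumerates the permutation null (no tie correction, so it is reserved
    for tie-free samples); ``'normal_approx'`` uses the tie-corrected
    normal approximation, with a continuity correction by default;
    ``'auto'`` picks exact when n1 + n2 <= 16 and the pooled sample is
    tie-free.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (a.size + b.size <= _EXACT_LIMIT and not has_ties) else "normal_approx"
    if mode == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal_approx":
        res = stats.mannwhitneyu(
            a,
            b,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=continuity,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fold_change_median(
    cohort: ClinicalCohort, alpha: float = 0.01, mode: str = "auto"
) -> DERecord:
    """Fold-change median with Mann-Whitney significance for one gene.

    ``fc_median = median(tumor) / median(normal)`` on the linear scale.
    When the normal median is 0 and the tumor median positive (transcript
    below detection in normal tissue) the ratio is reported as +inf with
    ``fc_defined=False``; both medians 0 gives NaN.
    """
    u, p = mann_whitney_u(cohort.tumor_values, cohort.normal_values, mode=mode)
    med_t = float(np.median(cohort.tumor_values))
    med_n = float(np.median(cohort.normal_values))
    if med_n == 0:
        fc = math.inf if med_t > 0 else math.nan
        defined = False
    else:
        fc = med_t / med_n
        defined = True
    if not defined:
        direction = "up" if fc == math.inf else "flat"
    elif fc > 1:
        direction = "up"
    elif fc < 1:
        direction = "down"
    else:
        direction = "flat"
    return DERecord(
        gene=cohort.gene,
        u_statistic=u,
        p_value=p,
        fc_median=fc,
        fc_defined=defined,
        direction=direction,
        significant=bool(p < alpha),
    )


def de_screen(cohorts, alpha: float = 0.01, mode: str = "auto") -> list[DERecord]:
    """Fold-change-median records for a sequence of per-gene cohorts."""
    return [fold_change_median(c, alpha=alpha, mode=mode) for c in cohorts]
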