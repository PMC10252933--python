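"""Expression-dichotomized survival comparison.

Patients are split at an expression cutoff (median by default; ties go to
the low group).  The two groups are compared with the standard log-rank
aggregation of observed-minus-expected events over the pooled event times,
with the discrete hypergeometric variance at tied times.  The hazard ratio
of high vs low expression is the Mantel-Haenszel one-step estimate
``exp((O_high - E_high) / V)`` — fully specified and checkable by hand,
unlike a fitted proportional-hazards model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SurvivalCohort

__all__ = ["KMResult", "km_logrank_hr", "survival_screen", "km_curve"]


@dataclass
class KMResult:
    """Log-rank comparison of high- vs low-expression halves for one gene."""

    gene: str
    cutoff: float
    n_high: int
    n_low: int
    o_high: float  # observed events, high group
    e_high: float  # expected events under the null, high group
    variance: float
    logrank_chi2: float
    p_value: float
    hazard_ratio: float  # NaN when a group has zero events
    hr_defined: bool
    direction: str  # 'adverse' (HR > 1) | 'protective' (HR < 1) | 'flat'
    significant: bool


def _logrank_oev(time, event, high):
    """Observed/expected events in the high group and the log-rank variance,
    aggregated over distinct event times (discrete tie handling)."""
    order = np.argsort(time, kind="stable")
    time = time[order]
    event = event[order]
    high = high[order]
    event_times = np.unique(time[event == 1])
    o = e = v = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & high).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o, e, v


def km_logrank_hr(
    cohort: SurvivalCohort,
    cutoff_rule: str | float = "median",
    alpha: float = 0.01,
) -> KMResult:
    """Log-rank test and one-step hazard ratio for an expression split.

    ``cutoff_rule`` is ``'median'``, a quantile spec ``'q0.25'`` or a raw
    cutoff value.  High group: expression strictly above the cutoff.  A
    group with zero events yields a flagged result without a hazard ratio.
    """
    expr = cohort.expression
    if isinstance(cutoff_rule, str):
        if cutoff_rule == "median":
            cutoff = float(np.median(expr))
        elif cutoff_rule.startswith("q"):
            cutoff = float(np.quantile(expr, float(cutoff_rule[1:])))
        else:
            raise ValueError(f"unknown cutoff rule {cutoff_rule!r}")
    else:
        cutoff = float(cutoff_rule)
    high = expr > cutoff
    n_high = int(high.sum())
    n_low = int((~high).sum())
    if n_high < 5 or n_low < 5:
        raise ValueError("each expression group needs at least 5 patients")
    ev_high = int(cohort.event[high].sum())
    ev_low = int(cohort.event[~high].sum())
    o, e, v = _logrank_oev(cohort.time, cohort.event, high)
    if ev_high == 0 or ev_low == 0 or v == 0:
        return KMResult(
            gene=cohort.gene,
            cutoff=cutoff,
            n_high=n_high,
            n_low=n_low,
            o_high=o,
            e_high=e,
            variance=v,
            logrank_chi2=float("nan"),
            p_value=float("nan"),
            hazard_ratio=float("nan"),
            hr_defined=False,
            direction="flat",
            significant=False,
        )
    chi2 = (o - e) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    hr = float(np.exp((o - e) / v))
    direction = "adverse" if hr > 1 else ("protective" if hr < 1 else "flat")
    return KMResult(
        gene=cohort.gene,
        cutoff=cutoff,
        n_high=n_high,
        n_low=n_low,
        o_high=o,
        e_high=e,
        variance=v,
        logrank_chi2=float(chi2),
        p_value=p,
        hazard_ratio=hr,
        hr_defined=True,
        direction=direction,
        significant=bool(p < alpha),
    )


def survival_screen(
    cohorts, cutoff_rule: str | float = "median", alpha: float = 0.01
) -> list[KMResult]:
    """One KMResult per gene cohort; empty input gives an empty list."""
    return [km_logrank_hr(c, cutoff_rule=cutoff_rule, alpha=alpha) for c in cohorts]


def km_curve(time, event):
    """Kaplan-Meier step function: (event times, survival probabilities).

    Product-limit estimate over distinct event times; censored-only times
    contribute to risk sets but add no step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ts = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in ts:
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / n
        surv.append(s)
    return ts, np.array(surv)
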