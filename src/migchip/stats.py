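"""Statistical conventions for migration-assay comparisons.

Migration distances are heavily non-normal (many channels stay at zero, a
tail reaches the channel exit), so group comparisons use the two-sided
Mann-Whitney U test.  Box summaries follow the plotting convention of the
assay figures: box at the quartiles, whiskers at the 5th/95th percentiles,
mean marked separately.  Significance stars: * p<0.05, ** p<0.01,
*** p<0.001 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "BoxSummary",
    "ComparisonResult",
    "mann_whitney",
    "box_summary",
    "star_label",
    "sphere_rate_ttest",
]

#: largest combined sample size for which the exact null distribution of U
#: is enumerated (C(12,6) = 924 arrangements at worst); larger or tied
#: samples use the tie-corrected normal approximation with continuity
#: correction.
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    mean: float
    min: float
    max: float


@dataclass(frozen=True)
class ComparisonResult:
    U: float
    p_value: float
    method: Literal["exact", "normal_approx"]
    stars: str


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Literal["two-sided"] = "two-sided",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    U is computed from joint midranks (tie-corrected).  The exact null
    distribution is enumerated for small tie-free samples
    (n1 + n2 <= ``EXACT_ENUMERATION_MAX_N``); otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (a.size + b.size <= EXACT_ENUMERATION_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        U=float(res.statistic),
        p_value=p,
        method="exact" if exact else "normal_approx",
        stars=star_label(p),
    )


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number-plus box summary with 5th/95th-percentile whiskers.

    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("sample must be non-empty")
    p5, q1, med, q3, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        p5=float(p5),
        p95=float(p95),
        mean=float(v.mean()),
        min=float(v.min()),
        max=float(v.max()),
    )


def star_label(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sphere_rate_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test (pooled variance).

    Utility for sphere-formation-rate comparisons across replicate devices;
    returns (t, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
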