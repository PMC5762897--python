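"""Prioritization of migration-associated tumor-initiating-cell genes.

Candidate regulators are genes differentially expressed between migratory
and non-migratory cells (p < 0.01 and fold change > 2 within each cell
line), changed in the same direction in both cell lines, and whose
expression level is associated with patient survival in the concordant
direction: a gene down in migratory cells must show worse survival in the
low-expression patient group (and symmetrically for up genes).  Survival
association is screened by a median-expression split compared with
Kaplan-Meier curves, a Mantel-Haenszel (O/E) hazard ratio and the log-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

__all__ = [
    "DEGeneRecord",
    "SurvivalRecord",
    "SurvivalScreen",
    "CandidateGene",
    "significant_genes",
    "overlap_concordant",
    "km_logrank",
    "concordance_filter",
]


@dataclass(frozen=True)
class DEGeneRecord:
    """Per-gene differential expression (migratory vs non-migratory)."""

    gene: str
    log2fc: float
    p_value: float
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")


@dataclass(frozen=True)
class SurvivalRecord:
    subject: str
    time: float
    event: int  # 1 = relapse/death observed, 0 = censored
    expression: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class SurvivalScreen:
    """Median-split survival association for one gene."""

    hr: float  # hazard of the low-expression group relative to high
    logrank_p: float
    logrank_stat: float
    low_group_worse: bool
    km_curves: dict = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    direction: Literal["up", "down"]
    log2fc_by_line: dict
    survival_hr: float
    logrank_p: float
    concordant: bool


# ---------------------------------------------------------------------------
# expression filters
# ---------------------------------------------------------------------------


def significant_genes(
    records: Iterable[DEGeneRecord] | pd.DataFrame,
    p_max: float = 0.01,
    min_fold: float = 2.0,
) -> dict[str, set[str]]:
    """Split one cell line's DE table into significant up/down gene sets.

    A gene is significant when p < ``p_max`` and |fold change| > ``min_fold``
    (both strict); direction follows the sign of log2fc.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            DEGeneRecord(str(r.gene), float(r.log2fc), float(r.p_value))
            for r in records.itertuples()
        ]
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.gene in seen:
            raise ValueError(f"duplicate gene {r.gene!r} within one cell line")
        seen.add(r.gene)
    lfc_min = np.log2(min_fold)
    up = {r.gene for r in records if r.p_value < p_max and r.log2fc > lfc_min}
    down = {r.gene for r in records if r.p_value < p_max and r.log2fc < -lfc_min}
    return {"up": up, "down": down}


def overlap_concordant(
    line_a: Mapping[str, set[str]], line_b: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Genes significant in the same direction in both cell lines."""
    return {
        "up": set(line_a["up"]) & set(line_b["up"]),
        "down": set(line_a["down"]) & set(line_b["down"]),
    }


# ---------------------------------------------------------------------------
# survival screen
# ---------------------------------------------------------------------------


def km_logrank(
    records: Sequence[SurvivalRecord],
    split: Literal["median"] = "median",
) -> SurvivalScreen:
    """Median-expression-split Kaplan-Meier comparison for one gene.

    Patients are split at the median expression (ties to the low group).
    Returns the Mantel-Haenszel hazard ratio of the low group relative to
    the high group (O/E ratio over distinct event times), the log-rank
    chi-square p (1 df), and the fitted Kaplan-Meier curves per group.
    """
    if split != "median":
        raise ValueError("only the median split is supported")
    if len(records) < 4:
        raise ValueError("need at least two subjects per split group")
    expr = np.array([r.expression for r in records])
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    cut = float(np.median(expr))
    low = expr <= cut
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValueError("median split leaves fewer than two subjects in a group")
    if event.sum() == 0:
        raise ValueError("no events observed")

    # log-rank observed/expected over distinct event times
    o = np.zeros(2)
    e = np.zeros(2)
    v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n1 = int((at_risk & low).sum())
        n2 = int((at_risk & ~low).sum())
        n = n1 + n2
        d1 = int(((time == t) & (event == 1) & low).sum())
        d2 = int(((time == t) & (event == 1) & ~low).sum())
        d = d1 + d2
        o += (d1, d2)
        e += (d * n1 / n, d * n2 / n)
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = float((o[0] - e[0]) ** 2 / v) if v > 0 else 0.0
    p = float(sps.chi2.sf(stat, df=1)) if v > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = float((o[0] / e[0]) / (o[1] / e[1])) if e[0] > 0 and o[1] > 0 else np.inf

    curves: dict[str, pd.DataFrame] = {}
    for name, sel in (("low", low), ("high", ~low)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event_observed=event[sel], label=name)
        curves[name] = kmf.survival_function_
    return SurvivalScreen(
        hr=hr,
        logrank_p=p,
        logrank_stat=stat,
        low_group_worse=hr > 1,
        km_curves=curves,
    )


def concordance_filter(
    candidates: Mapping[str, set[str]],
    survival_results: Mapping[str, SurvivalScreen],
    log2fc_by_line: Mapping[str, Mapping[str, float]] | None = None,
    alpha: float = 0.05,
) -> list[CandidateGene]:
    """Keep genes whose survival association matches their expression change.

    A down-regulated gene survives the screen when low expression predicts
    significantly worse survival (HR_low > 1, log-rank p < alpha); an
    up-regulated gene when high expression does (HR_low < 1, p < alpha).
    Output is sorted by |mean log2 fold change| descending when fold
    changes are supplied, else alphabetically.
    """
    out: list[CandidateGene] = []
    for direction in ("down", "up"):
        for gene in candidates.get(direction, set()):
            if gene not in survival_results:
                raise KeyError(f"no survival screen available for gene {gene!r}")
            scr = survival_results[gene]
            worse_matches = scr.low_group_worse if direction == "down" else not scr.low_group_worse
            kept = worse_matches and scr.logrank_p < alpha
            if not kept:
                continue
            fc = dict(log2fc_by_line.get(gene, {})) if log2fc_by_line else {}
            out.append(
                CandidateGene(
                    gene=gene,
                    direction=direction,
                    log2fc_by_line=fc,
                    survival_hr=scr.hr,
                    logrank_p=scr.logrank_p,
                    concordant=True,
                )
            )

    def sort_key(c: CandidateGene):
        if c.log2fc_by_line:
            return (-abs(float(np.mean(list(c.log2fc_by_line.values())))), c.gene)
        return (0.0, c.gene)

    return sorted(out, key=sort_key)
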