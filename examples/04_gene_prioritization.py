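"""Prioritize tumor-initiating-cell regulator candidates.

Starts from the packaged cross-line DE gene table, takes the genes changed
in the same direction in both cell lines, screens each against (simulated)
patient survival with a median-expression split, and keeps the genes whose
survival association is concordant with their expression change.
"""

import numpy as np

from migchip.datasets import de_gene_sets, load_top_de_genes
from migchip.prioritize import (
    SurvivalRecord,
    concordance_filter,
    km_logrank,
    overlap_concordant,
)

sum159, mdamb231 = de_gene_sets()
overlap = overlap_concordant(sum159, mdamb231)
print(f"shared up-regulated genes:   {len(overlap['up'])}")
print(f"shared down-regulated genes: {len(overlap['down'])}")

# simulate a survival cohort per gene; PISD's low-expression patients are
# given a genuinely higher hazard, the rest are null
rng = np.random.default_rng(1)
screens = {}
for gene in sorted(overlap["up"] | overlap["down"]):
    n = 200
    expr = rng.normal(size=n)
    hazard = np.where(expr <= np.median(expr), 2.0 if gene == "PISD" else 1.0, 1.0)
    times = rng.exponential(1.0 / hazard)
    screens[gene] = km_logrank(
        [SurvivalRecord(f"s{i}", t, 1, x) for i, (t, x) in enumerate(zip(times, expr))]
    )

table = load_top_de_genes().set_index("gene")
fc = {
    g: {"SUM159": table.loc[g, "log2fc_sum159"],
        "MDA-MB-231": table.loc[g, "log2fc_mdamb231"]}
    for g in screens
}
kept = concordance_filter(overlap, screens, log2fc_by_line=fc)
print("\nconcordant candidates (direction, HR of low-expression group, log-rank p):")
for c in kept:
    print(f"  {c.gene:>8} {c.direction:>5}  HR={c.survival_hr:.2f}  "
          f"p={c.logrank_p:.3g}  log2FC={c.log2fc_by_line}")
# PISD — the one planted association, a gene down in migratory cells whose
# low expression predicts worse survival — tops the list; with ~40 null
# genes screened at alpha = 0.05, the occasional chance hit rides along.
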