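"""Packaged reference tables from the migration-chip study.

``migratory_de_genes.csv`` holds the published top-ranked up- and
down-regulated genes in migratory versus non-migratory cells, with log2
fold changes for both cell lines (SUM159, MDA-MB-231).
``lda_outcomes.csv`` holds the limiting-dilution implantation outcomes
(100 cells per implantation) for the migratory and non-migratory arms of
both cell lines.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_top_de_genes", "de_gene_sets", "load_lda_outcomes"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("migchip.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_top_de_genes() -> pd.DataFrame:
    """Top-ranked DE genes with per-line log2 fold changes (published order)."""
    return _read("migratory_de_genes.csv")


def de_gene_sets() -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-line significant up/down gene sets from the packaged table.

    The published table lists only genes already passing the per-line
    significance filter (p < 0.01, fold change > 2) and gives no p-values,
    so membership plus the sign of the per-line log2 fold change defines
    the sets.  Returns (SUM159 sets, MDA-MB-231 sets).
    """
    df = load_top_de_genes()
    out = []
    for col in ("log2fc_sum159", "log2fc_mdamb231"):
        out.append(
            {
                "up": set(df.loc[df[col] > 0, "gene"]),
                "down": set(df.loc[df[col] < 0, "gene"]),
            }
        )
    return out[0], out[1]


def load_lda_outcomes() -> pd.DataFrame:
    """Limiting-dilution outcomes per cell line and migration arm."""
    return _read("lda_outcomes.csv")
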