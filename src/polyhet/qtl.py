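"""Gene-to-QTL interval overlap mapping.

Both gene and QTL intervals are 0-based half-open on named chromosomes.  A
gene hits a QTL when they share a chromosome and overlap by at least one
base — genes touching a QTL border only (half-open adjacency) do not count.
Per-trait summaries deduplicate genes within a trait but not across traits,
so one gene under QTLs of two traits contributes to both.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

HIT_COLUMNS = ["gene_id", "qtl_id", "trait", "overlap_bp"]


def map_genes_to_qtls(genes: pd.DataFrame, qtls: pd.DataFrame) -> pd.DataFrame:
    """All (gene, QTL) pairs with >= 1 bp overlap, via per-chromosome
    interval trees.

    ``genes`` needs columns gene_id, chrom, start, end; ``qtls`` needs
    qtl_id, trait, chrom, start, end.  Output is sorted by
    (trait, qtl_id, gene_id).
    """
    trees: dict[str, IntervalTree] = {}
    for row in qtls.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (row.qtl_id, row.trait))
    rows = []
    for row in genes.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            overlap = min(row.end, iv.end) - max(row.start, iv.begin)
            qtl_id, trait = iv.data
            rows.append({"gene_id": row.gene_id, "qtl_id": qtl_id,
                         "trait": trait, "overlap_bp": int(overlap)})
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["trait", "qtl_id", "gene_id"]).reset_index(drop=True)


def summarize_by_trait(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait counts: QTLs hit and unique genes (deduplicated per trait)."""
    if hits.empty:
        return pd.DataFrame(columns=["trait", "n_qtls_hit", "n_unique_genes"])
    grouped = hits.groupby("trait", sort=True).agg(
        n_qtls_hit=("qtl_id", "nunique"),
        n_unique_genes=("gene_id", "nunique"),
    ).reset_index()
    return grouped
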