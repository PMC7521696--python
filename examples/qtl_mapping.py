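"""Map simulated gene intervals onto yield-trait QTL intervals.

A hit is any >= 1 bp overlap on the same chromosome; per-trait summaries
deduplicate genes within a trait (a gene under two QTLs of one trait counts
once there) but not across traits.
"""

from polyhet import qtl, simulate

genes = simulate.generate_annotation(2000, n_chromosomes=12,
                                     chrom_length=30_000_000, seed=17)
qtls = simulate.generate_qtls(
    ["grain yield per panicle", "pollen fertility", "1000-grain weight",
     "male fertility restoration"],
    per_trait=8, n_chromosomes=12, chrom_length=30_000_000, seed=17)

hits = qtl.map_genes_to_qtls(genes, qtls)
print(f"{len(hits)} gene-QTL overlaps")
print(hits.head().to_string(index=False))
print()
summary = qtl.summarize_by_trait(hits)
print(summary.to_string(index=False))
print()
print("n_unique_genes counts each gene once per trait; overlap_bp is the")
print("shared length in bases under the half-open convention.")
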