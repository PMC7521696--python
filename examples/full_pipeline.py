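"""Run the whole pipeline on a simulated bundle and read the manifest.

Equivalent to `polyhet simulate ... && polyhet run --config ...`; writes
contrast tables, DEG set summaries, dominance calls, heterosis-candidate
lists, QTL hits and a manifest under out/results.
"""

import json
import tempfile
from pathlib import Path

from polyhet import io, pipeline, simulate

workdir = Path(tempfile.mkdtemp(prefix="polyhet_example_"))
exp = simulate.generate_experiment(simulate.SimConfig(n_genes=800, seed=17))
io.write_count_matrix(exp.counts, workdir / "counts.tsv")
io.write_sample_design(exp.design, workdir / "design.tsv")
ann = simulate.generate_annotation(800, 12, 30_000_000, seed=17,
                                   gene_ids=list(exp.counts.index))
io.write_gene_annotation(ann, workdir / "annotation.gff3", "gff3")
io.write_qtl_table(simulate.generate_qtls(
    ["pollen fertility", "1000-grain weight"], per_trait=10,
    n_chromosomes=12, chrom_length=30_000_000, seed=17),
    workdir / "qtls.tsv")

cfg = pipeline.PipelineConfig(
    counts=str(workdir / "counts.tsv"), design=str(workdir / "design.tsv"),
    annotation=str(workdir / "annotation.gff3"),
    qtls=str(workdir / "qtls.tsv"), out_dir=str(workdir / "results"),
    seed=17)
manifest = pipeline.run_pipeline(cfg)
print(json.dumps(manifest["stages"], indent=2))
print(f"\noutputs in {workdir / 'results'}:")
for p in sorted((workdir / "results").iterdir()):
    print(" ", p.name)
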