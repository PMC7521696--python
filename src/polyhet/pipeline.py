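"""End-to-end orchestration: DE -> set algebra -> dominance -> candidates ->
QTL mapping -> enrichment -> heterosis/cytology, with a JSON manifest.

The stage order mirrors how such hybrid-transcriptome studies proceed:
differential expression per (ploidy, stage), DEG set families and the
autotetraploid-specific set, dominance classification of those genes with
heterosis-candidate extraction, interval mapping of candidates onto QTLs,
term enrichment, and finally the phenotype-side statistics.  All outputs are
commented TSVs plus ``manifest.json``; a rerun with the same configuration
reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, de, dominance, enrich, io, qtl, sets, stats

logger = logging.getLogger("polyhet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts: str
    design: str
    out_dir: str
    annotation: str | None = None
    annotation_format: str = "gff3"
    qtls: str | None = None
    traits: str | None = None
    terms: str | None = None
    terms_namespace: str = "GO"
    cytology: str | None = None
    fc_min: float = 2.0
    fdr_max: float = 0.05
    min_corr: float = 0.8
    min_term_size: int = 3
    stages: tuple[str, ...] = ("meiosis", "single_microspore")
    seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (self.fc_min >= 1 and 0 < self.fdr_max <= 1):
            raise ValueError("fc_min must be >= 1 and fdr_max in (0, 1]")
        if not 0 <= self.min_corr <= 1:
            raise ValueError("min_corr must be in [0, 1]")
        for name in ("counts", "design"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("annotation", "qtls", "traits", "terms", "cytology"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if isinstance(self.stages, str):
            self.stages = (self.stages,)
        else:
            self.stages = tuple(self.stages)


def _contrast_name(ploidy: str, stage: str, label: str) -> str:
    return f"{ploidy}_{stage}_{label}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage configured inputs allow; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = de.DegThresholds(config.fc_min, config.fdr_max)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {"fc_min": config.fc_min, "fdr_max": config.fdr_max,
                       "min_corr": config.min_corr,
                       "min_term_size": config.min_term_size},
        "inputs": {k: getattr(config, k) for k in
                   ("counts", "design", "annotation", "qtls", "traits",
                    "terms", "cytology")},
        "stages": {},
    }

    def record(stage: str, **counts: int) -> None:
        manifest["stages"][stage] = counts

    # ---------------------------------------------------------------- load
    try:
        counts = io.read_count_matrix(config.counts)
        design = io.read_sample_design(config.design, counts)
        design = design.loc[[s for s in counts.columns if s in design.index]]
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc
    record("load", n_genes=len(counts), n_samples=counts.shape[1])

    # ------------------------------------------------------------------ qc
    try:
        retained = de.qc_replicates(counts, design, config.min_corr)
        counts = counts[retained]
        design = design.loc[retained]
    except Exception as exc:
        raise PipelineError(f"stage 'qc' failed: {exc}") from exc
    record("qc", n_retained=len(retained))

    # ------------------------------------------------------------------ de
    contrasts: dict[str, pd.DataFrame] = {}
    calls: dict[str, pd.DataFrame] = {}
    ploidies = tuple(dict.fromkeys(design["ploidy"]))
    try:
        for ploidy in ploidies:
            for stage in config.stages:
                block = io.select_samples(design, ploidy=ploidy, stage=stage)
                if not block:
                    continue
                sub = counts[block]
                sub_design = design.loc[block]
                for label, a, b in (("f1_vs_m", "hybrid", "maternal"),
                                    ("f1_vs_f", "hybrid", "paternal"),
                                    ("m_vs_f", "maternal", "paternal")):
                    name = _contrast_name(ploidy, stage, label)
                    res = de.test_contrast(sub, sub_design,
                                           {"role": a}, {"role": b})
                    contrasts[name] = res
                    calls[name] = de.call_degs(res, thresholds)
                    io.write_table(
                        res.reset_index(), out / f"contrast_{name}.tsv",
                        params={"contrast": name, "fc_min": config.fc_min,
                                "fdr_max": config.fdr_max})
    except Exception as exc:
        raise PipelineError(f"stage 'de' failed: {exc}") from exc
    record("de", n_contrasts=len(contrasts),
           **{f"n_degs_{k}": len(v) for k, v in calls.items()})

    # ---------------------------------------------------------------- sets
    families: dict[tuple[str, str], sets.DegSetFamily] = {}
    specific: dict[str, frozenset[str]] = {}
    try:
        for ploidy in ploidies:
            for stage in config.stages:
                key = _contrast_name(ploidy, stage, "m_vs_f")
                if key not in calls:
                    continue
                fam = sets.build_family(
                    calls[key],
                    calls[_contrast_name(ploidy, stage, "f1_vs_m")],
                    calls[_contrast_name(ploidy, stage, "f1_vs_f")],
                    ploidy=ploidy, stage=stage)
                families[(ploidy, stage)] = fam
        for stage in config.stages:
            if ("4x", stage) in families and ("2x", stage) in families:
                specific[stage] = sets.ploidy_specific(
                    families[("4x", stage)].degs_hp,
                    families[("2x", stage)].degs_hp)
        if families:
            io.write_table(sets.family_summary(families.values()),
                           out / "deg_set_summary.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'sets' failed: {exc}") from exc
    record("sets", n_families=len(families),
           **{f"n_4x_specific_{s}": len(g) for s, g in specific.items()})

    # ----------------------------------------------------------- dominance
    candidates: dict[str, frozenset[str]] = {}
    try:
        for stage, genes in specific.items():
            if not genes:
                candidates[stage] = frozenset()
                continue
            dom = dominance.classify_all(
                genes,
                contrasts[_contrast_name("4x", stage, "f1_vs_m")],
                contrasts[_contrast_name("4x", stage, "f1_vs_f")],
                contrasts[_contrast_name("4x", stage, "m_vs_f")],
                thresholds)
            summary = dominance.summarize(dom)
            candidates[stage] = dominance.heterosis_candidates(dom)
            io.write_table(dom, out / f"dominance_calls_{stage}.tsv")
            io.write_table(summary, out / f"dominance_summary_{stage}.tsv",
                           params={"classified": summary.attrs["classified"],
                                   "unclassified": summary.attrs["unclassified"]})
        if len(candidates) == 2:
            common = dominance.cross_stage_common(*candidates.values())
            (out / "candidates_common.txt").write_text(
                "\n".join(sorted(common)) + ("\n" if common else ""))
        for stage, cand in candidates.items():
            (out / f"candidates_{stage}.txt").write_text(
                "\n".join(sorted(cand)) + ("\n" if cand else ""))
    except Exception as exc:
        raise PipelineError(f"stage 'dominance' failed: {exc}") from exc
    record("dominance", **{f"n_candidates_{s}": len(c)
                           for s, c in candidates.items()})

    # ---------------------------------------------------------------- qtl
    if config.annotation and config.qtls:
        try:
            genes_ann = io.read_gene_annotation(config.annotation,
                                                config.annotation_format)
            qtl_table = io.read_qtl_table(config.qtls)
            focus = frozenset().union(*specific.values()) if specific else \
                frozenset(genes_ann["gene_id"])
            hits = qtl.map_genes_to_qtls(
                genes_ann[genes_ann["gene_id"].isin(focus)], qtl_table)
            io.write_table(hits, out / "qtl_hits.tsv")
            io.write_table(qtl.summarize_by_trait(hits),
                           out / "qtl_trait_summary.tsv")
            record("qtl", n_hits=len(hits),
                   n_traits=hits["trait"].nunique() if len(hits) else 0)
        except Exception as exc:
            raise PipelineError(f"stage 'qtl' failed: {exc}") from exc

    # ----------------------------------------------------------- enrichment
    if config.terms:
        try:
            annotation = io.read_term_annotation(config.terms,
                                                 config.terms_namespace)
            results = []
            for stage, genes in specific.items():
                universe = frozenset(
                    contrasts[_contrast_name("4x", stage, "f1_vs_m")]
                    .loc[lambda d: d["tested"]].index.astype(str))
                res = enrich.enrich(genes & universe, annotation, universe,
                                    config.min_term_size)
                res.insert(0, "stage", stage)
                results.append(res)
            if results:
                io.write_table(pd.concat(results, ignore_index=True),
                               out / "enrichment.tsv")
                record("enrichment",
                       n_terms_tested=int(sum(len(r) for r in results)))
        except Exception as exc:
            raise PipelineError(f"stage 'enrichment' failed: {exc}") from exc

    # ------------------------------------------------------------ heterosis
    if config.traits:
        try:
            records = io.read_trait_table(config.traits)
            table = stats.trait_heterosis_table(records)
            io.write_table(table, out / "heterosis.tsv")
            record("heterosis", n_traits=len(table))
        except Exception as exc:
            raise PipelineError(f"stage 'heterosis' failed: {exc}") from exc

    # ------------------------------------------------------------- cytology
    if config.cytology:
        try:
            cyt = io.read_table(config.cytology)
            required = {"genotype", "stage", "normal", "total"}
            if not required <= set(cyt.columns):
                raise io.FormatError(
                    f"cytology table missing columns: "
                    f"{sorted(required - set(cyt.columns))}")
            grouped = {
                g: [stats.CytologySummary(str(r.stage), int(r.normal),
                                          int(r.total))
                    for r in sub.itertuples(index=False)]
                for g, sub in cyt.groupby("genotype", sort=True)}
            io.write_table(stats.cytology_table(grouped),
                           out / "cytology_summary.tsv")
            record("cytology", n_genotypes=len(grouped))
        except Exception as exc:
            raise PipelineError(f"stage 'cytology' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
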