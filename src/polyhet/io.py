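"""Readers and writers for the tabular and interval formats the pipeline touches.

All genomic coordinates are 0-based half-open inside the package; 1-based
inclusive conventions (GFF3, the QTL table) are converted at the I/O boundary
and nowhere else.  Tables are plain UTF-8 TSV/CSV; every writer prepends a
commented header line recording the package version and any parameters, and
every reader skips ``#`` comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger("polyhet")

VALID_PLOIDIES = ("2x", "4x")
VALID_ROLES = ("maternal", "paternal", "hybrid")
VALID_STAGES = ("meiosis", "single_microspore")


class FormatError(ValueError):
    """A file violated the documented schema."""


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples count matrix and coerce it to int64.

    Raises :class:`FormatError` on duplicate gene ids, duplicate sample ids,
    negative or non-integer entries.
    """
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids: {dupes[:5]}")
    if counts.columns.duplicated().any():
        raise FormatError("duplicate sample ids")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count matrix contains non-numeric entries")
    if np.isnan(values.astype(float)).any():
        raise FormatError("count matrix contains missing values")
    if (values < 0).any():
        raise FormatError("count matrix contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise FormatError("count matrix contains non-integer entries")
    out = counts.astype(np.int64)
    out.index = out.index.astype(str)
    out.index.name = "gene_id"
    return out


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix (first column gene_id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return validate_count_matrix(df)


def write_count_matrix(counts: pd.DataFrame, path: str | Path,
                       params: Mapping[str, object] | None = None) -> None:
    _write_commented(counts.rename_axis("gene_id"), path, params, index=True)


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame,
                    counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a per-sample design table (index = sample id).

    Columns ``ploidy``, ``role``, ``stage``, ``replicate`` are mandatory.
    When ``counts`` is given, every count-matrix sample must appear exactly
    once in the design.
    """
    required = {"ploidy", "role", "stage", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    if design.index.duplicated().any():
        raise FormatError("duplicate sample ids in design")
    for col, valid in (("ploidy", VALID_PLOIDIES), ("role", VALID_ROLES),
                       ("stage", VALID_STAGES)):
        bad = set(design[col]) - set(valid)
        if bad:
            raise FormatError(f"invalid {col} values: {sorted(bad)}")
    if (design["replicate"].astype(int) < 1).any():
        raise FormatError("replicate numbers must be >= 1")
    if counts is not None:
        absent = set(counts.columns) - set(design.index)
        if absent:
            raise FormatError(f"samples missing from design: {sorted(absent)[:5]}")
    return design


def read_sample_design(path: str | Path,
                       counts: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return validate_design(df, counts)


def write_sample_design(design: pd.DataFrame, path: str | Path,
                        params: Mapping[str, object] | None = None) -> None:
    _write_commented(design.rename_axis("sample_id"), path, params, index=True)


def select_samples(design: pd.DataFrame, *, ploidy: str | None = None,
                   role: str | None = None, stage: str | None = None) -> list[str]:
    """Sample ids matching the given ploidy/role/stage filters."""
    mask = pd.Series(True, index=design.index)
    for col, val in (("ploidy", ploidy), ("role", role), ("stage", stage)):
        if val is not None:
            mask &= design[col] == val
    return list(design.index[mask])


# ---------------------------------------------------------------------------
# genomic intervals
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
QTL_COLUMNS = ["qtl_id", "trait", "chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if (df["start"] < 0).any():
        raise FormatError(f"{what}: negative start coordinate")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{what}: start >= end after conversion to half-open")
    return df


def read_gene_annotation(path: str | Path, fmt: str = "gff3") -> pd.DataFrame:
    """Read gene intervals from GFF3 (1-based inclusive) or BED (half-open).

    Returns a frame with columns gene_id, chrom, start, end, strand in
    internal 0-based half-open coordinates.  For GFF3 the gene id is taken
    from the ``ID=`` attribute (falling back to ``Name=``).
    """
    if fmt == "gff3":
        by_type: dict[str, list[dict]] = {"gene": [], "other": []}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"GFF3 line has {len(parts)} columns, expected 9")
                chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype not in ("gene", "mRNA", "transcript"):
                    continue
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                gid = attr_map.get("ID") or attr_map.get("Name")
                if gid is None:
                    raise FormatError("GFF3 record without ID/Name attribute")
                by_type["gene" if ftype == "gene" else "other"].append(
                    {"gene_id": gid, "chrom": chrom,
                     "start": int(start) - 1, "end": int(end), "strand": strand})
        rows = by_type["gene"] or by_type["other"]
        df = pd.DataFrame(rows, columns=GENE_COLUMNS)
        if not df.empty and df["gene_id"].duplicated().any():
            df = df.drop_duplicates("gene_id", keep="first")
    elif fmt == "bed":
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        if df.shape[1] < 4:
            raise FormatError("BED file needs at least 4 columns (chrom,start,end,name)")
        df = df.iloc[:, :6] if df.shape[1] >= 6 else df
        cols = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
        df.columns = cols
        if "strand" not in df.columns:
            df["strand"] = "."
        df = df[["gene_id", "chrom", "start", "end", "strand"]]
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")
    df = df.astype({"start": np.int64, "end": np.int64, "gene_id": str, "chrom": str})
    return _check_intervals(df.reset_index(drop=True), "gene annotation")


def write_gene_annotation(genes: pd.DataFrame, path: str | Path,
                          fmt: str = "gff3") -> None:
    """Write gene intervals as GFF3 (converting to 1-based inclusive) or BED."""
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(f"#! polyhet {__version__}\n")
            for row in genes.itertuples(index=False):
                fh.write(f"{row.chrom}\tpolyhet\tgene\t{row.start + 1}\t{row.end}\t.\t"
                         f"{getattr(row, 'strand', '.')}\t.\tID={row.gene_id}\n")
        elif fmt == "bed":
            for row in genes.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t"
                         f"{getattr(row, 'strand', '.')}\n")
        else:
            raise ValueError(f"unknown annotation format: {fmt!r}")


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    """Read a QTL TSV (trait, chrom, start_1based, end_1based, qtl_id).

    Coordinates are converted to internal 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"trait", "chrom", "start_1based", "end_1based", "qtl_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"QTL table missing columns: {sorted(missing)}")
    extra = set(df.columns) - required
    if extra:
        logger.warning("QTL table: ignoring unknown columns %s", sorted(extra))
    out = pd.DataFrame({
        "qtl_id": df["qtl_id"].astype(str),
        "trait": df["trait"].astype(str),
        "chrom": df["chrom"].astype(str),
        "start": df["start_1based"].astype(np.int64) - 1,
        "end": df["end_1based"].astype(np.int64),
    })
    return _check_intervals(out, "QTL table")


def write_qtl_table(qtls: pd.DataFrame, path: str | Path,
                    params: Mapping[str, object] | None = None) -> None:
    out = pd.DataFrame({
        "trait": qtls["trait"],
        "chrom": qtls["chrom"],
        "start_1based": qtls["start"] + 1,
        "end_1based": qtls["end"],
        "qtl_id": qtls["qtl_id"],
    })
    _write_commented(out, path, params, index=False)


# ---------------------------------------------------------------------------
# trait means and term annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitRecord:
    """Trait means for one trait: F1 hybrid and the two parents."""

    trait: str
    f1_mean: float
    p1_mean: float
    p2_mean: float
    sd: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        for v in (self.f1_mean, self.p1_mean, self.p2_mean):
            if not np.isfinite(v):
                raise FormatError(f"non-finite trait mean for {self.trait!r}")


def read_trait_table(path: str | Path) -> list[TraitRecord]:
    """Read a trait CSV with columns trait, f1, p1, p2 (optional sd, n)."""
    df = pd.read_csv(path, comment="#")
    required = {"trait", "f1", "p1", "p2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trait table missing columns: {sorted(missing)}")
    extra = set(df.columns) - required - {"sd", "n"}
    if extra:
        logger.warning("trait table: ignoring unknown columns %s", sorted(extra))
    records = []
    for row in df.itertuples(index=False):
        records.append(TraitRecord(
            trait=str(row.trait), f1_mean=float(row.f1),
            p1_mean=float(row.p1), p2_mean=float(row.p2),
            sd=float(row.sd) if "sd" in df.columns and np.isfinite(row.sd) else None,
            n=int(row.n) if "n" in df.columns and np.isfinite(row.n) else None,
        ))
    return records


@dataclass
class TermAnnotation:
    """Term -> gene-set map for one namespace (e.g. GO-BP or KEGG)."""

    namespace: str
    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: Iterable[str]) -> "TermAnnotation":
        """Intersect every term's gene set with ``universe``; drop empty terms."""
        uni = frozenset(universe)
        terms = {t: g & uni for t, g in self.terms.items()}
        return TermAnnotation(
            namespace=self.namespace,
            terms={t: g for t, g in terms.items() if g},
            term_names=self.term_names,
        )


def read_term_annotation(path: str | Path, namespace: str = "GO") -> TermAnnotation:
    """Read a two-column (term_id, gene_id) TSV; a third column names the term."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         dtype=str).dropna(how="all")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    ann = TermAnnotation(namespace=namespace)
    if df.empty:
        logger.warning("term annotation %s is empty", path)
        return ann
    if df.shape[1] < 2:
        raise FormatError("term annotation needs columns (term_id, gene_id)")
    grouped: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        term, gene = row[0], row[1]
        grouped.setdefault(term, set()).add(gene)
        if len(row) > 2 and isinstance(row[2], str):
            ann.term_names.setdefault(term, row[2])
    ann.terms = {t: frozenset(g) for t, g in grouped.items()}
    return ann


def write_term_annotation(annotation: TermAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# polyhet {__version__} namespace={annotation.namespace}\n")
        for term in sorted(annotation.terms):
            name = annotation.term_names.get(term, "")
            for gene in sorted(annotation.terms[term]):
                fh.write(f"{term}\t{gene}\t{name}\n" if name else f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# generic helpers
# ---------------------------------------------------------------------------

def _write_commented(df: pd.DataFrame, path: str | Path,
                     params: Mapping[str, object] | None, index: bool) -> None:
    with open(path, "w") as fh:
        items = "" if not params else " " + " ".join(
            f"{k}={v}" for k, v in params.items())
        fh.write(f"# polyhet {__version__}{items}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_table(df: pd.DataFrame, path: str | Path,
                params: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    """Write any result table as commented TSV."""
    _write_commented(df, path, params, index=index)


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
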