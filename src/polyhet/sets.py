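"""DEG set algebra: parent-parent, hybrid-parent, combined and ploidy-specific.

Terminology follows the field: DEGs_PP are genes differing between the two
parents; M/F1 and F/F1 are the maternal-vs-hybrid and paternal-vs-hybrid
sets; DEGs_HP (hybrid vs parents) is their union.  Direction is ignored in
the algebra — a gene is an element regardless of up/down — because set
sizes are reported as gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import pandas as pd


def _as_gene_set(calls) -> frozenset[str]:
    """Accept a gene iterable or a call frame with a gene_id column."""
    if isinstance(calls, pd.DataFrame):
        return frozenset(calls["gene_id"].astype(str))
    return frozenset(str(g) for g in calls)


@dataclass(frozen=True)
class DegSetFamily:
    """The DEG sets of one (ploidy, stage): PP, M/F1, F/F1 and their union."""

    ploidy: str
    stage: str
    degs_pp: frozenset[str]
    degs_mf1: frozenset[str]
    degs_ff1: frozenset[str]

    @property
    def degs_hp(self) -> frozenset[str]:
        return self.degs_mf1 | self.degs_ff1


def build_family(calls_pp, calls_mf1, calls_ff1, *, ploidy: str,
                 stage: str) -> DegSetFamily:
    """Assemble a :class:`DegSetFamily` from three per-contrast call sets."""
    fam = DegSetFamily(
        ploidy=ploidy, stage=stage,
        degs_pp=_as_gene_set(calls_pp),
        degs_mf1=_as_gene_set(calls_mf1),
        degs_ff1=_as_gene_set(calls_ff1),
    )
    assert fam.degs_hp == fam.degs_mf1 | fam.degs_ff1
    return fam


def ploidy_specific(hp_4x: Iterable[str], hp_2x: Iterable[str]) -> frozenset[str]:
    """Genes in the autotetraploid DEGs_HP absent from the diploid DEGs_HP."""
    return _as_gene_set(hp_4x) - _as_gene_set(hp_2x)


def venn_counts(named_sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Counts for every Venn region of 2-4 named sets.

    Keys are tuples of the set names an element belongs to (in input order);
    only non-empty membership combinations with a nonzero count appear except
    that all 2^k - 1 regions are reported (zeros included) so totals are
    auditable.  Region counts sum to the size of the union.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts supports 2-4 sets")
    sets = {n: _as_gene_set(named_sets[n]) for n in names}
    regions: dict[tuple[str, ...], int] = {}
    for membership in product([True, False], repeat=len(names)):
        inside = tuple(n for n, m in zip(names, membership) if m)
        if not inside:
            continue
        outside = [n for n, m in zip(names, membership) if not m]
        region = frozenset.intersection(*(sets[n] for n in inside))
        for n in outside:
            region = region - sets[n]
        regions[inside] = len(region)
    return regions


def family_summary(families: Iterable[DegSetFamily]) -> pd.DataFrame:
    """Per-(ploidy, stage) table of DEG set sizes."""
    rows = []
    for fam in families:
        rows.append({
            "stage": fam.stage, "ploidy": fam.ploidy,
            "degs_pp": len(fam.degs_pp), "degs_mf1": len(fam.degs_mf1),
            "degs_ff1": len(fam.degs_ff1), "degs_hp": len(fam.degs_hp),
        })
    return pd.DataFrame(rows)


def membership_table(named_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-gene boolean membership flags for the given named sets."""
    sets = {n: _as_gene_set(s) for n, s in named_sets.items()}
    universe = sorted(frozenset().union(*sets.values())) if sets else []
    return pd.DataFrame(
        {name: [g in genes for g in universe] for name, genes in sets.items()},
        index=pd.Index(universe, name="gene_id"),
    )
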