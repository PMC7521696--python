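"""Twelve-pattern expression-dominance classification of hybrid genes.

Each gene is summarised by three significance calls, every one of which uses
the same dual DEG criterion (fold change >= 2 and FDR <= 0.05) as the rest
of the pipeline:

* ``call_f1_p1`` — hybrid vs parent 1 (+ = hybrid significantly higher),
* ``call_f1_p2`` — hybrid vs parent 2,
* ``call_p1_p2`` — parent 1 vs parent 2 (+ = parent 1 higher).

With H the significantly higher parent and L the lower, the twelve patterns
collapse into five groups:

==============  =========================================================
group           definition (and pattern count)
==============  =========================================================
transgressive_up    hybrid significantly above both parents (3: P1/P2 +, 0, -)
transgressive_down  hybrid significantly below both parents (3)
additive            parents differ; hybrid significantly below H and above L (2)
hp_eld              parents differ; hybrid indistinguishable from H,
                    significantly above L (2)
lp_eld              parents differ; hybrid indistinguishable from L,
                    significantly below H (2)
==============  =========================================================

Every other combination — including the all-nonsignificant one and the
internally contradictory ones noise can produce — is ``unclassified``.
Pattern labels I-XII number the rows of the table above in order
(I-II additive, III-IV hp_eld, V-VI lp_eld, VII-IX transgressive_up,
X-XII transgressive_down).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .de import DegThresholds, call_degs

SigCall = Literal["+", "-", "0"]

GROUPS = ("additive", "hp_eld", "lp_eld", "transgressive_up",
          "transgressive_down")

#: (call_f1_p1, call_f1_p2, call_p1_p2) -> (pattern, group)
PATTERN_TABLE: dict[tuple[str, str, str], tuple[str, str]] = {
    # additive: parents differ, hybrid between them
    ("-", "+", "+"): ("I", "additive"),        # P1 high, F1 below P1 above P2
    ("+", "-", "-"): ("II", "additive"),       # P2 high
    # high-parent expression-level dominance
    ("0", "+", "+"): ("III", "hp_eld"),        # F1 = P1 (high), above P2
    ("+", "0", "-"): ("IV", "hp_eld"),         # F1 = P2 (high), above P1
    # low-parent expression-level dominance
    ("0", "-", "-"): ("V", "lp_eld"),          # F1 = P1 (low), below P2
    ("-", "0", "+"): ("VI", "lp_eld"),         # F1 = P2 (low), below P1
    # transgressive up-regulation: above both parents
    ("+", "+", "+"): ("VII", "transgressive_up"),
    ("+", "+", "0"): ("VIII", "transgressive_up"),
    ("+", "+", "-"): ("IX", "transgressive_up"),
    # transgressive down-regulation: below both parents
    ("-", "-", "+"): ("X", "transgressive_down"),
    ("-", "-", "0"): ("XI", "transgressive_down"),
    ("-", "-", "-"): ("XII", "transgressive_down"),
}


@dataclass(frozen=True)
class DominanceCall:
    gene_id: str
    pattern: str            # I-XII, or "-" when unclassified
    group: str              # one of GROUPS or "unclassified"


def classify_gene(call_f1_p1: SigCall, call_f1_p2: SigCall,
                  call_p1_p2: SigCall) -> tuple[str, str]:
    """Map one gene's three significance calls to (pattern, group).

    The parent ordering needed by the additive/ELD branches comes from the
    sign of the parent-parent call, so no separate mean comparison is
    required; combinations outside the twelve-pattern table are
    ``("-", "unclassified")``.
    """
    for c in (call_f1_p1, call_f1_p2, call_p1_p2):
        if c not in ("+", "-", "0"):
            raise ValueError(f"invalid significance call: {c!r}")
    return PATTERN_TABLE.get((call_f1_p1, call_f1_p2, call_p1_p2),
                             ("-", "unclassified"))


def _sig_calls(result: pd.DataFrame, genes: Iterable[str],
               thresholds: DegThresholds) -> pd.Series:
    """Per-gene +/-/0 calls for one contrast restricted to ``genes``."""
    calls = call_degs(result, thresholds)
    sign = pd.Series("0", index=pd.Index(list(genes), name="gene_id"))
    up = calls.loc[calls["direction"] == "up", "gene_id"]
    down = calls.loc[calls["direction"] == "down", "gene_id"]
    sign.loc[sign.index.intersection(up)] = "+"
    sign.loc[sign.index.intersection(down)] = "-"
    return sign


def classify_all(deg_hp_genes: Iterable[str],
                 contrast_f1_p1: pd.DataFrame,
                 contrast_f1_p2: pd.DataFrame,
                 contrast_p1_p2: pd.DataFrame,
                 thresholds: DegThresholds = DegThresholds()) -> pd.DataFrame:
    """Classify every DEGs_HP gene from its three contrast results.

    The contrast frames are ``test_contrast`` outputs with the hybrid (or
    parent 1) as group_a, i.e. positive log2fc means first-listed member
    higher.  Returns a frame (gene_id, pattern, group) covering exactly the
    genes in ``deg_hp_genes``.
    """
    genes = sorted(set(str(g) for g in deg_hp_genes))
    for name, result in (("F1 vs P1", contrast_f1_p1),
                         ("F1 vs P2", contrast_f1_p2),
                         ("P1 vs P2", contrast_p1_p2)):
        missing = set(genes) - set(result.index.astype(str))
        if missing:
            raise ValueError(
                f"contrast {name} lacks results for {len(missing)} genes "
                f"(e.g. {sorted(missing)[:3]})")
    s1 = _sig_calls(contrast_f1_p1, genes, thresholds)
    s2 = _sig_calls(contrast_f1_p2, genes, thresholds)
    s3 = _sig_calls(contrast_p1_p2, genes, thresholds)
    rows = []
    for g in genes:
        pattern, group = classify_gene(s1[g], s2[g], s3[g])
        rows.append({"gene_id": g, "pattern": pattern, "group": group})
    return pd.DataFrame(rows, columns=["gene_id", "pattern", "group"])


def summarize(calls: pd.DataFrame | Iterable[DominanceCall]) -> pd.DataFrame:
    """Group counts and percentages of classified genes (2-decimal percents).

    Unclassified genes are excluded from both the counts and the percentage
    denominator; an ``unclassified`` attribute on the returned frame records
    how many there were.
    """
    df = _as_frame(calls)
    classified = df[df["group"] != "unclassified"]
    counts = classified["group"].value_counts()
    total = int(counts.sum())
    rows = []
    for group in GROUPS:
        c = int(counts.get(group, 0))
        pct = round(100.0 * c / total, 2) if total else 0.0
        rows.append({"group": group, "count": c, "percent": pct})
    out = pd.DataFrame(rows, columns=["group", "count", "percent"])
    out.attrs["unclassified"] = int(len(df) - total)
    out.attrs["classified"] = total
    return out


def heterosis_candidates(calls: pd.DataFrame | Iterable[DominanceCall]) -> frozenset[str]:
    """Potential heterosis genes: high-parent dominance or transgressive up."""
    df = _as_frame(calls)
    mask = df["group"].isin(("hp_eld", "transgressive_up"))
    return frozenset(df.loc[mask, "gene_id"].astype(str))


def cross_stage_common(candidates_stage1: Iterable[str],
                       candidates_stage2: Iterable[str]) -> frozenset[str]:
    """Candidate genes shared by two developmental stages."""
    return frozenset(str(g) for g in candidates_stage1) & frozenset(
        str(g) for g in candidates_stage2)


def _as_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame(
        [{"gene_id": c.gene_id, "pattern": c.pattern, "group": c.group}
         for c in calls], columns=["gene_id", "pattern", "group"])
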