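"""Heterosis indices and cytology proportion statistics.

Mid-parent heterosis (MPH) and high-parent heterosis (HPH) measure F1
performance against the parental mean and the best parent:

    MPH = 100 * (F1 - MP) / MP,   MP = (P1 + P2) / 2
    HPH = 100 * (F1 - HP) / HP,   HP = max(P1, P2)

Values are kept at full precision internally; rounding to two decimals
happens only in the reporting tables.  "Best parent" is the algebraic
maximum of the parent means for every trait, including traits where a lower
value would be agronomically preferable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import TraitRecord


@dataclass(frozen=True)
class HeterosisResult:
    trait: str
    f1: float
    p1: float
    p2: float
    mp: float              # mid-parent mean
    hp: float              # best (higher) parent
    mph_percent: float     # full precision
    hph_percent: float


@dataclass(frozen=True)
class CytologySummary:
    """Normal-cell counts for one meiotic stage of one genotype."""

    stage: str
    normal: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total cell count must be positive")
        if not 0 <= self.normal <= self.total:
            raise ValueError("need 0 <= normal <= total")

    @property
    def frequency_percent(self) -> float:
        return 100.0 * self.normal / self.total


def mph(f1: float, p1: float, p2: float) -> float:
    """Mid-parent heterosis in percent (full precision)."""
    mp = (p1 + p2) / 2.0
    if mp == 0:
        raise ValueError("mid-parent mean is zero; MPH undefined")
    return 100.0 * (f1 - mp) / mp


def hph(f1: float, p1: float, p2: float) -> float:
    """High-parent (best-parent) heterosis in percent (full precision)."""
    hp = max(p1, p2)
    if hp == 0:
        raise ValueError("best-parent mean is zero; HPH undefined")
    return 100.0 * (f1 - hp) / hp


def trait_heterosis_table(records: Iterable[TraitRecord],
                          decimals: int = 2) -> pd.DataFrame:
    """One row per trait with MP, HP and rounded MPH/HPH percentages."""
    rows = []
    for rec in records:
        res = HeterosisResult(
            trait=rec.trait, f1=rec.f1_mean, p1=rec.p1_mean, p2=rec.p2_mean,
            mp=(rec.p1_mean + rec.p2_mean) / 2.0,
            hp=max(rec.p1_mean, rec.p2_mean),
            mph_percent=mph(rec.f1_mean, rec.p1_mean, rec.p2_mean),
            hph_percent=hph(rec.f1_mean, rec.p1_mean, rec.p2_mean),
        )
        rows.append({
            "trait": res.trait, "f1": res.f1, "p1": res.p1, "p2": res.p2,
            "mp": res.mp, "hp": res.hp,
            "mph_percent": round(res.mph_percent, decimals),
            "hph_percent": round(res.hph_percent, decimals),
        })
    return pd.DataFrame(rows, columns=["trait", "f1", "p1", "p2", "mp", "hp",
                                       "mph_percent", "hph_percent"])


def pollen_fertility(fertile: int, total: int) -> float:
    """Percent of fertile (round, fully stained) pollen grains."""
    if total <= 0:
        raise ValueError("total pollen count must be positive")
    if not 0 <= fertile <= total:
        raise ValueError("need 0 <= fertile <= total")
    return 100.0 * fertile / total


def normal_cell_frequency(summaries: Sequence[CytologySummary]) -> dict[str, float]:
    """Per-stage normal-cell percentages plus a pooled ``overall`` entry.

    The overall frequency pools the raw counts (sum normal / sum total); it
    is not the mean of the per-stage percentages.
    """
    if not summaries:
        raise ValueError("no cytology summaries given")
    out = {s.stage: s.frequency_percent for s in summaries}
    total = sum(s.total for s in summaries)
    out["overall"] = 100.0 * sum(s.normal for s in summaries) / total
    return out


def compare_proportions(x1: int, n1: int, x2: int, n2: int,
                        exact: bool = False) -> tuple[float, float]:
    """Compare two proportions; returns (difference in points, p-value).

    The default test is the two-proportion chi-square with Yates continuity
    correction; ``exact=True`` switches to Fisher's exact test for small
    counts.  Degenerate margins (all pooled successes or failures) give
    p = 1.0 with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("need 0 <= x <= n in each group")
    diff = 100.0 * (x1 / n1 - x2 / n2)
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate margins in proportion comparison; p = 1",
                      stacklevel=2)
        return diff, 1.0
    if exact:
        _, p = sps.fisher_exact(table)
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=True)
    return diff, float(p)


def cytology_table(counts: Mapping[str, Sequence[CytologySummary]]) -> pd.DataFrame:
    """Tidy per-genotype, per-stage normal-cell frequency table."""
    rows = []
    for genotype, summaries in counts.items():
        freqs = normal_cell_frequency(list(summaries))
        for s in summaries:
            rows.append({"genotype": genotype, "stage": s.stage,
                         "normal": s.normal, "total": s.total,
                         "frequency_percent": round(freqs[s.stage], 2)})
        rows.append({"genotype": genotype, "stage": "overall",
                     "normal": sum(s.normal for s in summaries),
                     "total": sum(s.total for s in summaries),
                     "frequency_percent": round(freqs["overall"], 2)})
    return pd.DataFrame(rows, columns=["genotype", "stage", "normal", "total",
                                       "frequency_percent"])
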