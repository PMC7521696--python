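"""Normalization, replicate QC and two-group negative-binomial contrasts.

Differential expression is called with the dual criterion used throughout
the pipeline: fold change >= ``fc_min`` (default 2) AND Benjamini-Hochberg
FDR <= ``fdr_max`` (default 0.05), both bounds inclusive.

The test itself is a desk-scale NB Wald test: library sizes are removed with
median-of-ratios size factors; a per-gene dispersion is estimated by the
method of moments and shrunk 50/50 toward the mean dispersion of similarly
expressed genes (a mean-expression trend over quantile bins); the Wald
statistic for the log2 fold change is referred to the standard normal, the
usual reference for moderated NB Wald tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import select_samples

logger = logging.getLogger("polyhet")

DISPERSION_FLOOR = 1e-4
PSEUDOCOUNT = 0.5
_TREND_BINS = 20


@dataclass(frozen=True)
class DegThresholds:
    """Dual DEG criterion: fold change >= fc_min and FDR <= fdr_max."""

    fc_min: float = 2.0
    fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over samples,
    computed on genes with no zero count; each sample's factor is the median
    of its ratios to the reference.
    """
    values = counts.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "normalization is undefined (consider a CPM-style fallback)")
    logs = np.log(values[usable])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def qc_replicates(counts: pd.DataFrame, design: pd.DataFrame,
                  min_corr: float = 0.8) -> list[str]:
    """Retain samples whose best within-group Pearson correlation passes.

    Correlations are computed on log2(normalized count + 1) within each
    (ploidy, role, stage) replicate group.  A sample is dropped when its
    maximum correlation with the other members of its group is below
    ``min_corr`` — but a group is never reduced below two retained
    replicates (a warning is emitted instead).
    """
    if min_corr <= 0:
        return list(counts.columns)
    norm = np.log2(normalized_counts(counts) + 1.0)
    retained: list[str] = []
    for _, group in design.groupby(["ploidy", "role", "stage"], sort=False):
        members = [s for s in group.index if s in norm.columns]
        if len(members) < 2:
            retained.extend(members)
            continue
        corr = norm[members].corr(method="pearson")
        np.fill_diagonal(corr.values, np.nan)
        max_corr = corr.max(axis=1)
        keep = [s for s in members if max_corr[s] >= min_corr]
        if len(keep) < 2:
            # keep the two most correlated samples rather than break testing
            ranked = max_corr.sort_values(ascending=False).index.tolist()
            keep = sorted(set(keep) | set(ranked[:2]), key=members.index)
            warnings.warn(
                f"replicate group {tuple(group.iloc[0][['ploidy', 'role', 'stage']])} "
                f"would fall below 2 replicates at min_corr={min_corr}; "
                "keeping the best-correlated pair", stacklevel=2)
        dropped = set(members) - set(keep)
        if dropped:
            logger.warning("QC dropped samples %s (max within-group r < %.3g)",
                           sorted(dropped), min_corr)
        retained.extend(keep)
    return [s for s in counts.columns if s in set(retained)]


def _resolve_group(design: pd.DataFrame,
                   group: Mapping[str, str] | Sequence[str]) -> list[str]:
    if isinstance(group, Mapping):
        samples = select_samples(design, **group)
    else:
        samples = list(group)
        missing = set(samples) - set(design.index)
        if missing:
            raise ValueError(f"samples not in design: {sorted(missing)}")
    if not samples:
        raise ValueError(f"group selects no samples: {group!r}")
    return samples


def test_contrast(counts: pd.DataFrame, design: pd.DataFrame,
                  group_a: Mapping[str, str] | Sequence[str],
                  group_b: Mapping[str, str] | Sequence[str],
                  factors: pd.Series | None = None) -> pd.DataFrame:
    """NB Wald test of group_a vs group_b for every gene.

    ``group_a``/``group_b`` are either explicit sample-id sequences or
    design filters like ``{"role": "hybrid", "ploidy": "4x", "stage":
    "meiosis"}``.  Returns a frame indexed by gene with columns ``mean_a``,
    ``mean_b`` (normalized group means), ``log2fc``
    (= log2((mean_a + 0.5) / (mean_b + 0.5))), ``p_raw``, ``q_fdr`` and
    ``tested``.  Genes with zero counts in every sample of both groups are
    excluded from the test (tested = False, statistics NaN) and from the BH
    family.
    """
    samples_a = _resolve_group(design, group_a)
    samples_b = _resolve_group(design, group_b)
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    if factors is None:
        factors = size_factors(counts)
    norm = (counts / factors).to_numpy(dtype=float)
    cols = list(counts.columns)
    ia = [cols.index(s) for s in samples_a]
    ib = [cols.index(s) for s in samples_b]
    ya, yb = norm[:, ia], norm[:, ib]
    na, nb = len(ia), len(ib)

    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    var_a, var_b = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)

    tested = (counts[samples_a + samples_b].to_numpy().sum(axis=1)) > 0

    # method-of-moments dispersion pooled over the two groups
    num = (na - 1) * (var_a - mean_a) + (nb - 1) * (var_b - mean_b)
    den = (na - 1) * mean_a ** 2 + (nb - 1) * mean_b ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(den > 0, np.clip(num / den, 0.0, None), 0.0)

    # mean-expression trend: mean raw dispersion within quantile bins
    overall = (na * mean_a + nb * mean_b) / (na + nb)
    alpha = np.full(len(overall), DISPERSION_FLOOR)
    if tested.sum() > 0:
        log_mean = np.log2(overall[tested] + PSEUDOCOUNT)
        n_bins = min(_TREND_BINS, max(1, tested.sum() // 10))
        ranks = pd.qcut(pd.Series(log_mean), q=n_bins, labels=False,
                        duplicates="drop")
        trend = pd.Series(alpha_raw[tested]).groupby(ranks).transform("mean")
        shrunk = 0.5 * alpha_raw[tested] + 0.5 * trend.to_numpy()
        alpha[tested] = np.clip(shrunk, DISPERSION_FLOOR, None)

    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    # delta-method variance of the log-mean difference under Var = mu + a*mu^2
    var_log = ((1.0 / (mean_a + PSEUDOCOUNT) + alpha) / na
               + (1.0 / (mean_b + PSEUDOCOUNT) + alpha) / nb)
    se_log2 = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2 > 0, log2fc / se_log2, 0.0)
    p_raw = 2.0 * sps.norm.sf(np.abs(z))

    q = np.full(len(p_raw), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p_raw[tested])

    result = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "p_raw": np.where(tested, p_raw, np.nan), "q_fdr": q,
        "tested": tested,
    }, index=counts.index)
    result.index.name = "gene_id"
    return result


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value in BH input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(result: pd.DataFrame,
              thresholds: DegThresholds = DegThresholds()) -> pd.DataFrame:
    """Apply the inclusive dual criterion to a contrast result.

    Returns a frame (gene_id, direction, log2fc, q_fdr) for genes with
    |log2fc| >= log2(fc_min) and q_fdr <= fdr_max; direction is ``up`` when
    group_a exceeds group_b.
    """
    lfc_min = np.log2(thresholds.fc_min)
    tested = result["tested"] if "tested" in result else pd.Series(True, index=result.index)
    mask = (tested
            & (result["log2fc"].abs() >= lfc_min)
            & (result["q_fdr"] <= thresholds.fdr_max))
    calls = result.loc[mask, ["log2fc", "q_fdr"]].copy()
    calls["direction"] = np.where(calls["log2fc"] > 0, "up", "down")
    calls = calls.reset_index().rename(columns={"index": "gene_id"})
    return calls[["gene_id", "direction", "log2fc", "q_fdr"]]


def relative_expression_ddct(ct_target_sample: float, ct_ref_sample: float,
                             ct_target_calibrator: float,
                             ct_ref_calibrator: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator; the result is 2**(-ddCt).
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator,
              ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = ((ct_target_sample - ct_ref_sample)
            - (ct_target_calibrator - ct_ref_calibrator))
    return float(2.0 ** (-ddct))
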