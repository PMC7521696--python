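"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-ploidy (2x diploid, 4x autotetraploid) anther
RNA-seq design with a maternal line, a paternal line and their F1 hybrid,
sampled at two developmental stages (meiosis and single microspore) with
three biological replicates each.  Counts are negative-binomial around
planted per-gene group means; a chosen fraction of genes carries one of the
five expression-dominance patterns (additive, high-/low-parent expression
level dominance, transgressive up/down), the rest are conserved.  Ground
truth — the planted group label and the true log2 group means — is returned
alongside the counts so that recovery tests can compare calls with truth.

Everything is driven by a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed``: identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PATTERN_GROUPS = (
    "additive",
    "hp_eld",
    "lp_eld",
    "transgressive_up",
    "transgressive_down",
)

#: Default planted-pattern fractions.  The mix is deliberately skewed the way
#: observed dominance spectra in polyploid hybrids are: transgressive
#: down-regulation dominates, additive and transgressive up-regulation are
#: rare.  About a third of genes carry some pattern; the rest are conserved.
DEFAULT_PATTERN_FRACTIONS: Mapping[str, float] = {
    "additive": 0.01,
    "hp_eld": 0.04,
    "lp_eld": 0.07,
    "transgressive_up": 0.01,
    "transgressive_down": 0.20,
}


class ConfigurationError(ValueError):
    """An invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic hybrid-transcriptome experiment.

    Parameters
    ----------
    n_genes:
        Number of simulated genes.
    n_replicates:
        Biological replicates per (ploidy, stage, role) group.
    stages, ploidies:
        Stage and ploidy labels to simulate.
    baseline_log_mean, baseline_log_sd:
        Per-gene baseline expression is drawn Normal(mean, sd) on the log2
        scale; the defaults give a realistic spread over ~4 orders of
        magnitude around a mean count of 2**7 = 128.
    dispersion:
        Negative-binomial dispersion alpha in Var = mu + alpha * mu**2.
    libsize_cv:
        Coefficient of variation of log-normal library-size factors
        (renormalised to geometric mean 1).
    pattern_fractions:
        Fraction of genes planted with each dominance pattern; the remainder
        is conserved.  Fractions must sum to <= 1.
    effect_log2fc:
        Planted |log2 fold change| (>= 1).  Parents of additive/ELD genes are
        separated by this amount; transgressive hybrids sit this far outside
        both parents.
    seed:
        Seed for the single RNG that drives every draw.
    """

    n_genes: int
    n_replicates: int = 3
    stages: Sequence[str] = ("meiosis", "single_microspore")
    ploidies: Sequence[str] = ("2x", "4x")
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 2.0
    dispersion: float = 0.1
    libsize_cv: float = 0.3
    pattern_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_FRACTIONS))
    effect_log2fc: float = 2.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be >= 0")
        if not (0 <= self.libsize_cv < 1):
            raise ConfigurationError("libsize_cv must be in [0, 1)")
        if self.effect_log2fc < 1:
            raise ConfigurationError("effect_log2fc must be >= 1")
        unknown = set(self.pattern_fractions) - set(PATTERN_GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown pattern groups: {sorted(unknown)}")
        if any(f < 0 for f in self.pattern_fractions.values()):
            raise ConfigurationError("pattern fractions must be >= 0")
        if sum(self.pattern_fractions.values()) > 1 + 1e-12:
            raise ConfigurationError("pattern fractions sum to > 1")


@dataclass
class SimExperiment:
    """Counts, design, truth labels and true log2 means of one simulation."""

    counts: pd.DataFrame          # genes x samples, int
    design: pd.DataFrame          # sample -> ploidy/role/stage/replicate
    truth: pd.Series              # gene -> planted pattern group (or conserved)
    true_log2_means: pd.DataFrame  # genes x (maternal, paternal, hybrid)
    config: SimConfig


def assign_patterns(n_genes: int, fractions: Mapping[str, float],
                    rng: np.random.Generator) -> pd.Series:
    """Assign pattern groups to genes: seeded shuffle, then contiguous blocks.

    Genes are permuted once with ``rng``; the first ``floor(f_g * n)`` genes
    of the permuted order go to each group ``g`` (in the canonical
    :data:`PATTERN_GROUPS` order), the remainder is labelled ``conserved``.
    """
    gene_ids = [f"g{i:06d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    labels = np.array(["conserved"] * n_genes, dtype=object)
    pos = 0
    for group in PATTERN_GROUPS:
        k = int(np.floor(fractions.get(group, 0.0) * n_genes))
        labels[perm[pos:pos + k]] = group
        pos += k
    return pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"),
                     name="group")


def _true_means(truth: pd.Series, config: SimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene true log2 means for maternal / paternal / hybrid."""
    n = len(truth)
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    # which parent is the high one, per gene (planted symmetrically)
    high_is_maternal = rng.random(n) < 0.5
    e = config.effect_log2fc
    half = e / 2.0

    mat = base.copy()
    pat = base.copy()
    hyb = base.copy()
    groups = truth.to_numpy()

    sep = np.isin(groups, ("additive", "hp_eld", "lp_eld"))
    sign = np.where(high_is_maternal, 1.0, -1.0)
    mat[sep] = base[sep] + sign[sep] * half
    pat[sep] = base[sep] - sign[sep] * half

    hyb[groups == "additive"] = base[groups == "additive"]  # mid-parent
    hi = np.where(high_is_maternal, mat, pat)
    lo = np.where(high_is_maternal, pat, mat)
    hyb[groups == "hp_eld"] = hi[groups == "hp_eld"]
    hyb[groups == "lp_eld"] = lo[groups == "lp_eld"]
    hyb[groups == "transgressive_up"] = base[groups == "transgressive_up"] + e
    hyb[groups == "transgressive_down"] = base[groups == "transgressive_down"] - e

    return pd.DataFrame(
        {"maternal": mat, "paternal": pat, "hybrid": hyb}, index=truth.index)


def _libsize_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv ** 2))
    raw = rng.lognormal(0.0, sigma, size=n)
    return raw / np.exp(np.mean(np.log(raw)))  # geometric mean 1


def generate_experiment(config: SimConfig) -> SimExperiment:
    """Simulate counts, design and truth for the full factorial design.

    Counts for sample j of role r are NB with mean
    ``libsize_factor_j * 2**true_log2_mean[gene, r]`` and dispersion
    ``config.dispersion``.  The same per-gene pattern (and true means) is
    realised in every (ploidy, stage) block.
    """
    rng = np.random.default_rng(config.seed)
    truth = assign_patterns(config.n_genes, config.pattern_fractions, rng)
    means = _true_means(truth, config, rng)

    sample_ids: list[str] = []
    design_rows: list[dict] = []
    for ploidy in config.ploidies:
        for stage in config.stages:
            for role in ("maternal", "paternal", "hybrid"):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{ploidy}_{stage}_{role}_r{rep}"
                    sample_ids.append(sid)
                    design_rows.append({"sample_id": sid, "ploidy": ploidy,
                                        "role": role, "stage": stage,
                                        "replicate": rep})
    design = pd.DataFrame(design_rows).set_index("sample_id")

    factors = _libsize_factors(len(sample_ids), config.libsize_cv, rng)
    r_shape = 1.0 / config.dispersion
    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        role = design.loc[sid, "role"]
        mu = factors[j] * np.exp2(means[role].to_numpy())
        p = r_shape / (r_shape + mu)
        counts[:, j] = rng.negative_binomial(r_shape, p)

    counts_df = pd.DataFrame(counts, index=truth.index, columns=sample_ids)
    return SimExperiment(counts=counts_df, design=design, truth=truth,
                         true_log2_means=means, config=config)


def generate_annotation(n_genes: int, n_chromosomes: int, chrom_length: int,
                        seed: int = 17, gene_ids: Sequence[str] | None = None,
                        min_len: int = 500, max_len: int = 5000) -> pd.DataFrame:
    """Place one interval per gene uniformly on random chromosomes.

    Returns a gene-annotation frame (gene_id, chrom, start, end, strand) in
    0-based half-open coordinates, all intervals within [0, chrom_length).
    """
    if max_len >= chrom_length:
        raise ValueError("chrom_length too small for the requested gene lengths")
    if min_len < 1 or min_len > max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:06d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("len(gene_ids) != n_genes")
    chroms = rng.integers(1, n_chromosomes + 1, size=n_genes)
    lengths = rng.integers(min_len, max_len + 1, size=n_genes)
    starts = rng.integers(0, chrom_length - lengths)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    return pd.DataFrame({
        "gene_id": list(gene_ids),
        "chrom": [f"chr{c}" for c in chroms],
        "start": starts.astype(np.int64),
        "end": (starts + lengths).astype(np.int64),
        "strand": strands,
    })


def generate_qtls(traits: Sequence[str], per_trait: int, n_chromosomes: int,
                  chrom_length: int, seed: int = 17,
                  min_len: int = 50_000, max_len: int = 500_000) -> pd.DataFrame:
    """QTL intervals per trait, uniform on random chromosomes.

    Returns a frame (qtl_id, trait, chrom, start, end) in 0-based half-open
    coordinates.  An empty trait list yields an empty frame.
    """
    if per_trait < 1:
        raise ValueError("per_trait must be positive")
    if max_len >= chrom_length:
        raise ValueError("chrom_length too small for the requested QTL lengths")
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        slug = "".join(ch if ch.isalnum() else "_" for ch in trait)
        for i in range(per_trait):
            length = int(rng.integers(min_len, max_len + 1))
            chrom = int(rng.integers(1, n_chromosomes + 1))
            start = int(rng.integers(0, chrom_length - length))
            rows.append({"qtl_id": f"q_{slug}_{i + 1}", "trait": trait,
                         "chrom": f"chr{chrom}", "start": start,
                         "end": start + length})
    return pd.DataFrame(rows, columns=["qtl_id", "trait", "chrom", "start", "end"])


def generate_cytology_counts(true_rate: float, n_cells: int,
                             seed: int = 17) -> tuple[int, int]:
    """Binomial cell-scoring counts: (number of normal cells, total cells)."""
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError("true_rate must be in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_cells, true_rate)), int(n_cells)
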