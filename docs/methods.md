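# Methods

## Setting

The package analyses a hybrid/parent trio (maternal line, paternal line, F1
hybrid) observed at two ploidy levels (diploid 2x, autotetraploid 4x) and
two anther developmental stages (meiosis, single microspore), with
biological replicates of gene-level RNA-seq counts. The questions it
answers: which genes does the hybrid express differently from its parents;
which of those are specific to the autotetraploid; what mode of inheritance
does each show; which are plausible heterosis genes; where do they fall
relative to yield QTLs; and how strong is the phenotype-level heterosis.

## Heterosis indices

For a trait with hybrid mean F1 and parent means P1, P2:

    MPH = 100 · (F1 − MP) / MP,  MP = (P1 + P2) / 2
    HPH = 100 · (F1 − HP) / HP,  HP = max(P1, P2)

Since HP ≥ MP always, HPH ≤ MPH for positive parent means (property-tested).
"Best parent" is the algebraic maximum for every trait, even where a lower
value is agronomically preferable — a documented caveat, not a bug. Values
are kept at full precision internally and rounded to two decimals only in
reporting tables, so printed values carry no accumulated rounding error.

## Differential expression

The DEG definition is the dual inclusive criterion: fold change ≥ 2 **and**
BH-FDR ≤ 0.05. The test behind it is deliberately desk-scale:

* **Normalization** — median-of-ratios to the per-gene geometric-mean
  reference, computed over genes with no zero count, factors rescaled to
  geometric mean 1. Multiplying a sample by a constant moves its factor by
  that constant (before rescale) and leaves fold changes unchanged
  (tested).
* **Replicate QC** — Pearson correlation on log2(normalized + 1) within
  each (ploidy, role, stage) group; a replicate whose best within-group
  correlation falls below 0.8 (default) is dropped, but never below two
  retained replicates per group (a warning is emitted instead). A
  threshold of 0 disables filtering.
* **Dispersion** — per-gene method-of-moments estimate of the NB
  dispersion α (Var = μ + αμ²) pooled over the two groups, then shrunk
  50/50 toward the mean dispersion of similarly expressed genes (up to 20
  quantile bins of mean expression), floored at 1e-4. With n = 3 the raw
  estimate is extremely noisy; the trend shrinkage is what makes the Wald
  statistic usable at this scale.
* **Test** — Wald statistic for the log2 fold change
  log2((m_a + 0.5)/(m_b + 0.5)) with delta-method standard error
  sqrt((1/m_a + α)/n_a + (1/m_b + α)/n_b)/ln 2, referred to the standard
  normal (the usual convention for moderated NB Wald tests; a t reference
  with n_a + n_b − 2 degrees of freedom is far too conservative once the
  dispersion is moderated — measured type-I error 0.013 vs the nominal
  0.05). Under the generator's null the empirical type-I error at nominal
  0.05 is ≈ 0.06.
* **Pseudocount 0.5** in the fold-change means stabilizes zeros; genes
  with zero counts in every sample of both groups are excluded from the
  test and from the BH family (the family is the tested hypotheses).
* **FDR** — Benjamini–Hochberg per contrast, not pooled across contrasts,
  matching per-comparison DEG counting. The implementation delegates to
  statsmodels and is tested against a hand-written step-up oracle.

Not modelled: covariates/batch, exact NB tests, isoform-level effects.

## DEG set algebra

DEGs_HP is the **union** of the two hybrid-parent call sets (a gene counted
once even when both contrasts call it, consistent with combined counts
being smaller than the sum of the parts). Direction is ignored in set
membership. The autotetraploid-specific set is DEGs_HP(4x) \ DEGs_HP(2x)
computed on a shared gene universe; the pipeline logs the universe size.

## Dominance classification

Each hybrid-parent DEG is summarised by three significance calls, each
using the same dual FC/FDR criterion (not raw p-values), giving a
27-combination space that the decision table maps onto twelve patterns in
five groups:

| group | calls (F1/P1, F1/P2, P1/P2) | patterns |
|---|---|---|
| additive | (−,+,+), (+,−,−) | I–II |
| hp_eld | (0,+,+), (+,0,−) | III–IV |
| lp_eld | (0,−,−), (−,0,+) | V–VI |
| transgressive_up | (+,+,·) | VII–IX |
| transgressive_down | (−,−,·) | X–XII |

Everything else — including the all-nonsignificant combination and the
cyclically contradictory triples noise can produce — is unclassified, and
unclassified genes are excluded from the percentage denominator.
The parent ordering needed by the additive/ELD rows comes from the sign of
the parent-parent call, so the classification is invariant under parent
relabelling (property-tested over all 27 combinations). Group percentages
are reported to two decimals; heterosis candidates are the union of the
hp_eld and transgressive_up genes, and cross-stage candidates are the
intersection across the two stages.

A boundary effect worth knowing: when the planted parental separation is e
on the log2 scale, an additive hybrid sits e/2 from each parent. With the
default e = 2 that distance is exactly the FC ≥ 2 gate, so roughly half of
a true additive gene's hybrid-parent contrasts fail the gate and the gene
is then called ELD or left unclassified. Additive calls are therefore
conservative near the gate — in real data as in simulation.

## Cytology and proportions

Pollen fertility and normal-cell frequencies are plain percentages;
pooling across meiotic stages uses summed counts, never the mean of
percentages. Genotype comparisons use the two-proportion chi-square test
with continuity correction (Fisher's exact on request for small counts);
degenerate margins return p = 1 with a warning.

## Gene-to-QTL mapping

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and the QTL table convert at the I/O boundary only. A hit is any ≥ 1 bp
same-chromosome overlap — genes at a QTL border should not vanish on a
containment convention. Implementation uses per-chromosome interval trees
and is tested against vectorised all-pairs brute force at 10⁴ genes ×
10³ QTLs. Per-trait summaries deduplicate genes within a trait but not
across traits.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) (scipy,
stable in log space; tested against exact PMF summation) with BH within
one namespace per call. The universe defaults to the genes tested in the
relevant DE contrasts rather than the whole genome, the standard guard
against expression-ascertainment bias. Terms with fewer than 3 universe
genes are not tested. Both raw p and q are reported, so either cut-off
convention can be applied downstream. No GO DAG propagation and no ranked
(GSEA-style) statistics.

## Synthetic data generator

The generator emulates the assumed experimental design: 2 ploidies × 2
stages × 3 roles × 3 replicates of NB counts.

* Per-gene baseline log2 mean ~ Normal(7, 2) — counts around 128 with a
  realistic several-order-of-magnitude spread.
* Dispersion default 0.1 (recovery simulations use 0.05 where stated);
  library-size factors log-normal with CV 0.3, renormalized to geometric
  mean 1, matching the normalization model.
* Pattern assignment: genes shuffled once with the seeded RNG, contiguous
  blocks of the permuted order assigned per fraction (auditable and
  re-implementable in tests). Default fractions mirror the skewed
  dominance spectrum reported for polyploid hybrid anthers —
  transgressive-down heavy, additive and transgressive-up rare:
  additive 0.01, hp_eld 0.04, lp_eld 0.07, transgressive_up 0.01,
  transgressive_down 0.20, remainder conserved.
* Planted means (log2 scale): additive hybrids at the parental midpoint
  with parents split by effect_log2fc (default 2); ELD hybrids equal to
  one parent; transgressive hybrids effect_log2fc outside both parents.
  True means and labels are returned for white-box recovery tests.
* Everything flows from one `numpy.random.Generator`; identical configs
  give byte-identical output (tested).

What the generator does **not** emulate — hence what passing recovery
tests do not establish about real data: GC/length biases, batch structure,
correlated genes, ploidy-dependent expression changes (patterns are planted
identically in both ploidies, so simulated ploidy-specific sets reflect
detection noise rather than biology), allele-dosage effects, and isoform
complexity. Sizes used in the standard test run (10,000-gene null, 2,000
gene recovery, 200-rep power checks) were chosen as comfortable desk-scale
defaults with tight binomial error on the measured rates.

## qRT-PCR helper

`de.relative_expression_ddct` implements relative expression
2^−ΔΔCt = 2^−((Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator)
for validating sequencing-based fold changes against qPCR.

## Known limitations

* The DE test is a moderated Wald approximation, not a likelihood-ratio or
  exact NB test; with two replicates per group after QC it is anti-
  conservative at extreme fold changes of very low-count genes.
* Additive classification is conservative near the FC gate (see above).
* QTL mapping assumes both inputs share one genome build; no liftover.
* Enrichment treats terms independently (no DAG-aware correction).
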