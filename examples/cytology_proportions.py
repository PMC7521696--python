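"""Normal-cell frequencies across meiotic stages and a proportion test.

Simulated cell-scoring counts for a hybrid and a parent: the pooled
frequency uses summed counts (not the mean of stage percentages), and the
chi-square test with continuity correction compares the two genotypes.
"""

from polyhet import simulate, stats

stages = ("metaphase_I", "anaphase_I", "metaphase_II", "anaphase_II")
hybrid, parent = [], []
for i, stage in enumerate(stages):
    n, t = simulate.generate_cytology_counts(0.93, 400, seed=100 + i)
    hybrid.append(stats.CytologySummary(stage, n, t))
    n, t = simulate.generate_cytology_counts(0.85, 400, seed=200 + i)
    parent.append(stats.CytologySummary(stage, n, t))

table = stats.cytology_table({"AF1": hybrid, "T449": parent})
print(table.to_string(index=False))

h_norm = sum(s.normal for s in hybrid)
h_tot = sum(s.total for s in hybrid)
p_norm = sum(s.normal for s in parent)
p_tot = sum(s.total for s in parent)
diff, p = stats.compare_proportions(h_norm, h_tot, p_norm, p_tot)
print(f"\nhybrid - parent normal-cell difference: {diff:.2f} points, "
      f"p = {p:.2e}")
print("A positive difference with small p indicates fewer chromosomal")
print("abnormalities in the hybrid than in its parent.")
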