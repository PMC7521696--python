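"""Hypergeometric over-representation of a gene set.

A term covering genes drawn preferentially into the query set should float
to the top with a small BH-corrected q; unrelated background terms should
not.
"""

import numpy as np

from polyhet import enrich
from polyhet.io import TermAnnotation

rng = np.random.default_rng(17)
universe = [f"g{i}" for i in range(1000)]

annotation = TermAnnotation("GO-BP", {
    "GO:0006520": frozenset(universe[:60]),    # amino-acid metabolism (planted)
    **{f"GO:00000{i:02d}": frozenset(rng.choice(universe, 60, replace=False))
       for i in range(8)},
}, term_names={"GO:0006520": "amino acid metabolic process"})

# query set: half from the planted term, half random
gene_set = set(universe[:40]) | set(rng.choice(universe[200:], 40,
                                               replace=False))
result = enrich.enrich(gene_set, annotation, universe)
print(result.to_string(index=False))
print()
print("k of K term genes appear among the n query genes (universe N);")
print("'fold' is k over its expectation, p_raw the hypergeometric upper")
print("tail and q_fdr the BH-corrected value within this namespace.")
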