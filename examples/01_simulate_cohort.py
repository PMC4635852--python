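"""Generate a synthetic expression cohort with planted ground truth.

The cohort mimics a small biopsy study: two molecular subtypes of 14
samples each, 3 outlier samples, 8 controls, and 2000 genes of which a
core class (100 genes) is shifted in both subtypes versus control and two
unique classes (60 each) are shifted in only one subtype.
"""

from collections import Counter

from txsubtypes import SyntheticConfig, generate

matrix, truth = generate(SyntheticConfig(seed=1))

print(f"matrix: {matrix.n_genes} genes x {matrix.n_samples} samples")
print("groups:", dict(Counter(matrix.groups.values())))
print("planted gene classes:", dict(Counter(truth.gene_class.values())))
print("planted outliers:", truth.outliers)
print("subtype sizes:", dict(Counter(truth.subtype.values())))
# The outliers belong to the case cohort, so the 31 TCMR samples hide
# 14 + 14 clusterable samples plus 3 aberrant ones the pipeline must drop.
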