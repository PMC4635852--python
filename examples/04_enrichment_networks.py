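"""Gene-set over-representation and interaction networks per gene list.

Run the hypergeometric test of each planted gene list against a gene-set
collection (reported at p < 0.01 with >= 2 overlapping genes), build the
pathway-overlap graph (edges need >= 30% shared genes), and induce the
regulatory and drug-target modules anchored on the list.
"""

from txsubtypes import (
    SyntheticConfig, generate, generate_genesets, generate_interactions,
    InteractionTable, partition_genes, run_three_way,
)

matrix, truth = generate(SyntheticConfig(seed=1))
collection = generate_genesets(truth, n_decoy_sets=5, seed=1)
interactions = generate_interactions(truth, seed=1)
tables = {k: InteractionTable(interactions.of_kind(k))
          for k in ("ppi", "regulatory", "drug_target")}

part = partition_genes(
    set(truth.core_genes) | set(truth.unique_a_genes),
    set(truth.core_genes) | set(truth.unique_b_genes))
results = run_three_way(part, collection, tables,
                        universe=list(truth.gene_class))

for name, result in results.items():
    top = result.enrichment.hits.head(1)
    set_id = top.index[0]
    print(f"{name}: top enriched set {set_id} "
          f"(p = {top['p'].iloc[0]:.2e}, q = {top['q'].iloc[0]:.2e}, "
          f"{int(top['n_overlap'].iloc[0])} shared genes)")
    reg = result.modules["regulatory"]
    tfs = sorted(n for n, d in reg.nodes(data=True) if d["type"] == "tf")
    drugs = sorted(n for n, d in result.modules["drug_target"].nodes(data=True)
                   if d["type"] == "drug")
    print(f"  regulators attached: {tfs}; drugs attached: {drugs}")
# Each list's own planted set dominates its enrichment, and module
# induction attaches exactly the planted per-class regulator and drug.
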