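"""Test a shared-gene list for pathway enrichment.

Genes extracted from cross-population modules are tested against a
user-supplied gene-set collection with a one-sided hypergeometric test
and Benjamini-Hochberg FDR control.
"""

import modbridge as mb

universe = [f"g{i:03d}" for i in range(200)]
collection = mb.GeneSetCollection({
    "amyloid_processing": ("toy pathway", universe[:20]),
    "lipid_transport": ("toy pathway", universe[20:45]),
    "synaptic_function": ("toy pathway", universe[45:80]),
})

# pretend these genes came out of the cross-population rotation:
# 8 of 12 fall in the first pathway
shared_genes = universe[:8] + universe[100:104]

result = mb.enrich_hypergeometric(shared_genes, collection, universe)
print(result.round(5).to_string(index=False))
# p is the upper-tail hypergeometric probability of seeing at least the
# observed overlap by chance given the universe; q corrects across sets.
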