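"""Discover dense disease modules in one simulated population.

Builds a synthetic three-population study with one planted 10-gene
disease module, runs covariate adjustment, moderated-t differential
expression and the greedy dense-module search for a single population,
and prints the retained modules next to the planted truth.
"""

import modbridge as mb

bundle = mb.simulate_study(mb.SimConfig(seed=42))
pop = "White"
expr, samples = bundle.expression[pop], bundle.samples[pop]
print(f"population {pop}: {expr.n_genes} genes x {expr.n_samples} samples")

adj = mb.adjust_covariates(expr, samples)          # sex, age, 4 PCs
de = mb.differential_expression(adj, samples)      # moderated t per gene
weights = mb.pvals_to_weights(de)                  # z = Phi^-1(1 - p)

modules, _ = mb.dense_module_search(
    bundle.graph, weights, mb.SearchConfig(n_perm=1000, seed=42),
    population=pop,
)

truth = set(bundle.truth["modules"][0]["members"])
effect = set(bundle.truth["modules"][0]["effect_genes"][pop])
print(f"planted module: {sorted(truth)}")
print(f"  genes carrying the case shift in {pop}: {sorted(effect)}\n")
print(f"{len(modules)} modules retained (top 1% by normalized score, perm p < 0.05):")
for m in modules:
    hits = len(m.members & truth)
    print(f"  seed {m.seed_gene}  k={m.k}  Z_m={m.raw_score:6.2f}  "
          f"Z_N={m.normalized_score:6.2f}  p={m.perm_p:.4f}  "
          f"planted members: {hits}/{m.k}")
# A high Z_N with p = 1/(n_perm+1) means the module outscored every
# size-matched random gene set; modules seeded in the planted region
# should collect this population's effect genes.
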