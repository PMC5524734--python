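"""Rank candidate SNPs by three discrimination procedures and build a panel.

A 120-SNP candidate panel with a discovery-like allele-frequency
spectrum is ranked by (i) per-locus Weir-Cockerham theta across
full-sib families, (ii) minor allele frequency, and (iii) random-forest
Gini importance for predicting the cross of origin.  The best 12
assayable loci (at most one per gene) form the working panel.
"""

import numpy as np

import pedtrace as pt

rng = np.random.default_rng(5)
freqs = np.clip(rng.beta(0.5, 2.0, size=120), 0.01, 0.5)
spec = pt.PopulationSpec(n_parents=73, n_loci=120, n_crosses=68,
                         allele_freqs=list(freqs), seed=5)
parents, design, _ = pt.generate_population(spec)
progeny, truth = pt.simulate_progeny_dataset(parents, design, n_per_cross=20, seed=6)
labels = truth["cross_id"].to_numpy()

rankings = {
    "fst": pt.rank_by_fst(progeny, labels),
    "maf": pt.rank_by_maf(parents),
    "rf": pt.rank_by_rf_importance(progeny, labels, n_trees=500, seed=5),
}
k = 12
for name, r in rankings.items():
    print(f"{name:>3} top-{k}: {', '.join(r.top(k)[:6])} ...")
shared = set(rankings["fst"].top(k)) & set(rankings["maf"].top(k)) \
    & set(rankings["rf"].top(k))
print(f"loci shared by all three top-{k} lists: {len(shared)}")

# platform constraints: some loci are not assayable, some share a gene
panel = pt.SNPPanel(
    rankings["rf"].locus_ids,
    gene_ids=[f"g{int(j) // 2}" for j in range(120)],  # two SNPs per gene
    assayable=rng.random(120) > 0.2,
)
chosen = pt.select_top_k(rankings["rf"], k, panel)
print(f"selected panel ({len(chosen)} loci): {', '.join(chosen)}")
# the walk skips unassayable loci and second SNPs within a gene, so the
# final panel trades a little raw importance for platform feasibility
# and low between-marker linkage.
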