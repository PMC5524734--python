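"""Per-locus informativeness statistics and the panel non-exclusion.

Computes the per-SNP summary a parentage study reports (MAF, observed
and expected heterozygosity, PIC, parent-pair non-exclusion NE-PP) for
a simulated parent panel, and shows the same arithmetic on the shipped
published 36-SNP table: the product of its printed NE-PP column gives
the panel-level probability (~3.1e-5) of failing to exclude a random
unrelated parent pair.
"""

import pedtrace as pt

parents = pt.generate_parents(
    pt.generate_allele_frequencies(
        pt.PopulationSpec(n_parents=73, n_loci=8, n_crosses=10, seed=3)
    ),
    n_parents=73, seed=4,
)
summary = pt.locus_summary(parents)
print(summary.round(3).to_string(index=False))
print(f"combined NE-PP of this 8-locus panel: "
      f"{pt.combined_nepp(summary['nepp']):.2e}")

table1 = pt.load_table1_fixture()
print(f"\npublished 36-SNP panel: combined NE-PP = "
      f"{pt.combined_nepp(table1['nepp']):.1e}")
# per-locus NE-PP is the HWE-weighted mass of Mendelian-compatible
# parent-pair x offspring genotype combinations; the smaller the product,
# the harder it is for an unrelated pair to pass as parents by chance.
print(f"NE-PP at allele frequency 0.5 (most informative case): "
      f"{pt.nepp_locus(0.5):.5f}")
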