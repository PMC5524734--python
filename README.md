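# pedtrace

SNP-based pedigree traceability for closed breeding programs that
multiply selected genotypes clonally — the motivating case is somatic
embryogenesis in white spruce, where elite parents are crossed under
control, embryogenic cell lines are cryopreserved, and any mislabelled
tissue is propagated *ad infinitum*. `pedtrace` provides the full
analytical pipeline such a program needs:

* **simulate** full-sib progeny genotypes over a mating design from the
  parents' SNP genotypes (Mendelian gamete sampling, unlinked loci);
* **rank and select** maximally informative SNP subsets by three
  discrimination procedures — per-locus Weir–Cockerham
  F<sub>ST</sub> across full-sib families, minor allele frequency, and
  random-forest Gini importance — under platform constraints
  (assayability, one SNP per gene);
* **assign** individuals to their cross of origin by Mendelian
  exclusion with an allele-mismatch tolerance, and by a likelihood
  model Σ<sub>loci</sub> log[(1−ε)·T(g<sub>o</sub>|g<sub>m</sub>,g<sub>f</sub>) + ε·P<sub>HWE</sub>(g<sub>o</sub>)];
* **quantify robustness** by injecting exact fractions of missing data
  and genotyping errors and measuring wrong / ambiguous / unassigned
  rates;
* **fingerprint** clonal lines (one symbol per locus, `A`/`H`/`B`/`?`),
  match with mismatch and missing-data tolerance, detect duplicates,
  and diagnose at which production stage (breeding, propagation,
  cryobank) an error entered.

Per-locus informativeness follows the standard parentage statistics:
expected heterozygosity He = 2pq, polymorphic information content
PIC = 2pq − 2p²q², and the Jamieson–Taylor parent-pair non-exclusion
probability NE-PP, computed here by exhaustive enumeration of the
3×3×3 parent-pair × offspring genotype table under Hardy–Weinberg
weights (the published closed form is kept as an independent
cross-check). Across independent loci the panel-level non-exclusion is
the product of per-locus values.

## Worked example

```python
import pedtrace as pt

spec = pt.PopulationSpec(n_parents=73, n_loci=36, n_crosses=68, seed=1)
parents, design, freqs = pt.generate_population(spec)
progeny, truth = pt.simulate_progeny_dataset(parents, design, n_per_cross=20, seed=2)

excl = pt.exclusion_assign(progeny, parents, design, tolerance_alleles=1)
lik  = pt.likelihood_assign(progeny, parents, design, epsilon=0.01)
print(pt.evaluate_assignment(excl, truth)[0])
```

Running `python examples/01_simulate_and_assign.py` prints:

```
73 parents, 68 crosses, 1360 simulated offspring at 36 loci
 exclusion: wrong 0.00%  ambiguous 1.10%  unassigned 0.00%
likelihood: wrong 0.22%  ambiguous 0.00%  unassigned 0.00%
```

On clean data the exclusion method never assigns wrongly (the true
cross always has zero mismatches); its 1.1% ambiguity comes from
offspring compatible with a second, parent-sharing cross — reported,
never silently resolved. The likelihood method breaks those ties but
can genuinely prefer a wrong cross whose expected genotype
distribution concentrates on the observed genotypes, hence its small
wrong rate. Under genotyping errors the picture reverses: a single
miscalled homozygote (allele distance 2) exceeds the exclusion
tolerance, while the ε-contamination term keeps the likelihood method
on target (see `examples/04_robustness_grid.py`).

The other `examples/` scripts cover panel statistics, marker
selection, the robustness grid, and cell-line certification. A thin
CLI mirrors the workflows:

```sh
pedtrace simulate --parents 73 --crosses 68 --loci 36 --offspring 100 \
    --seed 1 --out-prefix run1
pedtrace assign --method both --offspring run1.progeny.tsv \
    --parents run1.parents.tsv --design run1.design.tsv \
    --truth run1.truth.tsv run1.assign.tsv
```

## Layout

```
src/pedtrace/    library (data model, simulation, perturbation, stats,
                 selection, assignment, fingerprinting, pipelines, CLI)
tests/           pytest suite (unit, property-based, acceptance)
examples/        narrative scripts, one per capability
docs/methods.md  models, assumptions, parameter choices, limitations
```
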