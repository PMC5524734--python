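"""Fingerprint clonal lines and locate the stage of a planted error.

Each embryogenic cell line is represented by a cryobank tissue sample
and a field tree that should carry the same multilocus genotype.  One
line is deliberately mislabelled with the wrong putative cross (same
mother, different father — the signature of pollen contamination); the
certification workflow flags it and places the error at the breeding
stage.
"""

import numpy as np
import pandas as pd

import pedtrace as pt

parents, design, _ = pt.generate_population(
    pt.PopulationSpec(n_parents=16, n_loci=36, n_crosses=14, seed=9)
)
progeny, truth = pt.simulate_progeny_dataset(parents, design, n_per_cross=2, seed=10)

ids, rows, roles, lines, crosses = [], [], [], [], []
for k, (ind, cross) in enumerate(zip(truth["individual_id"], truth["cross_id"])):
    for role, suffix in (("cryobank_tissue", "c"), ("field_tree", "t")):
        ids.append(f"{ind}{suffix}")
        rows.append(progeny.row(ind).copy())
        roles.append(role)
        lines.append(f"LN{k:03d}")
        crosses.append(cross)
samples = pt.GenotypeMatrix(ids, list(parents.locus_ids), np.array(rows), roles)
putative = pd.DataFrame({"individual_id": ids, "line_id": lines,
                         "cross_id": crosses, "role": roles})

# mislabel one line: same mother, different father
victim_line, wrong = next(
    (line, other.cross_id)
    for line, grp in putative.groupby("line_id")
    for other in design
    if other.mother_id == design[grp["cross_id"].iloc[0]].mother_id
    and other.cross_id != grp["cross_id"].iloc[0]
)
putative.loc[putative["line_id"] == victim_line, "cross_id"] = wrong

report = pt.run_certification(samples, parents, design, putative)
print("stage counts:", report["stage_counts"])
bad = report["line_diagnoses"].query("stage != 'clean'")
print(bad.to_string(index=False))

fps = pt.fingerprints_from_matrix(samples)
dup = pt.find_duplicate_fingerprints(fps)
print(f"duplicate fingerprint groups: {len(dup.groups)} "
      "(cryobank/field copies of one line share a genotype by construction)")
print(f"fingerprint space at 36 SNPs: 3^36 = {pt.fingerprint_space(36):.2e} codes")
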