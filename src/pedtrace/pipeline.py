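"""End-to-end workflows: panel design, robustness grid, certification.

These orchestrate the lower-level modules into the three studies a
traceability program actually runs:

* :func:`run_panel_design` — simulate progeny over the mating design,
  rank candidate SNPs by one (or all) discrimination procedures, apply
  the platform constraints and report the selected panel's statistics;
* :func:`run_robustness_grid` — measure wrong/ambiguous/unassigned
  assignment percentages of both assignment methods over a grid of
  missing-data and genotyping-error rates;
* :func:`run_certification` — screen a batch of real or simulated
  samples: missingness filter, dual assignment, problem-parent
  classification, fingerprint matching and per-line stage diagnosis.

Every entry point returns its results together with a manifest (inputs,
seeds, parameters, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assignment import (
    classify_against_putative,
    evaluate_assignment,
    exclusion_assign,
    likelihood_assign,
)
from .crosses import simulate_progeny_dataset
from .fingerprint import (
    CellLineRecord,
    Fingerprint,
    LineMember,
    build_fingerprint,
    diagnose_cell_line,
    fingerprints_from_matrix,
    match_fingerprint,
)
from ._seeds import as_seedseq
from .matrix import (
    GenotypeMatrix,
    MatingDesign,
    SNPPanel,
    filter_individuals_by_missingness,
)
from .perturb import inject_combined
from .selection import (
    MarkerRanking,
    rank_by_fst,
    rank_by_maf,
    rank_by_rf_importance,
    select_top_k,
)
from .stats import combined_nepp, locus_summary

#: the benchmark perturbation grid: baseline, five missing-only levels,
#: five error-only levels and five paired combinations (percent scale)
DEFAULT_GRID: list[tuple[float, float]] = (
    [(0.0, 0.0)]
    + [(m, 0.0) for m in (3.5, 7.0, 10.0, 13.5, 17.0)]
    + [(0.0, e) for e in (0.5, 1.0, 2.0, 3.0, 5.0)]
    + [(3.5, 0.5), (7.0, 1.0), (10.0, 2.0), (13.5, 3.0), (17.0, 5.0)]
)


def run_robustness_grid(
    parents: GenotypeMatrix,
    design: MatingDesign,
    grid: Optional[Sequence[tuple[float, float]]] = None,
    n_reps: int = 5,
    n_per_cross: int = 100,
    seed: int = 0,
    tolerance_alleles: int = 1,
    epsilon: float = 0.01,
    methods: Sequence[str] = ("exclusion", "likelihood"),
) -> tuple[pd.DataFrame, dict]:
    """Assignment-robustness experiment over a perturbation grid.

    For each replicate a fresh progeny dataset is simulated; for each
    (missing %, error %) cell it is perturbed and assigned by each
    method, and scored against the simulation truth.  Rates in the grid
    are percentages.  Returns a long-format table with one row per
    (replicate, cell, method) and the run manifest.
    """
    grid = list(DEFAULT_GRID if grid is None else grid)
    rep_seeds = as_seedseq(seed).spawn(n_reps)
    rows = []
    for rep, rep_ss in enumerate(rep_seeds):
        sim_ss, perturb_root = rep_ss.spawn(2)
        progeny, truth = simulate_progeny_dataset(
            parents, design, n_per_cross=n_per_cross, seed=sim_ss
        )
        cell_streams = perturb_root.spawn(len(grid))
        for (miss_pct, err_pct), cell_ss in zip(grid, cell_streams):
            perturbed = inject_combined(
                progeny, miss_pct / 100.0, err_pct / 100.0, cell_ss
            )
            for method in methods:
                if method == "exclusion":
                    res = exclusion_assign(
                        perturbed, parents, design, tolerance_alleles
                    )
                elif method == "likelihood":
                    res = likelihood_assign(
                        perturbed, parents, design, epsilon=epsilon
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
                overall, _ = evaluate_assignment(res, truth)
                rows.append(
                    {
                        "replicate": rep,
                        "missing_pct": miss_pct,
                        "error_pct": err_pct,
                        "method": method,
                        **{k: v for k, v in overall.items() if k != "n"},
                        "n_individuals": overall["n"],
                    }
                )
    table = pd.DataFrame(rows)
    manifest = {
        "workflow": "robustness_grid",
        "version": __version__,
        "seed": seed,
        "n_reps": n_reps,
        "n_per_cross": n_per_cross,
        "grid": grid,
        "tolerance_alleles": tolerance_alleles,
        "epsilon": epsilon,
        "methods": list(methods),
        "n_parents": parents.n_individuals,
        "n_crosses": design.n_crosses,
        "n_loci": parents.n_loci,
    }
    return table, manifest


def run_panel_design(
    parents: GenotypeMatrix,
    design: MatingDesign,
    panel: Optional[SNPPanel] = None,
    procedure: str = "rf",
    k: int = 40,
    n_per_cross: int = 100,
    n_trees: int = 10_000,
    seed: int = 0,
) -> dict:
    """Four-step panel design: simulate, rank, constrain, select.

    All three rankings are computed so the report can show their
    overlap in the top-k; the panel itself is assembled from the
    requested ``procedure``.  The report carries the selected loci,
    their summary statistics on the parent panel, the panel-level
    combined non-exclusion probability, and the manifest.
    """
    sim_ss, rf_ss = as_seedseq(seed).spawn(2)
    progeny, truth = simulate_progeny_dataset(
        parents, design, n_per_cross=n_per_cross, seed=sim_ss
    )
    labels = truth["cross_id"].to_numpy()
    rankings: dict[str, MarkerRanking] = {
        "fst": rank_by_fst(progeny, labels),
        "maf": rank_by_maf(parents),
        "rf": rank_by_rf_importance(progeny, labels, n_trees=n_trees, seed=seed),
    }
    if procedure not in rankings:
        raise ValueError(f"unknown procedure {procedure!r}")
    selected = select_top_k(rankings[procedure], k, panel)
    tops = {name: set(r.top(k)) for name, r in rankings.items()}
    overlap = {
        "fst_maf": len(tops["fst"] & tops["maf"]),
        "fst_rf": len(tops["fst"] & tops["rf"]),
        "maf_rf": len(tops["maf"] & tops["rf"]),
        "all_three": len(tops["fst"] & tops["maf"] & tops["rf"]),
    }
    summary = locus_summary(parents.subset(loci=selected))
    return {
        "selected_loci": selected,
        "procedure": procedure,
        "rankings": rankings,
        "top_k_overlap": overlap,
        "locus_summary": summary,
        "combined_nepp": combined_nepp(summary["nepp"]),
        "manifest": {
            "workflow": "panel_design",
            "version": __version__,
            "seed": seed,
            "procedure": procedure,
            "k": k,
            "n_per_cross": n_per_cross,
            "n_trees": n_trees,
            "n_parents": parents.n_individuals,
            "n_crosses": design.n_crosses,
            "n_candidate_loci": parents.n_loci,
        },
    }


def run_certification(
    samples: GenotypeMatrix,
    parents: GenotypeMatrix,
    design: MatingDesign,
    putative: pd.DataFrame,
    fingerprint_db: Optional[Sequence[tuple[str, str, Fingerprint]]] = None,
    max_missing_fraction: float = 0.15,
    tolerance_alleles: int = 1,
    epsilon: float = 0.01,
    max_mismatch: int = 1,
) -> dict:
    """Certify a batch of samples against their putative crosses.

    ``putative`` needs columns ``individual_id``, ``line_id``,
    ``cross_id`` and ``role`` (cryobank_tissue / field_tree).  Per
    sample: missingness filter, exclusion assignment, likelihood
    confirmation (disagreements between the two methods are flagged for
    manual review), parent-error classification against the putative
    cross, and optional fingerprint match against a database.  Samples
    are then grouped by cell line and each line's error stage is
    diagnosed.
    """
    required = {"individual_id", "line_id", "cross_id", "role"}
    if not required <= set(putative.columns):
        raise ValueError(f"putative table needs columns {sorted(required)}")
    kept = filter_individuals_by_missingness(samples, max_missing_fraction)
    dropped = sorted(set(samples.individual_ids) - set(kept.individual_ids))
    put = putative[putative["individual_id"].isin(kept.individual_ids)]

    excl = exclusion_assign(kept, parents, design, tolerance_alleles)
    lik = likelihood_assign(kept, parents, design, epsilon=epsilon)
    cls = classify_against_putative(kept, parents, design, put, tolerance_alleles)

    per_sample = (
        excl.rename(
            columns={"status": "excl_status", "assigned_cross": "excl_cross"}
        )[["individual_id", "excl_status", "excl_cross", "mismatch_alleles"]]
        .merge(
            lik.rename(
                columns={"status": "lik_status", "assigned_cross": "lik_cross"}
            )[["individual_id", "lik_status", "lik_cross", "loglik_best",
               "loglik_second"]],
            on="individual_id",
        )
        .merge(cls, on="individual_id")
        .merge(put, on="individual_id")
    )
    both_assigned = (per_sample["excl_status"] == "assigned") & (
        per_sample["lik_status"] == "assigned"
    )
    per_sample["methods_discordant"] = both_assigned & (
        per_sample["excl_cross"] != per_sample["lik_cross"]
    )
    per_sample["legitimate"] = (
        (per_sample["excl_status"] == "assigned")
        & (per_sample["excl_cross"] == per_sample["cross_id"])
        & ~per_sample["methods_discordant"]
    )

    fps = {fp.individual_id: fp for fp in fingerprints_from_matrix(kept)}
    if fingerprint_db is not None:
        db_fps = [fp for _, _, fp in fingerprint_db]
        matches = {
            ind: match_fingerprint(fp, db_fps, max_mismatch=max_mismatch)
            for ind, fp in fps.items()
        }
    else:
        matches = {}

    diagnoses = []
    for line_id, group in per_sample.groupby("line_id"):
        members = [
            LineMember(
                fingerprint=fps[r.individual_id],
                role=r.role,
                legitimate=bool(r.legitimate),
                parent_error_class=r.parent_error_class,
            )
            for r in group.itertuples(index=False)
        ]
        record = CellLineRecord(
            line_id=str(line_id),
            putative_cross=str(group["cross_id"].iloc[0]),
            members=members,
        )
        diagnoses.append(diagnose_cell_line(record))
    diag_df = pd.DataFrame(
        {
            "line_id": [d.line_id for d in diagnoses],
            "stage": [d.stage for d in diagnoses],
            "subclass": [d.subclass for d in diagnoses],
            "warning": [d.warning for d in diagnoses],
        }
    )
    stage_counts = diag_df["stage"].value_counts().to_dict()
    return {
        "per_sample": per_sample,
        "line_diagnoses": diag_df,
        "stage_counts": stage_counts,
        "n_problematic_lines": int((diag_df["stage"] != "clean").sum()),
        "dropped_for_missingness": dropped,
        "fingerprint_matches": matches,
        "manifest": {
            "workflow": "certification",
            "version": __version__,
            "max_missing_fraction": max_missing_fraction,
            "tolerance_alleles": tolerance_alleles,
            "epsilon": epsilon,
            "max_mismatch": max_mismatch,
            "n_samples_in": samples.n_individuals,
            "n_samples_kept": kept.n_individuals,
            "n_crosses": design.n_crosses,
        },
    }
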