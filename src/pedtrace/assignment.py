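"""Assignment of offspring to their cross of origin.

Two complementary methods over a closed mating design:

* **Exclusion**: count, per candidate cross, the minimum number of
  allele substitutions that would make the offspring genotype
  Mendelian-compatible with the parent pair, summed across loci.  A
  cross is a candidate if this total is within an allele-mismatch
  tolerance (default 1 allele, summed over loci — a single homozygote
  miscall of distance 2 already exceeds it, which is exactly why pure
  exclusion is fragile under genotyping error).
* **Likelihood**: per-locus mixture (1 - eps) * Mendelian transmission
  + eps * Hardy–Weinberg, summed as log-likelihood over loci; the
  offspring is allocated to the argmax cross.  The contamination term
  keeps a single incompatible locus from vetoing the true cross.

Missing offspring genotypes are uninformative in both methods (zero
mismatches, likelihood factor 1).  Ambiguity — several crosses tied at
the optimum — is always reported as a status, never broken by id order
or randomness: a traceability verdict must be certain or flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .crosses import transmission_table
from .matrix import MISSING, GenotypeMatrix, MatingDesign

_T = transmission_table()

#: statuses an individual can receive
STATUSES = ("assigned", "ambiguous", "unassigned")

#: problematic-parent classes
ERROR_CLASSES = ("correct_pair", "wrong_father", "wrong_mother", "wrong_both",
                 "undetermined")


def _mismatch_table() -> np.ndarray:
    """M[g_m, g_f, g_o]: min allele substitutions in g_o for compatibility.

    Allele distance between genotype codes (B-allele counts) a and b is
    |a - b|; the entry is the minimum distance from g_o to any genotype
    with positive transmission probability under (g_m, g_f).
    """
    m = np.zeros((3, 3, 3), dtype=np.int8)
    for gm in range(3):
        for gf in range(3):
            compat = [go for go in range(3) if _T[gm, gf, go] > 0]
            for go in range(3):
                m[gm, gf, go] = min(abs(go - c) for c in compat)
    return m


_M = _mismatch_table()


def locus_mismatch(g_o: int, g_m: int, g_f: int) -> int:
    """Allele mismatch count {0, 1, 2} for one offspring locus.

    A missing offspring genotype is uninformative and contributes 0;
    missing parental genotypes are an error (candidate panels exclude
    them by construction).
    """
    if g_m == MISSING or g_f == MISSING:
        raise ValueError("parental genotypes must be non-missing")
    if g_o == MISSING:
        return 0
    return int(_M[g_m, g_f, g_o])


def _cross_parent_codes(
    parents: GenotypeMatrix, design: MatingDesign
) -> tuple[np.ndarray, np.ndarray]:
    """(n_crosses, n_loci) maternal and paternal genotype arrays."""
    design.validate_against(parents)
    gm = np.stack([parents.row(c.mother_id) for c in design])
    gf = np.stack([parents.row(c.father_id) for c in design])
    if (gm == MISSING).any() or (gf == MISSING).any():
        raise ValueError("parents referenced by the design must be fully genotyped")
    return gm, gf


def mismatch_totals(
    offspring: GenotypeMatrix, parents: GenotypeMatrix, design: MatingDesign
) -> np.ndarray:
    """(n_individuals, n_crosses) total allele mismatches."""
    gm, gf = _cross_parent_codes(parents, design)
    obs = offspring.genotypes
    informative = obs != MISSING
    obs_safe = np.where(informative, obs, 0)
    n_ind, n_loci = obs.shape
    totals = np.zeros((n_ind, design.n_crosses), dtype=np.int32)
    cols = np.arange(n_loci)
    for k in range(design.n_crosses):
        per_locus = _M[gm[k], gf[k]]          # (n_loci, 3) rows per locus
        vals = per_locus[cols[None, :], obs_safe]  # (n_ind, n_loci)
        totals[:, k] = np.where(informative, vals, 0).sum(axis=1)
    return totals


def exclusion_assign(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    design: MatingDesign,
    tolerance_alleles: int = 1,
) -> pd.DataFrame:
    """Exclusion-based assignment with an allele-mismatch tolerance.

    Candidate crosses are those whose total mismatch is within the
    tolerance (counted in alleles summed across loci).  The individual
    is ``assigned`` if a unique cross attains the minimum total among
    candidates, ``ambiguous`` if several tie, ``unassigned`` if no
    candidate exists.

    Returns a frame with one row per individual: ``individual_id``,
    ``status``, ``assigned_cross``, ``mismatch_alleles`` (the minimum
    total), ``n_candidates``.
    """
    if tolerance_alleles < 0:
        raise ValueError("tolerance must be >= 0")
    totals = mismatch_totals(offspring, parents, design)
    cross_ids = np.asarray(design.cross_ids, dtype=object)
    best = totals.min(axis=1)
    n_cand = (totals <= tolerance_alleles).sum(axis=1)
    n_best = (totals == best[:, None]).sum(axis=1)

    status = np.where(
        best > tolerance_alleles,
        "unassigned",
        np.where(n_best == 1, "assigned", "ambiguous"),
    )
    assigned = np.where(
        status == "assigned", cross_ids[totals.argmin(axis=1)], None
    )
    return pd.DataFrame(
        {
            "individual_id": offspring.individual_ids,
            "status": status,
            "assigned_cross": assigned,
            "mismatch_alleles": best,
            "n_candidates": n_cand,
        }
    )


def _hwe_geno_probs(freqs: np.ndarray) -> np.ndarray:
    """(3, n_loci) HWE genotype probabilities from A-allele frequencies."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return np.stack([p * p, 2 * p * q, q * q])


def likelihood_of_cross(
    g_offspring: np.ndarray,
    g_mother: np.ndarray,
    g_father: np.ndarray,
    freqs: np.ndarray,
    epsilon: float = 0.01,
) -> float:
    """Log-likelihood of one cross for one offspring genotype vector.

    Sum over non-missing loci of
    log[(1 - eps) * T(g_o | g_m, g_f) + eps * P_HWE(g_o)].
    With ``epsilon=0`` an incompatible locus makes the result -inf.
    """
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    g_o = np.asarray(g_offspring)
    hwe = _hwe_geno_probs(freqs)
    keep = g_o != MISSING
    idx = np.flatnonzero(keep)
    go = g_o[idx]
    t = _T[np.asarray(g_mother)[idx], np.asarray(g_father)[idx], go]
    per = (1.0 - epsilon) * t + epsilon * hwe[go, idx]
    with np.errstate(divide="ignore"):
        return float(np.log(per).sum())


def likelihood_assign(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    design: MatingDesign,
    freqs: Optional[np.ndarray] = None,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Likelihood-based allocation to the argmax candidate cross.

    ``freqs`` are the A-allele frequencies parameterising the
    contamination term; by default they are estimated from the parent
    panel.  Returns one row per individual with ``status``,
    ``assigned_cross``, ``loglik_best`` and ``loglik_second`` (their
    difference is the confidence margin).  Exact ties are ``ambiguous``.
    """
    from .stats import allele_freqs  # local import to avoid a cycle

    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    if freqs is None:
        freqs = allele_freqs(parents)
    gm, gf = _cross_parent_codes(parents, design)
    hwe = _hwe_geno_probs(freqs)  # (3, n_loci)
    obs = offspring.genotypes
    informative = obs != MISSING
    obs_safe = np.where(informative, obs, 0)
    n_ind, n_loci = obs.shape
    cols = np.arange(n_loci)
    loglik = np.empty((n_ind, design.n_crosses))
    with np.errstate(divide="ignore"):
        for k in range(design.n_crosses):
            t = _T[gm[k], gf[k]]              # (n_loci, 3)
            per = (1.0 - epsilon) * t[cols[None, :], obs_safe] \
                + epsilon * hwe[obs_safe, cols[None, :]]
            contrib = np.where(informative, np.log(per), 0.0)
            loglik[:, k] = contrib.sum(axis=1)
    order = np.argsort(-loglik, axis=1, kind="stable")
    best_idx = order[:, 0]
    best = loglik[np.arange(n_ind), best_idx]
    second = (
        loglik[np.arange(n_ind), order[:, 1]]
        if design.n_crosses > 1
        else np.full(n_ind, -np.inf)
    )
    ties = (loglik == best[:, None]).sum(axis=1) > 1
    all_impossible = np.isneginf(best)
    status = np.where(
        all_impossible, "unassigned", np.where(ties, "ambiguous", "assigned")
    )
    cross_ids = np.asarray(design.cross_ids, dtype=object)
    assigned = np.where(status == "assigned", cross_ids[best_idx], None)
    return pd.DataFrame(
        {
            "individual_id": offspring.individual_ids,
            "status": status,
            "assigned_cross": assigned,
            "loglik_best": best,
            "loglik_second": second,
        }
    )


def _single_parent_mismatch(g_o: np.ndarray, g_p: np.ndarray) -> int:
    """Alleles to change in the offspring to share one allele with a parent.

    Only opposite homozygotes (AA vs BB) conflict; each such locus
    costs one substitution.  Missing calls on either side are skipped.
    """
    g_o = np.asarray(g_o)
    g_p = np.asarray(g_p)
    keep = (g_o != MISSING) & (g_p != MISSING)
    return int((np.abs(g_o[keep] - g_p[keep]) == 2).sum())


def classify_parentage_error(
    g_offspring: np.ndarray,
    g_mother: np.ndarray,
    g_father: np.ndarray,
    tolerance_alleles: int = 1,
) -> str:
    """Diagnose which parent of a failed cross is problematic.

    Each parent is tested for single-parent compatibility (offspring
    shares at least one allele at every mutually non-missing locus,
    within the same allele tolerance).  Mother ok / father not ->
    ``wrong_father``; father ok / mother not -> ``wrong_mother``;
    neither -> ``wrong_both``; both compatible -> ``undetermined``
    (the pairwise failure cannot be pinned on a single parent).
    """
    mom_ok = _single_parent_mismatch(g_offspring, g_mother) <= tolerance_alleles
    dad_ok = _single_parent_mismatch(g_offspring, g_father) <= tolerance_alleles
    if mom_ok and not dad_ok:
        return "wrong_father"
    if dad_ok and not mom_ok:
        return "wrong_mother"
    if not mom_ok and not dad_ok:
        return "wrong_both"
    return "undetermined"


def classify_against_putative(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    design: MatingDesign,
    putative: pd.DataFrame,
    tolerance_alleles: int = 1,
) -> pd.DataFrame:
    """Vector version: classify each individual against its putative cross.

    ``putative`` maps ``individual_id`` to ``cross_id``.  Individuals
    whose genotype is fully compatible with the putative pair get
    ``correct_pair``.
    """
    lut = dict(zip(putative["individual_id"], putative["cross_id"]))
    rows = []
    for ind in offspring.individual_ids:
        cross = design[lut[ind]]
        g_o = offspring.row(ind)
        g_m = parents.row(cross.mother_id)
        g_f = parents.row(cross.father_id)
        pair_total = int(
            sum(locus_mismatch(o, m, f) for o, m, f in zip(g_o, g_m, g_f))
        )
        if pair_total <= tolerance_alleles:
            cls = "correct_pair"
        else:
            cls = classify_parentage_error(g_o, g_m, g_f, tolerance_alleles)
        rows.append({"individual_id": ind, "parent_error_class": cls})
    return pd.DataFrame(rows)


def evaluate_assignment(
    results: pd.DataFrame, truth: pd.DataFrame
) -> tuple[dict, pd.DataFrame]:
    """Score assignment results against a truth table.

    Wrong = assigned to a cross different from the true one.  Returns
    an overall dict with percentages over *all* individuals
    (``wrong_pct`` + ``correct_pct`` + ``ambiguous_pct`` +
    ``unassigned_pct`` = 100), plus ``wrong_pct_of_assigned`` over
    assigned individuals only, and a per-true-cross breakdown frame.
    """
    merged = results.merge(truth, on="individual_id", how="left", validate="1:1")
    if merged["cross_id"].isna().any():
        missing = merged.loc[merged["cross_id"].isna(), "individual_id"].iloc[0]
        raise ValueError(f"truth table lacks individual {missing!r}")
    n = len(merged)
    is_assigned = merged["status"] == "assigned"
    wrong = is_assigned & (merged["assigned_cross"] != merged["cross_id"])
    correct = is_assigned & ~wrong
    amb = merged["status"] == "ambiguous"
    unas = merged["status"] == "unassigned"
    overall = {
        "n": n,
        "wrong_pct": 100.0 * wrong.sum() / n,
        "correct_pct": 100.0 * correct.sum() / n,
        "ambiguous_pct": 100.0 * amb.sum() / n,
        "unassigned_pct": 100.0 * unas.sum() / n,
        "wrong_pct_of_assigned": (
            100.0 * wrong.sum() / is_assigned.sum() if is_assigned.any() else 0.0
        ),
    }
    merged["outcome"] = np.select(
        [wrong, correct, amb, unas],
        ["wrong", "correct", "ambiguous", "unassigned"],
        default="unassigned",
    )
    per_cross = (
        merged.groupby("cross_id")["outcome"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .mul(100.0)
        .rename_axis(index="cross_id")
        .reset_index()
    )
    return overall, per_cross
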