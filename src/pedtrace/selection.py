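"""Marker-informativeness ranking and constrained panel assembly.

Three discrimination procedures rank candidate SNPs by how well they
separate full-sib families: per-locus Weir–Cockerham theta across
families, minor allele frequency (closer to 0.5 is better), and Gini
importance from a random-forest classifier trained to predict the cross
of origin from genotype codes.  Panel assembly then walks a ranking
best-first under platform constraints (assayability, at most one SNP
per gene).

All ties break lexicographically on locus id so every ranking is
reproducible; the forest procedure is additionally seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, SNPPanel
from .stats import allele_freqs, fst_per_locus, minor_allele_freq


@dataclass
class MarkerRanking:
    """Ordered loci (best first) with per-locus scores.

    ``procedure`` is one of ``fst``, ``maf``, ``rf``.  For ``fst`` and
    ``rf`` higher scores are better; for ``maf`` the score is the
    distance |MAF - 0.5| and lower is better.
    """

    locus_ids: list[str]
    scores: np.ndarray
    procedure: str

    def top(self, k: int) -> list[str]:
        return self.locus_ids[:k]


def _order(locus_ids, scores, descending: bool) -> MarkerRanking:
    key = pd.DataFrame({"locus_id": list(locus_ids), "score": np.asarray(scores, float)})
    key = key.sort_values(
        ["score", "locus_id"], ascending=[not descending, True], kind="mergesort"
    )
    return key


def _require_complete(m: GenotypeMatrix, who: str) -> None:
    if (m.genotypes == MISSING).any():
        raise ValueError(
            f"{who} requires complete genotypes; filter or impute missing calls first"
        )


def rank_by_fst(progeny: GenotypeMatrix, truth_labels) -> MarkerRanking:
    """Rank loci by descending per-locus theta across full-sib families."""
    df = fst_per_locus(progeny, truth_labels)
    ordered = _order(df["locus_id"], df["theta"], descending=True)
    return MarkerRanking(list(ordered["locus_id"]), ordered["score"].to_numpy(), "fst")


def rank_by_maf(parents: GenotypeMatrix) -> MarkerRanking:
    """Rank loci by ascending |MAF - 0.5| on the parent panel.

    Parental frequencies determine the expected progeny frequencies, so
    this procedure needs no simulated offspring.
    """
    _require_complete(parents, "MAF ranking")
    maf = minor_allele_freq(allele_freqs(parents))
    dist = np.abs(maf - 0.5)
    ordered = _order(parents.locus_ids, dist, descending=False)
    return MarkerRanking(list(ordered["locus_id"]), ordered["score"].to_numpy(), "maf")


def rank_by_rf_importance(
    progeny: GenotypeMatrix,
    truth_labels,
    n_trees: int = 10_000,
    seed: int = 0,
) -> MarkerRanking:
    """Rank loci by random-forest Gini importance for cross-of-origin.

    Features are the numeric genotype codes 0/1/2; the target is the
    true cross label.  Importance is the mean decrease in Gini impurity
    across ``n_trees`` classification trees (default 10,000), so a
    constant locus scores exactly 0.
    """
    from sklearn.ensemble import RandomForestClassifier

    _require_complete(progeny, "random-forest ranking")
    y = np.asarray(truth_labels)
    if y.shape != (progeny.n_individuals,):
        raise ValueError("truth labels must align with individuals")
    if len(pd.unique(y)) < 2:
        raise ValueError("random-forest ranking needs at least two classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0]) % (2**31),
        n_jobs=1,
    )
    rf.fit(progeny.genotypes.astype(float), y)
    ordered = _order(progeny.locus_ids, rf.feature_importances_, descending=True)
    return MarkerRanking(list(ordered["locus_id"]), ordered["score"].to_numpy(), "rf")


def select_top_k(
    ranking: MarkerRanking,
    k: int,
    panel: Optional[SNPPanel] = None,
) -> list[str]:
    """Assemble a k-locus panel from a ranking under platform constraints.

    Walks the ranking best-first, skipping loci the platform cannot
    assay and loci whose gene is already represented (one SNP per gene
    minimises linkage between markers).  If the gene constraint alone
    prevents reaching ``k``, it is relaxed with a warning; if fewer than
    ``k`` assayable loci exist at all, that is an error.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if panel is None:
        if k > len(ranking.locus_ids):
            raise ValueError(f"k={k} exceeds {len(ranking.locus_ids)} candidates")
        return ranking.locus_ids[:k]
    assayable = {
        loc for loc, ok in zip(panel.locus_ids, panel.assayable) if ok
    }
    eligible = [loc for loc in ranking.locus_ids if loc in assayable]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} assayable loci in the ranking; cannot select {k}"
        )
    chosen: list[str] = []
    genes_used: set[str] = set()
    skipped_gene: list[str] = []
    for loc in eligible:
        gene = panel.gene_of(loc)
        if gene is not None and gene in genes_used:
            skipped_gene.append(loc)
            continue
        chosen.append(loc)
        if gene is not None:
            genes_used.add(gene)
        if len(chosen) == k:
            return chosen
    # gene constraint prevented reaching k: relax it in rank order
    warnings.warn(
        "one-SNP-per-gene constraint relaxed to reach the requested panel size"
    )
    for loc in skipped_gene:
        chosen.append(loc)
        if len(chosen) == k:
            break
    return chosen
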