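"""Per-locus and panel-level population-genetic statistics.

Covers the summary statistics a parentage study reports per SNP —
minor allele frequency, observed/expected heterozygosity, polymorphic
information content (PIC), the parent-pair non-exclusion probability
(NE-PP) of Jamieson & Taylor, their product across a panel — plus the
Weir–Cockerham fixation index across full-sib families used as a marker
discrimination score.

NE-PP is computed by exhaustive enumeration of the 3x3x3 parent-pair x
offspring genotype table under Hardy–Weinberg weights, which makes the
definition auditable; the published closed form is kept alongside as an
independent cross-check.
"""

from __future__ import annotations

import itertools
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .crosses import transmission_table
from .matrix import MISSING, GenotypeMatrix

_T = transmission_table()


def allele_freqs(m: GenotypeMatrix) -> np.ndarray:
    """Per-locus frequency of the A (reference) allele.

    p = (2 n_AA + n_AB) / (2 n_non-missing); missing calls are excluded
    from both numerator and denominator.  A locus with no non-missing
    genotype has no defined frequency and raises.
    """
    g = np.ma.masked_equal(m.genotypes, MISSING)
    n = (~g.mask).sum(axis=0) if g.mask is not np.ma.nomask else \
        np.full(m.n_loci, m.n_individuals)
    if (np.asarray(n) == 0).any():
        j = int(np.argmax(np.asarray(n) == 0))
        raise ValueError(f"locus {m.locus_ids[j]!r}: all genotypes missing")
    b_alleles = g.sum(axis=0).filled(0)  # code counts B alleles
    return 1.0 - b_alleles / (2.0 * np.asarray(n))


def minor_allele_freq(p) -> np.ndarray:
    """MAF = min(p, 1-p)."""
    p = np.asarray(p, dtype=float)
    return np.minimum(p, 1.0 - p)


def expected_heterozygosity(p):
    """He = 2p(1-p) (no small-sample correction; see methods note)."""
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p)


def pic(p):
    """Botstein polymorphic information content, biallelic form.

    PIC = 2pq - 2 p^2 q^2, the biallelic specialisation of
    1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 2.0 * p * q - 2.0 * p * p * q * q


def maf_from_he(he):
    """Minor allele frequency from He: smaller root of 2p(1-p) = He."""
    he = np.asarray(he, dtype=float)
    if ((he < 0) | (he > 0.5)).any():
        raise ValueError("He must lie in [0, 0.5] for a biallelic locus")
    return (1.0 - np.sqrt(1.0 - 2.0 * he)) / 2.0


def _hwe_weights(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([p * p, 2 * p * q, q * q])  # codes 0 (AA), 1, 2 count B


def nepp_locus(p: float) -> float:
    """Parent-pair non-exclusion probability by exhaustive enumeration.

    Probability that a random unrelated candidate pair (both parents and
    the offspring drawn independently from HWE at allele frequency
    ``p``) is *not* Mendelian-excluded as the offspring's parent pair:
    the HWE-weighted mass of the compatible cells of the 3x3x3 genotype
    table.  A monomorphic locus excludes nothing and returns 1 (with a
    warning).
    """
    if not 0 <= p <= 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    if p in (0.0, 1.0):
        warnings.warn("monomorphic locus: non-exclusion probability is 1")
        return 1.0
    w = _hwe_weights(p)
    total = 0.0
    for gm, gf, go in itertools.product(range(3), repeat=3):
        if _T[gm, gf, go] > 0:
            total += w[gm] * w[gf] * w[go]
    return total


def nepp_closed_form(p: float) -> float:
    """Jamieson–Taylor closed form for the parent-pair non-exclusion.

    1 - P3 with P3 = 1 + 4a4 - 4a5 - 3a6 - 8a2^2 + 8 a2 a3 + 2 a3^2,
    a_n = sum of allele frequencies to the n-th power.  Used as an
    independent cross-check of :func:`nepp_locus`.
    """
    ps = np.array([p, 1.0 - p])
    a = {n: float((ps ** n).sum()) for n in range(2, 7)}
    p3 = 1 + 4 * a[4] - 4 * a[5] - 3 * a[6] - 8 * a[2] ** 2 + 8 * a[2] * a[3] + 2 * a[3] ** 2
    return 1.0 - p3


def combined_nepp(nepp_values) -> float:
    """Panel-level non-exclusion: product across independent loci."""
    v = np.asarray(nepp_values, dtype=float)
    if ((v <= 0) | (v > 1)).any():
        raise ValueError("per-locus non-exclusion probabilities must lie in (0, 1]")
    return float(np.prod(v))


def locus_summary(m: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary table: maf, ho, he, pic, nepp.

    ``ho`` is the observed heterozygote fraction among non-missing
    calls; ``he``/``pic``/``nepp`` derive from the sample allele
    frequency.  Monomorphic loci get pic 0 and nepp 1 so they sort last
    in any informativeness ranking.
    """
    p = allele_freqs(m)
    miss = m.missing_mask()
    n_called = (~miss).sum(axis=0)
    ho = (m.genotypes == 1).sum(axis=0) / n_called
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nepp = np.array([nepp_locus(x) for x in p])
    return pd.DataFrame(
        {
            "locus_id": m.locus_ids,
            "maf": minor_allele_freq(p),
            "ho": ho,
            "he": expected_heterozygosity(p),
            "pic": pic(p),
            "nepp": nepp,
        }
    )


def load_table1_fixture() -> pd.DataFrame:
    """Published 36-SNP summary table shipped with the package.

    Columns: locus, snp_name, ho, he, pic, nepp.  Used by tests and the
    reproduction script as the reference for internal consistency of
    the He / PIC / NE-PP columns.
    """
    with resources.files("pedtrace.data").joinpath("table1_fixture.tsv").open("rt") as fh:
        return pd.read_csv(fh, sep="\t")


def fst_per_locus(m: GenotypeMatrix, family_labels) -> pd.DataFrame:
    """Weir–Cockerham theta per locus, full-sib families as demes.

    ``family_labels`` aligns with ``m.individual_ids``.  Returns a frame
    with columns ``locus_id``, ``theta`` and ``monomorphic``; loci that
    are monomorphic overall have no defined theta and are reported as 0
    with the flag set (so they rank last).  Requires at least two
    families with at least two genotyped individuals each.
    """
    labels = np.asarray(family_labels)
    if labels.shape != (m.n_individuals,):
        raise ValueError("family_labels must align with individuals")
    fams = pd.unique(labels)
    r = len(fams)
    if r < 2:
        raise ValueError("need at least two families")
    geno = m.genotypes
    masks = [labels == f for f in fams]
    for f, mk in zip(fams, masks):
        if mk.sum() < 2:
            raise ValueError(f"family {f!r} has fewer than two individuals")

    thetas = np.zeros(m.n_loci)
    mono = np.zeros(m.n_loci, dtype=bool)
    for j in range(m.n_loci):
        col = geno[:, j]
        ni, pi, hi = [], [], []
        for mk in masks:
            sub = col[mk]
            sub = sub[sub != MISSING]
            if sub.size == 0:
                continue
            ni.append(sub.size)
            pi.append(1.0 - sub.sum() / (2.0 * sub.size))  # A-allele freq
            hi.append(float((sub == 1).mean()))
        ni = np.asarray(ni, float)
        pi = np.asarray(pi, float)
        hi = np.asarray(hi, float)
        ri = ni.size
        nbar = ni.mean()
        pbar = (ni * pi).sum() / (ri * nbar)
        if pbar in (0.0, 1.0) or ri < 2 or nbar <= 1:
            mono[j] = pbar in (0.0, 1.0)
            thetas[j] = 0.0
            continue
        nc = (ri * nbar - (ni ** 2).sum() / (ri * nbar)) / (ri - 1)
        s2 = (ni * (pi - pbar) ** 2).sum() / ((ri - 1) * nbar)
        hbar = (ni * hi).sum() / (ri * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (ri - 1) / ri * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (ri - 1) / ri * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        thetas[j] = a / denom if denom != 0 else 0.0
    return pd.DataFrame({"locus_id": m.locus_ids, "theta": thetas, "monomorphic": mono})


def fst_overall(m: GenotypeMatrix, family_labels) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of summed components)."""
    labels = np.asarray(family_labels)
    fams = pd.unique(labels)
    masks = [labels == f for f in fams]
    num = den = 0.0
    geno = m.genotypes
    for j in range(m.n_loci):
        col = geno[:, j]
        ni, pi, hi = [], [], []
        for mk in masks:
            sub = col[mk]
            sub = sub[sub != MISSING]
            if sub.size:
                ni.append(sub.size)
                pi.append(1.0 - sub.sum() / (2.0 * sub.size))
                hi.append(float((sub == 1).mean()))
        ni = np.asarray(ni, float)
        pi = np.asarray(pi, float)
        hi = np.asarray(hi, float)
        ri = ni.size
        if ri < 2:
            continue
        nbar = ni.mean()
        if nbar <= 1:
            continue
        pbar = (ni * pi).sum() / (ri * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (ri * nbar - (ni ** 2).sum() / (ri * nbar)) / (ri - 1)
        s2 = (ni * (pi - pbar) ** 2).sum() / ((ri - 1) * nbar)
        hbar = (ni * hi).sum() / (ri * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (ri - 1) / ri * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (ri - 1) / ri * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        num += a
        den += a + b + c
    return num / den if den else 0.0
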