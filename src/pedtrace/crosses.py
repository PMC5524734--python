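"""Mendelian progeny simulation for controlled crosses.

Offspring genotypes at each locus are built by drawing one allele
uniformly from each parent's two alleles, independently across loci and
offspring (full-sib families, unlinked loci).  The same 3x3x3
transmission table drives both the simulator and the likelihood-based
assigner, so the two can never disagree about Mendelian support.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ._seeds import as_seedseq
from .matrix import MISSING, GenotypeMatrix, MatingDesign


def transmission_table() -> np.ndarray:
    """T[g_m, g_f, g_o]: offspring genotype probabilities per parent pair.

    Codes count B alleles; a parent with code c transmits B with
    probability c/2.  Entries are exact in binary floating point
    (multiples of 1/4), and each (g_m, g_f) row sums to exactly 1.
    """
    t = np.zeros((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            bm, bf = gm / 2.0, gf / 2.0
            t[gm, gf, 0] = (1 - bm) * (1 - bf)
            t[gm, gf, 1] = bm * (1 - bf) + (1 - bm) * bf
            t[gm, gf, 2] = bm * bf
    return t


_T = transmission_table()


def transmission_prob(g_o: int, g_m: int, g_f: int) -> float:
    """Probability of offspring genotype ``g_o`` from parents (g_m, g_f)."""
    for name, g in (("offspring", g_o), ("mother", g_m), ("father", g_f)):
        if g == MISSING:
            raise ValueError(f"missing {name} genotype has no transmission probability")
        if g not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {g} for {name}")
    return float(_T[g_m, g_f, g_o])


def simulate_offspring(
    g_mother: np.ndarray,
    g_father: np.ndarray,
    n: int,
    seed,
) -> np.ndarray:
    """Simulate ``n`` offspring genotype vectors for one cross.

    Returns an ``(n, n_loci)`` int8 array.  Parents must be fully
    genotyped (candidate panels are prefiltered to guarantee this).
    """
    g_mother = np.asarray(g_mother)
    g_father = np.asarray(g_father)
    if g_mother.shape != g_father.shape:
        raise ValueError("parent genotype vectors differ in length")
    if (g_mother == MISSING).any() or (g_father == MISSING).any():
        j = int(np.argmax((g_mother == MISSING) | (g_father == MISSING)))
        raise ValueError(f"missing parental genotype at locus index {j}")
    rng = np.random.default_rng(seed)
    pm = g_mother / 2.0  # P(transmit B) per locus
    pf = g_father / 2.0
    shape = (n, g_mother.size)
    allele_m = rng.random(shape) < pm[None, :]
    allele_f = rng.random(shape) < pf[None, :]
    return (allele_m.astype(np.int8) + allele_f.astype(np.int8))


def simulate_progeny_dataset(
    parents: GenotypeMatrix,
    design: MatingDesign,
    n_per_cross: int = 100,
    seed: int = 0,
    id_prefix: str = "O",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a full-sib progeny dataset over a mating design.

    Returns the progeny matrix and a separate truth table
    (``individual_id``, ``cross_id``); true origins are deliberately not
    encoded in the individual ids, so assignment code cannot read them.
    ``n_per_cross`` defaults to 100 offspring per cross.
    """
    design.validate_against(parents)
    streams = as_seedseq(seed).spawn(design.n_crosses)
    blocks: list[np.ndarray] = []
    truth_ids: list[str] = []
    truth_cross: list[str] = []
    counter = 0
    for c, ss in zip(design, streams):
        gm = parents.row(c.mother_id)
        gf = parents.row(c.father_id)
        blocks.append(simulate_offspring(gm, gf, n_per_cross, ss))
        for _ in range(n_per_cross):
            counter += 1
            truth_ids.append(f"{id_prefix}{counter:06d}")
            truth_cross.append(c.cross_id)
    geno = (
        np.concatenate(blocks, axis=0)
        if blocks and n_per_cross
        else np.empty((0, parents.n_loci), dtype=np.int8)
    )
    progeny = GenotypeMatrix(
        truth_ids, list(parents.locus_ids), geno, roles=["progeny"] * len(truth_ids)
    )
    truth = pd.DataFrame({"individual_id": truth_ids, "cross_id": truth_cross})
    return progeny, truth
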