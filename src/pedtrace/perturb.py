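"""Controlled injection of missing data and genotyping errors.

Perturbations use exact counts, not per-cell Bernoulli draws: a rate of
3.5% on a 100x36 matrix blanks exactly round(0.035 * 3600) = 126 cells,
sampled uniformly without replacement over the individual x locus grid.
This matches benchmark designs where each altered dataset carries a
fixed, known contamination level.  When errors and missingness are
combined, errors are applied first and missing cells are drawn from the
remaining cells, so a cell is never both erroneous and masked (masking
an error would silently lower the realised error rate).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np

from ._seeds import as_seedseq
from .matrix import MISSING, GenotypeMatrix

ErrorMode = Literal["genotype", "allele"]


def _cell_coords(flat: np.ndarray, n_loci: int) -> np.ndarray:
    """Flat indices -> (row, col) pairs, sorted for reproducible audits."""
    flat = np.sort(flat)
    return np.column_stack((flat // n_loci, flat % n_loci))


def inject_missing(
    m: GenotypeMatrix,
    rate: float,
    seed,
    return_cells: bool = False,
):
    """Blank an exact fraction of cells, uniformly over the whole grid."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    n_cells = m.n_individuals * m.n_loci
    count = round(rate * n_cells)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_cells, size=count, replace=False) if count else np.array([], int)
    out = m.copy()
    out.genotypes.reshape(-1)[chosen] = MISSING
    if return_cells:
        return out, _cell_coords(chosen, m.n_loci)
    return out


def inject_errors(
    m: GenotypeMatrix,
    rate: float,
    seed,
    mode: ErrorMode = "genotype",
    return_cells: bool = False,
):
    """Corrupt an exact fraction of cells with wrong genotype calls.

    Only non-missing cells are eligible; each altered cell ends up
    different from its original value.  Two error models:

    * ``"genotype"`` (default): replace by one of the two *other*
      genotype states, uniformly.
    * ``"allele"``: flip one of the two alleles (AA -> AB, BB -> AB,
      AB -> AA or BB with equal probability).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    n_cells = m.n_individuals * m.n_loci
    count = round(rate * n_cells)
    flat = m.genotypes.reshape(-1)
    eligible = np.flatnonzero(flat != MISSING)
    if count > eligible.size:
        raise ValueError(
            f"cannot corrupt {count} cells: only {eligible.size} non-missing cells"
        )
    rng = np.random.default_rng(seed)
    chosen = (
        rng.choice(eligible, size=count, replace=False) if count else np.array([], int)
    )
    out = m.copy()
    tgt = out.genotypes.reshape(-1)
    orig = tgt[chosen].astype(np.int8)
    if mode == "genotype":
        # original + 1 or 2 (mod 3) is always one of the two other states
        shift = rng.integers(1, 3, size=orig.size).astype(np.int8)
        tgt[chosen] = (orig + shift) % 3
    elif mode == "allele":
        new = orig.copy()
        new[orig == 0] = 1
        new[orig == 2] = 1
        hets = orig == 1
        new[hets] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(hets.sum()))
        tgt[chosen] = new
    else:
        raise ValueError(f"unknown error mode {mode!r}")
    if return_cells:
        return out, _cell_coords(chosen, m.n_loci)
    return out


def inject_combined(
    m: GenotypeMatrix,
    missing_rate: float,
    error_rate: float,
    seed,
    mode: ErrorMode = "genotype",
    return_cells: bool = False,
):
    """Apply genotyping errors, then missingness, on disjoint cell sets."""
    n_cells = m.n_individuals * m.n_loci
    n_err = round(error_rate * n_cells)
    n_miss = round(missing_rate * n_cells)
    if n_err + n_miss > n_cells:
        raise ValueError("combined perturbation counts exceed the grid size")
    s_err, s_miss = as_seedseq(seed).spawn(2)
    out, err_cells = inject_errors(m, error_rate, s_err, mode=mode, return_cells=True)
    # sample missing cells from cells not already altered
    flat_err = err_cells[:, 0] * m.n_loci + err_cells[:, 1]
    remaining = np.setdiff1d(np.arange(n_cells), flat_err, assume_unique=False)
    rng = np.random.default_rng(s_miss)
    chosen = (
        rng.choice(remaining, size=n_miss, replace=False) if n_miss else np.array([], int)
    )
    out.genotypes.reshape(-1)[chosen] = MISSING
    if return_cells:
        return out, err_cells, _cell_coords(chosen, m.n_loci)
    return out
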