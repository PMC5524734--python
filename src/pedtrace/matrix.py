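"""Core containers: genotype matrices, SNP panels and mating designs.

Genotypes at a biallelic locus are coded by the count of the alternate
("B") allele: 0 = AA, 1 = AB, 2 = BB.  Missing calls use the dedicated
sentinel :data:`MISSING` (-1); every arithmetic routine in the package
masks it explicitly, it never enters a sum or a frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: sentinel for a missing genotype call (never used in arithmetic)
MISSING: int = -1

#: valid genotype codes, including the missing sentinel
VALID_CODES = frozenset({MISSING, 0, 1, 2})

#: per-individual role labels used by the certification workflow
ROLES = ("parent", "progeny", "cryobank_tissue", "field_tree")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci genotype matrix.

    Parameters
    ----------
    individual_ids, locus_ids
        Unique row / column identifiers.
    genotypes
        ``(n_individuals, n_loci)`` integer array with codes
        ``{0, 1, 2, MISSING}``.
    roles
        Optional per-individual role tag (one of :data:`ROLES`).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    roles: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(i) for i in self.locus_ids]
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if n != len(self.individual_ids) or m != len(self.locus_ids):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        _check_unique(self.individual_ids, "individual")
        _check_unique(self.locus_ids, "locus")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {int(self.genotypes[i, j])} for "
                f"individual {self.individual_ids[i]!r} at locus {self.locus_ids[j]!r}"
            )
        if self.roles is not None:
            if len(self.roles) != n:
                raise ValueError("roles must align with individual_ids")
            for r in self.roles:
                if r not in ROLES:
                    raise ValueError(f"unknown role {r!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row(self, individual_id: str) -> np.ndarray:
        """Genotype vector of one individual (panel order)."""
        return self.genotypes[self.individual_ids.index(individual_id)]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def individual_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1) if self.n_loci else np.zeros(self.n_individuals)

    def locus_missing_count(self) -> np.ndarray:
        return self.missing_mask().sum(axis=0)

    # -- subsetting -----------------------------------------------------
    def subset(
        self,
        individuals: Optional[Sequence[str]] = None,
        loci: Optional[Sequence[str]] = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given ids (given order)."""
        if individuals is None:
            ridx = np.arange(self.n_individuals)
            individuals = self.individual_ids
        else:
            pos = {v: k for k, v in enumerate(self.individual_ids)}
            try:
                ridx = np.array([pos[i] for i in individuals], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown individual id: {e.args[0]!r}") from None
        if loci is None:
            cidx = np.arange(self.n_loci)
            loci = self.locus_ids
        else:
            pos = {v: k for k, v in enumerate(self.locus_ids)}
            try:
                cidx = np.array([pos[i] for i in loci], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown locus id: {e.args[0]!r}") from None
        roles = None
        if self.roles is not None:
            roles = [self.roles[i] for i in ridx]
        geno = self.genotypes[np.ix_(ridx, cidx)] if len(ridx) and len(cidx) else \
            np.empty((len(ridx), len(cidx)), dtype=np.int8)
        return GenotypeMatrix(list(individuals), list(loci), geno, roles)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids),
            list(self.locus_ids),
            self.genotypes.copy(),
            None if self.roles is None else list(self.roles),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and self.roles == other.roles
        )


@dataclass
class SNPPanel:
    """Per-locus metadata for a candidate or assembled SNP panel.

    ``assayable`` marks loci that can be carried by the target genotyping
    platform (adequate flanking sequence etc.); ``quality_score`` is the
    genotype-call quality in [0, 1] (e.g. an array GC score);
    ``gene_ids`` ties each locus to a gene so panel assembly can favour
    one SNP per gene.
    """

    locus_ids: list[str]
    gene_ids: Optional[list[Optional[str]]] = None
    assayable: Optional[np.ndarray] = None
    quality_scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.locus_ids = [str(i) for i in self.locus_ids]
        _check_unique(self.locus_ids, "locus")
        n = len(self.locus_ids)
        if self.assayable is None:
            self.assayable = np.ones(n, dtype=bool)
        else:
            self.assayable = np.asarray(self.assayable, dtype=bool)
            if self.assayable.shape != (n,):
                raise ValueError("assayable must align with locus_ids")
        if self.gene_ids is not None and len(self.gene_ids) != n:
            raise ValueError("gene_ids must align with locus_ids")
        if self.quality_scores is not None:
            self.quality_scores = np.asarray(self.quality_scores, dtype=float)
            if self.quality_scores.shape != (n,):
                raise ValueError("quality_scores must align with locus_ids")
            finite = np.isfinite(self.quality_scores)
            if ((self.quality_scores[finite] < 0) | (self.quality_scores[finite] > 1)).any():
                raise ValueError("quality scores must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def gene_of(self, locus_id: str) -> Optional[str]:
        if self.gene_ids is None:
            return None
        return self.gene_ids[self.locus_ids.index(locus_id)]

    def subset(self, loci: Sequence[str]) -> "SNPPanel":
        pos = {v: k for k, v in enumerate(self.locus_ids)}
        idx = [pos[i] for i in loci]
        return SNPPanel(
            [self.locus_ids[i] for i in idx],
            None if self.gene_ids is None else [self.gene_ids[i] for i in idx],
            self.assayable[idx],
            None if self.quality_scores is None else self.quality_scores[idx],
        )


@dataclass(frozen=True)
class Cross:
    cross_id: str
    mother_id: str
    father_id: str


@dataclass
class MatingDesign:
    """Closed list of controlled crosses (cross id, mother, father)."""

    crosses: list[Cross]

    def __post_init__(self) -> None:
        _check_unique([c.cross_id for c in self.crosses], "cross")
        for c in self.crosses:
            if c.mother_id == c.father_id:
                raise ValueError(
                    f"cross {c.cross_id!r}: mother and father are the same "
                    f"individual ({c.mother_id!r})"
                )

    @property
    def cross_ids(self) -> list[str]:
        return [c.cross_id for c in self.crosses]

    @property
    def parent_ids(self) -> list[str]:
        """Distinct parent ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.crosses:
            seen.setdefault(c.mother_id)
            seen.setdefault(c.father_id)
        return list(seen)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def __iter__(self):
        return iter(self.crosses)

    def __getitem__(self, cross_id: str) -> Cross:
        for c in self.crosses:
            if c.cross_id == cross_id:
                return c
        raise KeyError(cross_id)

    def validate_against(self, parents: GenotypeMatrix) -> None:
        """Check that every parent id resolves in the parent matrix."""
        have = set(parents.individual_ids)
        for c in self.crosses:
            for pid in (c.mother_id, c.father_id):
                if pid not in have:
                    raise KeyError(
                        f"cross {c.cross_id!r} references unknown parent {pid!r}"
                    )


# -- quality prefilters -------------------------------------------------

def filter_individuals_by_missingness(
    m: GenotypeMatrix, max_missing_fraction: float
) -> GenotypeMatrix:
    """Drop individuals whose missing-call fraction strictly exceeds the cap.

    The comparison is a strict ``>`` so an individual sitting exactly on
    the threshold (e.g. 15% with ``max_missing_fraction=0.15``) is kept.
    Order of the survivors is preserved; the result may be empty.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = m.individual_missing_fraction()
    keep = [i for i, f in zip(m.individual_ids, frac) if f <= max_missing_fraction]
    return m.subset(individuals=keep)


def prefilter_panel(
    parents: GenotypeMatrix, panel: SNPPanel, min_quality: float = 0.60
) -> SNPPanel:
    """Candidate-locus prefilter used before any marker selection.

    Keeps loci with (1) no missing parental genotype and (2) a quality
    score greater than or equal to ``min_quality``.  Loci without a
    quality score pass criterion (2) vacuously.
    """
    pos = {v: k for k, v in enumerate(parents.locus_ids)}
    keep: list[str] = []
    for j, locus in enumerate(panel.locus_ids):
        if locus not in pos:
            raise KeyError(f"panel locus {locus!r} absent from parent matrix")
        col = parents.genotypes[:, pos[locus]]
        if (col == MISSING).any():
            continue
        if panel.quality_scores is not None:
            q = panel.quality_scores[j]
            if not math.isnan(q) and q < min_quality:
                continue
        keep.append(locus)
    return panel.subset(keep)
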