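"""Readers and writers for the plain-text exchange formats.

Genotype tables are tab-separated: a header row of locus ids, then one
row per individual with the individual id in the first column and one
genotype token per locus.  Default tokens are ``AA``/``AB``/``BB``/``NA``
(``BA`` is accepted as ``AB``; heterozygote allele order carries no
information).  Mating designs are 3-column TSV with header
``cross_id  mother_id  father_id``.  VCF import is read-only and
restricted to biallelic records.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .matrix import MISSING, Cross, GenotypeMatrix, MatingDesign

#: default token <-> code mapping for genotype tables
DEFAULT_TOKENS: Mapping[str, int] = {
    "AA": 0,
    "AB": 1,
    "BA": 1,
    "BB": 2,
    "NA": MISSING,
}

_CODE_TO_TOKEN = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}


def read_genotype_table(
    path: str | os.PathLike,
    tokens: Optional[Mapping[str, int]] = None,
) -> GenotypeMatrix:
    """Parse a TSV genotype table into a :class:`GenotypeMatrix`.

    An unrecognised genotype token raises instead of being coerced to
    missing, so file corruption cannot silently inflate missingness.
    """
    tokens = DEFAULT_TOKENS if tokens is None else tokens
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: no individuals (empty file)")
    header = lines[0].split("\t")
    locus_ids = header[1:]
    if len(lines) == 1:
        raise ValueError(f"{path}: no individuals (header only)")
    ids: list[str] = []
    rows: list[list[int]] = []
    for k, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(locus_ids) + 1:
            raise ValueError(
                f"{path}:{k}: ragged row ({len(fields) - 1} genotypes, "
                f"expected {len(locus_ids)})"
            )
        ind = fields[0]
        if ind in ids:
            raise ValueError(f"{path}:{k}: duplicate individual id {ind!r}")
        codes = []
        for locus, tok in zip(locus_ids, fields[1:]):
            try:
                codes.append(tokens[tok])
            except KeyError:
                raise ValueError(
                    f"{path}:{k}: unknown genotype token {tok!r} at locus {locus!r}"
                ) from None
        ids.append(ind)
        rows.append(codes)
    return GenotypeMatrix(ids, locus_ids, np.array(rows, dtype=np.int8))


def write_genotype_table(m: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the TSV dialect read by :func:`read_genotype_table`."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(m.locus_ids) + "\n")
        for ind, row in zip(m.individual_ids, m.genotypes):
            fh.write(ind + "\t" + "\t".join(_CODE_TO_TOKEN[int(g)] for g in row) + "\n")


def read_mating_design(path: str | os.PathLike) -> MatingDesign:
    """Read a 3-column TSV (cross_id, mother_id, father_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cross_id", "mother_id", "father_id"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: expected columns {required}, found {list(df.columns[:3])}"
        )
    crosses = [
        Cross(r.cross_id, r.mother_id, r.father_id) for r in df.itertuples(index=False)
    ]
    return MatingDesign(crosses)


def write_mating_design(design: MatingDesign, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("cross_id\tmother_id\tfather_id\n")
        for c in design:
            fh.write(f"{c.cross_id}\t{c.mother_id}\t{c.father_id}\n")


def read_truth_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 2-column individual_id -> cross_id truth table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["individual_id", "cross_id"]:
        raise ValueError(f"{path}: expected columns individual_id, cross_id")
    return df


def write_truth_table(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth[["individual_id", "cross_id"]].to_csv(path, sep="\t", index=False)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Import biallelic SNP genotypes from a VCF file.

    GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multi-allelic records are rejected: the assignment mathematics is
    defined for biallelic SNPs only.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF import

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    locus_ids: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(only biallelic SNPs are supported)"
            )
        name = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        locus_ids.append(name)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.full(len(ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        cols.append(col)
    if not locus_ids:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix(ids, locus_ids, np.column_stack(cols))
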