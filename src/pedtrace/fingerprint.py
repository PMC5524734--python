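"""Multilocus genotype fingerprints for clonal-line identity control.

A fingerprint is the concatenation of all single-locus genotypes of an
individual in fixed panel order, one symbol per locus: ``A`` (AA),
``H`` (heterozygote), ``B`` (BB), ``?`` (missing).  With 36 biallelic
loci the space of complete fingerprints holds 3^36 > 1.5e17 distinct
codes, so two unrelated lines sharing a fingerprint is effectively
impossible and even full sibs collide only rarely.

Matching tolerates genotyping error and missing data: two fingerprints
are compared only over loci called in both, a mismatch budget and a
minimum overlap guard the verdict.  The module also diagnoses at which
production stage a problematic cell line went wrong, by combining
member fingerprints (cryobank tissue vs field trees) with their
parentage-assignment results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

SYMBOLS = {0: "A", 1: "H", 2: "B", MISSING: "?"}
_CODES = {v: k for k, v in SYMBOLS.items()}


@dataclass(frozen=True)
class Fingerprint:
    individual_id: str
    code: str

    def __post_init__(self) -> None:
        bad = set(self.code) - set("AHB?")
        if bad:
            raise ValueError(f"invalid fingerprint symbols: {sorted(bad)}")

    @property
    def n_loci(self) -> int:
        return len(self.code)

    @property
    def n_missing(self) -> int:
        return self.code.count("?")

    @property
    def complete(self) -> bool:
        return "?" not in self.code

    def genotypes(self) -> np.ndarray:
        return np.array([_CODES[s] for s in self.code], dtype=np.int8)


def build_fingerprint(genotypes: np.ndarray, individual_id: str = "") -> Fingerprint:
    """Canonical fingerprint string from a panel-ordered genotype vector."""
    code = "".join(SYMBOLS[int(g)] for g in np.asarray(genotypes))
    return Fingerprint(individual_id, code)


def fingerprints_from_matrix(m: GenotypeMatrix) -> list[Fingerprint]:
    return [
        build_fingerprint(row, ind) for ind, row in zip(m.individual_ids, m.genotypes)
    ]


def fingerprint_space(n_loci: int) -> int:
    """Number of distinct complete fingerprints over ``n_loci`` biallelic loci."""
    return 3 ** n_loci


def default_min_overlap(panel_size: int) -> int:
    """ceil(0.85 * panel size): mirrors a 15% missingness tolerance."""
    return math.ceil(0.85 * panel_size)


def compare_fingerprints(a: Fingerprint, b: Fingerprint) -> tuple[int, int]:
    """(mismatches, overlap) over loci non-missing in both fingerprints."""
    if a.n_loci != b.n_loci:
        raise ValueError("fingerprints come from different panels")
    ga, gb = a.genotypes(), b.genotypes()
    both = (ga != MISSING) & (gb != MISSING)
    overlap = int(both.sum())
    mism = int((ga[both] != gb[both]).sum())
    return mism, overlap


def match_fingerprint(
    query: Fingerprint,
    database: Sequence[Fingerprint],
    max_mismatch: int = 1,
    min_overlap: Optional[int] = None,
) -> pd.DataFrame:
    """Rank database entries matching a query fingerprint.

    Entries within ``max_mismatch`` over at least ``min_overlap``
    mutually-called loci are returned ranked by (mismatches ascending,
    overlap descending).  If the query never reaches ``min_overlap``
    against any entry the empty result carries
    ``attrs["insufficient_data"] = True``.
    """
    if min_overlap is None:
        min_overlap = default_min_overlap(query.n_loci)
    rows = []
    any_overlap_ok = False
    for entry in database:
        mism, overlap = compare_fingerprints(query, entry)
        if overlap >= min_overlap:
            any_overlap_ok = True
            if mism <= max_mismatch:
                rows.append(
                    {
                        "individual_id": entry.individual_id,
                        "mismatches": mism,
                        "overlap": overlap,
                    }
                )
    out = pd.DataFrame(rows, columns=["individual_id", "mismatches", "overlap"])
    if len(out):
        out = out.sort_values(
            ["mismatches", "overlap", "individual_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    out.attrs["insufficient_data"] = bool(len(database)) and not any_overlap_ok
    return out


@dataclass
class DuplicateReport:
    """Duplicate-fingerprint findings.

    ``groups`` are sets of individuals with *complete* identical
    fingerprints (equality is transitive there).  ``links`` are
    pairwise zero-mismatch matches in which at least one member has
    missing data; such links are reported as pairs and never closed
    into groups, because indistinguishability is not transitive once
    loci are masked.
    """

    groups: list[list[str]]
    links: list[tuple[str, str]]


def find_duplicate_fingerprints(
    fingerprints: Sequence[Fingerprint],
    min_overlap: Optional[int] = None,
) -> DuplicateReport:
    """Detect fingerprints that cannot be told apart."""
    if not fingerprints:
        return DuplicateReport([], [])
    if min_overlap is None:
        min_overlap = default_min_overlap(fingerprints[0].n_loci)
    by_code: dict[str, list[str]] = {}
    incomplete: list[Fingerprint] = []
    complete: list[Fingerprint] = []
    for fp in fingerprints:
        if fp.complete:
            by_code.setdefault(fp.code, []).append(fp.individual_id)
            complete.append(fp)
        else:
            incomplete.append(fp)
    groups = [sorted(v) for v in by_code.values() if len(v) >= 2]
    groups.sort()
    links: list[tuple[str, str]] = []
    for i, fp in enumerate(incomplete):
        for other in complete + incomplete[i + 1 :]:
            mism, overlap = compare_fingerprints(fp, other)
            if mism == 0 and overlap >= min_overlap:
                links.append(tuple(sorted((fp.individual_id, other.individual_id))))
    return DuplicateReport(groups, sorted(set(links)))


def replicate_concordance(pairs: Sequence[tuple[Fingerprint, Fingerprint]]) -> float:
    """Fraction of agreeing genotype calls across replicate pairs.

    Pooled over all pairs, counting only loci called in both members of
    a pair (assay reproducibility estimate).
    """
    agree = total = 0
    for a, b in pairs:
        mism, overlap = compare_fingerprints(a, b)
        agree += overlap - mism
        total += overlap
    if total == 0:
        raise ValueError("no mutually called loci across the replicate pairs")
    return agree / total


# -- cell-line stage diagnosis -----------------------------------------

@dataclass
class LineMember:
    fingerprint: Fingerprint
    role: str  # cryobank_tissue | field_tree
    legitimate: bool  # assigned to the putative cross of the line
    parent_error_class: str = "undetermined"


@dataclass
class CellLineRecord:
    line_id: str
    putative_cross: str
    members: list[LineMember]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cell line {self.line_id!r} has no members")
        sizes = {m.fingerprint.n_loci for m in self.members}
        if len(sizes) > 1:
            raise ValueError(f"cell line {self.line_id!r}: members on different panels")


@dataclass
class LineDiagnosis:
    line_id: str
    stage: str  # clean | breeding_stage_error | production_stage_error | cryobank_error | inconsistent
    subclass: Optional[str] = None
    warning: Optional[str] = None


def _members_identical(members: Sequence[LineMember], max_mismatch: int = 0) -> bool:
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            mism, _ = compare_fingerprints(
                members[i].fingerprint, members[j].fingerprint
            )
            if mism > max_mismatch:
                return False
    return True


def diagnose_cell_line(record: CellLineRecord) -> LineDiagnosis:
    """Locate the production stage at which a cell line's error occurred.

    * every member identical and illegitimate vs the putative cross ->
      ``breeding_stage_error`` (subclass from the parent-error class:
      a wrong father points to pollen contamination, a wrong mother or
      both parents to parental misidentification);
    * cryobank tissue legitimate but a field tree illegitimate or
      mismatched -> ``production_stage_error`` (lab / cutting /
      planting);
    * field trees legitimate but the cryobank tissue illegitimate ->
      ``cryobank_error``;
    * everything legitimate and identical -> ``clean``.

    Without a cryobank member only breeding-level conclusions are
    possible; the diagnosis then carries a warning.
    """
    cryo = [m for m in record.members if m.role == "cryobank_tissue"]
    trees = [m for m in record.members if m.role == "field_tree"]
    identical = _members_identical(record.members)
    all_legit = all(m.legitimate for m in record.members)
    all_illegit = all(not m.legitimate for m in record.members)

    def breeding_subclass() -> str:
        classes = {m.parent_error_class for m in record.members}
        if classes == {"wrong_father"}:
            return "pollen_contamination"
        if classes <= {"wrong_mother", "wrong_both", "wrong_father"}:
            return "parental_misidentification"
        return "unresolved"

    if not cryo:
        if identical and all_illegit:
            return LineDiagnosis(
                record.line_id, "breeding_stage_error", breeding_subclass(),
                warning="no cryobank member: field-only diagnosis",
            )
        if all_legit and identical:
            return LineDiagnosis(
                record.line_id, "clean",
                warning="no cryobank member: field-only diagnosis",
            )
        return LineDiagnosis(
            record.line_id, "production_stage_error",
            warning="no cryobank member: cannot separate production from cryobank",
        )

    if identical and all_illegit:
        return LineDiagnosis(record.line_id, "breeding_stage_error", breeding_subclass())
    cryo_legit = all(m.legitimate for m in cryo)
    trees_legit = all(m.legitimate for m in trees) if trees else True
    if identical and all_legit:
        return LineDiagnosis(record.line_id, "clean")
    if cryo_legit and (not trees_legit or not identical):
        return LineDiagnosis(record.line_id, "production_stage_error")
    if trees_legit and not cryo_legit:
        return LineDiagnosis(record.line_id, "cryobank_error")
    return LineDiagnosis(
        record.line_id, "inconsistent",
        warning="mixed legitimacy pattern does not fit a single stage",
    )


# -- plain-text fingerprint database -----------------------------------

def write_fingerprint_db(
    entries: Sequence[tuple[str, str, Fingerprint]], path
) -> None:
    """Write (line_id, role, fingerprint) rows as an append-friendly TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("line_id\trole\tfingerprint\n")
        for line_id, role, fp in entries:
            fh.write(f"{line_id}\t{role}\t{fp.code}\n")


def read_fingerprint_db(path) -> list[tuple[str, str, Fingerprint]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:3]) != ["line_id", "role", "fingerprint"]:
        raise ValueError(f"{path}: expected columns line_id, role, fingerprint")
    return [
        (r.line_id, r.role, Fingerprint(r.line_id, r.fingerprint))
        for r in df.itertuples(index=False)
    ]
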