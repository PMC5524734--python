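"""Synthetic parent panels and mating designs.

Emulates the structure of an elite conifer breeding population: a few
dozen parents genotyped at biallelic SNPs with intermediate allele
frequencies, crossed in a few dozen controlled matings in which a parent
may serve in several crosses.  Parents are drawn from Hardy–Weinberg
proportions at configurable allele frequencies; the default frequency
rule (uniform on [0.1, 0.5] for the B allele) gives a panel with mostly
high expected heterozygosity and a tail of weakly informative loci, so
marker-ranking procedures have real signal to separate.

All generators are deterministic under a single integer seed; pipeline
stages derive independent substreams from it via ``SeedSequence``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .matrix import Cross, GenotypeMatrix, MatingDesign

FrequencyRule = Union[Sequence[float], tuple]


@dataclass
class PopulationSpec:
    """Parameters of a synthetic breeding population.

    ``allele_freqs`` is either an explicit vector of B-allele
    frequencies (length ``n_loci``, open interval (0,1) for polymorphic
    loci) or a rule: ``("uniform", lo, hi)`` or ``("constant", value)``.
    Defaults mirror a 73-parent / 68-cross / 36-SNP program.
    """

    n_parents: int = 73
    n_loci: int = 36
    n_crosses: int = 68
    allele_freqs: FrequencyRule = ("uniform", 0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 2:
            raise ValueError("need at least two parents")
        max_pairs = self.n_parents * (self.n_parents - 1) // 2
        if not 1 <= self.n_crosses <= max_pairs:
            raise ValueError(
                f"n_crosses={self.n_crosses} infeasible for {self.n_parents} "
                f"parents ({max_pairs} unordered pairs exist)"
            )


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_allele_frequencies(spec: PopulationSpec) -> np.ndarray:
    """Realise the per-locus B-allele frequency vector of a spec."""
    rule = spec.allele_freqs
    if not isinstance(rule, tuple) or (rule and not isinstance(rule[0], str)):
        freqs = np.asarray(rule, dtype=float)
        if freqs.shape != (spec.n_loci,):
            raise ValueError("explicit frequency vector must have length n_loci")
    elif rule[0] == "constant":
        freqs = np.full(spec.n_loci, float(rule[1]))
    elif rule[0] == "uniform":
        lo, hi = float(rule[1]), float(rule[2])
        if not 0 < lo <= hi < 1:
            raise ValueError("uniform frequency bounds must satisfy 0 < lo <= hi < 1")
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        freqs = rng.uniform(lo, hi, size=spec.n_loci)
    else:
        raise ValueError(f"unknown frequency rule {rule[0]!r}")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return freqs


def generate_parents(
    freqs: np.ndarray,
    n_parents: int,
    seed: int,
    id_prefix: str = "P",
) -> GenotypeMatrix:
    """Draw parents from Hardy–Weinberg proportions.

    At a locus with B-allele frequency ``q`` the genotype code (count of
    B alleles) is Binomial(2, q), i.e. probabilities
    {(1-q)^2, 2q(1-q), q^2} for {AA, AB, BB}.  No missing data: real
    candidate panels are prefiltered to loci fully typed in the parents.
    """
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, freqs[None, :], size=(n_parents, freqs.size)).astype(np.int8)
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n_parents)]
    return GenotypeMatrix(ids, [f"L{j + 1:03d}" for j in range(freqs.size)], geno,
                          roles=["parent"] * n_parents)


def generate_mating_design(
    parent_ids: Sequence[str],
    n_crosses: int,
    seed: int,
    shared_parent_bias: float = 0.0,
) -> MatingDesign:
    """Sample distinct unordered parent pairs as controlled crosses.

    With ``shared_parent_bias=0`` the design is a uniform draw without
    replacement from all unordered pairs, so parent re-use arises
    naturally whenever ``n_crosses`` approaches or exceeds
    ``n_parents/2``.  A positive bias over-weights pairs involving a
    parent already used, stressing half-sib confusability downstream.
    """
    parent_ids = list(parent_ids)
    pairs = list(itertools.combinations(range(len(parent_ids)), 2))
    if n_crosses > len(pairs):
        raise ValueError(
            f"n_crosses={n_crosses} infeasible: only {len(pairs)} unordered pairs"
        )
    rng = np.random.default_rng(seed)
    if shared_parent_bias < 0:
        raise ValueError("shared_parent_bias must be >= 0")
    chosen: list[tuple[int, int]] = []
    if shared_parent_bias == 0:
        idx = rng.choice(len(pairs), size=n_crosses, replace=False)
        chosen = [pairs[i] for i in idx]
    else:
        used: set[int] = set()
        avail = list(pairs)
        for _ in range(n_crosses):
            w = np.array(
                [1.0 + shared_parent_bias * ((a in used) + (b in used)) for a, b in avail]
            )
            pick = rng.choice(len(avail), p=w / w.sum())
            a, b = avail.pop(pick)
            chosen.append((a, b))
            used.update((a, b))
    crosses = [
        Cross(f"C{k + 1:03d}", parent_ids[a], parent_ids[b])
        for k, (a, b) in enumerate(chosen)
    ]
    return MatingDesign(crosses)


def generate_population(
    spec: PopulationSpec,
    shared_parent_bias: float = 0.0,
) -> tuple[GenotypeMatrix, MatingDesign, np.ndarray]:
    """Convenience: frequencies + parents + design from one spec/seed."""
    sub = np.random.SeedSequence(spec.seed).spawn(3)
    freqs = generate_allele_frequencies(spec)
    parents = generate_parents(freqs, spec.n_parents, sub[1])
    design = generate_mating_design(
        parents.individual_ids, spec.n_crosses, sub[2], shared_parent_bias
    )
    return parents, design, freqs
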