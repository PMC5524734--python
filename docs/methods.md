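# Methods

## Setting and scope

`pedtrace` models a *closed* breeding program: a fixed panel of parents,
an explicit list of controlled crosses, and samples (offspring, clonal
tissue, planted trees) that must be traced back to one of those crosses.
Everything is defined for biallelic SNPs; genotypes are coded by the
count of the alternate allele (0 = AA, 1 = AB, 2 = BB) with a dedicated
missing sentinel that never enters arithmetic. Open-population paternity
search, sibship reconstruction, multi-allelic markers and genotype
imputation are out of scope.

## Genotype model and prefilters

Candidate marker panels are prefiltered the way an operational program
would before any selection: loci with any missing parental genotype are
dropped (downstream simulation and assignment assume fully typed
parents) and loci below a genotype-call quality threshold (default
0.60, the usual array GC-score cut) are dropped. Individuals are
filtered on missingness with a *strict* inequality — "more than 15%
missing" removes an individual, one sitting exactly at 15% stays. The
boundary convention is arbitrary in principle; strictness was chosen so
the filter matches its plain-language description and is asserted in
tests.

## Synthetic populations

Parents are drawn from Hardy–Weinberg proportions at configurable
per-locus allele frequencies; mating designs are sampled uniformly
without replacement from all unordered parent pairs, so parent re-use
arises naturally when the number of crosses approaches the number of
parents (the default emulates 73 parents and 68 crosses, which forces
only mild sharing). A `shared_parent_bias` knob over-weights
already-used parents to stress half-sib confusability; the real degree
of sharing in any given program is an input, not something the
generator estimates.

The default frequency rule is uniform on [0.1, 0.5] for the minor
allele: a working traceability panel is made of pre-selected,
intermediate-frequency SNPs with a tail of weaker loci, and a spread of
frequencies gives ranking procedures signal to order. Two features of
real data are deliberately not emulated: relatedness among parents
(elite trees are often cousins; synthetic parents are unrelated HWE
draws, which makes crosses *more* distinguishable than in practice) and
linkage (loci are independent; real panels minimise linkage by design,
one SNP per gene). Passing tests therefore demonstrate correctness of
the machinery and the qualitative behaviour of the methods, not the
numeric error rates of any particular real program.

All generators take one integer seed; pipelines derive per-stage
substreams via `numpy.random.SeedSequence.spawn`, so end-to-end runs
are bit-reproducible and stages stay statistically independent.

## Progeny simulation

For each cross and locus, one allele is drawn uniformly from each
parent's two alleles, independently across loci and offspring — exactly
the 3×3×3 Mendelian transmission table T(g_o | g_m, g_f), whose entries
are multiples of 1/4 and hence exact in binary floating point. The same
table drives the likelihood assigner, so simulator and assigner cannot
disagree about Mendelian support. Truth labels are emitted as a
separate table and never encoded in individual ids.

## Perturbation model

Missing data and genotyping errors are injected as *exact counts*
(round(rate × cells), sampled without replacement over the
individual × locus grid), not per-cell Bernoulli draws: benchmark
datasets carry a fixed, known contamination level. The error model
replaces a genotype by one of the two other states uniformly — the
simplest model consistent with errors on called genotypes; an
allele-flip mode (AA→AB, BB→AB, AB→AA/BB) is available as a flag. When
missingness and errors are combined, errors are applied first and
missing cells are drawn from the remaining cells, because masking an
erroneous cell would silently lower the realised error rate.

## Per-locus statistics

* He = 2pq, with no small-sample correction: at the sample sizes this
  tool targets (thousands of genotypes) the unbiased correction is
  < 1e-4, far below the 3-decimal reporting precision.
* PIC = 2pq − 2p²q² (biallelic Botstein form).
* NE-PP — the probability that a random unrelated candidate pair is
  *not* excluded as parents of a random offspring — is computed by
  exhaustive enumeration of the 27 parent-pair × offspring genotype
  combinations with HWE weights at the sample allele frequency. The
  Jamieson–Taylor closed form (1 − P3, P3 = 1 + 4a₄ − 4a₅ − 3a₆ − 8a₂²
  + 8a₂a₃ + 2a₃², aₙ = Σpᵢⁿ) is implemented separately and agrees with
  the enumeration to < 1e-12 across the frequency grid; a property test
  pins this equivalence. The reference population for both the pair and
  the offspring is HWE at the sample frequency (validated: p = 0.5
  gives 0.71875, printing as 0.719).
* `maf_from_he` inverts He to the minor root of 2p(1−p) = He, letting
  published He columns parameterise recomputation.
* Monomorphic loci: PIC 0, NE-PP 1, theta flagged 0 — chosen so
  degenerate loci sort last in every ranking.
* F_ST is Weir–Cockerham theta with full-sib families as demes,
  written out from the a/b/c variance components (handles unequal
  family sizes); a multi-locus ratio-of-sums variant aggregates across
  loci, while per-locus theta is used for ranking.

The shipped `table1_fixture.tsv` is a published 36-SNP summary table
used for internal-consistency checks. One of its rows (A-005) prints an
NE-PP of 0.718, *below* the biallelic minimum 0.71875 attained at
p = 0.5 — no allele frequency can reproduce it, so it is treated as a
rounding/typesetting slip and tolerated at 0.003 instead of the 0.002
used for the other 35 rows.

## Marker selection

The three procedures rank candidates by per-locus theta (descending),
by |MAF − 0.5| (ascending; computed on the parent panel, since parental
frequencies determine expected progeny frequencies and selection
happens before progeny exist in a new program), and by random-forest
Gini importance (scikit-learn `RandomForestClassifier`, genotype codes
as features, true cross as the class; default 10,000 trees). All ties
break lexicographically on locus id for reproducibility. Panel assembly
walks a ranking best-first, skipping unassayable loci and second SNPs
within a gene; the gene constraint is relaxed with a warning when it
alone prevents reaching k, while too few assayable loci is an error.

## Assignment

**Exclusion.** Per locus, the mismatch is the minimum number of allele
substitutions making the offspring genotype Mendelian-compatible with
the parent pair (allele distance between genotype codes a, b is
|a − b|). Totals are summed *across loci* and compared to an
allele-mismatch tolerance (default 1 allele). Counting in alleles over
the whole profile means a single AA→BB miscall (distance 2) already
exceeds tolerance 1 — which is precisely the fragility to genotyping
error that pure exclusion methods show. Missing offspring loci
contribute 0 (uninformative), which is why exclusion barely reacts to
missing data. An individual is `assigned` when a unique cross attains
the minimum total within tolerance, `ambiguous` on ties, `unassigned`
when no cross qualifies; ambiguity is never broken by id order or
randomness.

**Likelihood.** Per locus, (1−ε)·T(g_o|g_m,g_f) + ε·P_HWE(g_o), summed
in log over non-missing loci; the offspring goes to the argmax cross,
with best and second-best log-likelihoods reported as a confidence
margin. The contamination mixture is the simplest error model that
keeps one bad locus from vetoing the true cross; ε defaults to 0.01 and
is exposed everywhere. With ε = 0 an incompatible locus yields −∞.

**Problem-parent classification.** When an individual fails its
putative cross, each parent is tested alone: only opposite homozygotes
(offspring AA vs parent BB) conflict, each costing one substitution,
with the same allele tolerance. Mother-compatible/father-not is a
wrong father (pollen-contamination signature), the reverse a wrong
mother, neither a wrong pair, both compatible is undetermined.

**Evaluation** reports percentages over all individuals (wrong +
correct + ambiguous + unassigned = 100) *and* the wrong rate among
assigned individuals, because published robustness figures do not
always state their denominator. The robustness benchmarks in the test
suite compare methods on the *failed-assignment* rate
(wrong + ambiguous + unassigned): with unrelated synthetic parents the
exclusion method almost never mis-assigns uniquely — errors push the
true cross over tolerance and leave the individual unassigned — so the
failure rate is the quantity that exhibits the methods' characteristic
asymmetry (exclusion fragile to errors, insensitive to missingness;
likelihood the reverse).

## Fingerprinting and stage diagnosis

Fingerprints are fixed-width strings (A/H/B/?), trivially diffable and
appendable in a plain-TSV database. Matching compares only loci called
in both fingerprints, with a mismatch budget (default 1) and a minimum
overlap (default ⌈0.85 × panel⌉, mirroring the 15% missingness
tolerance). Duplicate detection reports groups only among *complete*
fingerprints, where identity is transitive; zero-mismatch links
involving missing data are reported as pairs and never closed into
groups, since indistinguishability is not transitive once loci are
masked. Stage diagnosis combines member legitimacy and identity: all
members identical and illegitimate places the error at breeding (then
wrong-father → pollen contamination, wrong mother/both → parental
misidentification); legitimate cryobank tissue with deviant field trees
places it in propagation/planting; legitimate trees with deviant
cryobank tissue places it in the cryobank; without a cryobank member
the diagnosis is limited and carries a warning.

## Benchmark problem sizes

Simulation-based tests use 73 parents / 68 crosses / 36 loci with 20
offspring per cross and 5 replicate populations — large enough for the
qualitative contrasts (error monotonicity, method asymmetry,
procedure ordering) to be stable under the fixed seeds, small enough to
keep the whole suite fast. The marker-selection benchmark uses a
120-SNP candidate panel with a discovery-like skewed frequency spectrum
(beta(0.5, 2) clipped to [0.01, 0.5]) and selects 12 loci with
300-tree forests: an unselected candidate panel has many weak, low-MAF
markers, which is exactly the regime in which ranking procedures
differ — per-locus theta over-rewards rare alleles that discriminate
only the few families carrying them, MAF ignores realised family
structure, and the forest sees both.

## Known limitations

* Unrelated synthetic parents overstate cross distinguishability
  relative to real pedigrees; absolute error rates from synthetic runs
  should not be quoted for real programs.
* The likelihood error model is a stand-in (uniform HWE contamination);
  real genotyping error is platform- and genotype-dependent.
* Error/missingness injection is homogeneous across loci and
  individuals; no allele-dropout or locus-specific failure model.
* Duplicate detection with heavy missingness degrades to pairwise
  links by design; a probabilistic identity likelihood-ratio is not
  implemented.
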