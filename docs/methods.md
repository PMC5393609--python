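# Methods

`panrbh` reconstructs a bacterial pan-genome from per-genome protein sets
and summarizes its structure: which gene families are shared by every
strain (core), which are dispensable (accessory), whether the species'
gene pool is open or closed, how the strains relate phylogenetically, and
which proteins carry surface-association signatures. This note records
the models, the tunable parameters, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Pairwise scoring and the SRV statistic

All-vs-all protein comparison uses exact Smith–Waterman local alignment
with affine gaps under BLOSUM62 (gap open 11, gap extend 1; a gap of
length L costs 11 + L, the standard protein-BLAST convention). Using the
exact algorithm instead of a seeded heuristic removes heuristic
nondeterminism; at the scale of bacterial proteomes the cost is
acceptable (the kernel is JIT-compiled and scores a pair of 200-residue
proteins in ~0.1 ms).

Each hit's raw score is normalized against the query's self-hit score,
giving the **score ratio value**:

    SRV(q → s) = 100 · SW(q, s) / SW(q, q)

Because the BLOSUM62 diagonal dominates every row, the self-hit optimum
is the ungapped diagonal sum, and 0 ≤ SRV ≤ 100. SRV is asymmetric: a
short protein fully contained in a longer one reaches SRV 100 as query
but not as subject. The ambiguity residue X scores 0 against everything,
including itself.

Hits are retained when the Karlin–Altschul E-value

    E = K · m · n · exp(−λ · S)

is ≤ 10⁻⁴, with the standard gapped-BLOSUM62 constants λ = 0.267 and
K = 0.041 (both configurable). Unrelated random proteins of ~50–400
residues essentially never pass this cutoff, which is what makes the
downstream best-hit structure clean.

An optional prefilter skips pairs that share no 4-mer before aligning
them. A pair clearing E ≤ 10⁻⁴ needs a raw score far above what two
sequences without a single shared tetrapeptide can realistically attain,
and on synthetic proteomes the retained hit set with the prefilter on is
identical to the unfiltered one (tested); the prefilter is on by default
in the pipeline paths and off in the low-level API.

## Orthology: reciprocal best hits at SRV ≥ 35

Two loci in different genomes are orthologs when each is the other's
best-scoring hit and **both** directional SRVs are ≥ 35. Best hits are
made deterministic by breaking raw-score ties on higher SRV, then on the
lexicographically smallest subject locus tag.

Pairwise orthologs are consolidated into cross-genome families by a
reference-pivot sweep: every locus of the reference genome seeds a
family; the remaining genomes are processed in order, and each locus
joins the family of its reciprocal-best partner in the earliest
already-processed genome. When partners point at different families, the
link with the highest min(SRV) wins (logged as a warning); a family that
already holds a member of the joining genome is skipped, preserving the
at-most-one-member-per-genome invariant. Every locus ends up in exactly
one family, so family sizes sum to the total locus count. RBH is
one-to-one by construction: co-orthologs cannot be represented, and
in-paralogs remain singleton families.

## Pan-genome structure and openness

Families present in all genomes are **core**; everything else is
**accessory**; accessory families confined to a single genome are
additionally counted as **unique** (strain-specific). By construction
pan = core + accessory and unique ⊆ accessory.

Development curves track cumulative pan size (union), core size
(intersection), and first-seen family count as genomes are added one at
a time. By default the curves are medians over 200 random genome orders
(seeded); an explicit ordering — e.g. the additive order in which the
genomes entered the study — can be supplied instead. The per-added-genome
novelty is fitted to the power law

    n(N) = κ · N^(−α)

by nonlinear least squares over N ≥ 2 (the N = 1 point conflates genome
size with gain rate), initialized from a log–log linear fit so
convergence needs no hand-picked start values. The cumulative pan curve
is fitted as κ′·N^γ; under the power-law model γ = 1 − α. The verdict is
**open** iff α < 1: novelty decays too slowly for the gene pool to
saturate. If all novelty medians are zero the fit is undefined and the
verdict is closed with α = ∞ as sentinel. The core curve receives only a
descriptive exponential-decay fit (κ_c·e^(−N/τ) + Ω); its parameters are
reported but not used for any verdict.

A structural caveat discovered while validating the generator: when
accessory genes are largely strain-specific, the *median-over-random-
orders* novelty curve is nearly flat in N regardless of how novelty was
scheduled, because each position in a random order draws an exchangeable
genome. The planted decay law is therefore recovered by fitting the
additive (generation) order, which is how the parameter-recovery
experiment below is run; the permutation-median curve remains the
default output of the openness stage because it is the standard
presentation for real data.

## Core-genome phylogeny

Pairwise genome distances are derived from the already-computed SRVs:

    d(i, j) = 1 − mean over core families of (SRV(i→j) + SRV(j→i)) / 200

This replaces a concatenated multiple-alignment distance; it reuses the
scoring stage, keeps the tool self-contained, and preserves the
neighbor-joining step, but branch lengths are on an SRV-dissimilarity
scale, not substitutions per site, and should be read comparatively
only. Neighbor joining is the classic agglomerative algorithm on the
Q-criterion with the standard two-point branch-length formulas; ties are
broken lexicographically on a canonical node label (the smallest leaf
name in each subtree), so output is deterministic and invariant to taxon
order. NJ recovers the generating topology exactly on additive
matrices (property-tested on random trees up to 8 taxa). Small negative
branch lengths, a known NJ artifact, are clamped to zero at Newick
serialization with a warning.

## Surface-proteome screen

Trained predictors for secretion signals, lipoproteins, wall anchors and
transmembrane topology are statistical models that cannot be
re-derived from their publications; this module instead applies
transparent rules anchored to the published anatomy of each feature.
Consequences: calls are anatomy-based, and counts are not comparable to
the output of the trained tools.

* **Lipoprotein**: lipobox `[LVI]-[AST]-[GA]-C` starting within the
  first 40 residues, with ≥ 6 hydrophobic residues among the (up to) 10
  preceding — a proxy for the h-region of the signal-peptidase-II signal.
* **LPXTG anchor**: `L-P-x-T-G` starting within the C-terminal 50
  residues, ≥ 5 hydrophobic residues in the following 15 (the
  membrane-spanning stretch), and ≥ 2 K/R in the final 10 (the
  positively charged tail). Only the strict five-residue motif is
  matched; "LPXTG-like" variants are not.
* **Transmembrane helices**: Kyte–Doolittle window of 19 with mean ≥ 1.6;
  maximal runs of qualifying window positions separated by ≥ 5
  non-qualifying positions each count as one helix.
* **Sec signal (heuristic)**: ≥ 1 K/R in residues 1–5 and an 8-residue
  window within positions 6–30 of mean hydropathy ≥ 2.0.

The hydrophobic set for stretch tests is {A,V,L,I,M,F,W,C}; positions are
1-based. Proteins of ≤ 45 residues are excluded before screening (the
screens, not orthology, apply this filter). Calls are flagged
core/accessory through the locus's ortholog family.

## Synthetic data generator

The generator emulates the statistical structure the pipeline must
recover, with defaults chosen as a desk-scale miniature of a
nine-strain bacterial study: 9 genomes, a 60-family conserved core,
accessory novelty κ = 120, α = 0.7 (an open pan-genome, novelty decaying
from ~120 to ~26 genes across nine genomes), sharing probability 0.15
for copying an accessory gene into later genomes, per-copy divergence
0.05 (per-site substitution probability — comfortably inside the range
where SRV stays far above 35), and gene lengths uniform on 120–400
residues. Ancestral sequences are i.i.d. uniform over the 20 residues,
which keeps E-value behavior predictable; there is no composition bias,
no indels, and no codon-level process. Optional clade structure draws a
clade-level ancestor at the global divergence and genome copies at a
lower within-clade divergence (default one fifth), producing the
within-clade < between-clade distance ordering a host-clade tree needs.
Motif planting rewrites the termini of randomly chosen loci with
construction-valid lipobox or LPXTG anatomy and records locus and
position; planting happens after mutation, so motif regions are exact.

All randomness flows through one seeded generator: identical parameters
and seed regenerate byte-identical FASTA and truth tables.

What passing on this generator does **not** show: robustness to real
annotation noise (fragmented ORFs, pseudogene calls, locus-tag drift),
domain-level mosaicism, indel-rich divergence, or composition-biased
proteomes. The generator is a correctness instrument, not a realism
claim.

## Verification experiments and problem sizes

The acceptance script and test suite recompute, at desk scale:

* aligner vs an independent explicit-gap-enumeration DP oracle, 50
  random pairs ≤ 60 aa;
* RBH pairing vs an independent all-pairs enumeration, 5 genomes × ~30
  genes;
* exact planted-partition recovery at divergence 0 (5 genomes) and at
  the generator defaults (9 genomes, divergence 0.05);
* recovery of a planted α = 0.7 within ±0.1, averaged over 20 simulation
  seeds (9 genomes, core 30, κ = 100, genes 80–160 aa — sizes chosen so
  exact alignment stays cheap while novelty counts remain well above
  rounding noise);
* NJ topology recovery on 100 random additive trees of 4–8 taxa;
* 100% recall of 20 planted motifs and zero false calls over 100
  composition-preserving shuffled decoys. A shuffle occasionally
  recreates a valid motif anatomy by chance; decoy ground truth is
  therefore an independent restatement of the anatomy rules, and the
  detectors must agree with it exactly.
* the mean genome size (2.04 Mbp) and mean ORF count (2053) of the nine
  published strain-attribute rows shipped as package data. The published
  protein-count mean is non-integral (1930.9) and is reported under both
  rounding conventions.

## Known limitations

* RBH orthology cannot represent co-orthologs or gene fusions.
* SRV-derived distances compress at high divergence (SRV hits 0 before
  homology is undetectable) and are not substitution-rate estimates.
* The family construction is reference-pivot and order-dependent in
  pathological conflict cases; a connected-components alternative
  (``build_families(..., method="components")``) merges more aggressively
  and is available for sensitivity analysis but is not the default.
* The surface screens trade the sensitivity of trained models for
  transparency; they are motif-anatomy detectors.
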