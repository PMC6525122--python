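# Methods

`mhchap` implements a complete in-silico version of a homozygote-anchored
MHC class IIa haplotyping study: genotype calling from mixed Sanger
consensus sequences, combinatorial haplotype inference across linked loci,
distance-based locus assignment for the duplicated DQB genes, and
codon-model tests of positive selection.  This note records the models,
their assumptions, the tunable parameters, and the design choices made
where the design was genuinely open.

## The genotyping model

A diploid PCR product co-amplifies between one and four allele sequences:
two at a single locus in a heterozygote, up to four when a primer pair
amplifies a duplicated locus pair (DQA2 + DQA2-like, DQB2 + DQB2-like) or
cross-amplifies allele-dependently.  The Sanger consensus of such a product
carries, per position, the IUPAC code for the set of superposed bases.
Genotype calling inverts this superposition by strict accounting: a set of
known alleles explains an observation only if its positionwise union
*equals* the observed codes.  All cardinality-minimal explaining sets are
enumerated (exhaustively, up to `kmax = 4` alleles, after pruning
incompatible candidates); one minimal set is a call, several are an
ambiguous call, none marks a suspected novel allele.  Candidates identical
over the assayed region are collapsed into an ambiguity group beforehand,
so indistinguishability yields a called group rather than a spurious
ambiguity (e.g. two alleles identical throughout exon 2).

Two deliberate semantics:

* **Exact equality, not containment.** A heterozygote's observed `R` must
  be *produced* by the candidate set, not merely permitted; containment
  would let a homozygote "explain" any mixture it is compatible with.
* **`N` is a genuine four-peak position by default.** An observed `N`
  must be produced by all four bases.  This is required for the
  deconvolution-equals-brute-force property to hold on generated data,
  where four-allele mixtures genuinely produce `N` columns.  Data sources
  that use `N` as a no-call can opt into `treat_n_as_missing=True`, which
  excludes such positions from both compatibility and equality checks.

Length-polymorphic mixtures (a 1-bp indel among the co-amplified alleles,
as with one DRB1 allele under the full-exon primer pair) shift the reading
of every downstream peak; they are flagged and reported as
`uncallable_frameshift`, never resolved by alignment — the remedy is a
different primer pair whose region excludes the indel (modelled as a
3'-anchored assay region).

## Haplotype inference

The anchor locus (DRB1 by default) has locus-specific primers and a
one-allele-per-haplotype guarantee, so an anchor-homozygous individual
carries two haplotypes bearing the same anchor allele.  Inference proceeds:

1. **Anchoring.** Individuals whose anchor call is a single allele (or a
   single ambiguity group) are grouped per anchor allele.
2. **Extension.** Within an anchor group, each individual's downstream
   profile (the called entry set per assay, with `no product` an
   informative empty set) is collected.  Pure haplotype homozygotes have
   componentwise-minimal profiles; anchor-homozygous individuals carrying
   two different haplotypes that share the anchor allele have profiles
   that are unions of two minimal ones.  Minimal profiles become
   haplotypes (this is how one anchor allele splits into several
   haplotypes); a composite profile covered by exactly one minimal profile
   contributes its componentwise residue as an additional, flagged
   haplotype.
3. **Heterozygote subtraction.** An anchor allele with no homozygotes is
   recovered from heterozygotes whose partner anchor allele maps to
   exactly one fully known haplotype: the partner's expected alleles are
   removed from each assay's call and the residue assigned to the rare
   haplotype.  Because calls are sets, an allele shared between the rare
   haplotype and one partner is invisible in that individual's residue;
   residues from different partner backgrounds are therefore pooled by
   union, and every usable individual's observation must equal
   union + partner (a genuine conflict otherwise).
4. **Validation-driven refinement.** The residue completion of step 2 has
   the same blind spot with no second background inside the anchor group.
   Anchor-heterozygous individuals elsewhere in the cohort expose a
   missing shared allele as validation failures, so candidate restorations
   of alleles shared with the covering haplotype are scored by the number
   of individuals left without any consistent haplotype pair, and the most
   parsimonious restoration minimising that count is kept.
5. **Validation.** Every individual is checked against all unordered
   haplotype pairs; a pair is consistent when, for every assay, its
   expected product (including expected `no product` at null loci) matches
   the observed call.  Individuals with no consistent pair are reported
   per assay (cross-amplifying assays cannot always localise the locus).
   Frequencies and homozygosity are estimated from resolved individuals,
   with equal fractional weights when several pairs are consistent.

`min_support` (default 4, the number of homozygotes the source protocol
genotyped per allele) does not suppress extensions below threshold; it
flags them low-confidence.  Statistical phasing (EM over unphased
genotypes) is intentionally out of scope — the method is purely
combinatorial, like the protocol it reproduces.

## The synthetic cohort generator

The generator emulates the study conditions, not sequencing physics:

* Diploid individuals are formed by random union of panel haplotypes
  (Hardy–Weinberg); the source population's haplotype frequencies are not
  published, so the default is uniform over the eight panel haplotypes.
  Inbreeding and cohort structure are not modelled.
* Assay profiles reproduce the printed primer behaviour: locus-specific
  DQA1 (null haplotypes yield no product), DQA2 co-amplifying DQA2-like,
  DQB primers with allele-dependent cross-amplification, cDNA assays with
  allele-specific dropout, and the full-exon DRB1 assay that produces a
  length conflict whenever the 1-bp-deletion allele is mixed with others.
* There is no noise model: with dropout and novel-allele injection
  disabled, observations are a deterministic function of genotype.  Novel
  alleles are injected per individual at a configurable rate and
  divergence (exact substitution count).
* All randomness derives from one master seed through fixed per-operation
  child seeds, so adding operations never perturbs earlier draws.

Passing tests on these cohorts show that the inference logic is correct
under the stated assay behaviour; they do not show robustness to base-call
errors, allelic imbalance in peak heights, or contamination, none of which
the curated-consensus workflow exposes.

### The packaged panel fixture

The eight-haplotype panel ships with the real allele names, sharing
structure, null loci, ambiguity group and fragment/full-length status, but
**synthetic stand-in sequences** (the real exon-2 alignments are published
only as images).  Stand-ins are generated deterministically: per gene
family a random in-frame ancestor (DRB1 80 codons, DQA 83, DQB 78), locus
ancestors at 24 substitutions from the family root (~10% divergence),
alleles at 2–8 substitutions from their locus ancestor, stop codons
excluded.  Full-length DQB alleles carry a 30-nt locus-specific 3' UTR
tag; exon-2-only fragments do not, which is what makes them
low-confidence in phylogenetic locus assignment.  Because the stand-ins
evolve neutrally by construction, selection analyses on the fixture
alignment correctly find nothing; the selection machinery is validated on
simulations with known omega classes instead.  Sequence positions are
1-based within the stored amplicon; the genomic offsets of exon 2 from
the translation start (83 for DQA, 110 for DQB) are carried as metadata
and never applied silently.

## Locus phylogenetics

Distances are K80 (Kimura two-parameter): with transition and transversion
proportions P and Q over pairwise-complete sites,
`d = 1/2 ln(1/(1-2P-Q)) + 1/4 ln(1/(1-2Q))`; saturation (domain violation)
is an error naming the pair.  Gap/N sites are deleted pairwise so that
exon-2-only fragments remain comparable with full-length alleles.

Trees are built by neighbour joining (Saitou–Nei Q criterion); negative
intermediate branch lengths are clamped to zero with the deficit moved to
the sister edge, and Q ties resolve to the first index pair, making the
output deterministic.  Support comes from a nonparametric bootstrap over
alignment columns.  This replaces Bayesian MCMC inference (the desk-scale
substitute is sufficient for cluster membership, which is all the locus
assignment needs); gamma rate heterogeneity is omitted since no shape
parameter is reported.  An outgroup is unnecessary — assignment operates
on unrooted bipartitions.

A query is assigned per bootstrap replicate to the locus whose references
it clusters with: the smallest clade containing the query plus all of a
locus's references must contain no other locus's references, and the
tightest admissible clade wins (this keeps a query branching immediately
outside a two-member reference cherry assignable).  The majority locus
across replicates is reported with its support fraction; support below
0.5 leaves the query unassigned.  Queries with more than 5% missing
columns (no 3' UTR) are flagged low-confidence.  If the reference
clusters are not monophyletic on the full-data tree, assignment falls
back to nearest mean K80 distance, flagged.

## Selection analysis

Pairwise dN/dS uses Nei–Gojobori (1986) counting: per-codon synonymous
site fractions (substitutions to stop codons count as nonsynonymous),
differences averaged over all minimal mutational paths with equal weight
(paths through stops excluded), Jukes–Cantor correction on both
proportions, ratio undefined when dS = 0.

The likelihood route uses a GY94-style codon model: single-nucleotide
changes only, rate(i→j) ∝ π_j · κ^[transition] · ω^[nonsynonymous], with
F3x4 codon frequencies and the matrix scaled so the class-weighted
expected substitution rate is one per codon per unit branch length.
Site-class mixtures:

| model | classes | free parameters |
|-------|---------|-----------------|
| M0    | one ω | ω, κ |
| M1a   | ω0 < 1, ω1 = 1 | p0, ω0, κ |
| M2a   | M1a + ω2 > 1 | p0, p1, ω0, ω2, κ |
| M7    | Beta(p, q) on (0,1), 10 equal-probability categories by mean | p, q, κ |
| M8    | M7 + ω_s > 1 | p, q, p0, ω_s, κ |

Likelihoods are computed by Felsenstein pruning vectorised over sites,
with the reversible rate matrix diagonalised once per class via the
π-symmetrised form; gap/ambiguous codons contribute partial likelihood
one.  Fits use bounded L-BFGS-B from three fixed starting points
(parameter bounds: ω0 ∈ (1e-4, 0.999), ω2/ω_s ∈ (1, 50), κ ∈ (0.1, 20),
beta shapes ∈ (0.05, 99); convergence tolerance 1e-8 on the
log-likelihood).  Branch lengths are fixed from the NJ guide tree after an
M0 pre-fit that estimates a single global scale into substitutions/codon;
joint branch-length optimisation is not performed, matching the
fixed-input-tree workflow.  When fitting a nested pair, the alternative
receives an extra start at the null's optimum (ω2 at its lower bound,
positive-class weight near zero), which guarantees the nesting inequality
numerically.

Nested models are compared by 2Δℓ against chi-squared with 2 degrees of
freedom (the statistic is clamped at zero; under the boundary null the
test is conservative-to-nominal, which the calibration test checks).
Bonferroni correction is α/m.

Per-site classification is naive empirical Bayes (NEB) under the fitted
M2a: class posteriors proportional to weight × site likelihood at the
MLEs, positive-selection flag at posterior > 0.95.  NEB plugs in point
estimates without integrating parameter uncertainty and can be
anti-conservative when estimates are poor; it replaces the Bayes
empirical Bayes variant, whose prior-integration grid has no stated
settings to reproduce.  The FEL-style scan fixes κ and branch lengths
from the M0 pre-fit, maximises each site's likelihood over a synonymous
rate α and nonsynonymous rate β (matrix αR_syn + βR_nonsyn, normalised so
α = β = 1 gives one expected substitution per codon), and tests β = α
with a one-sided df = 1 LRT; the positive flag requires p < 0.05 *and*
β̂ > α̂.  Per-site statistics below 1e-4 (optimizer resolution) are
reported as exactly zero.  MEME-style episodic selection is out of scope.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen to be the smallest that make the checked
properties sharp: cohorts of 200–400 individuals for panel recovery (at
n ≥ 300 and uniform frequencies, every haplotype has at least one
homozygote in almost every draw, and the subtraction/refinement paths
cover the remainder — measured exact recovery 40/40 seeds at both n = 200
and n = 300); 6-taxon, 60-codon alignments for the 100–200-replicate LRT
null calibration (single optimizer start — the null surface is
well-behaved, and the paired-fit seeding preserves nesting); 16-taxon,
60–100-codon alignments with tree length ≈ 7.5 substitutions/codon for
power and per-site detection.  The bootstrap default in the demo pipeline
is B = 200 (B = 5000-scale runs are supported but add nothing to cluster
membership on these data).

## Known limitations

* Set-valued calls cannot count allele copies, so subtraction and residue
  completion are blind to alleles shared with the subtracted haplotype;
  the union-pooling and validation-refinement steps recover these when a
  second genetic background exists in the cohort, and flag the haplotype
  low-confidence otherwise.
* The synthetic stand-in sequences preserve combinatorial structure, not
  the real substitution pattern; amino-acid similarity rankings between
  haplotypes and any selection signal in the fixture alignments are not
  meaningful, and the real study's per-site selection results are not
  reproducible without the external reference alignments.
* NEB site classification inherits MLE uncertainty; FEL at these sample
  sizes has modest power and its false positives are controlled only at
  the nominal per-site level.
* No recombination between haplotypes is modelled (haplotypes are treated
  as fixed units, as in the source protocol), and no recombination
  detection precedes the selection tests.
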