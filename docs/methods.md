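# Methods

This note documents the models, parameter choices and numerical
conventions behind `mitofounder`, and what the synthetic studies do and
do not establish.

## Reference, coordinates and consequences

Positions are 1-based on the linearised 16,569-bp circular mtDNA
reference.  The coding region is defined as positions 577–16023
inclusive (`constants.CODING_START/END`); the circular span
16024–…–576 is the control region.  Only single-nucleotide
substitutions are modelled; insertions, deletions and heteroplasmies
are rejected with a parse error, because every downstream computation
(parsimony counting, rho dating, N/S classification) operates on
substitution events.

The bundled reference FASTA is **synthetic**: the gene coordinates are
the standard human mtDNA annotation, but the sequence is random except
at anchor positions, where codons are planted so that the catalogued
pathogenic variants reproduce their published gene, amino-acid change
and codon index (e.g. T3394C → ND1 Y30H, ATA read as methionine under
the vertebrate mitochondrial code).  Any 16,569-bp FASTA can be
substituted via `load_reference(path)`.

Protein-coding genes are translated in the frame given by their
`frame_anchor` (the first base of codon 1; for the light-strand gene
ND6 the anchor is the 3'-most heavy-strand coordinate and translation
uses the reverse complement).  Incomplete terminal codons — mtDNA stop
codons completed by polyadenylation — are padded with A.  A variant in
the ATP8/ATP6 or ND4L/ND4 overlap is classified against each gene; for
N/S counting it is nonsynonymous if nonsynonymous in *any* frame
(conservative OR rule).  The classifier is verified against an
independent oracle that translates the whole gene before and after each
substitution with Biopython's table-2 translation.

The pathogenicity table filter removes records that are synonymous or
control-region against the reference, mirroring the curation convention
of pathogenic-mutation catalogues ("synonymous and HVS mutations
removed").

## Trees and rho dating

Edges carry mutation lists; leaves carry haplotype ids and one or more
samples.  `build_tree` is a greedy maximum-parsimony construction:
variant carrier sets (relative to a designated root haplotype) are
accepted in order of decreasing carrier count into a laminar family,
which yields a perfect phylogeny; each rejected (recurrent) site is
then placed once on the stem of every maximal clade wholly contained in
its carrier set — the minimal placement on the fixed tree.

For a clade with n member samples, ρ is the mean number of mutations on
the path from the clade root to each sample (per *sample*, not per
distinct haplotype, since the statistic averages over sequences; a
per-haplotype mode can be had by attaching one sample per leaf), and

σ² = Σₑ (nₑ/n)² mₑ

over edges below the clade root, where nₑ is the number of member
samples below edge e and mₑ its mutation count.  This is the standard
branch-weighted variance of ρ.  Ages are linear in ρ: the
`complete_linear` clock preset uses 1/(1.691×10⁻⁸ subs/site/year ×
16,569 sites) ≈ 3,569 years per mutation; the time-dependent
purifying-selection rate correction is *not* implemented — the clock is
a single configurable scalar, which is exact for the synthetic data
(generated under a linear clock) and an approximation for real data.

## Founder analysis

Under the f0 criterion (no minimum source-side frequency), a node is a
founder if

1. its haplotype is carried by both sink and source samples, or
2. it is a reconstructed ancestor with (a) no sampled carriers and both
   sink- and source-containing immediate derivative branches, (b) only
   sink carriers and a source-containing derivative, or (c) only source
   carriers and a sink-containing derivative.

"Carriers" of an internal node's haplotype are samples on zero-mutation
child leaves.  Each sink sample is assigned to its most recent founder
ancestor, so clusters partition the assignable sink samples.  Clades on
a back-migration whitelist have their source members masked throughout,
so limited lowland membership neither blocks sink-specificity nor
spawns spurious internal founders.

The founder-age scan evaluates density(t) ∝ Σₖ wₖ·Normal(t; ageₖ,
max(sdₖ, 200 y)) on the 0–50,000-year grid at 200-year spacing (251
cells), normalised to sum 1.  The Gaussian kernel is a choice (the
classical founder-analysis literature sums per-founder age
distributions without naming a kernel); flooring the kernel SD at one
grid step prevents exactly-dated founders from collapsing onto a single
cell.

The partition step computes, per cluster k and migration time τⱼ, the
likelihood L(k,j) = Poisson(mₖ; nₖτⱼ/ypm) of the cluster's total
mutation count, a uniform-prior posterior P(j|k) ∝ L(k,j), and the
lineage fractions pⱼ = Σₖ wₖP(j|k)/Σₖ wₖ with weights wₖ = n_adj
(membership restricted to the designated random subset).  The Poisson
form treats per-sample path counts as independent; shared edges within
a cluster make the true variance larger, which broadens posteriors
slightly but does not bias the weighted mean.  Standard errors come
from a nonparametric bootstrap over clusters (default B = 1000); the
choice of cluster-level resampling is a design decision, as is the
uniform prior.

## Synthetic data: what it emulates

The generator builds a source phylogeny (random-join topology with
uniform-ordered internal node ages, root at 60 kya by default), attaches
one sink clade per founder event on a source branch alive at the event
time, and drops mutations on every branch as Poisson(duration/ypm) with
variant identities drawn without positional replacement (recurrence by
explicit knob, or automatically once positions are exhausted).  Sink
clades either coalesce below the founder (`clade_shape="coalescent"`,
stem mutations accrue on the real stem duration) or radiate directly
from it (`"star"`, instant post-founding expansion).  Five sink
population labels emulate the multi-ethnic sampling structure; planted
pathogenic variants are placed verbatim on named stems and recorded in
the truth file.

The default study conditions are three waves at 30.0, 16.8 and 8.0 kya
holding 5/30/65% of sink lineages — the published three-phase
colonisation model — with ~60 founders and ~430 sink samples at the
whole-molecule clock.  Under those conditions the *partition* recovers
the wave proportions within its bootstrap SEs, but scan peaks are
localised only to ±1–2 ky: peak standard error scales as
√(ypm·τ/N_wave), which at 3,570 y/mutation and desk-scale sample sizes
is mutation-noise-limited.  The dedicated wave-recovery study
(`wave_recovery_config`) therefore uses a dense-marker clock (200 years
per mutation) and star clades with ~9,600 sink samples, which brings
the 30-kya peak's standard error to ~110 years so the 200-year grid is
informative.  This validates the scan/partition machinery, which is
clock-agnostic; it does not claim 200-year dating precision for real
mtDNA.  What the synthetic data do not emulate: mutational spectrum
(transition bias), rate heterogeneity across sites, sequencing error,
and realistic source-side population structure.

## Exact tests

2×2 tables use the two-sided hypergeometric rule (sum of tables with
point probability ≤ the observed, via scipy); the 2×3 test is a
Freeman–Halton full enumeration over the first-row margin with
probabilities computed in log space and the standard (1+10⁻⁷) slack on
the ≤-observed comparison.  The published lineage comparison is
reconstructed as the 2×3 table of lineages by {0, 1, ≥2} pathogenic
defining mutations, (11, 6, 5) vs (6088, 701, 68) with the specific
lineages *included* in the comparison set; this is the construction
whose exact p (4.87×10⁻⁸) matches the published value, and it is the
default (`enrichment_test(..., "2x3")`), with 2×2 collapses available.
Mann–Whitney U is exact (enumeration) for pooled n ≤ 12 without ties,
otherwise a tie-corrected normal approximation with continuity
correction.  Defining variants of a lineage are the mutations on its
stem branch only.

## N/S statistics

Each branch mutation is counted once; RNA and control-region mutations
are excluded from both N and S, and unannotatable positions (intergenic
spacers) are excluded with a logged count.  A branch is binned by
round-half-up of the ρ of the clade it subtends, capped at the maximum
bin; leaf branches are external (bin 0), bins 1..4 pooled form the
internal class (1..3 in the simulation statistic, matching the
published binning there).  When a bin has S = 0 its ratio is reported
as an infinity sentinel and excluded from comparisons.

## Forward simulation

A haploid Wright–Fisher population evolves through piecewise-constant
epochs: each generation, parents are drawn multinomially with weights
∝ fitness; offspring receive Poisson(L·μ) new mutations, each
nonsynonymous with probability f_ns = 0.7; a fraction 0.8 of
nonsynonymous mutations is selected, of which a fraction 0.1 is lethal
(the carrier's fitness is 0: it neither reproduces nor is sampled —
our reading of a "non-lethality 0.9" convention) and the rest
multiply fitness by (1+s) with s = γ/N_ref, N_ref the initial epoch
size.  Fitness is renormalised each generation (only ratios matter).
Full per-generation parent and typed-mutation-count arrays are kept
(compact dtypes, a few MB at these scales) and the sample genealogy is
rebuilt at the end by walking parent pointers backward, accumulating
each individual's birth mutations onto the current lineage stem;
mutations above the sample MRCA are discarded.  R = (N/S over ρ bins
1–3)/(N/S over bin 0); runs with an undefined ratio are excluded from
exceedance estimates and counted.

Desk-scale presets cap sizes at 2,000 with ~550 generations and rescale
μ to 2×10⁻⁶/site/generation (the θ-preserving convention for
scaled-down forward runs; the biological rate is ≈4.2×10⁻⁷).  The
initial epoch size is 500 so that γ = −50 maps to s = −0.1: at much
smaller N_ref the same γ gives s so strong that selected variants are
purged instantly and the statistic rebounds toward neutrality — an
over-scaling artefact, not the regime of interest.  Exceedance
monotonicity in γ is asserted only within 2 SE; even at full scale the
−20 → −50 step need not be monotone.  Under these presets the neutral
median R is ≈1 and every selected model's exceedance of R ≥ 1.129 falls
clearly below the neutral value, which is the qualitative signature the
simulation exists to demonstrate.

## Known limitations

* The linear clock ignores time-dependent rate calibration; real-data
  ages produced with it are systematically uncorrected.
* The partition likelihood treats cluster mutation totals as Poisson;
  tree correlation makes it mildly over-confident (bootstrap SEs
  absorb most of this).
* Greedy parsimony is exact for compatible data and minimal for
  isolated recurrences, but is not a general maximum-parsimony search.
* The simulator models no recombination (appropriate for mtDNA) and no
  diploid or epistatic selection; demography presets are shape
  approximations, not fitted trajectories.
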