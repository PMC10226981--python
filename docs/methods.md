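# Methods

This note records the models and estimators evoscreen implements, the
choices made where several conventions were defensible, and what the
synthetic generators do and do not emulate.

## Pairwise dN/dS (NG86 counting)

**Sites.** For each sense codon, the synonymous site count is the sum
over its three positions of (synonymous single-nucleotide changes)/3,
where changes creating a stop codon never count as synonymous but stay
in the denominator of 3. Hence S + N = 3 per codon exactly. Columns
containing a gap, an ambiguity code or a stop codon in either row are
excluded from both site and difference counts; site totals are averaged
over the two sequences.

**Differences.** Codon pairs differing at k > 1 positions are compared
along all k! single-step orderings, classifying each step as synonymous
or nonsynonymous, and averaging uniformly over the orderings that avoid
stop-codon intermediates (over all orderings if none avoids one).

**Distances.** pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p). When pS ≥ 3/4 (or S = 0) dS is flagged
inestimable; ω = dN/dS is reported only when dS > 0, otherwise it is
undefined — never coerced to 0 or infinity.

This counting estimator replaces likelihood codon models (PAML-style):
it has no free model parameters, is exactly reproducible, and its
accuracy is validated by simulation recovery (below) rather than by
equivalence to any particular ML implementation.

**Orthology and alignment.** Reciprocal best hits under local BLOSUM62
alignment (gap open −11, extend −1, ties to the lexicographically
smallest id) stand in for bidirectional BLASTP at package scale;
pairwise protein alignment is global Needleman–Wunsch with the same
scoring, and codon alignments are obtained by projecting the protein
alignment onto the CDSs (each protein gap becomes the codon gap `---`),
after verifying that each CDS translates to its protein row.

**Genome-pair filter.** A genome pair enters the screen only if its
median dS over genes with defined dS lies in the closed interval
[0.27, 0.47] — distant enough for signal, close enough to avoid
saturation. The bounds are inclusive because the operating range is
quoted as a closed interval.

**Clade contrast and FDR.** Per-gene ω samples (one per genome pair)
are compared between two clades with a two-sided Welch t test
(Mann–Whitney U available via `method="mannwhitney"`); with fewer than
two defined ω in a clade the gene's contrast is missing, and two
zero-variance clades give the degenerate p = 1 (identical constants)
or 0 (different constants). Benjamini–Hochberg step-up q-values
(via statsmodels) control the FDR at 0.001 by default. Mean percent
identity per clade is computed over gap-free alignment columns only,
and genes below 60% (strict) are flagged LOW_IDENTITY.

## Sequence-to-ecology scan

**Distances.** Trait tables use Gower distance: numeric traits
contribute range-normalised absolute differences, categorical traits
0/1 mismatches, averaged per species pair over the traits non-missing
in both (support counts are retained). A numeric trait with zero range
is skipped as uninformative. Sequence windows use uncorrected
p-distance over columns where both rows are non-gap. Missing cells are
explicit (NaN), never silently zero; the PanTHERIA sentinel −999 maps
to missing at read time.

**Dendrograms.** UPGMA (average linkage, via scipy) with labels sorted
lexicographically first, so the result is invariant to input order and
ties break deterministically. Merge heights are half the cophenetic
distances. Incomplete matrices are rejected; the window scan handles
them by greedy pairwise deletion (repeatedly dropping the species with
most missing pairs).

**Correlation.** The cophenetic correlation of two dendrograms is the
Pearson correlation of their cophenetic distance vectors over shared
leaves; it is undefined (missing) with fewer than 3 shared leaves or a
zero-variance vector. The phylogenetic reference uses patristic
distances on the supplied tree directly.

**Windows and ties.** The scan slides a 2-column window with step 1 by
default (overlapping windows give a smooth per-position profile; both
are configurable). A window is a *trend tie* iff r_eco is defined,
r_eco ≥ min_r (default 0.5), and r_eco ≥ r_phylo; maximal runs of
consecutive tie windows merge into regions reported in 1-based
inclusive columns. The tie rule is an operational stand-in for "the
ecological signal ties or beats phylogeny" and is deliberately simple
and parameterised.

## Introgression analysis

**Fixed differences.** Within a region, a site qualifies iff it is
biallelic across the union of panels, every non-missing modern genotype
is homozygous for one allele and every non-missing archaic genotype
homozygous for a different one, and the missing fraction per panel is
≤ `max_missing` (default 0 — fixity is absolute). Polarisation:
modern allele = ancestral ⇒ derived on the archaic lineage; archaic
allele = ancestral ⇒ derived on the modern lineage; otherwise
unpolarised.

**LD and blocks.** Fully phased panels use haplotype r² =
D²/(pA·qA·pB·qB); any unphased call switches to composite LD (squared
Pearson correlation of genotype dosages), always flagged in the result,
since real archaic genotypes are unphased. Block membership is strict:
r² with the tag > 0.8. The tag SNP is a user input, with an auto mode
choosing the SNP with most linked partners (ties to the lowest
position). Intervals are 1-based inclusive throughout, so a span
s..e has length e − s + 1; the published span chr14:57958614–58046101
therefore measures 87,488 bp (~87 kb).

**Survival test.** Under incomplete lineage sorting, recombination
breakpoints accumulate at r·t per bp (r in crossovers/bp/generation =
cM/Mb × 1e-8; t = combined modern + archaic branch length in
generations), so the surviving ancestral haplotype length around a
focal site is Gamma(shape 2, mean L = 1/(r·t)) and the survival
probability of an observed length m is exp(−m/L)(1 + m/L). The closed
form is used directly; tests verify it against numerical integration
(1e-9) and the regularised incomplete Gamma function (1e-12).

**Resolving t.** t is always an input, never hard-coded in the
library. The default used by the pipeline and the acceptance script is
t = 1.19e4 generations: with the published local recombination rate of
1.47 cM/Mb and the 87,488 bp haplotype this gives L ≈ 5,717 bp and
p = 3.7e-06, and corresponds to roughly 170 thousand years per branch
at 29 years per generation. Published branch-length estimates for the
modern–archaic divergence vary severalfold depending on calibration and
on the age of the archaic specimens; users with a preferred estimate
should pass it via `--t-generations` (p is extremely sensitive to t, so
the choice should always be reported alongside p).

**Frequencies.** Population allele frequencies divide the allele count
by 2 × (fully called diploid samples) of that population.

## Synthetic generators

**Codon pairs.** The ancestral sequence is uniform over the 61 sense
codons; each lineage accepts random single-nucleotide proposals —
synonymous with probability 1, nonsynonymous with probability ω
(relative) — until the accepted synonymous changes reach
ds_target × (ancestral synonymous sites), split evenly between the two
lineages. Stop-creating proposals are rejected; because rejected stop
opportunities still sit in the NG86 nonsynonymous site denominator, the
nonsynonymous acceptance probability is multiplied by a per-codon
compensation factor (nonsynonymous neighbours including stops /
excluding stops, ≈ 1.06 on average) so that the realised nonsynonymous
rate per NG86 site is exactly ω times the synonymous rate — the
property that defines ω for this generator. Without the compensation
the estimator would systematically read ω̂ ≈ 0.945 ω. Recovery measured
over 20 seeds per ω ∈ {0.1, 0.3, 0.5, 1.0} at dS ≈ 0.3 and 10,000
codons stays within mean |ω̂ − ω| ≤ 0.05 and mean |d̂S − 0.3| ≤ 0.03.
The scheme is an acceptance-ratio process, not a matrix-exponential
codon model: adequate for estimator validation, not for likelihood
comparisons.

**Trait-scan fixtures.** Species trees are random coalescent-style
ultrametric trees (Kingman waiting times, height scaled to 1), whose
long deep branches concentrate cophenetic structure in a few splits —
the property that lets a 2-column window carry tree signal at all.
Background columns evolve down the phylogeny and planted-window columns
down an independent trait tree (per-branch substitution probability
1 − e^(−rate·length), rate 1.5); traits are Brownian motion on the trait
tree plus relative noise (default 0.1). Defaults: 24 species, 60
columns, a 6-column planted window, 24 numeric traits.

**Genotype panels.** Defaults mirror the study conditions: modern
populations of 108 (scan), 208 (focal) and 64 samples, 3 archaic
genomes, 23 fixed differences of which 14 co-segregate on one phased
introgressed haplotype spanning exactly 87,488 bp at frequency 0.01 in
the focal population (0.008 in the secondary one), a 20/3 ancestral
split, and 60 background polymorphic sites (one scan-population sample
is forced heterozygous at each so background sites can never qualify as
fixed differences). With 416 focal haplotypes the realised carrier
frequency is 4/416 ≈ 0.96% — frequency granularity is one haplotype.
Non-member fixed differences receive independently placed carriers
(avoiding the introgressed haplotypes) so their LD with the tag stays
near zero. The archaic panel can be emitted unphased to exercise the
composite-LD fallback.

**What the generators do not emulate.** Recombination within the
simulated region (the planted block is in perfect LD; real blocks decay
at the edges), demographic structure, genotyping error, empirical
PanTHERIA value distributions, alignment error, and among-site rate
variation. Passing tests therefore demonstrate correctness of the
estimators and of the recovery logic under the stated statistical
structure, not performance on real consortium data.

## Numerical and degenerate-input conventions

- Coordinates 1-based inclusive everywhere; VCF is the serialisation.
- Undefined quantities (ω with dS = 0, correlations with < 3 shared
  leaves or zero variance, frequencies with no called samples) are
  None/NaN with an explanatory flag where applicable — never 0.
- Multiallelic VCF sites are kept whole; the fixed-difference logic
  excludes them via its biallelic-union rule.
- All generators are deterministic under a single integer seed; the
  pipeline report is byte-identical across reruns with the same
  configuration.

## Problem sizes

The shipped validation suite uses 10,000-codon simulations (80 for the
recovery grid), 2,000 null replicates for test calibration, 5 seeded
trait-scan fixtures of 24 species × 60 columns, and one 380 + 3 sample
panel of 83 sites per seed — sizes at which every quantity above is
stable to well within its stated tolerance.
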