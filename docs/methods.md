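# Methods

This note documents the models implemented in `atbias`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing
results.

## Composition profiling

AT content is the fraction of A+T among *called* bases: N and IUPAC
ambiguity codes are excluded from the denominator, and gaps never count.
This keeps windowed and per-feature values comparable between sequences
of different quality. U is normalized to T on ingest so RNA genes and
DNA use one alphabet; all handling is case-insensitive.

Windowed profiles use fixed, non-overlapping windows (default 200 bp,
the resolution at which AT structure in small organellar genomes is
usually plotted). The trailing partial window is dropped by default so
every value covers the same number of bases; `include_partial=True`
emits it. Length-weighted AT over a set of records is computed as the
AT content of their concatenation, which weights by called bases.

The per-feature summary reports length-weighted AT for each feature
kind (protein_coding, ncRNA, intron, intergenic) and a *coding
fraction*: the proportion of genome positions covered by protein-coding
or ncRNA features (i.e., neither intergenic nor intronic), with
overlapping features counted once.

## The stop-codon probability model

The null model treats a codon as three independent draws from a base
composition. `BaseComposition` holds either one probability vector or
three position-specific vectors (an F3×4-style null); the uniform-AT
constructor puts α/2 on A and T and (1−α)/2 on C and G. Expected codon
frequencies are products of per-position base probabilities; expected
amino-acid frequencies aggregate them by the genetic code and
renormalize over non-stop codons — observed proteins contain no internal
stops, so the null must condition on the codon not being a stop.

For the uniform-α composition and any code with stop set
{TAA, TAG, TGA} the stop probability collapses to the cubic
α²/4 − α³/8; the package exposes both the closed form and the 64-codon
enumeration, which agree to 1e-12, and the expected stop spacing
floor(1/P(stop)). The default genetic code is NCBI table 11
(bacterial/plastid). Plastomes that recruit TAG as a tryptophan codon
are expressed with `GeneticCode.with_overrides({"TAG": "W"})`, which
shrinks the stop set accordingly.

## The AT-column-removal convergence test

Extreme AT content can make unrelated lineages look alike: most columns
of an alignment then carry A or T in the shifted taxa regardless of
history. The diagnostic removes every column in which a focal taxon has
a definite A or T call (a gap or ambiguity code in the focal row
*retains* the column — it contains neither an A nor a T for that taxon),
rebuilds the tree, and compares placements.

Tree inference is distance-based by design: the diagnostic is the
filter-and-placement logic, not the tree engine, and neighbor joining
is small enough to verify exactly — against brute-force least-squares
topology search at five taxa and against patristic-distance recovery on
additive matrices. Distances are p-distance, JC69
(d = −(3/4)·ln(1 − 4p/3)) or K2P with pairwise deletion of
gap/ambiguous sites. Pairs beyond the JC69 saturation point
(p ≥ 0.749, or non-positive log arguments in K2P) are capped at 5
substitutions/site with a warning; the cap keeps saturated distances
finite and maximally distant without letting one pair dominate the NJ
Q-criterion numerically. A likelihood tree produced by an external
engine can be analyzed with the same placement functions, since they
accept any dendropy tree.

Bootstrap supports are the percentage of column-resampled replicate
trees (default 100 replicates, explicit seed) containing each
bipartition of the point-estimate tree; a replicate whose resampled
columns leave some pair with no comparable sites is redrawn. Supports
below 70 are collapsed before placement — the conventional threshold
for treating a clade as resolved.

Placement is operationalized by a versioned rule printed in every
report: take the smallest side over all non-trivial bipartitions of the
collapsed tree that contains the focal taxon (falling back to the whole
taxon set when collapse leaves a star); the placement label is the group
holding a strict majority of that side's non-focal members, otherwise
"unresolved". Ties are never broken arbitrarily. The paired test
(`convergence_test`) reports placements before and after filtering and
`moved = labels differ`; a filtered alignment shorter than a
configurable minimum (default 50 columns) adds a warning to the report
rather than failing.

## Coverage-bias correlation

Windows of the depth track (default 200 bp, matching the AT profile;
configurable, since the appropriate window depends on insert size and
genome size) are summarized by mean depth and correlated with window AT
content using Spearman's rank correlation (mean ranks for ties, via
scipy). Windows with zero covered bases are excluded with a logged
count: they usually mark assembly or mapping artifacts rather than
gradations of bias. Insert sizes are assigned to windows by pair
midpoint and summarized by the window mean; the correlation is over
windows with at least one pair. Rank correlation is used because the
depth–AT relationship is strongly nonlinear (orders of magnitude of
depth over a ~20-point AT range) while the claim of interest is purely
monotone.

## Genome-size estimation

Read arithmetic is exact algebra: coverage = n_reads·read_len/G and
G = n_reads·read_len/coverage, mutual inverses. The k-mer route divides
the total k-mer mass above an error cutoff by the multiplicity of the
genome peak (the largest count above the cutoff; ties resolve to the
lowest multiplicity with a warning). The error cutoff is an explicit
parameter, default multiplicity 3 — low enough to keep genuine peaks at
coverage ≥ 15×, high enough to drop the error spike that dominates
multiplicities 1–2 in real spectra. When no bin lies above the cutoff
the estimator raises instead of guessing: the peak is buried in the
error region and only a lower bound on genome size (read mass divided
by the cutoff) can be quoted.

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed and are byte-reproducible; there is
no global random state.

**Alignments.** Sites evolve independently along a binary guide tree
under HKY85 with *branch-specific* equilibrium frequencies and rate
multipliers, the transition matrix per branch being expm(Q·t·rate) with
Q normalized to one expected substitution per unit time. HKY with
per-branch frequencies is the minimal nonhomogeneous model that
produces compositional convergence; κ defaults to 2, a typical
transition/transversion ratio for organellar sequence. The default
convergence scenario places a focal taxon inside a plant-like clade and
an attractor inside a protist-like clade (8 + 8 taxa, 1,200 bp), with
background equilibrium AT 0.434 (typical of autotrophic-plant rRNA
genes) and the two shifted terminal branches at equilibrium AT 0.88
with a 20× rate multiplier. Under these conditions the two shifted taxa
reach ~85–90% AT and their mutual distance is far below their (often
saturated) distances to everything else, so unfiltered NJ groups them —
the artifact the diagnostic is built to detect. Not emulated: indels
(the guide alignment is gap-free), within-site rate variation,
selection, and codon structure; conclusions about real alignments with
heavy gapping rest on the filter semantics, not on these simulations.

**Depth tracks.** Window mean depth follows a log-linear decay in
window AT, d(AT) = d_max · exp(−λ·(AT − AT_min)) with
λ = ln(d_max/d_min)/(AT_max − AT_min), which hits d_max at the least
AT-rich window and d_min at the most AT-rich exactly (defaults 3,000×
and 17×). The log-linear form is a modeling choice — the motivating
observations are endpoint depths, not a curve — and the parameters are
exposed in `CoverageScenario`. Per-position depths are negative
binomial around the window mean (variance = mean + dispersion·mean²,
default dispersion 0.1; dispersion 0 gives the rounded deterministic
curve). Insert means fall linearly from 300 bp at the lowest window AT
to 200 bp at the highest, with Gaussian noise (sd 15 bp) and 25 pairs
per window. Not emulated: mappability structure, PCR duplicates, or
strand effects; the generator exists to give the correlation machinery
realistic monotone structure plus noise, not to model a sequencer.

**Genomes.** Alternating coding/intergenic blocks (gene lengths normal
around 800 bp, spacers sized to the target coding fraction) with i.i.d.
bases at per-kind AT targets; defaults 78.5% coding, coding AT 0.881,
intergenic AT 0.938. Realized per-kind AT is within ~2 percentage
points of target at ≥ 10 kb.

**K-mer spectra.** Each of ~G distinct genomic k-mers draws a Poisson
multiplicity at the k-mer coverage implied by read coverage
(coverage·(read_len − k + 1)/read_len, k = 21, read_len = 150), and
error k-mers pile up at multiplicity 1. Heterozygosity and repeats are
not modeled, so the spectrum has exactly one genome peak; the recovery
tests therefore validate the estimator's arithmetic, not its behavior
on repeat-rich nuclear genomes.

## Numerical conventions and tie-breaks

* NJ resolves Q-criterion ties by the first row-major minimum, so
  results are deterministic for a given taxon order. Branch lengths are
  not clamped; additive inputs yield exact non-negative lengths.
* Bipartitions are compared as leaf-label sets normalized to the side
  containing the lexicographically smallest leaf.
* Bootstrap supports are rounded to integers 0–100 and stored both as
  node attributes and newick internal-node labels.
* Smallest-clade ties in placement resolve by lexicographically
  smallest sorted leaf set; group-majority ties always yield
  "unresolved".
* Reports print numbers at 6 significant digits; JSON reports embed the
  tool version, the full parameter set and the seed, with timestamps
  confined to a `metadata` field so reruns are comparable.

## Problem sizes used in the test suite

The statistical acceptance checks run at sizes chosen to make the
effects unambiguous while keeping the whole suite fast on one CPU:
16-taxon, 1,200-bp alignments with 25 bootstrap replicates over 50
simulation seeds for the convergence comparison; 20-kb genomes
(100 windows) over 20 seeds for the depth correlation; and 100-kb
genomes at 15–30× for k-mer size recovery. These are desk-scale
versions of the motivating analyses; the deterministic results (stop
model, read arithmetic, filter/collapse/NJ oracles) are size-independent.

## Known limitations

* NJ placement is a stand-in for likelihood tree inference; it shares
  the qualitative vulnerability to compositional attraction but not the
  quantitative behavior of GTR+Γ ML trees.
* The AT-column filter conditions on definite A/T calls only; heavily
  gapped focal rows can retain many uninformative columns.
* The coverage model treats windows independently; no spatial
  autocorrelation of depth beyond what AT structure induces.
* `size_from_histogram` assumes a haploid single-peak spectrum.
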