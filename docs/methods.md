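# Methods

This note documents the models, numerical choices and known limitations of
`zoymap`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Cross simulation (`simdata`)

**Meiosis.**  Each gamete is an independent mosaic over the transmitting
parent's two homologs: the crossover count on a chromosome of length
*L* cM is Poisson with mean *L*/100 (the length in Morgans), crossover
positions are uniform, and the starting homolog is a fair coin.  Crossover
interference is deliberately not modelled — the analysis chain never
assumes it, Haldane's map function is the exact inverse of this process,
and Kosambi is applied only at the *estimation* stage (below).  The
realized gamete-level recombination fraction over *d* cM therefore
converges to r = (1 − e^(−2d/100))/2, which the suite verifies at
binomial tolerance.

**Genome template.**  The default genome is the 20-chromosome zoysiagrass
reference map shipped with the package (per-chromosome genetic lengths
53.5–126.4 cM, 1788.4 cM total; physical lengths 7.7–21.1 Mb).  Markers
are evenly spaced at a configurable cM interval (default 1 cM) or, for
study-scale runs, at the template's per-chromosome marker counts (8402 in
total).  Physical marker positions are interpolated proportionally to cM.
The default F2 size is 530 progeny, the size of the genotyped reference
population.

**Transmission-ratio distortion.**  A distortion locus has a favoured
parental allele and a transmission parameter k ∈ [0.5, 1].  In *gametic*
mode (the default), gametes carrying the disfavoured allele at the locus
survive with probability (1−k)/k, so the favoured allele is transmitted
with probability k per gamete; k = 1 fixes the favoured allele.  In
*zygotic* mode the same survival applies to disfavoured-homozygous
zygotes, so complete distortion (k = 1) leaves the 1 hom : 2 het pattern
(≈33%/66%) seen at fully distorted loci in real interspecific crosses,
where only the favoured parent's homozygotes and heterozygotes are
observed.  The two modes are distinguishable precisely by this signature:
one-sided gametic elimination yields 1:1 hom:het, zygotic elimination 1:2.
Gametic distortion is applied to both meioses of a selfed F1.

**Observation model.**  True genotypes (AA/AB/BB → A/H/B relative to
parent 1) are corrupted in four stages: (1) miscoding to one of the two
other definite codes with probability ε (default 0.005); (2) degradation
to a partial code with probability 0.02 (A→D, B→C, H→C or D with equal
chance) — partial codes C ("B or H") and D ("A or H") stand in for the
depth-threshold heterozygote-calling ambiguity of GBS pipelines, whose
exact generating mechanism is not modelled; (3) a negative-binomial read
depth (mean 30, dispersion 5) with cells under 8× scored U, matching the
standard per-sample depth filter; (4) extra missingness at rate 0.02.
These defaults produce matrices with realistic (~5–10%) missingness that
survive the 20% filters.  What the simulator does *not* emulate: linked
non-biallelic variation, scaffold misassembly (so physical order is always
truthful), depth-dependent allelic dropout, and shared library/batch
effects.  Passing tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to assembly or
batch artefacts.

**Causal gene.**  The two SNPs of the anthocyanin gene are placed fully
linked at one map position.  Phenotypes follow the deterministic penetrance
rules (below) applied to the realized diplotype, with an optional
misclassification rate that flips each tissue call independently.

## Mapping scores and filters (`genocode`)

Calls are encoded A/B/H (hom-ref / hom-alt / het), U below 8× depth,
after site filters (biallelic, MAF > 5%, QD > 10).  Caller merging unions
two call sets by (scaffold, position); per-sample conflicts at shared keys
resolve by Haplotype-Caller precedence (configurable, or to missing).
Tag consolidation greedily bins SNPs within 1 kb along a scaffold and
combines each individual's codes by genotype-set intersection: agreement
keeps the code, a definite code absorbs a compatible partial (A with D →
A), and a contradiction yields U.

Reorientation swaps A↔B and C↔D everywhere for markers whose parent calls
contradict their roles (P1 = B or P2 = A) and whose progeny fit 1:2:1.
Markers with H, a partial code, or missing data in either parent have
unknown linkage phase and are duplicated, the copy (suffix "r") carrying
the swap.  Cosegregating markers are collapsed on *exact* full score
strings including U — missing-tolerant matching would merge non-identical
information — keeping the lowest (scaffold, bp) as representative, with a
bin map for later re-expansion.  Filters run progeny-first (a bad sample
cannot eliminate markers): progeny then markers above 20% missingness,
then markers failing the 1:2:1 Pearson χ² test at p < 10⁻¹⁰, with C/D
cells excluded from the test counts (simple and conservative; fractional
allocation would require a model the data do not identify).  Removal
lists feed the distorted-region rescue.

## Linkage mapping (`linkage`)

**Two-point likelihood.**  For two markers in an F2 the joint genotype
distribution comes from two independent doubly heterozygous gametes in
coupling: a parental haplotype has probability (1−r)/2 and a recombinant
r/2, giving the familiar 9-cell table (P(AA,AA) = (1−r)²/4,
P(AB,AB) = ((1−r)² + r²)/2, P(AA,BB) = r²/4, …).  Partial codes
contribute the summed probability of their compatible genotypes; pairs
with a missing member are skipped (their marginal contribution is
constant in r).  The MLE is located on a 0.001 grid of precomputed
log-probability tables and refined by bounded 1-D search; LOD =
log₁₀ L(r̂)/L(0.5).

The likelihood optionally mixes in a genotyping-error confusion
P(observed | true) with rate ε, the same device classical mappers use for
error detection.  This matters quantitatively: with 0.5% miscoding and
1 cM marker spacing, error-blind adjacent estimates inflate the total map
by ~60% (measured 2875 vs 1788 cM at n = 530), while ε-aware estimates
recover it within 1% — the acceptance suite asserts recovery within 10%.
The error-free likelihood remains the default and is what the grid-search
oracle test checks.

**Grouping.**  Linkage groups are connected components of the graph with
an edge wherever LOD ≥ 12 — a deliberate simplification of MST-based
grouping, defensible because at this threshold components and MST clusters
coincide on realistic marker densities.  Within a component, markers whose
nearest neighbour exceeds 15 cM (Kosambi-transformed r̂) are set aside as
unplaceable; the 15 cM "no-mapping" rule is implemented as this placement
gate.  Mirror groups created by phase duplication (marker sets that
correspond 1:1 under the "r" pairing) collapse to the copy with more
non-reversed markers, ties broken lexicographically; a marker co-occurring
with its own twin is reported and left for ordering-stage resolution.

**Ordering.**  Groups of ≤ 8 markers are ordered exactly by enumeration.
Larger groups start from a seriation framework — the first principal
coordinate of the Kosambi distance matrix (classical MDS) — and are
polished by 2-opt segment reversals minimizing SARF, with 5 seeded random
restarts.  Adjacent markers separated by no recombination are ordered by
(scaffold, bp) when that does not increase SARF.  A final physical polish
swaps adjacent same-scaffold markers that are out of bp order whenever the
total double-recombination count does not grow: sampling noise at n ≈ 500
routinely inverts adjacent r̂ values of ~0.04 vs ~0.09, and such
transpositions masquerade as double crossovers.  This is the automated
analogue of manually verifying marker order against the genome assembly
and accepting a reordering only without a net gain in recombination
events.  Orientation puts the smaller physical position first on the
majority scaffold.

**Cleanup and distances.**  A double recombination is an X–Y–X pattern
(flanks equal, all three codes definite, middle different); markers with
more than 10 events across the population are removed — at ~0.2 cM marker
spacing a genuine double crossover within two intervals is vanishingly
rare, so the pattern is diagnostic of genotyping error.  Adjacent r̂
values then map to Kosambi centimorgans d = 25 ln((1+2r)/(1−2r))
(inverse r = tanh(2d/100)/2; the roundtrip is exact to 1e−12), with
distances at r → 0.5 capped at 50 cM with a warning.  Distortion-filtered
markers whose scaffolds belong to a target group can be rescued: they are
re-admitted and the group re-ordered without the χ² filter, recovering
driver-locus regions that the filter amputates.

**Two-point vs multipoint.**  Adjacent distances use two-point estimates
rather than multipoint EM re-estimation; at the marker densities this
package targets (≤ 5 cM spacing) the two agree closely, and the
error-aware likelihood covers the main benefit multipoint would bring.

## QTL scanning (`qtlscan`)

Conditional genotype probabilities on a grid (2.5 cM steps merged with
marker positions) come from a per-chromosome forward–backward pass over
states {AA, AB, BB} with the F2 stationary distribution (¼, ½, ¼).
Transitions invert *Haldane* distances — the no-interference convention of
interval mappers — even though reported map distances are Kosambi; the
mixed convention mirrors common practice and is the main deliberate
inconsistency in the chain.  Emissions give a definite code probability
1−ε on its state (ε/2 elsewhere, default ε = 10⁻⁴), partial codes 1−ε on
both compatible states, and U is uninformative.

Haley–Knott regression fits phenotype on the additive contrast
P(BB) − P(AA) and dominance P(AB) plus optional covariates by least
squares; LOD = (n/2) log₁₀(RSS₀/RSS₁) against the covariate-only null.
Binary phenotypes (green = 1, purple = 2) are analysed by least squares
because that is what Haley–Knott regression is; the LOD curve is invariant
to any affine recoding.  The covariate list is free-form: the reference
analysis used three marker covariates whose identity is not recoverable,
so the default is none and marker dosages can be passed explicitly.
Permutation thresholds shuffle phenotype labels jointly across the genome
(vectorized over permutations via QR projections), record the genome-wide
maximum LOD, and return the empirical (1−α) quantile with type-7
interpolation.  PVE = 1 − 10^(−2·LOD/n), algebraically identical to
1 − RSS₁/RSS₀ at the peak.  Support intervals take the contiguous
LOD ≥ peak − 1.5 run around the peak expanded outward to the nearest
flanking markers (the reference tables report flanking markers without
stating a rule; 1.5-LOD drop is the field's default).

At study scale (425 individuals, 20 chromosomes, 8402 markers, 2.5 cM
grid, 1000 permutations) the null α = 0.05 threshold computed by
`scripts/acceptance.py` lands at 4.06–4.36 LOD across seeds (4.27 at
seed 1), matching the published 4.3 for the same configuration.

## Two-SNP gene model (`inheritance`)

Phenotype rules (full penetrance): stolons are green iff SNP_917 is AA;
seed heads are green iff SNP_917 is AA, or SNP_632 is TT, or the plant is
heterozygous at both (GA and GT).  Enumerating the 9 unphased genotype
combinations, 6 give green seed heads and 3 green stolons.  The TT rule
follows from the genetic argument (homozygosity for the seed-head
mutation suffices) even though a TT plant cannot arise from the reference
crosses and was never observed.  Intragenic recombination between the two
SNPs (~1.7 kb apart) defaults to 0 but is configurable; with rational
inputs, cross expectations are exact rationals.  Misclassification lives
only in the simulator — the rules themselves are deterministic.

In-silico CAPS genotyping substitutes each allele's base into the
amplicon, matches the recognition site with IUPAC ambiguity in both
orientations (overlapping occurrences included), and places one
double-strand break per site occurrence at the top-strand cut offset —
for palindromic sites (DdeI's CTNAG) forward and reverse readings
coincide and are cut once; complete digestion is assumed.  Fragment sets
are compared as sets of lengths, as on a gel; a heterozygote shows the
union of both alleles' bands.

## Map reporting (`mapreport`)

"Region covered" is last-marker bp − first-marker bp (0 for singletons),
% coverage its ratio to the chromosome length; totals and averages are
sums and arithmetic means over groups, and the mean inter-marker distance
is total cM over total intervals (markers − groups).  The mean of per-LG
coverages and the pooled ratio agree within 0.5 points on the reference
table (both round to 98.9%).  The genetic-vs-physical length correlation
is reported against both the chromosome length and the covered span,
because published values rarely state which was used; on the reference
table r² vs chromosome length is 0.867.  The distortion scan tests each
marker's definite counts against 1:2:1 (default flag threshold 10⁻¹⁰),
labels the over-represented parent, and reports contiguous flagged runs.

## Problem sizes and tolerances

The test suite runs the permutation-threshold check at the full study
scale (n = 425, 8402 markers, 1000 permutations; ±0.3 LOD, the
seed-to-seed spread of the statistic itself) and the recovery properties
at their stated sizes: map length at n = 530 with 1 cM spacing (±10%),
QTL peak within 2.5 cM (one grid step) in ≥ 90% of 50 replicates at
n = 425, support-interval coverage at n = 200, RF estimates within 1e−3
of a 0.001-step grid oracle, ordering exact for ≤ 8 markers.  Grouping
and end-to-end map-building tests use 2–20 chromosomes at 5–10 cM marker
spacing with 150–530 progeny, sizes at which pairwise RF estimation stays
in seconds.

## Known limitations

* Pairwise RF estimation is O(m²) in markers; building a full 8402-marker
  map is out of intended scope (grouping at that density would want the
  MST machinery this package deliberately replaces).
* The simulator's distortion acts at a point locus; real drive systems
  produce distortion gradients along the chromosome.
* Mirror-group resolution assumes the "r" suffix convention produced by
  the phase-duplication step.
* The HMM assumes marker order and distances are correct; it does not
  re-estimate the map.
* F1-family simulation models founders as marker-homozygous, so its
  score matrices are uninformative for mapping (the design exists for the
  gene-model tests, where parental heterozygosity at the gene is what
  matters).
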