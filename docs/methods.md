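# Methods

This note documents the models, estimators and numerical choices behind
`ylinkkit`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem was genuinely open.

## The population model (`simpop`)

A discrete-generation Wright–Fisher population of `pop_size` diploids with a
fixed male fraction (`sex_ratio`, default 0.5). Each offspring draws a
random mother and father with replacement; sons receive the father's Y and
one maternal X chosen uniformly, daughters the father's X and one maternal
X; at each autosomal locus the offspring receives one allele from each
parent. Mutation is infinite-sites with Poisson(`mu_per_locus`) new,
globally unique mutations per transmitted locus copy (realized by thinning:
a Poisson total over all copies scattered uniformly — exactly equivalent to
iid per-copy draws).

**Linkage structure.** Loci assort independently (free recombination between
loci) but are internally non-recombining, so each locus carries its own
genealogy — except the Y, where all loci ride the single paternal lineage,
as a non-recombining Y does in nature. This choice matters: a model in which
each compartment is one linked block has the correct expected diversity
ratios but a single-genealogy coalescent variance so large that means over a
handful of replicates are uninformative. With 200 quasi-independent loci per
compartment the per-replicate standard deviation of θ̂_X/θ̂_A is ≈0.02 and of
θ̂_Y/θ̂_A ≈0.07 (the Y stays noisy because its loci share one genealogy).

**Defaults** (the study conditions all tests use): `pop_size=200`,
`sex_ratio=0.5`, `mu_per_locus=0.005` and `n_loci=200` for each of A/X/Y,
burn-in `10·pop_size = 2000` generations (configurable — equilibrium
convergence is the premise of the neutral-ratio checks), samples of 20 males
and 20 females. With copy numbers 2N : 1.5N : 0.5N these give
E[θ_X/θ_A] = 3/4 and E[θ_Y/θ_A] = 1/4. `theta_ratios()` divides each
compartment's per-locus θ̂_W by its mutation rate first, so unequal rates
still estimate pure copy-number ratios. Haplotype states are parent-pointer
chains of mutation events, so memory scales with mutation events, not
population-by-generation tables.

**Layout overlay.** Sampled mutations are placed on a genome layout
(0-based half-open internally; VCF written 1-based). Autosomal mutations go
on the autosomes *and the PAR* — the PAR recombines freely, so autosomal
statistics are the right behavior there. X mutations go on stratum I+II
coordinates. Y mutations map to stratum II with probability `stratum2_frac`
(default 0.3; X and Y both align to the female reference there — divergence
without coverage loss) and otherwise to stratum I, where only
`stratum1_mappable_frac` (default 0.7) remain visible as male-limited
heterozygous SNPs; the rest stand for Y sequence too diverged to map, whose
effect appears instead in the synthesized depth tables. Sampled males are
grouped into `n_y_lineages` classes by average-linkage clustering of Jaccard
distances between Y mutation sets, and each class receives
`marker_snps_per_lineage` (default 5) lineage-marker SNPs in stratum I so
classes stay distinguishable even when the sampled genealogy is shallow.
The truth manifest lists planted male-limited and fully-male-linked
positions (sites whose alt allele lives on the Y or is a marker); chance
male-limited genotype patterns on autosomes are discoverable but are not
truth.

Genotype support values default to "clean": depth Poisson(30) clamped ≥8,
het allele depths balanced with ≥3 reads per allele, QUAL uniform in
(100, 900), strand counts ≥3 per strand. Under these defaults the filter
cascade's only active rule is the allele-balance decile (which removes the
lowest tenth of non-fixed sites *by definition*); noisier settings are for
stress tests.

**Depth synthesis** draws per-window median depths Poisson around sex means
(defaults 30× male, 20× female, the coverage asymmetry typical of such
designs); male windows overlapping a degenerate subinterval are scaled by
`degeneracy_factor` (default 0.75 — one of two male haplotypes contributing
half coverage over the Y-divergent half).

**Sequence synthesis** builds a random reference whose base at every variant
position equals the REF allele, applies each individual's phased alleles,
and inserts a Y-only segment (default 200 bp; per-lineage variants optional)
into each male's Y haplotype at the midpoint of the first degenerate
interval. The manifest lists the canonical k-mers fully inside the
insertion (length − k + 1 of them); junction k-mers spanning the insertion
boundary are also Y-only but are excluded from the planted count. Insertion
k-mers are drawn until none collides with the reference. k-mer count tables
emulate reads by scaling per-copy counts with Poisson(copies × coverage)
and sprinkling sub-floor error k-mers. Sequence work uses the small
(hundreds-of-kb) layout; the chromosome-scale layout exists for windowed
statistics where no sequence is materialized.

**Molecule synthesis** places barcode-tagged molecules (20–60 kb) uniformly
per haplotype. With a Y inversion (a, b), molecules on the male Y haplotype
crossing a breakpoint split into two reference-space footprints via the
mirror map x → a + b − x; molecules fully inside the inversion stay
contiguous and are left at their drawn coordinates (their mirrored position
is irrelevant to the distant-pair statistic).

**What the generator does not emulate:** read-level sequencing error and
mapping bias, linked selection and demography (no bottlenecks, no
migration — the "two populations" of a river are emulated by splitting one
panmictic sample, the limiting case in which Y haplotypes are freely
shared), recombination within loci, phase-switch errors (haplotypes are
perfectly phased), and TE biology. Passing tests therefore demonstrate the
*statistical machinery* — estimators, thresholds, null calibration,
planted-feature recovery — not robustness to alignment or phasing artifacts
in real data.

## Filter cascade (`vcfguard`)

Rules run in a fixed order and every removed site is attributed to the first
rule that removes it, making audits deterministic; order-shuffling the input
changes nothing but that attribution. Cohort constants are computed once on
the input: the **average depth** of the max-depth rule is the cohort mean of
*per-genotype* DP (the cap `avg + 3√avg` is compared to single-genotype
depths, so they must share a scale), and the **allele-balance threshold** is
the 10th percentile of site AB (mean het alt-fraction) among non-fixed
sites; fixed sites are exempt. Both constants are recorded in the audit and
can be passed back in, which makes re-filtering idempotent. "Homozygous
variants with quality <50 and depth <4" is applied as genotype-level
masking of homozygous genotypes at sub-threshold sites; a site is removed
when no alt-carrying genotype remains. Heterozygous genotypes with fewer
than 3 reads supporting either allele are masked to missing; SNPs with >10%
missing genotypes after masking are dropped. Multiallelic records are
rejected at the VCF reader (decomposition is an upstream concern).

## Windowed statistics (`covwin`, `divstats`)

Windows are non-overlapping, 0-based half-open, tiling each chromosome
(default 50 kb; a short trailing window is kept). Coverage normalization
divides by each individual's genome-wide median window depth, making the
M:F ratio invariant to per-individual sequencing effort; the ratio is a
ratio of sex means (robust to unequal sample sizes) with a log2 option.
Interval densities merge overlapping inputs before counting covered bp.

Hudson F_ST is the ratio of sums ΣN/ΣD (the standard choice for this
estimator; per-site ratios are unstable), over biallelic SNPs after
excluding cohort-wide singletons (minor allele on exactly one chromosome,
applied before the per-sex missingness filter) and sites with ≥20% missing
genotypes in either sex; windows need ≥5 usable sites (tunable) and a
nonzero denominator, else NaN. The bootstrap band resamples autosomal
*window values* with replacement and takes the percentile interval of
replicate means. Note that a mean-CI is necessarily much narrower than the
window scatter: it bounds the autosomal mean, and sex-linked windows exceed
it by orders of magnitude, but individual autosomal windows above the band
are expected and not an error. Watterson's θ_W = S/(a_n L) counts a column
as segregating when it holds >1 distinct non-missing state; for SNP-only
alignments L is the window's genomic span (intervening sites are invariant
by construction). Kruskal–Wallis and χ² delegate to scipy (identical groups
short-circuit to H=0, p=1, which scipy rejects).

## Male-linked SNPs (`sexsnp`)

Candidacy requires every non-missing female homozygous for one allele and
the other allele appearing *only* as male heterozygotes; any homozygous
carrier of the male-limited allele disqualifies the site (this is
label-independent, which the permutation machinery exploits). Either allele
may be the male-limited one — at sites where the alt is fixed on all X
copies, the *reference* allele marks the Y. Tier fractions use non-missing
males only and thresholds are strict (>0.88, >0.77, >0.66; "full" is
exactly 1). The null permutes individual sex labels preserving group
sizes; classification across a batch of permutations reduces to three
matrix products of genotype-state indicators with the label matrix, so
10,000 iterations take seconds. "Accounting for chromosome size" is
implemented as per-Mb rates against the null's 95th percentile; enrichment
χ² tests use expectations proportional to stratum length and, when
positions are supplied, to stratum SNP content.

## Gene trees and networks (`treescan`)

Windows are consecutive blocks of exactly 100 SNP columns (trailing
remainder dropped); every individual contributes two leaves. Distances:
p-distance with pairwise deletion of missing characters; JC69
−(3/4)ln(1−4p/3) with saturated pairs (p ≥ 3/4) capped at 5.0; F84 by the
closed-form inversion from transition/transversion proportions and
empirical base frequencies (one pseudocount per base keeps it defined on
degenerate alignments), cross-checked in tests against a numerical ML
optimizer over the F84 generator. NJ and BIONJ are implemented directly
with deterministic tie-breaking: taxa are sorted by label before
agglomeration, so results are independent of input row order. BIONJ uses
the variance-weighted reduction with λ clamped to [0, 1]. SPR refinement is
deliberately omitted: in 100-SNP windows the monophyly call is driven by
clustering, and distance-tree topologies suffice — a documented fidelity
deviation from refined-tree practice.

Monophyly is evaluated on bipartitions of the unrooted tree. A side
qualifies for a population when it contains no female leaves (from any
population) and more than 2/3 of that population's males contribute exactly
one haplotype each; a male with both haplotypes on the side is not counted
toward the quota but does not disqualify it (so incomplete lineage sorting
is not punished). A window is "shared" when a qualifying side carries
haplotypes of both populations and meets the quota in at least one — the
per-population quota for the XY call and the at-least-one quota for sharing
are both available. The clade-diversity baseline takes one haplotype per
male (random haplotype index per male per window) from 1,000 randomly
sampled autosomal windows; a single haplotype *in total* would leave
diversity undefined, so the per-male reading is the operative one.
Haplotype networks collapse identical sequences, keep multiplicity and
population composition, and build a Kruskal MST on Hamming distances with
edges pre-sorted by (weight, node index) for determinism; non-tree edges
tying the maximum-weight edge on the tree path between their endpoints are
reported as alternative links. "Mean mutational steps within a population"
averages MST edge weights between nodes that both contain that population.

## Y-mers (`ymer`)

k-mers are encoded 2-bit; the canonical form is the numeric (equivalently
lexicographic) minimum of a k-mer and its reverse complement, and k-mers
touching non-ACGT characters are skipped. The published "counts <3 in any
individual" rejection is read as a *per-individual presence floor*: counts
below 3 are sequencing-error absences in both sexes — the literal global
reading would discard every Y-mer because all females lack them. The mean
count condition averages raw counts over all same-sex individuals (zeros
included) and is strict (>5). The false-positive rate at a carrier
threshold is the ratio of female-specific to male-specific k-mer counts
under identical thresholds (undefined when no male-specific k-mers
survive); the chosen threshold is the smallest with FPR < 5%. Scaffold
mapping is exact (canonical codes match both orientations); k-mers hitting
more than one scaffold are excluded from unique counts, and enrichment
needs ≥100 unique Y-mers plus more than the homologous haplotype when a
pairing is supplied.

## Barcode scan (`bxscan`)

The linked-read rearrangement scan is a *reconstruction* of a qualitatively
described method, not a replication: per individual, a barcode links two
windows when its molecules overlap both and the window starts differ by at
least `min_gap` (default 1 Mb); a pair is called sex-differential when
supported in ≥80% of one sex and ≤10% of the other. On symmetric input the
call set is empty by construction; a planted Y inversion is called at the
breakpoint windows, in males only.

## Numerical and degenerate-input choices

- Windows with no usable sites, zero denominators, or empty alignments are
  NaN/missing, never zero.
- Normalization by a zero or undefined median depth raises.
- Watterson's estimator requires ≥2 haplotypes; clade diversity requires ≥2
  Y and ≥2 X leaves; Hudson's correction terms require ≥2 chromosomes per
  group — all enforced with errors, not silent NaNs.
- The S ≤ L sanity check on θ_W is lifted for infinite-sites loci, where
  one locus legitimately carries several segregating mutations.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; identical seeds give byte-identical fixture files.

## Problem sizes

The shipped configurations — 200 diploids, 2,000 burn-in generations,
200 loci per compartment, 40-sample cohorts on a ~90-Mb four-chromosome
layout, a ~450-kb layout for sequence/k-mer fixtures and a 6-Mb layout for
molecule fixtures, 10 replicate simulations for the neutral-ratio checks and
10,000 permutation iterations — are the package's chosen study conditions;
they run in seconds to a couple of minutes each on a single CPU.

## Known limitations

- The simulator's "two populations" share one panmictic gene pool; shared-Y
  detection is exercised in its easiest regime, and population-specific Y
  haplotypes arise only through sampling.
- No read-level simulation: vcfguard's max-depth and strand rules are
  exercised with planted support values, not with realistic error
  processes.
- BIONJ/NJ without SPR can misplace individual leaves on noisy windows; the
  monophyly quota (>2/3, one-haplotype-per-male counting) absorbs most but
  not all of this.
- F84 distances on 100-SNP windows estimate base frequencies from variant
  columns only, which overweights variable sites; JC69 is the default for
  that reason.
- The barcode statistic has no base-pair breakpoint resolution and no
  split-read evidence; it localizes to the window grid.
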