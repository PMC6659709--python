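# Methods

This note documents the models implemented in `mtpopgen`, the conventions
and defaults behind them, what the synthetic-data generator does and does
not emulate, and the package's known limitations. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Data model

All statistics operate on a haploid allele-index matrix over a single
non-recombining contig. Organellar variant callers usually emit
diploid-coded genotypes; homozygous calls collapse to one allele index
and heterozygous (heteroplasmic) or half-missing calls follow a policy —
by default they become missing, because heteroplasmy is noise for a
uniparentally inherited genome. A "major-allele" policy (assign the
site's majority allele, missing on ties) is available for users who
prefer to rescue those calls.

Coordinates are 1-based in `VariantRecord` (VCF convention); all window
arithmetic is 0-based half-open internally. A variant is a SNP iff the
reference and every alternate allele are single bases; Ts/Tv is defined
for biallelic SNPs only. Annotation regions follow the precedence
CDS > ORF > intergenic, with `gene` features counted at ORF precedence,
because coding-region and reading-frame counts are reported separately.

## Filters and summaries

The quality filter retains sites with minor allele frequency ≥ 0.01 and
missingness ≤ 0.20, both computed on non-missing haploid calls over a
configurable sample scope (default: the whole collection; per-group
re-filtering is explicit, since collection-wide and subset HQ counts
differ). Filtering is idempotent for a fixed scope.

A variant counts as "present" in a group when at least one member
carries a non-reference, non-missing allele. This default reflects a
reference genome that is itself a member of one subgroup, so
non-reference carriage is what varies between subgroups; a
"polymorphic-within-group" rule is available. The shared-variant table
is the exact inclusion–exclusion partition: each variant is assigned to
the cell of precisely those groups where it is present.

## Diversity

Site diversity for allele counts `c_1..c_k` among `n` non-missing calls
is `1 − Σ c_i(c_i−1)/(n(n−1))` (mean pairwise difference,
pairwise-complete per site). Window π divides the summed site values by
the full window length — monomorphic and uncalled positions count as
invariant, the convention of VCF-based window tools. Windows are 1000 bp
with a 500 bp step by default; a 500 bp window is a one-flag change
(both appear in the literature this package serves; the Methods-style
1000/500 pair is the default). InDels count as single segregating events
at their anchor position for π (group diversity is conventionally
reported on "whole variation"), while Tajima's D and the μ scan use SNPs
only, where the infinite-sites mutation model is closest to true.

Group comparisons use a Welch two-sample t-test on window π values.
Windows are overlapping and share one genealogy, so the p-value should
be read as a descriptive contrast, not as if windows were independent.

## Tajima's D

`D = (π̂ − S/a₁) / √(e₁S + e₂S(S−1))` with the standard constants from
the sample size. Because the constants assume a fixed `n`, sites with
any missing call within the group are dropped for this statistic; `π̂`
is the mean pairwise-difference count summed over the retained sites.
`D` is NA when `S = 0` or `n < 4`.

On a fully linked genome the neutral expectation of `D` is not zero:
with one shared genealogy the statistic's skewness is not averaged away
across loci. Our neutral simulations at `n = 20` put the genome-wide
mean near −0.14 (cross-checked against an independent coalescent
simulator). Window-averaged D at the default resolution sits closer to
zero. Users comparing a single non-recombining genome's D against 0
should keep this offset in mind.

## F_ST

The Weir–Cockerham (1984) variance-component estimator adapted to
haploid data: each call is one allele draw, the within-individual
("heterozygosity") components vanish identically, and the estimator
reduces to `a / (a + b)` per allele, combined across sites and alleles
as a ratio of sums (the "weighted" estimator). Sites need at least two
non-missing calls in each group and pooled polymorphism to contribute;
multiallelic sites contribute one component pair per allele. Negative
per-window values are reported as computed; only the genome-wide ratio
of sums is the headline number.

## PCA and MDS

PCA is an SVD of the mean-imputed, frequency-centered sample × biallelic
SNP dosage matrix (imputation to the site mean is deterministic and
standard). MDS is classical (Torgerson) scaling of the pairwise
identity-by-state mismatch distance, computed pairwise-complete. For a
Euclidean-embeddable distance matrix classical MDS reproduces the PCA
configuration up to rotation and sign.

## Reduction-of-diversity scan

Per aligned window, `r = π_wild / π_cultivated`. Windows with
`π_c = 0 < π_w` — exactly the windows a sweep in a bottlenecked group
produces — are capped at +∞ and rank above every finite ratio rather
than being dropped; windows with `π_w = π_c = 0` carry no information
and are excluded. Selection takes the windows at or above the
`k = ceil(cutoff% × n_scored)`-th largest score, including boundary
ties (deterministic and order-independent); adjacent or overlapping
selected windows merge into regions by interval union. The cutoff
defaults to 5%; a 2.5% reading is one flag away.

Recovery scoring (`simulate.evaluate_recovery`) calls a planted sweep
detected when the scan's merged regions cover at least half of the true
interval. The majority-coverage rule was fixed from window geometry
before any recovery measurement: a real ≥10 kb sweep depresses
diversity in essentially all of its 1 kb windows, while at a 5% cutoff
noise windows are scattered singles — any-overlap against ~50 selected
windows would flag a fixed 10 kb probe in most neutral replicates, which
is a property of the probe, not of the scan.

## Composite μ

Windows are the `W = 20` SNPs nearest each grid point (grid step 50 bp),
split into halves; only biallelic SNPs segregating within the scanned
group enter. The factors:

- `μ_var = span_bp / (L · W)` — sweeps leave SNP deserts, stretching the
  span of a fixed-count window;
- `μ_sfs` = fraction of window sites whose minor allele count is 1 (the
  folded singleton class; without an outgroup the spectrum cannot be
  polarized, so derived singletons and (n−1)-count alleles collapse into
  this one class);
- `μ_ld` = (mean r² within left half + within right half) / mean r²
  between halves, with r² on haploid allele indicators (mean-imputed at
  missing calls). If the between-half mean is zero the factor is 1 when
  the within terms are also zero and equals the within sum otherwise — a
  bounded convention for a degenerate case that is rare on real data.

`μ` is their product; factor values are reported alongside. **Power
caveat:** the generator models sweeps by thinning diversity only, and a
non-recombining genome is one linkage block, so in simulated data the
SFS and LD factors carry no sweep signal — they only multiply noise. The
acceptance check asking the mean μ inside a 10 kb planted sweep to clear
the background's 95th percentile in ≥80% of replicates fails under
those conditions (the span factor alone separates; the composite does
not). On real data with genuine post-sweep SFS skew the composite is
expected to behave better; for thinning-style simulations the ROD scan
is the reliable detector.

## Introgression painting

Diagnostic alleles for an ordered group pair are those with frequency
strictly above 0.95 in the focal group and strictly below 0.05 in the
background group (≥5 non-missing calls per group per site). Painting
walks each accession along the position-sorted union of both directions'
diagnostic loci; runs of at least `min_run = 2` consecutive other-group
calls become candidate fragments (a single locus is indistinguishable
from homoplasy or a genotyping error; `min_run = 1` restores the
literal reading). Missing or non-diagnostic calls do not break a run by
default. Fragment bp extent runs midpoint-to-midpoint between flanking
informative loci, with edge loci extended by half the median
inter-locus spacing — the locus positions bound the true breakpoints
only to the neighboring intervals, and midpoints are the unbiased
convention. The introgression proportion is total fragment bp over the
reference length.

## Haplotype network

Haplotypes collapse identical allele vectors after handling missing data
by dropping incomplete sites (default, mirroring common haplotype
software) or incomplete samples. Haplotype counts are therefore
policy-dependent, and both policies are exposed. The network is a
minimum spanning tree over pairwise Hamming distances with a
deterministic lexicographic tie-break; a connection limit (fixed, or
derived from a 0.95 parsimony criterion) cuts longer edges into
components. The full statistical-parsimony network with inferred
intermediate haplotypes is intentionally simplified to the MST: the
network is used for sharing and cluster structure, not ancestral-state
inference. The parsimony-95 limit uses a Poisson multiple-hit argument:
for `j` observed differences over `m` sites, with `d` the Jukes–Cantor
substitution number at `p = j/m`, the chance all `j` changed sites are
single hits is `(d·e^{−d}/(1−e^{−d}))^j`; the limit is the largest `j`
keeping this at ≥0.95 — the same confidence level the TCS criterion
uses, with a simpler estimator behind it.

## Bottleneck test

For each polymorphic locus (group-level MAF ≥ 0.05, per the standard
pre-filter for this test) the observed unbiased gene diversity
`He = n/(n−1)(1 − Σp²)` is compared with its equilibrium distribution
under the infinite-allele model conditional on the observed allele
count: θ is matched by solving the Ewens expectation
`Σ_{i<n} θ/(θ+i) = k`, configurations are simulated by a vectorized
Hoppe-urn scheme and rejection-conditioned on `k`. Only the IAM is
offered — the stepwise mutation models target microsatellites and are
meaningless for sequence variants.

Two numerical choices matter for the across-loci test:

1. The one-tailed Wilcoxon signed-rank is applied to mid-rank
   probability-integral-transformed deviations (the quantile of each
   `He_obs` within its simulated equilibrium sample, minus ½) rather
   than to raw `He_obs − mean(Heq)` differences. For biallelic loci the
   equilibrium He distribution is strongly right-skewed, violating the
   symmetry the signed-rank assumes and inflating its size severalfold;
   the quantile deviations are symmetric about zero under the null by
   construction. Per-locus standardized deviations (`DH`) are still
   reported.
2. Each locus receives an independent resample of `reps` (default 1000)
   values from a 20×-larger conditioned pool per `(k, n)`. Sharing one
   fixed sample across hundreds of loci would let the pool's estimation
   error shift every locus's quantile coherently and inflate the test's
   size; independent resamples decorrelate those errors at negligible
   cost.

**Linkage caveat:** the test's null assumes independent loci. All sites
of a non-recombining genome share one genealogy, so on organellar data
the across-loci p-value is anticonservative regardless of the
implementation — our single-genealogy simulations reject far above
nominal even without any bottleneck. The type-I calibration in the
acceptance suite therefore uses the unlinked-locus generator
(`simulate_unlinked_loci`, exact marginal neutral SFS per site), which
is the regime the test is defined for; a small p on mtDNA data is
evidence worth weighing, not a calibrated error rate.

## dN/dS (NG86)

Synonymous site fractions count, per codon position, the share of the
three single-nucleotide changes that preserve the amino acid; changes
creating stop codons count as nonsynonymous, so `S + N = 3 ×` codons
exactly. Observed differences average the synonymous/nonsynonymous step
counts over all minimal mutational pathways between the two codons;
pathways passing through a stop codon are excluded unless every pathway
is blocked. Gap- or ambiguity-containing codon pairs drop pairwise; a
terminal stop shared by both sequences is trimmed, any other stop is an
error. Proportions are Jukes–Cantor corrected
(`d = −¾ ln(1 − 4p/3)`, undefined at `p ≥ ¾`), and ω is NA when
`dS = 0` (flagged as nonsynonymous-only when `dN > 0`). The per-gene
screen averages pairwise ω between foreground and background sequences,
removes genes with ω > 5 as outliers, and flags ω > 1 as positive.
The plant mitochondrial code is the standard table, the default; any
NCBI table id can be passed. Branch-model maximum-likelihood ω and its
LRT are deliberately out of scope — they require external ML machinery
and multi-species orthologue sets; NG86 is the package's counting-based
measure.

## Synthetic-data generator

One genealogy per dataset from a structured coalescent: a wild ancestor
(relative size 1) and two domesticated lineages founded `t` coalescent
units ago, each at constant reduced size `B ∈ (0,1]` from founding to
the present — the standard constant-bottleneck rendering of
domestication (smaller `B`, stronger bottleneck, faster coalescence,
fewer haplotypes). Mutations are Poisson at `θ_wild/2` per site per
unit branch length, placed uniformly at distinct positions, so wild
diversity has expectation `θ_wild` per site. Sweeps are phenomenological:
within a lineage's sweep interval, variants private to that lineage
(all carriers inside it) are removed with probability 0.95. A
configurable fraction of mutations becomes 1–5 bp InDels; missing calls
are added i.i.d., with a small fraction of high-dropout sites so the
missingness filter has work to do; a small rate of heterozygous-coded
calls exercises the heteroplasmy policy. Optional migrant copies
(whole-haplotype transfers between lineages) create shared haplotypes
on demand.

Defaults are the emulated study conditions: 490,520 bp genome; 54 wild
(36 + 18 across two wild taxa), 66 indica-like, 278 japonica-like
(250 temperate + 28 tropical) samples; `θ_wild = 0.005` per site
(within the window-diversity range such collections report, and the
same θ as the neutral calibration conditions); founding at 0.5
coalescent units with `B = 0.5` (indica-like) and `B = 0.1`
(japonica-like — the stronger bottleneck); sweeps at distinct positions,
[250, 260) kb and [100, 110) kb respectively; 30% InDels; 0.5% missing
calls plus 1% of sites at 30% dropout. The deep founding split encodes
what the maternal data themselves show in this system — the two
cultivated lineages carry long-diverged maternal haplogroups (higher
between-lineage F_ST than lineage-to-wild, zero shared haplotypes). It
is also what makes domesticated diversity mostly lineage-private, the
precondition for private-polymorphism thinning to express a sweep at
all; at shallow splits domesticated diversity is mostly shared with
wild and no thinning-style sweep is expressible.

What the generator does **not** emulate: recombination (correct for
organelles and deliberate), post-sweep recovery mutations and hence SFS
skew, LD breakpoints at sweep edges (impossible without recombination),
population growth, gene conversion, sequencing-error autocorrelation,
and repeat-mediated structural variation of real plant mitochondria.
Passing recovery tests therefore demonstrates correctness of the
statistics and the detectability of diversity-reduction signatures —
not calibrated performance on real resequencing data.

`simulate_unlinked_loci` is a second, deliberately different regime:
every site drawn from the exact marginal neutral SFS independently, for
calibrating per-locus equilibrium tests whose null assumes unlinked
loci.

## Problem sizes in the test suite

The acceptance tests use 100 random instances per oracle check, 200
neutral replicates (n = 20, θ = 0.005, 50 kb) for statistic calibration,
and 50 full-genome replicates for recovery scoring; property tests use
scaled-down configurations (20–60 replicates, 30–120 kb) chosen so the
full suite runs in minutes on one CPU while keeping Monte-Carlo standard
errors well inside the asserted bands. Seeds are fixed throughout; the
acceptance script derives all randomness from its `--seed`.

## Known limitations

- Tajima's D on a fully linked genome has a negative neutral mean
  (≈ −0.14 at n = 20); see above.
- The bottleneck test's across-loci p-value is anticonservative on
  linked data by model mismatch, not implementation.
- The composite μ has little power against thinning-style sweeps in
  non-recombining data; the ROD scan is the primary detector there.
- Haplotype counts depend on the missing-data policy; report the policy
  with the counts.
- The MST network draws a single tree; reticulations that a full
  statistical-parsimony network would display are not represented.
- The NG86 screen averages pairwise ω, which saturates for highly
  diverged pairs (JC correction undefined past p = 0.75); such pairs are
  dropped from the per-gene mean rather than extrapolated.
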