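# Methods

This note records the models and estimators implemented in `kirhaplo`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Locus and motif model

The KIR locus is modelled as 13 loci — 11 genes and 2 pseudogenes (2DP1,
3DP1) — with four framework loci (3DL3, 3DP1, 2DL4, 3DL2) present on every
haplotype structure. Allele-level names that behave as alleles of one locus
are registered as aliases: 2DL2/2DL3 → 2DL2L3, 3DL1/3DS1 → 3DL1S1,
2DS3/2DS5 → 2DS3S5, and positional 2DL5A (telomeric) / 2DL5B (centromeric)
→ 2DL5. Gene-content operations (presence, decomposition) work at locus
level; motif definitions keep alias identity because motif membership
depends on it (cA01 carries 2DL3 where cB01/cB02 carry 2DL2).

Motif gene contents ship as an editable data fixture
(`src/kirhaplo/data/registry.yaml`), not hard-coded:

| motif | gene order |
|---|---|
| cA01 | 3DL3 – 2DL3 – 2DP1 – 2DL1 |
| cB01 | 3DL3 – 2DS2 – 2DL2 – 2DL5B – 2DS3S5 – 2DP1 – 2DL1 |
| cB02 | 3DL3 – 2DS2 – 2DL2 |
| cB03 | 3DL3 – 2DS2 – 2DL3 – 2DP1 – 2DL1 |
| tA01 | 2DL4 – 3DL1 – 2DS4 – 3DL2 |
| tB01 | 2DL4 – 3DS1 – 2DL5A – 2DS3S5 – 2DS1 – 3DL2 |

3DP1 is treated as the centromeric half of the central framework and is
included in every structure's content (and in the centromeric allele
vector for combination numbering). cB03's content is a provisional
transcription from figure-level evidence; edit the fixture if better
information becomes available. The 2DS3S5 locus can occur in both the
centromeric and telomeric slots of one haplotype; the registry models
positional occurrences through the motif orders and reports locus-level
presence.

Combination numbers (`cA01:001` …) are assigned per motif in registration
order starting at 001; identical allele vectors reuse their number. No
frequency-based ordering is attempted because no such rule is defined for
the nomenclature.

## Haplotype-pair deduction and EM frequency estimation

A typing signature is (a) a locus-level presence set over the assayed loci
and (b) a set of detected cis links, each an adjacent (alias-level) gene
pair from one motif's gene order. The default panel assays all 13 loci and
every within-motif adjacency, but nothing across the 3DP1–2DL4 junction —
the configuration that leaves exactly the classic cross-central phase
ambiguities (e.g. cA01|tA01 + cB01|tB01 versus cA01|tB01 + cB01|tA01)
unresolvable. The panel is configurable; ambiguity structure is treated as
panel-dependent, not a constant. Nested motifs (cB02's assayed content and
links are subsets of cB01's) produce additional, genuine collisions that
gene-content typing cannot resolve; these are enumerated rather than
hidden.

Frequencies are estimated by EM over the registered haplotypes plus one
pooled "other" class:

- E-step: each genotype's posterior is distributed over its compatible
  unordered pairs proportional to 2 f_i f_j (f_i² for homozygotes).
- M-step: expected allele counting over 2n chromosomes.
- A genotype matching no registered pair is decomposed as (h, other) over
  the registered haplotypes h whose assayed content and links are subsets
  of the observation, or as (other, other) when none fits. This mirrors
  how unmatched chromosomes are accounted per chromosome, not per
  individual, in gene-content surveys: the resolvable chromosome of such
  an individual still informs the registered frequencies, and the "other"
  frequency estimates the rare-haplotype chromosome mass.

Initialisation is uniform; iteration stops when the log-likelihood gain
falls below `tol` (default 1e-8) or at `max_iter` (1000). The
log-likelihood is asserted non-decreasing at every step. With no ambiguous
signatures the first M-step equals direct allele counting exactly. The
likelihood for this model class at this scale is well-behaved; no restarts
are performed, so runs are deterministic.

Reported tables give expected chromosome counts per population (from
population-wise EM), pooled counts, and pooled percentages rounded to one
decimal.

## Nucleotide diversity

π is the mean number of nucleotide differences per site over all sequence
pairs; its sampling variance is Nei (1987) eq. 10.7,

V(π) = (n+1)/(3(n−1)L) · π + 2(n²+n+3)/(9n(n−1)) · π².

Complete deletion (drop any column containing `-` or `N`) is the default,
matching the usual default of diversity software for per-gene estimates;
pairwise deletion is available by flag, in which case each pair is scored
over its own comparable columns and L in the variance formula is the mean
pairwise site count. Per-gene extracts run from 250 bp upstream of the
start codon through the polyadenylation-site column, with truncated genes
(3DP1-style, ending at exon 5) ending at their terminal exon. Sliding-window
profiles default to 500-column windows every 100 columns; trailing partial
windows are dropped. Segment summaries take the arithmetic mean of
per-gene π within user-supplied Cen-A/Cen-B/Tel-A/Tel-B grouping labels —
grouping is an input because the residence of shared genes (2DL1, 2DP1,
2DL5 by 2DS3/2DS5 linkage and position) is an annotation decision, not
derivable from sequence.

## Phylogenetics

TN93 distances use the closed form with two transition classes and
observed base frequencies, computed per pair over the pair's comparable
sites (pairwise deletion default). Saturated pairs (non-positive log
argument) are reported at a configurable ceiling (5.0 substitutions/site)
with a warning rather than failing. The implementation is cross-checked in
the test suite against an independent evaluation of the closed form and
against the R `ape` package.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q criterion;
ties are broken by the lexicographically lowest pair of cluster
representative labels, and negative branch lengths are clamped to zero
with the deficit moved to the sister branch. On additive matrices the
reconstruction is exact (path-length equivalence is a test invariant).
Parsimony search is deliberately omitted: for these data NJ and parsimony
are reported to agree, so a second tree-search machinery adds nothing
testable.

Bootstrap support resamples alignment columns with replacement (default
B = 500), rebuilds each replicate with the same distance and deletion
settings as the point estimate, and scores each internal bipartition of
the point tree by the percentage of replicates containing it. Midpoint
rooting places the root halfway along the longest leaf-to-leaf path, with
lexicographic tie-breaking; rerooting preserves all path lengths.

The recombination breakpoint scan replaces an interactive
recombination-detection workflow with an executable statistic: every
polymorphic column is classified as cleanly supporting candidate grouping
1, grouping 2, or neither; the breakpoint maximises the 2×2 chi-square of
(support-1, support-2) counts left versus right of a split, and
significance comes from permuting the order of informative-site categories
(default 999 permutations, seeded). The breakpoint estimate is the
midpoint between the flanking informative sites, so localisation error
shrinks as parental divergence (informative-site density) grows.

## Divergence dating

A strict molecular clock is assumed: the expected distance between
lineages that split t My ago is d = 2 r t. Calibrations are dated group
pairs (e.g. human–chimpanzee 6.5–10 My, gorilla > 10 My, orangutan
< 18 My, rhesus macaque 23–34 My); two-sided calibrations use the interval
midpoint, one-sided bounds use the bound value with an explicit flag.
The rate is fitted by least squares through the origin over all
calibrations, r = Σ d_k t_k / (2 Σ t_k²), with d_k the arithmetic mean
TN93 distance over all cross pairs (robust to non-ultrametric noise, and
the same quantity the identity d = 2 r t refers to). Query ages follow as
t = d/(2r); confidence intervals come from a column bootstrap that
re-estimates both d and r per replicate, so calibration-distance
uncertainty propagates. Estimated ages scale exactly linearly with
calibration ages (scale equivariance), and on clock-like simulations the
estimator is unbiased within Monte-Carlo error.

This distance-based estimator deliberately replaces a Bayesian
dated-phylogeny machinery: it reproduces the same quantity (node ages
under fossil calibration) with a desk-scale, fully testable computation.
Its accuracy is assessed by parameter recovery on simulated data, not by
matching any published real-data value, which would require the original
sequence datasets and method. Sequences flagged as recombinant must be
excluded before dating (`exclude_recombinants`), since mosaic sequences
violate the single-history assumption; which sequences to exclude is
configurable and typically comes from the breakpoint scan.

## Synthetic-data generators

All generators are seed-deterministic and return the generating truth.

**Cohorts.** 2n haplotypes are drawn i.i.d. from a frequency vector whose
default is the pooled reference-panel distribution (cA01|tA01 0.604,
cA01|tB01 0.115, cB01|tB01 0.026, cB02|tA01 0.089, cB01|tA01 0.073,
cB02|tB01 0.034, cB03|tA01 0.005, other 0.055, from the per-population
chromosome counts of a published 192-donor panel; the published totals
column contains one entry inconsistent with its own population breakdown,
and the consistent per-population counts are used). The "other" mass is
spread over three rare structures chosen to emulate deletion/hybrid
variants whose typing patterns are detectable as non-matching against the
common partner haplotypes — deliberately so, because an observed
rare-chromosome rate is by construction a *detected* rate. A small
fraction of rare chromosomes drawn opposite a masking partner (for
example, a deletion variant opposite a haplotype whose content covers it)
is genuinely invisible to gene-content typing; this produces the mild
upward shift (≈0.5–1 percentage point) of common-haplotype estimates seen
in the recovery simulations and reflects a real limitation of the assay,
not of the estimator.

**Sequences.** Alignments evolve site-independently along a dated tree
under a Kimura two-parameter process (default transition/transversion
rate ratio κ = 2.0); an edge of t My at rate r contributes r·t expected
substitutions/site via the exact K2P transition probabilities. The
generator is deliberately simpler than the TN93 model used for estimation
(uniform stationary composition, no rate heterogeneity, no indels), so
estimator consistency is testable without circularity. Two-clade and
mosaic helpers build the recombination fixtures; the multi-gene A/B
fixture draws each gene on a star genealogy with expected pairwise
diversity θ_group, so segment-ranking statements (e.g. Tel-A highest) are
testable across seeds.

What passing tests on these generators show: correctness of the
estimators under their stated models at realistic parameter values. What
they do not show: robustness to alignment error, indels, rate
heterogeneity, population structure within cohorts, or typing error —
none of which the generators emulate.

## Problem sizes and numerical choices

- EM: tol 1e-8 on the log-likelihood, max 1000 iterations, uniform start.
- Recovery simulations: 200 cohorts × 192 individuals (the acceptance
  script's configuration); Monte-Carlo SE of the reported means ≈ 0.2
  percentage points.
- π oracle checks: 1000 random gapped alignments, n ≤ 8, L ≤ 200, both
  deletion modes.
- NJ exactness: 100 random additive trees, 4–12 taxa.
- Breakpoint recovery: 20 mosaics, parents 5% divergent, L = 1000,
  tolerance ±25 columns.
- Dating recovery: 50 replicates, L = 2000 at rate 0.002/site/My,
  B = 200 bootstrap replicates per dating call (B = 500 is the API
  default).
- Saturated TN93 pairs: ceiling 5.0 subs/site with a warning.
- Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive; partitions are BED-like TSV.

## Known limitations

- Gene-content typing cannot see a deletion haplotype opposite a partner
  that covers it; the "other" class is therefore a lower bound on rare
  chromosome mass.
- The strict clock ignores lineage rate variation; calibration midpointing
  ignores within-interval uncertainty beyond what the bootstrap captures.
- The breakpoint scan assumes a single dominant breakpoint per query pair
  of groupings; multiple breakpoints require repeated scans on
  sub-intervals.
- Pairwise-deletion variance uses the mean pairwise site count in Nei's
  formula, an approximation when missingness is very uneven.
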