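# Methods

## Data model

The pipeline operates on a biallelic variant call set for a panel of diploid
individuals from five species, two of the *slender* morphotype and three of
the *stout* morphotype. Genotypes are stored as alternative-allele dosages
(0/1/2, −1 missing); VCF coordinates stay 1-based while windows use 0-based
half-open intervals internally. The convergence analyses contrast two
ordered species pairs (slenderA, stoutA) and (slenderB, stoutB); the fifth
species enters the per-species analyses (π, fixed differences, MK pairs)
and, optionally, the all-species fixation mode. Indels are retained for
site-level analyses and excluded from window-level analyses (π, Dxy, CSS)
by default.

## Site filters

Filters act on genotype evidence only (no BAM-level signals):

| filter | default | note |
|---|---|---|
| missingness cap | > 20% missing → site dropped | applied after call masking |
| depth band | per-site summed depth outside the 2.5–97.5 percentiles | percentiles computed once on the pre-filter distribution, so re-filtering is a no-op |
| het allele balance | two-sided exact binomial on (ref, alt) read depths at p = 0.5; PHRED = −10·log10(p) > 20 → that call set missing | masks the call, not the site; the site is only lost if missingness then exceeds the cap |
| inbreeding coefficient | F = 1 − Het_obs/Het_exp < −0.2 → site dropped | negative F means excess heterozygosity, the usual paralog-collapse signature; the threshold is configurable |

Depth percentiles are taken over per-site total depth across samples rather
than per-genotype depth — the site-level reading of a depth-band filter.
The excess-heterozygosity threshold is deliberately exposed because the
sign convention of such filters varies between tools; the default −0.2
keeps sites with moderate heterozygote excess and drops gross outliers.

## Convergence score

For per-species alternative-allele frequencies AF (alt copies / called
copies), the score is the product of the two slender–stout differences.
Properties relied on throughout: invariance to allele polarisation (both
factors negate), |score| ≤ 1 with ±1 only at opposite fixation in both
pairs, and exact-zero representability (frequencies are ratios of small
integers, so "nonzero score" is an exact comparison — no epsilon). Sites
where any pairing species has no called copies are flagged undefined and
excluded from scoring and from the excess-test denominator. The outlier
threshold of 0.25 corresponds to an average per-pair frequency shift of
0.5; both strict and non-strict comparisons at the threshold are available
(non-strict default).

The excess test is an exact two-sided binomial at p = ½ using the
minimum-likelihood two-sided convention (sum of all outcome probabilities
not exceeding the observed one), which is also scipy's default.

## Windows

π per species sums the unbiased per-site heterozygosity
2·n_ref·n_alt/(n·(n−1)) over SNPs and divides by window length; Dxy sums
p_A(1−p_B) + p_B(1−p_A); Da = Dxy − (π_A+π_B)/2 holds exactly for every
record. Windows are 20 kb with 10 kb step by default, one window per step
start before the contig end with the last windows truncated. Da outliers
are the points strictly above the genome-wide empirical 95th percentile
(computed per comparison over all windows, not per chromosome); an all-tied
input therefore yields no outliers. The outlier-overlap test reports the
observed intersection against the hypergeometric expectation |A||B|/N with
a one-sided permutation p (add-one estimator).

CSS uses an allele-sharing distance (1 − shared-allele proportion over
jointly called sites), projects individuals onto the first two principal
coordinates of that matrix, and contrasts the mean between-morph Euclidean
distance with the size-weighted mean within-morph distance; a raw-distance
variant (no projection) is available behind a flag. Significance comes from
permuting individuals over the two group sizes, p = (1 + #{perm ≥ obs}) /
(n_perm + 1), so the smallest achievable p is 1/(n_perm+1). Windows with
fewer than 5 SNPs are flagged undefined rather than scored as zero.

The ABBA-BABA D statistic is frequency-based:
ABBA = Σ(1−p₁)p₂p₃(1−p₄), BABA = Σp₁(1−p₂)p₃(1−p₄),
D = (ABBA−BABA)/(ABBA+BABA); Dmin is the minimum |D| over the three
arrangements of the ingroup trio with the outgroup fixed. Only point
estimates are produced — block-jackknife standard errors are out of scope.

## Differential fixation

A site is differentially fixed for species s when s has frequency exactly 0
or 1 (on called copies, with at least 8 called copies in every species to
guard against missingness artefacts) and every other species is fixed for
the opposite allele; per-species sets are disjoint by construction. The set
algebra runs at gene level (site sets mapped through the annotation and
deduplicated): two-species mode intersects the two same-morph sets and
subtracts the union of the opposite pair; all-species mode adds the third
stout species to the stout intersection and the slender subtraction. The
permutation test enumerates all three balanced 2+2 partitions of the four
pairing species and reports the rank of the true partition's
within-morph shared-gene count, so the attainable p floor is 1/3 — an
explicitly coarse but exact null for a four-species design.

## McDonald–Kreitman machinery

For a species pair, a coding site is a divergence when the pair is fixed
for opposite alleles (other species ignored) and a polymorphism when it
segregates in either species without being a fixed difference; a site
segregating in both species is counted once (pooled). Effects map
missense-like classes to nonsynonymous and synonymous to synonymous;
noncoding sites are excluded. NI_TG pools genes as
Σ Ds·Pn/(Ps+Ds) / Σ Dn·Ps/(Ps+Ds); its parametric bootstrap redraws each
gene's four counts from independent Poisson distributions at the observed
values, 1,000 replicates by default, reporting the 2.5–97.5 percentile band
and a two-sided p against 1. When fewer than max(50, n_boot/10) replicates
are defined (sparse divergence), the interval and p are reported as
undefined rather than estimated from a handful of draws. The cross- vs
within-morph comparison of NI_TG values is a one-sided exact Mann–Whitney
test (cross-morph lower), suitable for the handful of pairs a five-species
radiation affords. Per-gene positive selection requires a BH-corrected
Fisher p below α and NI < 1; raw-p mode is exposed.

## Enrichment

Over-representation only: hypergeometric upper tail of the query/term
intersection against a custom background, BH step-up across tested terms,
significance at q < 0.05. Term maps are flat (no GO-DAG propagation);
term-size filters are available but off by default. The uniqueness screen
re-runs the analysis for every permuted morph assignment and keeps terms
significant in the true comparison and in none of the permutations.

## Synthetic radiation generator

The generator emulates the study design the pipeline assumes, and its
defaults are the conditions under which the calibration properties are
stated:

* **Panel**: five species (slenderA, stoutA, slenderB, stoutB, stoutC) with
  12/11/12/11/12 diploid individuals (58 total, within the 10–13 per
  species design).
* **Sites**: 20,000 biallelic sites by default over two 1 Mb contigs, 14%
  indels; ancestral frequencies from a 1/p density on [0.01, 0.99], heavy
  in rare variants as real site-frequency spectra are.
* **Drift**: Balding–Nichols beta perturbation per tree branch (child
  p ~ Beta(p(1−F)/F, (1−p)(1−F)/F), variance F·p(1−p)), chosen for
  closed-form moments and speed; a coalescent backend could be plugged in
  but is not required. The default tree mirrors the study radiation —
  slenderA basal, (stoutC, stoutA) the youngest split — with branch F of
  0.1–0.3, deep enough that lineage-private fixation arises at a low rate.
* **Introgression**: one edge mixing the frequencies of stoutA and stoutC
  38.3% toward slenderA, the proportion and direction of the radiation's
  inferred ancient gene-flow event.
* **Planted convergence**: a configurable number of loci (default 50) where
  a new allele absent elsewhere is set to frequency δ (default 0.9) in both
  slender species after drift and admixture — independent selection on a
  shared variant, tip-specific so the planted signal is not diluted by
  descent.
* Genotypes are binomial(2, p) draws, 2% missingness, Poisson read depth
  (mean 20) with binomially split allelic depths at heterozygous calls.
  Genes are 5 kb tiles every 20 kb so gene and window bookkeeping is
  exactly computable; effects inside genes follow a 10/15/75
  synonymous/nonsynonymous/noncoding mix, indels always noncoding.

What the generator does *not* emulate: linkage and recombination structure
(sites are independent), mutation-rate heterogeneity, BAM-level artefacts
(mapping quality, strand bias), and the sheer scale of a real call set.
Consequences worth knowing:

* Because the species tree is asymmetric, drift on branches shared between
  the two species pairs is correlated and the null distribution of the
  convergence score is *not* sign-symmetric — default simulations show a
  genuine tree-driven excess of positive scores. Calibration tests
  therefore use a star tree (independent drift), under which the excess
  test is exactly null; the default tree is the realistic condition, the
  star tree the statistical null.
* Differential fixation (one species against all four others) is orders of
  magnitude rarer per site here than in a deep radiation's full call set,
  so desk-scale simulations yield few or no candidate genes; the set
  algebra and permutation machinery are validated on constructed
  frequency fixtures instead.
* Per-gene MK divergence counts are sparse at default scale; the pooled
  NI_TG machinery reports undefined intervals rather than pretending
  precision.

Passing tests on synthetic data therefore demonstrate correctness of the
statistics and calibration of the permutation/binomial machinery, not
end-to-end power on real resequencing data.

## Numerical and design choices

* Exact binomial and Fisher tests use scipy's implementations, verified in
  the suite against full enumeration oracles at small n.
* Permutation p-values always use the add-one estimator; p = 0 is never
  reported.
* Allele-frequency fixation checks use exact 0/1 comparisons on ratios of
  small integers (no tolerance), which is safe in binary floating point.
* BH adjustment is the standard step-up, q_(i) = min over j ≥ i of
  N·p_(j)/j capped at 1, cross-checked against statsmodels.
* The bootstrap and every simulation draw from a single seeded
  `numpy.random.Generator`; no wall-clock entropy anywhere. Test problem
  sizes (hundreds of sites/windows, hundreds of replicates, 20 seeds for
  recovery) were chosen as the smallest scales at which the calibration
  assertions are statistically meaningful.

## Known limitations

* No haplotype-level analyses: phasing, identity-by-descent tracts and
  shared-haplotype lengths around candidates are out of scope.
* No multiallelic decomposition — multiallelic records are dropped.
* The 2+2 morph-label permutation has only three partitions; its p-values
  are exact but coarse.
* D statistics come without jackknife significance.
* CSS follows the two-axis principal-coordinate formulation; other CSS
  variants in the literature differ in normalisation, so absolute values
  are comparable only within a run.
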