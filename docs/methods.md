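# Methods

## The design and model

A half-diallel crosses `p` inbred parents in every unordered pair without
reciprocals, keeping the selfed parents, for `p(p+1)/2` genotypes (the
default study conditions use `p = 10`: 45 hybrids + 10 parents = 55
genotypes). Genotypes are grown in a randomized complete block design with
`b` blocks (default 3). The analysis is Griffing's Method 2 under Model 1
(fixed effects): the cell mean of cross i × j is

    x̄_ij = μ + g_i + g_j + s_ij        (selfs: x̄_ii = μ + 2 g_i + s_ii)

with general combining abilities (GCA) `g_i` summing to zero and specific
combining abilities (SCA) `s_ij` the saturated remainder. Closed-form
estimators (with `x_i.` the symmetric row sum of the cell-mean matrix,
diagonal counted once, and `x..` the upper-triangle total):

    μ̂  = 2 x.. / (p(p+1))
    ĝ_i = (x_i. + x̄_ii − 2 x.. / p) / (p + 2)
    ŝ_ij = x̄_ij − μ̂ − ĝ_i − ĝ_j

These are exactly the least-squares solutions of the additive model on the
half-diallel cells under the sum-to-zero constraint (asserted against a KKT
solve in the tests), and the model is saturated: the fitted effects
reproduce every cell mean to machine precision.

### ANOVA and the partition identity

The plot-level ANOVA is the standard RCBD decomposition (blocks, genotypes,
error). The genotype stratum is partitioned on the genotype-mean basis:

    SS'_GCA = (1/(p+2)) Σ_i (x_i. + x̄_ii)² − (4/(p(p+2))) x..²
    SS'_SCA = Σ_{i≤j} x̄_ij² − (1/(p+2)) Σ_i (x_i. + x̄_ii)² + (2/((p+1)(p+2))) x..²

each multiplied by `b` to sit on the plot basis. SS_GCA + SS_SCA equals the
genotype SS as an algebraic identity (tested at 1e-8 relative tolerance).
Degrees of freedom: blocks b−1, genotypes p(p+1)/2 − 1, GCA p−1, SCA
p(p−1)/2, error (p(p+1)/2 − 1)(b−1). All mean squares are tested against
the single RCBD error (fixed-effects convention).

### Variance components, ratios, heritabilities

From plot-basis mean squares with `b` blocks:

    σ̂²_GCA  = (MS_GCA − MS_e) / (b (p + 2))
    σ̂²_SCA  = (MS_SCA − MS_e) / b
    σ̂²_e    = MS_e

The 1/b factor makes the genetic components commensurate with the error
variance and with the generative variances of the simulator; without it the
genetic components come out multiplied by b. Both GCA/SCA ratios are
b-invariant and both are reported:

* component ratio σ²_GCA / σ²_SCA — the quantity published diallel tables
  computed this way actually print;
* Baker's ratio 2σ²_GCA / (2σ²_GCA + σ²_SCA), the textbook measure of the
  relative weight of additive effects.

Heritabilities use the component scale:

    h²  = 2σ²_GCA / (2σ²_GCA + σ²_SCA + σ²_e)
    H²  = (2σ²_GCA + σ²_SCA) / (2σ²_GCA + σ²_SCA + σ²_e)

With the 1/b correction these formulas reproduce, at the 2-decimal printing
precision, the h²/H² columns of the reference eggplant trial whose mean
squares ship with the acceptance script (24 of 28 published rows; the
misses are rows whose mean squares are printed with too few significant
digits, e.g. an error MS printed as 0.00). An alternative broad-sense form
from the genotype MS, ((MS_gen − MS_e)/b)/((MS_gen − MS_e)/b + MS_e), is
selectable (`h2_variant="genotypic"`).

Negative component estimates are reported as estimated and flagged; they
are clamped to zero only inside the heritability formulas (also flagged).
The component ratio is undefined (flagged) when σ̂²_SCA ≤ 0.

Caveat: under Method 2 expected mean squares the GCA component absorbs
σ²_SCA/(p+2); the recovery simulations assert against that expectation
rather than pretending the estimator is exactly unbiased. Averaging
per-replicate component *ratios* is upward-biased (noisy denominator), so
recovery of a true ratio is checked on the ratio of averaged components.

### Heterosis, SCA percent, group comparison

Mid-parent heterosis per hybrid: Het = 100 (F1 − MP)/MP with F1 the hybrid
genotype mean and MP the parents' average; MP = 0 is flagged undefined.
SCA is also expressed as a percentage of the mean of all hybrid means
(scale-invariant). Parents vs hybrids are compared per trait with a
two-sided Welch t-test on genotype means (pooled-variance variant behind a
flag); two constant groups return t = 0, p = 1 with a degenerate flag.

## Trait correlations

Pearson correlations are taken across genotype means (parents and hybrids,
n = p(p+1)/2 = 55 for the complete default design) for all t(t−1)/2 trait
pairs. Instead of adjusting each p-value, the family-wise level α is turned
into one critical threshold

    r* = t* / sqrt(t*² + n − 2),   t* = t_{1 − α/(2m), n−2}

flagging |r| ≥ r* — the identical decision rule to Bonferroni-adjusted
p-values. For n = 55, m = 378, α = 0.05 this gives r* = 0.4928.

## Genetic distances and clustering

Genotypes are diploid biallelic dosages (0/1/2 alternate-allele copies)
read from VCF via cyvcf2; multi-allelic and non-SNP records are skipped and
counted. Filtering is site-wise complete-case, then monomorphic-site
removal, preserving order. Distances:

* identity-by-state: per-site IBS = 1 − |d_a − d_b|/2, GD = 1 − mean IBS;
* Hamming (bitwise): mean per-site fraction of differing allele copies.

On dosage data both definitions coincide (asserted); both are exposed
because published pipelines compute GD with one tool and cluster with the
other. Note that restricting to polymorphic sites renormalizes distances
upward relative to raw per-site divergence rates — a property shared with
any polymorphic-only SNP panel.

UPGMA is implemented directly (not delegated) because its determinism is
pinned: the minimum-average-distance pair merges at height d/2, and exact
ties break on the lexicographically smallest combined member-id tuple,
with children ordered the same way. scipy's average-linkage with cophenetic
distances serves as the independent oracle in tests. Bootstrap supports
resample loci (not samples) with replacement, default B = 1000; an internal
node's support is the percentage of replicate trees containing its exact
leaf set as a clade. Trees serialize to Newick through scikit-bio with
branch lengths `height(parent) − height(child)` and integer supports as
internal labels.

## Genetic distance vs hybrid performance

Each hybrid contributes one record per trait: parental GD, hybrid genotype
mean, mid-parent heterosis, and ŝ_ij. Pearson r with two-sided p (n − 2 df)
is reported per trait × response, for the full parent set and for labeled
subsets (e.g. dropping a divergent wild parent leaves 36 of 45 hybrids at
p = 10). Stars (0.05/0.01/0.001) are per-cell and unadjusted — deliberately
a different convention from the trait–trait screen, mirroring how such
tables are published. Because hybrids sharing a parent are not independent,
these correlations are descriptive; the calibration test therefore draws
i.i.d. records, where the nominal 5% level is exact.

## Synthetic data

The phenotype generator draws g ~ N(0, σ²_GCA), symmetric s ~ N(0, σ²_SCA)
(selfs included, same distribution), block effects and residuals, and emits
y_ijk = μ + g_i + g_j + s_ij + β_k + ε_ijk from a single seeded RNG stream
(draw order: g, upper-triangle s, blocks, residuals, trait by trait).
Defaults: p = 10, b = 3, μ = 100, σ²_GCA = 4, σ²_SCA = 1, σ²_block = 0.5,
σ²_error = 1 — a strong-additive regime (h² = 0.8) typical of the fruit
morphology traits such trials target.

The SNP generator perturbs an ancestral homozygous dosage vector per
cluster (flip probability `between_rate`) and per sample (`within_rate`),
then injects heterozygous and missing calls. Defaults: 10 samples in
clusters of 9 + 1 (one divergent accession against a main group), 7,335
sites, between 0.015 / within 0.005, 1% heterozygosity, 2% missing calls.
Cluster membership is encoded in sample names, so truth needs no side
channel.

What the generators do *not* emulate: linkage disequilibrium among sites,
epistasis, genotype-by-environment interaction, and any coupling between
the SNP panel and the phenotypes (they are independent by construction, as
the analysis treats them). Passing tests therefore demonstrate correctness
of the estimators under the stated model, not biological realism of any
particular dataset.

## Numerical and design choices

* Canonical order: the ParentSet's id order indexes every matrix; crosses
  are stored under (min index, max index).
* Analyses require a complete design; gaps are reported as cell lists
  (fatal in the estimators, advisory in `design_counts`). No imputation,
  no outlier handling.
* Trait names are exact, case-sensitive strings.
* Problem sizes in the test suite and acceptance script (2,000 null
  replicates at p = 6 for F-test calibration, 500 replicates at p = 10 for
  recovery, B = 200 bootstrap on 1,000-site panels) were chosen to give
  Monte-Carlo error well inside the asserted tolerances while keeping the
  default run fast.
* All stochastic steps take explicit seeds; identical seeds give
  byte-identical outputs (asserted for the CLI).

## Known limitations

Standard errors of individual ĝ_i/ŝ_ij (and hence per-effect significance
stars) are not computed; random-effects (Model 2) and reciprocal designs
(Methods 1/3/4) are out of scope; the distance module does no LD pruning or
imputation. Heritability estimates inherit the usual caveats of
fixed-effects diallels on a diverse panel: they describe this parent set,
not a breeding population.
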