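# Methods

`orchardkit` analyses a clonal seed-orchard trial on two data layers — ramet-level
phenotypes from a randomized complete block (RCB) design, and codominant SSR
genotypes of the same clones — and tests the congruence of the classifications
the two layers induce.  This note records the models, the conventions chosen
where several are in circulation, the design of the synthetic-data generators,
and the problem sizes the test suite runs at.

## Phenotypic model

Each trait is analysed under the additive single-tree-plot model

    Y_ij = mu + beta_i + a_ij + eps_ij

with fixed block effects `beta_i`, random clonal (genotypic) values `a_ij` and
independent residuals.  Because every block holds exactly one ramet per clone
there is no clone-by-block interaction term.  Estimation is by the
expected-mean-squares method of moments on the two-way ANOVA: `sigma2_e =
MS_resid` and `sigma2_a = (MS_clone - MS_resid)/b`, where `b` is the number of
ramets per clone — the harmonic mean when mortality makes the layout
unbalanced.  For unbalanced data the sums of squares come from sequential
least squares with blocks entered before clones; on complete layouts this
reduces to the orthogonal closed form (and is unit-tested against a
statsmodels OLS/ANOVA fit, which is a cross-check, not a runtime dependency).
Negative moment estimates of `sigma2_a` are truncated to zero with a warning.

Derived quantities:

- **Clonal repeatability** `H2 = sigma2_a / (sigma2_a + sigma2_e)` — the
  fraction of phenotypic variance attributable to clone identity.
- **PCV** `= 100 * sqrt(sigma2_Y) / mean` (percent).  Several definitions of a
  phenotypic CV exist; this package uses the total phenotypic standard
  deviation over the trait mean.
- **QST** `= s2_B / (s2_B + 2 s2_W)` between clone-origin sites, computed from
  clone genotypic values (the per-clone means of `a_ij`) via a one-way moment
  decomposition with the unequal-group-size coefficient `n0`.  Values are
  clipped into [0, 1].
- **Genetic correlations** between traits from clone genotypic values.  The
  default is the standard product convention `cov/sqrt(var_x * var_y)`; a
  `sum` convention `cov/sqrt(var_x + var_y)` is selectable because some trial
  reports normalise by summed variances.  The two differ by scale only.
- **Stem volume** `DBH^2 * Ht * 3.14 * 0.41 / 40000` (DBH in cm, height in m,
  volume in m^3).  The rounded `pi` and the conifer form factor 0.41 are kept
  literally so volumes match the forestry convention the trait catalog uses.
- The stem-straightness score is squared before analysis when the optional
  transform is enabled in the trait catalog.

## Molecular statistics

Allele frequencies are relative frequencies of non-missing gene copies,
per population (origin site) and pooled with gene-copy weights.  Per locus and
group: allele count Na, effective alleles `Ne = 1/sum(p^2)`, Shannon index
`I = -sum(p ln p)`, observed heterozygosity Ho, gene diversity
`He = 1 - sum(p^2)`, its small-sample correction `uHe = (2N/(2N-1)) He`, and
the fixation index `F = (He - Ho)/He` (undefined and flagged at He = 0).
Differentiation per locus is `Fst = (Ht - mean He)/Ht` with `mean He` the
unweighted mean over groups; `Ht` uses gene-copy-weighted pooled frequencies
by default, with unweighted pooling behind a flag since software packages
differ on this convention.  PIC is the Botstein et al. (1980) measure
`1 - sum(p^2) - sum_{i<j} 2 p_i^2 p_j^2`, always ≤ He.  The report's per-locus
rows are means over the two origin-site groups with standard errors over
groups; the summary row is the unweighted mean over loci with standard errors
over loci.  Groups with fewer than two typed individuals at a locus are
skipped rather than silently averaged.

**AMOVA.** Sums of squares follow the squared-distance formulation on the
codominant allele-count metric (`d2 = ||y_i - y_j||^2 / 2` on per-locus allele
count vectors; 0 for identical genotypes, 4 for opposite homozygotes).
`SS_total = sum_{i<j} d2 / N`, `SS_within = sum_g sum_{i<j in g} d2 / n_g`,
among = total − within.  Degrees of freedom default to the gene-copy level
(G−1, 2N−G, 2N−1) — the convention codominant AMOVA software reports for
diploids — with the unequal-size coefficient `n0` computed on gene-copy
counts; an individual-level alternative (N−G) is available.  Phi_ST tests use
random permutation of individuals across groups with the add-one p-value
rule.  Negative among-group components are truncated before percentages.

**Distances and trees.** Between populations: Nei (1972) standard distance
`-ln(Jxy / sqrt(Jx Jy))` with identities pooled over loci.  Between
individuals: shared-allele dissimilarity, `1 -` (mean over loci of half the
multiset intersection of allele pairs); pairs skip loci missing in either
member.  Phenotypic distances are Mahalanobis on standardized clonal values
(ridge pseudo-inverse when the trait covariance is singular).  Clustering:
UPGMA on `1 - Pearson` profile correlation via scipy average linkage
(deterministic given the input), and a Saitou–Nei neighbor-joining
implementation with lowest-index tie-breaking; negative NJ branch lengths are
clamped to zero with the deficit moved to the sister branch so the joined
pair's path length is preserved.  Both trees export Newick.

**Mantel test.** Pearson correlation of upper-triangle distances, permutation
null on the second matrix's labels, one-sided "greater" by default (the
working hypothesis is positive congruence between phenotypic and molecular
distances), add-one p-value.

## Admixture model

The Bayesian clustering model is the standard admixture model for unlinked
codominant loci: cluster allele frequencies `P_kl ~ Dirichlet(lambda)` with
`lambda = 1`, individual memberships `Q_n ~ Dirichlet(alpha)` with `alpha`
fixed at 1 (no alpha update — adequate at these scales; a Metropolis alpha
update was deliberately left out), and a latent origin per gene copy.  All
three updates are conjugate, so the sampler is a pure Gibbs scheme; a
no-admixture variant samples one origin per individual.  Missing genotypes
contribute to neither likelihood nor counts.  The data log-probability is
estimated from the recorded log-likelihood trace as `mean(L) - var(L)/2`, and
K is selected with the Evanno statistic `deltaK = |L(K+1) - 2L(K) + L(K-1)| /
sd(K)` over replicate runs, undefined (flagged) at the range ends or at zero
replicate spread.  Label switching across replicates is resolved by greedy
correlation matching of Q columns before averaging.  The correctness anchor is
the K = 1 case, where the posterior mean of P has the closed conjugate form
`(counts + lambda)/(2N + lambda * Na)`.

Run-length defaults are 5000 burn-in + 5000 recorded sweeps with 10
replicates (library level); the pipeline and the test suite use desk-scale
settings of 500 + 1000 with 5 replicates over K = 1..6, which this sampler's
mixing comfortably supports at ~100–150 individuals and 16 loci.

## Synthetic data

No raw measurements are distributed with the package, so both layers are
emulated by seeded generators; all analyses can be exercised end to end on
them.

- **Orchard phenotypes**: 110 clones × 10 complete blocks by default, clones
  assigned to two origin sites 90/20.  Clone effects are multivariate normal
  across the 28-trait catalog with a target genetic-correlation matrix
  (identity by default); each trait's total variance comes from its PCV and
  nominal mean, split by its H2 target.  Site differentiation is induced by
  fixed site shifts calibrated so the one-way moment estimator is centred on
  the trait's QST target; block effects are fixed draws at half the
  phenotypic SD; residuals are independent normal.  The bundled catalog's
  PCV/H2/QST defaults reflect the orchard trial's reported ranges (PCV
  4–24%, H2 0.02–0.98); the trait means are nominal working values, since
  trial means are not part of the variation summary.  An optional latent
  clone grouping shifts clone effects along a random direction per group (in
  units of genetic SD) to create recoverable clusters for end-to-end
  clustering checks.
- **SSR genotypes**: Balding–Nichols model.  Ancestral frequencies are
  uniform-Dirichlet per locus; population frequencies are
  `Dirichlet(p (1-theta)/theta)`, so per-locus Fst is centred near `theta`
  (exact copies at theta = 0); diploid genotypes by random union of gametes,
  optionally through per-individual admixture proportions.  The default panel
  is 16 loci with 2–9 alleles and `theta = 0.03`, the regime of the trial's
  markers; three-deme scenarios use `theta = 0.2`.

What the generators do **not** emulate: spatial autocorrelation within the
orchard, genotype-by-environment interaction, SSR mutation processes and
null alleles, linkage between loci, and any genuine phenotype–genotype
coupling beyond a shared latent grouping.  Passing recovery tests therefore
demonstrates the estimators' correctness under their own model assumptions,
not robustness to these real-data complications — in particular the Mantel
correlation between the two layers is near zero under the default generator,
which only exercises the machinery.

## Numerical choices and degenerate inputs

- Frequencies must sum to 1 within 1e-8; distance matrices are symmetrized
  defensively and validated by the `skbio.DistanceMatrix` container.
- `F`, `Fst`, `uHe` are flagged `nan` rather than fabricated when their
  denominators vanish (monomorphic loci, N = 1).
- Nei distance returns `inf` when two groups share no alleles.
- All samplers and permutation tests take explicit seeds; the pipeline spawns
  per-stage child seeds from one master seed and logs them in its manifest,
  so full runs are bit-reproducible.
- Permutation p-values use the add-one rule and are therefore never zero.

## Problem sizes used by the test suite

Monte-Carlo checks run at sizes chosen to keep each check's sampling error
well inside its assertion band: variance-component recovery uses 120
replicates of the 110 × 10 layout; QST and genetic-correlation recovery use
60 and 30 replicates; Mantel type-I error uses 400 null simulations at n = 10
with 99 permutations; AMOVA null uniformity uses 120 simulated datasets; the
Evanno check runs one full K = 1..6 scan (5 replicates each) on 150
individuals.  The acceptance script repeats that scan over 5 independent
pipeline replicates and reports the modal selected K.
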