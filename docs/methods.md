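# Methods

## The model

`hiergwas` tests biological *systems* — ontology terms with their propagated
gene sets — for association with a binary case/control phenotype in a single
step. For each system a dosage matrix **G** (N individuals × S SNPs, minor
allele counts 0/1/2) is assembled from all SNPs within 10 kb of any gene in
the system. **G** is column-centred and reduced to its leading principal
components, **T** = **GW**, keeping the smallest k explaining 95% of the
variance, capped at 50 components (and at the numerical rank). The components
enter a logistic regression

  f1: logit P(y = 1) = **T**α + **C**β + intercept

compared against the covariate-only null

  f0: logit P(y = 1) = **C**β + intercept

by a likelihood-ratio χ² test on k degrees of freedom. **C** holds clinical
covariates (age, sex, current smoking status, pack-years) and the first 10
principal components of the genome-wide genotype matrix, which absorb
population structure. Bonferroni multiplication over the number of systems
actually tested controls the family-wise error rate. The fitted component
coefficients map back to per-SNP log-odds contributions per minor-allele
copy via **e** = **W**α̂.

Assumptions worth keeping in mind: the phenotype is binary; dosages are
additively coded; the principal components are unsupervised, so very large
systems drift toward the genome-wide structure axes; and the χ² reference
distribution for the LRT is asymptotic, which is why the permutation
calibration below exists.

## Building the hierarchy

OBO "is a" and "part of" edges both become child → parent links. The three
ontology aspects are joined under one synthetic root, annotations (minus a
configurable evidence-code exclusion list, IEA by default) are propagated so
each term inherits all descendants' genes, then:

1. size filter — systems with fewer than 3 or more than 75 genes are
   removed (bounds inclusive: 3 and 75 survive);
2. similarity collapse — any parent with a child covering ≥ 90% of its gene
   set (S(P, C) = |A_C|/|A_P|) is removed and its children attach to all of
   its parents; passes iterate to a fixed point so that pairs created by
   reconnection are also checked.

Children of size-filtered systems reconnect to their nearest surviving
ancestors the same way; the ontology's own statement of the procedure covers
reconnection only for the collapse, and applying it uniformly is this
package's choice to keep every retained system reachable from the root.
The synthetic root itself is exempt from both filters — it exists only to
keep the DAG single-rooted and is never tested.

## Conditional localisation

Nested gene sets light up together, so two follow-up tests localise signal:
the **top-child test** removes every SNP within the window of any gene of
the system's most associated child and re-runs the pipeline (PCs recomputed
from scratch on the reduced matrix); the **top-gene test** does the same for
the most associated single gene. Removal is strict: a SNP near both a
removed and a kept gene is removed. Ties for "most associated" break by
smaller p, then more SNPs, then lexicographic id, so reports are
deterministic. Childless systems are marked not-applicable; if removal
empties the SNP set the conditional p is missing, meaning the child or gene
fully accounts for the system's genetic context.

## Permutation machinery

**Type-I calibration.** Outcome labels are permuted within deciles of a
covariate-only logistic propensity score, preserving the covariate–outcome
association structure while breaking any genotype link; case counts are
preserved exactly per stratum. The type-I error estimate is the mean
fraction of systems with p < 0.05 across permutations. Undersized strata
(< 2 members) merge into a neighbour. The decile-propensity scheme is this
package's concrete choice of balancing mechanism; it is the stated goal
(covariate balance) implemented with standard tools.

**Competitive recalibration.** 100 random ontologies are built by applying a
global bijection to gene labels — node set, edges and per-system gene counts
are untouched, so each permuted system occupies the same structural position
with a random gene set of the same size. A system's competitive p-value is
the add-one empirical estimator (r + 1)/(n + 1), where r counts permuted
p-values at or below the observed one; with 100 permutations and zero
exceedances this floors at 1/101 ≈ 0.01. A per-system independent shuffle
was rejected because it would destroy parent–child nestedness.

## Simulation study: one-step vs two-step

Two schemas simulate a 10-SNP system for 1000 cases and 1000 controls:

* independent — i.i.d. Bernoulli entries, success probability 0.02 (cases)
  vs 0.01 (controls);
* Ising — binary SNPs coupled by a random graph (each pair an edge with
  probability 0.5, weight 1), activation thresholds −3.5 (cases) vs −5.0
  (controls), sampled exactly from the enumerated 2^10-state distribution.

Noise sweeps 0–0.1: added to both success probabilities in the independent
schema (shrinking the relative contrast), and applied in the Ising schema by
flipping each entry to 1 with probability equal to the noise (keeping
entries binary). Both interpretations are this package's reading of "noise
added to the simulated SNP probabilities"; both monotonically erode the
case/control contrast. Edge weight 1 and {0,1} state coding are likewise
declared conventions — the source describes only the connectivity
probability and thresholds.

Each of 100 repetitions draws one dataset per noise level and applies both
tests to the same draw: the one-step test (pooled PCA, 95%/50-PC rule,
logistic LRT on the label) and the two-step test (per-SNP univariate
logistic p-values combined by Fisher's method against χ² with 2m df).
Power is 1 minus the fraction of repetitions with p ≥ 0.05.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not any
particular array platform:

* **genes and SNPs** — genes laid 100 kb apart (windows stay disjoint), 4
  SNPs per gene, MAF uniform on [0.1, 0.4];
* **LD** — the two allele draws of each SNP share a per-gene Gaussian
  copula factor. Thresholding attenuates correlation, so the latent
  correlation is inflated by the inverse of the threshold-model
  linearisation to make the realised *dosage* correlation land near the
  requested `ld_block_rho` (default 0.3, a typical within-block r);
* **population structure** — two equal subpopulations with allele
  frequencies shifted ±divergence/2 (default 0.05) and a phenotype offset
  (default 0.3 log-odds), so the population-PC adjustment has real work;
* **covariates** — age ~ N(60, 8), sex ~ Bernoulli(0.5), current smoking ~
  Bernoulli(0.45), pack-years ~ N(40, 15) clipped at 10, with log-odds
  effects 0.02/yr, 0.2, 0.4 and 0.01/pack-year: modest, epidemiologically
  plausible magnitudes for a smoking-related disease cohort;
* **phenotype** — Bernoulli through a logit linear in centred planted SNP
  dosages, centred covariate terms and the subpopulation offset; the
  intercept targets the requested case fraction.

Planted effects are specified per system as (id, per-SNP log-odds effect,
fraction of genes carrying signal). The recovery experiment plants 0.18
log-odds per minor allele (odds ratio ≈ 1.2) across all six genes of one
system among 200 — strong enough in aggregate to dominate the scan,
individually far below genome-wide significance, mirroring a convergent
multi-locus architecture. The conditional-test scenarios use 0.35 (spread
across five genes) and 0.8 (one dominant gene) to produce unambiguous
child-concentrated, distributed, and single-gene-driven cases.

What the generator does **not** emulate: realistic recombination maps or
haplotype panels, imputation uncertainty, variable gene lengths and SNP
densities, more than two ancestry components, missing covariates. Passing
tests therefore demonstrate correctness of the machinery and calibration
under idealised LD-blocked genotypes, not performance on real array data.

## Numerical choices

* Logistic fits use damped Newton/IRLS; convergence when the largest
  scale-invariant coefficient change falls below 1e-8, at most 100
  iterations. (Quasi-)separation — divergence of a scaled coefficient past
  30, or non-convergence — marks the system's p as missing rather than
  aborting a scan; such fits are excluded from permutation denominators.
* Component columns that are zero or collinear with the null design are
  dropped before the LRT (QR with column pivoting); the reported df counts
  the columns actually tested, and an empty set yields χ² = 0, p = 1.
* SVD signs are fixed so each component's largest-magnitude loading is
  positive, making outputs reproducible across BLAS implementations.
* The randomized SVD path probes `k_probe` components (default: the cap)
  and applies the k rule against the exact total variance of the centred
  matrix, so exact and randomized paths select comparable k.
* The Hardy-Weinberg QC test is the exact conditional test on the
  heterozygote count, computed in log space; MAF and HWE thresholds default
  to 0.01 and 1e-6 (common array-QC values; the source names the filters
  without values). HWE uses controls when a control mask is supplied.
* Missing dosages are mean-imputed per SNP before centring; dosage columns
  are centred but deliberately not scaled, so higher-MAF SNPs contribute
  more variance (the behaviour the unsupervised projection is known for).
* Permutation p floors at (0+1)/(n+1); QQ tables clamp p = 0 to the
  smallest positive float with a warning.

## Problem sizes used by the checks

The calibration experiment runs 1500 individuals × 200 three-gene systems
× 250 balanced permutations (the larger sample keeps the χ² reference of
the ~10-df LRT in its asymptotic regime); the recovery experiment 800 individuals × 200
six-gene systems × 20 seeds; the power study the full 10 SNP / 1000 + 1000 /
100-repetition design at five noise levels. These sizes give Monte-Carlo
error comfortably inside the tolerances asserted while keeping a full run in
minutes on one core.

## Known limitations

Logit link only (no quantitative traits); no Firth correction for separated
fits (they are reported as missing); no LD pruning before population PCs
(offered upstream of the model as a caller responsibility); no X-chromosome
or multi-allelic handling; the competitive recalibration refits every
permuted system from scratch and is the slowest path in the package.
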