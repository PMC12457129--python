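# Methods

## Scores

The partitioned polygenic score of sample `i` in cluster `c` is
`Σ_j w_{jc} e_{ij}` over the harmonized variants, with `e_{ij}` the
effect-allele dosage (ALT dosage, or `2 − d` when the effect allele is
the VCF REF).  There is no normalization by variant count.  Scores are
reported raw and per-SD standardized; all association models consume the
standardized form, so logistic coefficients are per score SD.

**Inclusion rule.** A weight-table row is retained when its maximum
cluster weight is strictly greater than the threshold (default 0.7802).
Whether a retained variant should contribute to *all* clusters or only
to the clusters where it passes the threshold is genuinely ambiguous;
we default to passing-clusters (sub-threshold weights are zeroed), which
keeps each cluster score on its own mechanism's signal, and expose
`contribute="all-clusters"` for the other reading.

**Harmonization.** Matching is by chromosome:position (chr-prefix
insensitive) plus allele set, not rsID, to be robust to ID drift.
Effect = ALT ⇒ no flip; effect = REF ⇒ flip (`e = 2 − d`); any other
allele configuration is reason-coded `allele_mismatch`.  A/T and C/G
pairs are dropped by default (`palindromic`) because strand cannot be
resolved from alleles alone without frequency information.  Failures are
coded, never raised, and the reason codes partition the table.

**Missing dosages** default to the variant's mean effect dosage over
non-missing samples (standard polygenic-score practice); `zero` and
`drop_sample` policies are available.  The DR2 ≥ 0.3 imputation-quality
filter treats variants with no DR2 annotation as directly genotyped and
always passes them: the filter exists to remove poorly *imputed*
variants.

## Population structure

Genotypes are standardized as `x = (d − 2p̂)/√(2p̂(1−p̂))` with `p̂` the
sample allele frequency — the binomial-variance convention of ancestry
PCA — with missing entries set to 0 after centering and monomorphic
variants dropped.  PCA is a thin SVD; each component's sign is fixed so
its largest-magnitude variant loading is positive, making coordinates
identical across runs.  New samples are projected with the *reference*
frequencies and loadings over shared variants, so projecting the
reference samples reproduces their coordinates exactly.  LD pruning is
off by default (the simulator draws variants independently, so there is
no LD to prune); population labels for downstream models come from the
sample table, with the PCA scatter serving as the structure check.

## Association battery

* Derived traits: BMI = weight kg / (height m)², WHR = WC/HC (cm/cm),
  AIP = (TC − HDL)/HDL (mmol/L).  Nonpositive denominators produce a
  missing value plus a warning rather than an error.
* Log transformation is the natural log, applied by default to BMI, TG,
  WC, HC, WHR, sBP, dBP, TC, HDL, AIP and HbA1c; LDL is analyzed
  untransformed (configurable).
* Standardized OLS z-scores the outcome and continuous predictors;
  binary covariates (sex, T2D) stay 0/1.  With one predictor and no
  covariates the standardized beta equals the Pearson correlation, which
  the tests assert to 1e-10.
* The population scan dummy-codes populations against a declared
  reference category, adjusting for T2D, z(age) and sex; the interaction
  scan adds population×T2D product columns and reports only those.
* Logistic T2D models: one per cluster, OR = exp(β) per score SD with
  Wald 95 % CIs on the log-odds scale (the CI method is our choice; only
  OR + 95 % CI is conventionally reported).  Covariate tiers: none;
  age/sex/BMI; + ancestry labels; + first 10 genotype PCs.
  (Quasi-)complete separation is flagged on the result (`separated`,
  infinite CI) instead of raising.
* Mann-Whitney uses the exact null distribution when min(n) ≤ 8 and the
  pooled sample has no ties, else the tie-corrected normal approximation
  *without* continuity correction — chosen so that U equal to its null
  mean yields p = 1 exactly, which is the natural two-sided convention
  for identical groups.
* BH families are per scan table (phenotype scan; interaction scan;
  12-cluster battery; per-SNP scan within each population) — the most
  conservative reading of "correction for multiple comparisons" when no
  family definition is given.  Adjusted p ≥ raw p always.
* The per-SNP one-vs-rest scan regresses the population indicator on
  dosage per SNP; in the pipeline it runs over the scored SNPs only
  (the SNPs entering the pPGS), mirroring the study design; monomorphic
  SNPs are skipped with a reason code.

## Synthetic cohorts

The simulator emulates the statistical structure the analyses assume,
not any real genome:

* **Frequencies.** Ancestral `p ~ U(0.1, 0.9)`; population frequencies
  Balding–Nichols, `p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, independently
  per population, so `E[p_pop] = p` and `Var = F·p(1−p)`.  Default
  F = 0.1 per population; the Hudson FST between two populations then
  estimates F (verified within 10 % at 5,000 variants).
* **Genotypes.** HWE within population, `d ~ Binomial(2, p_pop)`;
  optional uniform missingness; DR2 annotations clean for in-table
  variants and mixed (absent / below 0.3 / passing) elsewhere so the
  quality filter is exercised without touching planted signal.
* **Weights.** `n_weighted` variants (default 60) get one cluster each,
  round-robin, with weight `threshold + U(0.05, 0.7)·weight_scale` —
  always strictly above threshold and monotone in the scale; an equal
  number of decoy rows stays strictly below, so the filter's retained
  count equals the planted count by construction.
* **Disease.** `P(T2D) = logistic(β0 + Σ γ_c z_c + age/sex terms)` with
  `z_c` the standardized planted scores.  Default β0 = log(90/185)
  matches a 90/275 cohort prevalence; γ defaults to zero.  Per-population
  case counts are then rebalanced to the configured 62/30, 63/30, 60/30
  shape by flipping the least-liable cases or most-liable controls
  (weighted sampling, seeded) — this preserves the direction of planted
  score–disease associations but slightly attenuates them, so
  parameter-recovery runs disable rebalancing.
* **Clinical traits.** Log-normal with additive log-scale population and
  T2D shifts; defaults (e.g. ln BMI ~ N(ln 26, 0.15), HbA1c T2D shift
  +0.25 on the log scale) give realistic adult ranges and a null
  population contrast unless shifts are planted.  Weight is derived from
  drawn BMI and height so BMI recomputes consistently.  Age is uniform
  30–70; sex is Bernoulli(0.585) for women, the cohort's composition.
* **Population score shifts** arise from frequency divergence itself; a
  per-population `freq_bias` adds a constant to the *effect-allele*
  frequency at weighted variants to plant a guaranteed directional
  shift (0.15 yields ≈ 0.8 SD per cluster with 5 variants/cluster).

What passing tests show — and do not.  The generator has no LD,
no demography beyond the one-parameter divergence, no genotyping error
structure, and clinical traits are exactly log-normal with linear
covariate structure.  Tests therefore validate the *computations*
(scoring, harmonization, PCA, the statistical battery) and the
detectability of planted effects under idealized conditions; they say
nothing about imputation artifacts, LD-induced weight miscalibration,
or model misspecification in real cohorts.

## Numerical choices and scale

Scores are plain matrix products (agreement with a brute-force double
loop to 1e-9 is part of the acceptance checks; observed ≈ 4e-15).
Standardization uses population SD (ddof = 0).  PCA tolerances are 1e-8
against a dense eigendecomposition.  Exact Mann-Whitney is enumerated by
scipy's exact method and cross-checked against full combinatorial
enumeration for group sizes ≤ 6.  Every stochastic routine takes its
generator from `(seed, stage index)`, so identical configs are
byte-identical across runs, which the pipeline manifest records via
SHA-256 digests.

Default problem sizes (275 samples; 1,000–10,000 variants; 100
replicates for power/null rates) are chosen so the full suite and the
acceptance script each complete in minutes on one CPU while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

* The published 12-cluster supplementary weight table is not
  redistributed; the loader accepts its layout, and the 285-row filter
  count check runs only when the user supplies the table at
  `data/smith_weights.tsv`.
* ADMIXTURE-style ancestry proportions, phasing/imputation, LD pruning
  defaults, and liftover are out of scope; the pipeline consumes
  already-imputed VCFs on one build.
* Logistic CIs are Wald; with very small per-stratum counts (the
  regime where separation flags appear) profile or exact CIs would be
  preferable.
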