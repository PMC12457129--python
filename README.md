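# ppgskit

Partitioned polygenic scores (pPGS) and ancestry-stratified association
testing for structured type 2 diabetes cohorts.

## The problem

Type 2 diabetes is mechanistically heterogeneous: GWAS variants cluster
into groups acting through distinct processes (beta-cell dysfunction,
obesity-mediated insulin resistance, lipodystrophy-like fat distribution,
hepatic lipid metabolism, ...).  A *partitioned* polygenic score summarizes
an individual's genetic load within one such cluster:

    pPGS_c(i) = Σ_j  w_{jc} · e_{ij}

where `w_{jc} ≥ 0` is variant `j`'s weight in cluster `c` and `e_{ij}` ∈
[0, 2] is the effect-allele dosage of sample `i`.  A variant enters the
scores only when its weight exceeds a strict inclusion threshold
(`w > 0.7802`) in at least one of the 12 clusters (Beta Cell 1/2,
Proinsulin-negative, Obesity, Lipodystrophy 1/2, Hyper Insulin,
Cholesterol-negative, Liver-Lipid, ALP-negative, Bilirubin, SHBG-LpA).

When cohorts span several ancestry groups, allele-frequency divergence
alone shifts cluster scores between populations, so the analysis needs
population-structure inference (genotype PCA) and ancestry-aware models.
`ppgskit` provides the full chain for analysts working with such cohorts:

1. **geno_io** — imputed VCF → dosage matrix (`DS` preferred over `GT`),
   with the `DR2 ≥ 0.3` imputation-quality filter;
2. **weights** — cluster weight-table parsing, strict `> 0.7802`
   filtering, and allele harmonization against the VCF (flip detection,
   palindromic A/T / C/G drop, reason-coded mismatches);
3. **ppgs** — the score computation itself, raw and per-SD standardized;
4. **ancestry** — PCA on `2p(1−p)`-standardized genotypes, with
   projection of new samples into a reference PC space;
5. **assoc** — the statistical battery: derived phenotypes
   (BMI = weight/height², WHR = WC/HC, AIP = (TC − HDL)/HDL), natural-log
   transformation, standardized OLS (betas in SD/SD), population and
   population×T2D interaction scans, per-cluster logistic T2D models
   with Wald odds-ratio CIs under four covariate tiers, Mann-Whitney,
   Pearson correlation, Benjamini–Hochberg correction, and per-SNP
   one-vs-rest population tests;
6. **synth** — a Balding–Nichols cohort simulator with planted truth
   (three populations shaped 62+30 / 63+30 / 60+30 healthy+T2D);
7. **pipeline** — seeded end-to-end orchestration with a run manifest.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
simulated cohort (they must run in order; step 01 regenerates the cohort
files that the later steps read):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_clusters.py
python analysis/03_ancestry_pca.py
python analysis/04_association_scans.py
```

Step 01 simulates 275 samples × 2,000 variants in the three-population
shape above.  Step 02 prints

```
DR2 filter: 1719/2000 variants retained
weight filter (> 0.7802): 60/120 rows retained
harmonization: {'matched': 60}
scored 275 samples; variants per cluster: {'Beta Cell 1': 5, ...}
```

i.e. 281 imputed variants fell below DR2 0.3, the strict threshold kept
exactly the 60 planted weight rows (the 60 decoys were excluded), and
every cluster score rests on 5 harmonized SNPs.  Step 03 reports that
PC1+PC2 carry 73.6 % of the top-10 PC variance and prints per-population
PC centroids — the three populations separate cleanly at F = 0.1.
Step 04 runs the scans; with no planted clinical or score→disease
effects the population and interaction scans report 0 BH-significant
terms, the logistic battery's best cluster is null
(`OR 0.83 [0.64, 1.08], adj P 0.678`), while the per-SNP one-vs-rest
scan flags 117 of 180 tests — frequency divergence between populations
is real under F = 0.1 even when nothing else is planted.

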