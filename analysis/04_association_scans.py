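#!/usr/bin/env python
"""Run the association battery on the simulated cohort.

Derives BMI/WHR/AIP, log-transforms the skewed traits, then runs the
population phenotype scan, the population x T2D interaction scan, the
12-cluster logistic T2D battery (age/sex/BMI tier), per-SNP one-vs-rest
population tests over the scored SNPs, and the cross-cluster Pearson
correlation.  BH correction is applied within each scan table.
"""

import os

import numpy as np
import pandas as pd

from ppgskit import assoc, geno_io
from ppgskit.ppgs import PartitionedScoreMatrix, standardize_scores
from ppgskit.weights import CLUSTER_NAMES

BASE = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main() -> None:
    pt = pd.read_csv(os.path.join(BASE, "cohort", "phenotypes.tsv"), sep="\t")
    pt = assoc.log_transform(assoc.compute_derived_phenotypes(pt))
    phenos = [f for f in assoc.DEFAULT_LOG_FIELDS + ("ldl",) if f in pt.columns]

    scores = pd.read_csv(os.path.join(BASE, "scores.tsv"), sep="\t", index_col="sample")
    psm = standardize_scores(
        PartitionedScoreMatrix(
            samples=list(scores.index),
            cluster_names=CLUSTER_NAMES,
            score=scores[list(CLUSTER_NAMES)].to_numpy(),
            n_variants_used=np.zeros(12, dtype=int),
        )
    )

    scan = assoc.population_phenotype_scan(pt, "Tatar", phenos)
    assoc.results_to_frame(scan).to_csv(
        os.path.join(BASE, "population_phenotype_scan.tsv"), sep="\t", index=False)
    n_sig = sum(r.p_adj <= 0.05 for r in scan)
    print(f"population scan: {len(scan)} terms, {n_sig} BH-significant at 0.05")

    inter = assoc.interaction_scan(pt, "Tatar", phenos)
    assoc.results_to_frame(inter).to_csv(
        os.path.join(BASE, "interaction_scan.tsv"), sep="\t", index=False)
    print(f"interaction scan: {len(inter)} terms, "
          f"{sum(r.p_adj <= 0.05 for r in inter)} BH-significant")

    battery = assoc.ppgs_t2d_logistic(psm, pt, "age_sex_bmi")
    assoc.results_to_frame(battery).to_csv(
        os.path.join(BASE, "ppgs_t2d_logistic.tsv"), sep="\t", index=False)
    top = min(battery, key=lambda r: r.p_raw)
    print(f"logistic battery: top cluster {top.term}: OR {top.estimate:.2f} "
          f"[{top.ci_low:.2f}, {top.ci_high:.2f}], adj P {top.p_adj:.3f}")

    r = assoc.pearson_corr(scores["Beta Cell 1"], scores["Hyper Insulin"])
    print(f"Pearson r(Beta Cell 1, Hyper Insulin) = {r:.3f}")

    gm = geno_io.read_vcf(os.path.join(BASE, "cohort", "cohort.vcf"))
    keys = set(pd.read_csv(os.path.join(BASE, "scores.tsv"), sep="\t", nrows=0).columns)
    # restrict the per-SNP scan to SNPs carrying an above-threshold weight
    wt = pd.read_csv(os.path.join(BASE, "cohort", "weights.tsv"), sep="\t")
    scored_pos = set(wt.loc[wt[list(CLUSTER_NAMES)].max(axis=1) > 0.7802, "pos"])
    idx = [j for j, v in enumerate(gm.variants) if v.pos in scored_pos]
    snp = assoc.per_snp_population_scan(gm.subset_variants(np.array(idx)), pt)
    assoc.results_to_frame(snp).to_csv(
        os.path.join(BASE, "per_snp_population_scan.tsv"), sep="\t", index=False)
    tested = [x for x in snp if "monomorphic" not in x.model]
    print(f"per-SNP scan: {len(tested)} tests, "
          f"{sum(x.p_adj <= 0.05 for x in tested)} BH-significant")


if __name__ == "__main__":
    main()
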