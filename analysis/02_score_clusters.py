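#!/usr/bin/env python
"""Filter variants, harmonize the weight table, compute the 12 pPGS.

Reads the simulated cohort from step 01, applies the DR2 >= 0.3
imputation-quality filter, retains weight-table rows with any cluster
weight > 0.7802, harmonizes effect alleles against the VCF, and writes
raw and per-SD standardized score tables.
"""

import os

from ppgskit import geno_io
from ppgskit.ppgs import compute_ppgs, standardize_scores
from ppgskit.weights import filter_weight_table, harmonize, load_weight_table

BASE = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main() -> None:
    gm = geno_io.read_vcf(os.path.join(BASE, "cohort", "cohort.vcf"))
    n0 = gm.n_variants
    gm = geno_io.filter_by_dr2(gm, 0.3)
    print(f"DR2 filter: {gm.n_variants}/{n0} variants retained")

    wt = load_weight_table(os.path.join(BASE, "cohort", "weights.tsv"))
    kept = filter_weight_table(wt, 0.7802)
    print(f"weight filter (> 0.7802): {kept.n_variants}/{wt.n_variants} rows retained")

    hmap = harmonize(kept, gm)
    print(f"harmonization: {hmap.counts()}")

    psm = compute_ppgs(gm, kept, hmap, missing_policy="mean_dosage")
    psm.to_tsv(os.path.join(BASE, "scores.tsv"))
    standardize_scores(psm).to_tsv(os.path.join(BASE, "scores_standardized.tsv"))
    used = dict(zip(psm.cluster_names, psm.n_variants_used.tolist()))
    print(f"scored {len(psm.samples)} samples; variants per cluster: {used}")


if __name__ == "__main__":
    main()
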