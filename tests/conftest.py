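"""Shared fixtures and builders for the test suite.

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgskit.geno_io import GenotypeMatrix, VariantRecord
from ppgskit.weights import CLUSTER_NAMES, ClusterWeightTable


def make_weight_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a weight-table DataFrame from row dicts.

    Each dict needs chrom/pos/effect_allele/other_allele and a
    ``weights`` mapping (cluster name -> weight); unlisted clusters get 0.
    """
    out = []
    for r in rows:
        rec = {
            "chrom": r.get("chrom", "1"),
            "pos": r["pos"],
            "rsid": r.get("rsid", "."),
            "effect_allele": r["effect_allele"],
            "other_allele": r["other_allele"],
        }
        for c in CLUSTER_NAMES:
            rec[c] = r.get("weights", {}).get(c, 0.0)
        out.append(rec)
    return pd.DataFrame(out)


def make_gm(dosage, pos=None, ref="A", alt="G", samples=None, dr2=None) -> GenotypeMatrix:
    """GenotypeMatrix from a dosage array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    pos = pos if pos is not None else [100 + 10 * j for j in range(m)]
    refs = [ref] * m if isinstance(ref, str) else ref
    alts = [alt] * m if isinstance(alt, str) else alt
    dr2s = [None] * m if dr2 is None else dr2
    variants = [
        VariantRecord("1", int(pos[j]), f"v{j}", refs[j], alts[j], dr2s[j])
        for j in range(m)
    ]
    samples = samples or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def random_score_instance(rng: np.random.Generator, n_samples=20, n_variants=50):
    """A random genotype matrix + filtered weight table + harmonization map.

    Alleles are non-palindromic; effect alleles randomly ALT or REF so
    flips occur.  Weights are above-threshold in one random cluster per
    row.  Returns (gm, table, hmap).
    """
    from ppgskit.weights import filter_weight_table, harmonize

    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    idx = rng.integers(0, len(pairs), size=n_variants)
    refs = [pairs[i][0] for i in idx]
    alts = [pairs[i][1] for i in idx]
    dosage = rng.integers(0, 3, size=(n_samples, n_variants)).astype(float)
    miss = rng.random((n_samples, n_variants)) < 0.05
    dosage[miss] = np.nan
    gm = make_gm(dosage, ref=refs, alt=alts)

    rows = []
    for j in range(n_variants):
        eff_is_alt = rng.random() < 0.5
        cluster = CLUSTER_NAMES[rng.integers(0, 12)]
        rows.append(
            {
                "pos": gm.variants[j].pos,
                "effect_allele": alts[j] if eff_is_alt else refs[j],
                "other_allele": refs[j] if eff_is_alt else alts[j],
                "weights": {cluster: 0.7802 + rng.uniform(0.05, 1.0)},
            }
        )
    t = filter_weight_table(ClusterWeightTable(rows=make_weight_frame(rows)))
    hmap = harmonize(t, gm)
    return gm, t, hmap


def brute_force_ppgs(gm, t, hmap, missing_policy="mean_dosage"):
    """Independent O(n*m*12) double-loop score oracle.

    Resolves missing dosages per policy, orients each variant to its
    effect allele, and accumulates weight * dosage one term at a time.
    """
    w = t.weight_matrix()
    n = gm.n_samples
    score = np.zeros((n, 12))
    # per-variant oriented dosages with missing resolved
    for k in range(hmap.n_matched):
        j = hmap.gm_index[k]
        i_t = hmap.table_index[k]
        col = []
        for i in range(n):
            if gm.missing_mask[i, j]:
                col.append(None)
            else:
                d = gm.dosage[i, j]
                col.append(2.0 - d if hmap.flip[k] else d)
        known = [v for v in col if v is not None]
        fill = (sum(known) / len(known)) if known else 0.0
        for i in range(n):
            v = col[i]
            if v is None:
                v = {"mean_dosage": fill, "zero": 0.0}[missing_policy]
            for c in range(12):
                score[i, c] += w[i_t, c] * v
    return score


@pytest.fixture(scope="session")
def small_cohort():
    """One default-shaped synthetic cohort (275 samples, desk scale)."""
    from ppgskit.synth import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_variants=300, n_weighted=24, seed=11))
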