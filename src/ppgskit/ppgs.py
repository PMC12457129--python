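"""Partitioned polygenic score computation.

For each sample i and cluster c the score is the weighted sum of effect
-allele dosages over the harmonized, threshold-passing variants:

    score[i, c] = sum_j w[j, c] * e[i, j]

where e[i, j] is the ALT dosage when the effect allele is ALT and
2 - dosage when it is REF.  There is no per-sample normalization by
variant count: the score is the plain weighted allele count.  Missing
dosages are resolved before the sum, by default to the variant's mean
effect dosage over non-missing samples (standard polygenic-score
practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ppgskit.geno_io import GenotypeMatrix
from ppgskit.weights import ClusterWeightTable, HarmonizationMap

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("mean_dosage", "zero", "drop_sample")


@dataclass
class PartitionedScoreMatrix:
    """Samples x 12 cluster scores.

    ``n_variants_used[c]`` counts the harmonized variants with a nonzero
    weight in cluster c; ``dropped_samples`` lists samples removed under
    the ``drop_sample`` missing policy.
    """

    samples: list[str]
    cluster_names: tuple[str, ...]
    score: np.ndarray
    n_variants_used: np.ndarray
    standardized: bool = False
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.samples), len(self.cluster_names)):
            raise ValueError("score shape mismatch")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.score, index=self.samples, columns=list(self.cluster_names))
        df.index.name = "sample"
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def compute_ppgs(
    gm: GenotypeMatrix,
    t: ClusterWeightTable,
    hmap: HarmonizationMap,
    missing_policy: str = "mean_dosage",
) -> PartitionedScoreMatrix:
    """Compute the 12 per-cluster scores for every sample.

    ``t`` must already be threshold-filtered and ``hmap`` built against
    ``gm`` and ``t``.  Raises if the harmonization map is empty ("no
    scorable variants") or the policy is unknown.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}; choose from {MISSING_POLICIES}")
    if hmap.n_matched == 0:
        raise ValueError("no scorable variants: empty harmonization map")

    dosage = gm.dosage[:, hmap.gm_index]
    missing = gm.missing_mask[:, hmap.gm_index]
    # Orient to the effect allele.
    eff = np.where(hmap.flip[None, :], 2.0 - dosage, dosage)

    dropped: list[str] = []
    samples = list(gm.samples)
    if missing_policy == "drop_sample":
        bad = missing.any(axis=1)
        dropped = [s for s, b in zip(samples, bad) if b]
        if dropped:
            logger.info("drop_sample policy removed %d samples: %s", len(dropped), dropped)
        eff = eff[~bad]
        missing = missing[~bad]
        samples = [s for s, b in zip(samples, bad) if not b]
    elif missing_policy == "zero":
        eff = np.where(missing, 0.0, eff)
    else:  # mean effect dosage over non-missing samples
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(missing, np.nan, eff), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        eff = np.where(missing, col_mean[None, :], eff)

    w = t.weight_matrix()[hmap.table_index, :]  # matched variants x 12
    score = eff @ w
    n_used = (w != 0).sum(axis=0)
    return PartitionedScoreMatrix(
        samples=samples,
        cluster_names=t.cluster_names,
        score=score,
        n_variants_used=np.asarray(n_used, dtype=int),
        dropped_samples=dropped,
    )


def standardize_scores(psm: PartitionedScoreMatrix) -> PartitionedScoreMatrix:
    """Z-score each cluster column (mean 0, SD 1 over samples).

    Raises naming the cluster if a column has zero variance.  Idempotent to
    numerical precision.
    """
    mu = psm.score.mean(axis=0)
    sd = psm.score.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance cluster: {psm.cluster_names[zero[0]]!r}")
    return PartitionedScoreMatrix(
        samples=list(psm.samples),
        cluster_names=psm.cluster_names,
        score=(psm.score - mu) / sd,
        n_variants_used=psm.n_variants_used.copy(),
        standardized=True,
        dropped_samples=list(psm.dropped_samples),
    )
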