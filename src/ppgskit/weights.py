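"""Cluster weight tables: parsing, threshold filtering, allele harmonization.

The 12 mechanistic T2D clusters (soft-clustering of GWAS variants by their
multi-trait association patterns) each assign a nonnegative weight to a set
of SNPs.  A variant enters the partitioned scores only if its weight
exceeds a strict inclusion threshold (default 0.7802) in at least one
cluster; by default it then contributes only to the clusters where its
weight passes the threshold (sub-threshold weights are zeroed), which keeps
each cluster score on its own mechanism's signal.  The alternative reading
-- an included variant contributes to every cluster -- is available via
``contribute="all-clusters"``.

Harmonization orients VCF ALT dosages to the table's effect alleles.
Matching is by chromosome:position (chr-prefix insensitive) plus allele
set; rsIDs are annotation only.  A/T and C/G (palindromic) pairs are
dropped by default since strand cannot be resolved from alleles alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ppgskit.geno_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: The 12 mechanistic cluster names, in canonical order.
CLUSTER_NAMES: tuple[str, ...] = (
    "Beta Cell 1",
    "Beta Cell 2",
    "Proinsulin-negative",
    "Obesity",
    "Lipodystrophy 1",
    "Lipodystrophy 2",
    "Hyper Insulin",
    "Cholesterol-negative",
    "Liver-Lipid",
    "ALP-negative",
    "Bilirubin",
    "SHBG-LpA",
)

#: Default inclusion threshold: a variant is scored only if some cluster
#: weight is strictly greater than this.
DEFAULT_WEIGHT_THRESHOLD = 0.7802

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class WeightTableError(ValueError):
    """Raised for malformed weight tables."""


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class ClusterWeightTable:
    """Per-variant effect-allele weights for the 12 clusters.

    ``rows`` is a DataFrame with columns ``chrom, pos, rsid, effect_allele,
    other_allele`` followed by one column per cluster; ``key`` combines
    normalized chromosome and position.
    """

    rows: pd.DataFrame
    cluster_names: tuple[str, ...] = CLUSTER_NAMES
    threshold: float = DEFAULT_WEIGHT_THRESHOLD

    def __post_init__(self):
        missing = [c for c in self.cluster_names if c not in self.rows.columns]
        if missing:
            raise WeightTableError(f"missing cluster columns: {missing}")
        if len(self.cluster_names) != 12:
            raise WeightTableError(f"expected 12 clusters, got {len(self.cluster_names)}")
        w = self.rows[list(self.cluster_names)].to_numpy(dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            bad = self.rows.index[np.any((w < 0) | ~np.isfinite(w), axis=1)][0]
            raise WeightTableError(f"negative or non-finite weight in row {bad}")
        keys = self.keys()
        dup = keys[keys.duplicated()]
        if len(dup):
            raise WeightTableError(f"duplicate variant key {dup.iloc[0]!r}")

    def keys(self) -> pd.Series:
        return (
            self.rows["chrom"].map(_norm_chrom)
            + ":"
            + self.rows["pos"].astype(int).astype(str)
        )

    @property
    def n_variants(self) -> int:
        return len(self.rows)

    def weight_matrix(self) -> np.ndarray:
        """n_variants x 12 weight array in cluster order."""
        return self.rows[list(self.cluster_names)].to_numpy(dtype=float)

    def to_tsv(self, path: str) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def load_weight_table(path: str, threshold: float = DEFAULT_WEIGHT_THRESHOLD) -> ClusterWeightTable:
    """Load a weight table TSV.

    Expects columns ``chrom pos rsid effect_allele other_allele`` plus the
    12 cluster columns; raises :class:`WeightTableError` naming the problem
    row on duplicate keys, negative weights, or missing cluster columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "effect_allele", "other_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise WeightTableError(f"{path}: missing required columns {missing}")
    if "rsid" not in df.columns:
        df["rsid"] = "."
    missing_clusters = [c for c in CLUSTER_NAMES if c not in df.columns]
    if missing_clusters:
        raise WeightTableError(f"{path}: missing cluster columns {missing_clusters}")
    order = required[:2] + ["rsid"] + required[2:] + list(CLUSTER_NAMES)
    return ClusterWeightTable(rows=df[order].copy(), threshold=threshold)


def filter_weight_table(
    t: ClusterWeightTable,
    threshold: float | None = None,
    contribute: str = "passing-clusters",
) -> ClusterWeightTable:
    """Apply the strict inclusion rule: keep rows with max weight > threshold.

    With ``contribute="passing-clusters"`` (default) a retained variant's
    sub-threshold weights are zeroed, so it contributes only to clusters
    where it passes; ``contribute="all-clusters"`` keeps all its weights.
    """
    if threshold is None:
        threshold = t.threshold
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if contribute not in ("passing-clusters", "all-clusters"):
        raise ValueError(f"unknown contribute mode {contribute!r}")
    w = t.weight_matrix()
    keep = w.max(axis=1) > threshold
    rows = t.rows.loc[keep].reset_index(drop=True).copy()
    if contribute == "passing-clusters" and len(rows):
        wk = w[keep]
        wk = np.where(wk > threshold, wk, 0.0)
        rows[list(t.cluster_names)] = wk
    logger.info(
        "weight filter at >%.4g: retained %d of %d variants", threshold, keep.sum(), len(w)
    )
    return ClusterWeightTable(rows=rows, cluster_names=t.cluster_names, threshold=threshold)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand is unresolvable from alleles."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class HarmonizationMap:
    """Result of matching weight-table rows against a genotype matrix.

    ``gm_index``/``table_index``/``flip`` are parallel arrays over matched
    variants; ``flip`` is True when the effect allele is the VCF REF, i.e.
    the effect dosage is 2 - ALT dosage.  ``reasons`` maps every weight
    -table row index to its status: matched / absent / allele_mismatch /
    palindromic (a partition of the table's rows).
    """

    gm_index: np.ndarray
    table_index: np.ndarray
    flip: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.gm_index)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reasons.values():
            out[r] = out.get(r, 0) + 1
        return out

    def report(self, t: ClusterWeightTable) -> pd.DataFrame:
        """Per-row harmonization report (key, status, flip)."""
        keys = t.keys()
        flips = dict(zip(self.table_index.tolist(), self.flip.tolist()))
        return pd.DataFrame(
            {
                "key": keys,
                "status": [self.reasons[i] for i in range(len(keys))],
                "flip": [bool(flips.get(i, False)) for i in range(len(keys))],
            }
        )


def harmonize(
    t: ClusterWeightTable,
    gm: GenotypeMatrix,
    drop_palindromic: bool = True,
) -> HarmonizationMap:
    """Match weight-table rows to VCF variants and orient effect alleles.

    Matching is by normalized ``chrom:pos``; within a positional match the
    allele sets must agree.  ``flip=False`` when effect==ALT, ``flip=True``
    when effect==REF; other allele configurations are ``allele_mismatch``.
    Failures are reason-coded, never raised.
    """
    by_pos: dict[str, int] = {}
    for j, v in enumerate(gm.variants):
        by_pos.setdefault(f"{_norm_chrom(v.chrom)}:{v.pos}", j)

    gm_idx: list[int] = []
    tbl_idx: list[int] = []
    flips: list[bool] = []
    reasons: dict[int, str] = {}

    eff = t.rows["effect_allele"].str.upper().to_numpy()
    oth = t.rows["other_allele"].str.upper().to_numpy()
    keys = t.keys().to_numpy()

    for i in range(len(t.rows)):
        j = by_pos.get(keys[i])
        if j is None:
            reasons[i] = "absent"
            continue
        if drop_palindromic and is_palindromic(eff[i], oth[i]):
            reasons[i] = "palindromic"
            continue
        v = gm.variants[j]
        if eff[i] == v.alt and oth[i] == v.ref:
            flip = False
        elif eff[i] == v.ref and oth[i] == v.alt:
            flip = True
        else:
            reasons[i] = "allele_mismatch"
            continue
        reasons[i] = "matched"
        gm_idx.append(j)
        tbl_idx.append(i)
        flips.append(flip)

    hmap = HarmonizationMap(
        gm_index=np.asarray(gm_idx, dtype=int),
        table_index=np.asarray(tbl_idx, dtype=int),
        flip=np.asarray(flips, dtype=bool),
        reasons=reasons,
    )
    logger.info("harmonization: %s", hmap.counts())
    return hmap
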