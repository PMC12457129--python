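"""Population-structure inference by PCA on standardized genotypes.

Genotypes are standardized with the binomial-variance convention of
ancestry PCA: per variant j, with allele-frequency estimate
p_j = mean(dosage)/2 over non-missing samples,

    x[i, j] = (d[i, j] - 2 p_j) / sqrt(2 p_j (1 - p_j)),

missing entries set to 0 after centering (mean imputation) and
monomorphic variants dropped.  The principal components are the top
singular vectors of the standardized matrix; each component's sign is
fixed so its largest-magnitude variant loading is positive, which makes
runs reproducible.  Study samples can be projected into a reference PCA
space through the reference's frequencies and loadings, mirroring the
practice of placing a cohort against public reference panels.

LD pruning is available as a hook but defaults off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ppgskit.geno_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Top-K principal components of a genotype matrix.

    ``coordinates`` are sample scores (n x K); ``explained_variance`` the
    corresponding eigenvalues of the sample covariance, non-increasing;
    ``loadings`` the variant-space directions (m x K) and ``variant_means``
    the allele-frequency estimates used for centering, both keyed by
    ``variant_keys`` so new samples can be projected.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    explained_variance: np.ndarray
    loadings: np.ndarray
    variant_means: np.ndarray
    variant_keys: list[str]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"PC{i+1}" for i in range(self.k)],
        )
        df.index.name = "sample"
        return df


def standardize_genotypes(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale dosages by the 2p(1-p) binomial variance.

    Returns ``(x, p_hat, kept)`` where ``x`` is the standardized matrix
    restricted to polymorphic variants, ``p_hat`` their frequency
    estimates, and ``kept`` the retained variant indices.  Monomorphic
    variants (p_hat in {0, 1}) are dropped with a counted warning; raises
    if every variant is monomorphic.
    """
    d = np.where(gm.missing_mask, np.nan, gm.dosage)
    with np.errstate(invalid="ignore"):
        p_hat = np.nanmean(d, axis=0) / 2.0
    poly = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    n_mono = int((~poly).sum())
    if n_mono == gm.n_variants:
        raise ValueError("all variants are monomorphic; PCA is undefined")
    if n_mono:
        logger.warning("dropped %d monomorphic variants before PCA", n_mono)
    kept = np.flatnonzero(poly)
    p = p_hat[kept]
    x = (d[:, kept] - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    x = np.where(np.isfinite(x), x, 0.0)  # missing -> 0 after centering
    return x, p, kept


def _fix_signs(loadings: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Sign convention: the largest-|.| loading of each component is positive.
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
            coords[:, c] = -coords[:, c]
    return loadings, coords


def pca(gm: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Top-k PCA of the standardized genotype matrix.

    ``k`` must satisfy k <= min(n_samples - 1, n_polymorphic_variants).
    Deterministic: component signs follow the largest-loading-positive
    convention.
    """
    x, p_hat, kept = standardize_genotypes(gm)
    n, m = x.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_samples-1, n_variants) = {min(n - 1, m)}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T.copy()
    loadings, coords = _fix_signs(loadings, coords)
    explained = (s[:k] ** 2) / (n - 1)
    return PcaResult(
        sample_ids=list(gm.samples),
        coordinates=coords,
        explained_variance=explained,
        loadings=loadings,
        variant_means=p_hat,
        variant_keys=[gm.variants[i].key for i in kept],
    )


def project(reference: PcaResult, gm: GenotypeMatrix) -> np.ndarray:
    """Project new samples into a reference PCA space.

    New dosages are standardized with the *reference* allele frequencies
    and mapped through the reference loadings over the shared variants.
    Raises if no variant is shared.  Projecting the reference samples
    themselves reproduces their coordinates.
    """
    ref_pos = {key: i for i, key in enumerate(reference.variant_keys)}
    shared_gm: list[int] = []
    shared_ref: list[int] = []
    for j, v in enumerate(gm.variants):
        i = ref_pos.get(v.key)
        if i is not None:
            shared_gm.append(j)
            shared_ref.append(i)
    if not shared_gm:
        raise ValueError("no variants shared with the reference PCA model")
    logger.info("projection uses %d of %d reference variants", len(shared_ref), len(reference.variant_keys))

    p = reference.variant_means[shared_ref]
    d = np.where(gm.missing_mask[:, shared_gm], np.nan, gm.dosage[:, shared_gm])
    x = (d - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    x = np.where(np.isfinite(x), x, 0.0)
    return x @ reference.loadings[shared_ref, :]


def plot_pca(
    result: PcaResult,
    labels: pd.Series | None,
    path: str,
) -> None:
    """Scatter PC1 vs PC2 colored by population label, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    coords = result.coordinates
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=12)
    else:
        labels = labels.reindex(result.sample_ids)
        for pop in sorted(labels.dropna().unique()):
            m = (labels == pop).to_numpy()
            ax.scatter(coords[m, 0], coords[m, 1], s=12, label=str(pop))
        ax.legend(title="population", frameon=False)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
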