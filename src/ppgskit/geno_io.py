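"""Genotype I/O: VCF -> dosage matrix, imputation-quality filtering, writers.

Genotypes are represented as effect-of-ALT dosages in [0, 2].  When an
imputed dosage (``DS``) is present it takes precedence over the hard call
(``GT``) because it carries the imputation uncertainty; this is logged once
per file.  Only biallelic SNPs are accepted: the cluster weight tables this
package consumes key SNPs, so indels are skipped (with a counted warning)
and records with more than one ALT allele raise, since they should have
been split upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised for malformed or unsupported VCF content."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP.

    ``dr2`` is the imputation dosage-R^2 quality in [0, 1]; ``None`` means
    the variant carries no imputation annotation (directly genotyped).
    """

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str
    dr2: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} at {self.vid}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _SNP_ALLELES or len(allele) != 1:
                raise ValueError(
                    f"{name} allele {allele!r} at {self.chrom}:{self.pos} is not a SNP allele"
                )
        if self.dr2 is not None and not 0.0 <= self.dr2 <= 1.0:
            raise ValueError(f"DR2 {self.dr2} outside [0,1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosages with a missingness mask.

    ``dosage`` holds values in [0, 2]; entries where ``missing_mask`` is
    True are undefined (kept as NaN).  Downstream modules own the missing
    -data policy; this container only preserves it.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.dosage)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.missing_mask.shape != self.dosage.shape:
            raise ValueError("missing_mask shape mismatch")
        ok = self.dosage[~self.missing_mask]
        if ok.size and (np.nanmin(ok) < 0 or np.nanmax(ok) > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )


def read_vcf(path: str, dr2_info_key: str = "DR2") -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage comes from the ``DS`` FORMAT field when present, else from the
    ALT-allele count of ``GT``.  Missing hard calls (``./.``) with no DS are
    flagged in the missing mask.  The imputation quality is read from the
    INFO key ``dr2_info_key`` when present.

    Raises
    ------
    VcfParseError
        If the file is malformed or a record carries more than one ALT
        allele (multiallelics must be split upstream).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    missing_cols: list[np.ndarray] = []
    n_skipped_non_snp = 0
    ds_logged = False

    for var in vcf:
        if len(var.ALT) != 1:
            raise VcfParseError(
                f"record {var.CHROM}:{var.POS} {var.REF}->{var.ALT} has "
                f"{len(var.ALT)} ALT alleles; split multiallelics upstream"
            )
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or set(ref + alt) - _SNP_ALLELES:
            n_skipped_non_snp += 1
            continue

        dr2 = var.INFO.get(dr2_info_key)
        rec = VariantRecord(
            chrom=var.CHROM,
            pos=var.POS,
            vid=var.ID or f"{var.CHROM}:{var.POS}",
            ref=ref,
            alt=alt,
            dr2=float(dr2) if dr2 is not None else None,
        )

        # GT-derived dosage: count of ALT alleles; -1 -> missing.
        gt = np.asarray(var.gt_types)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt_dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])

        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            if not ds_logged:
                logger.info("DS field present in %s; DS takes precedence over GT", path)
                ds_logged = True
            ds = np.asarray(ds, dtype=float).reshape(len(samples))
            col = np.where(np.isfinite(ds), ds, gt_dos)
        else:
            col = gt_dos

        variants.append(rec)
        dosage_cols.append(col)
        missing_cols.append(~np.isfinite(col))

    if n_skipped_non_snp:
        logger.warning("%s: skipped %d non-SNP records", path, n_skipped_non_snp)
    if not variants:
        raise VcfParseError(f"no biallelic SNP records in {path}")

    dosage = np.column_stack(dosage_cols)
    missing = np.column_stack(missing_cols)
    dosage[missing] = np.nan
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage, missing_mask=missing)


def filter_by_dr2(gm: GenotypeMatrix, threshold: float = 0.3) -> GenotypeMatrix:
    """Retain variants with DR2 >= ``threshold`` or no DR2 annotation.

    Variants lacking a DR2 annotation are treated as directly genotyped and
    always pass: the quality filter applies to imputed variants only.  The
    input matrix is not modified; an empty result is legal.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"DR2 threshold must lie in [0,1], got {threshold}")
    keep = np.array(
        [v.dr2 is None or v.dr2 >= threshold for v in gm.variants], dtype=bool
    )
    logger.info("DR2 filter at %.3g: retained %d of %d variants", threshold, keep.sum(), gm.n_variants)
    return gm.subset_variants(np.flatnonzero(keep))


def write_vcf(gm: GenotypeMatrix, path: str, write_ds: bool | None = None) -> None:
    """Write the matrix as an uncompressed VCFv4.2 text file.

    Integral dosages are written as GT hard calls; with ``write_ds`` (auto
    -enabled when any dosage is fractional) a DS field carries the exact
    dosage.  DR2 annotations, when present, go to INFO.  GT-only matrices
    round-trip exactly through :func:`read_vcf`.
    """
    dosage, missing = gm.dosage, gm.missing_mask
    if write_ds is None:
        ok = dosage[~missing]
        write_ds = bool(ok.size) and bool(np.any(ok != np.round(ok)))
    fmt = "GT:DS" if write_ds else "GT"
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: dict[str, None] = {}
        for v in gm.variants:
            seen.setdefault(v.chrom)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,Description="Imputation dosage R2">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if write_ds:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, v in enumerate(gm.variants):
            info = f"DR2={v.dr2:g}" if v.dr2 is not None else "."
            cells = []
            for i in range(gm.n_samples):
                if missing[i, j]:
                    cells.append("./.:." if write_ds else "./.")
                    continue
                d = dosage[i, j]
                gt = gt_strings[int(round(d))]
                cells.append(f"{gt}:{d:g}" if write_ds else gt)
            row = [v.chrom, str(v.pos), v.vid, v.ref, v.alt, ".", "PASS", info, fmt]
            fh.write("\t".join(row + cells) + "\n")


def write_dosage_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Write samples x variants dosages as TSV; missing encoded as ``NA``."""
    import pandas as pd

    df = pd.DataFrame(gm.dosage, index=gm.samples, columns=gm.variant_keys())
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
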