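"""Genotype container, minimal-VCF I/O, QC filters, allele frequencies, PCA.

Genotypes live in an additive dosage matrix (count of alternate alleles,
0/1/2, NaN for missing) with per-variant metadata.  The VCF dialect is
deliberately minimal: biallelic records, GT as the only FORMAT field,
``./.`` for missing calls; anything richer is rejected rather than
silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "QCReport",
    "read_vcf",
    "write_vcf",
    "maf",
    "maf_vector",
    "apply_qc",
    "compute_pcs",
]

VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


class VCFDialectError(ValueError):
    """A record falls outside the minimal GT-only biallelic dialect."""


@dataclass
class GenotypePanel:
    """Dosage matrix plus ordered variant metadata and sample ids.

    Parameters
    ----------
    dosages
        ``n_subjects x n_snps`` float array over {0, 1, 2, NaN}.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt``; positions are
        1-based and strictly increasing within each chromosome.
    subjects
        Ordered sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D subjects x snps matrix")
        self.variants = pd.DataFrame(self.variants).reset_index(drop=True)
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {sorted(missing_cols)}")
        self.subjects = list(self.subjects)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_subj, n_snp = self.dosages.shape
        if len(self.subjects) != n_subj:
            raise ValueError(f"{len(self.subjects)} subject ids for {n_subj} dosage rows")
        if len(self.variants) != n_snp:
            raise ValueError(f"{len(self.variants)} variant records for {n_snp} dosage columns")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id: {dup!r}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom!r}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage outside {{0,1,2,missing}}: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, subjects: np.ndarray | None = None, snps: np.ndarray | None = None) -> "GenotypePanel":
        """Row/column subset by boolean mask or integer index, preserving order."""
        subj_idx = np.arange(self.n_subjects) if subjects is None else np.asarray(subjects)
        snp_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if subj_idx.dtype == bool:
            subj_idx = np.flatnonzero(subj_idx)
        if snp_idx.dtype == bool:
            snp_idx = np.flatnonzero(snp_idx)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(subj_idx, snp_idx)],
            variants=self.variants.iloc[snp_idx],
            subjects=[self.subjects[i] for i in subj_idx],
        )

    def snp_index(self, snp: str) -> int:
        hits = np.flatnonzero((self.variants["id"] == snp).to_numpy())
        if hits.size == 0:
            raise KeyError(f"no variant with id {snp!r}")
        return int(hits[0])


@dataclass
class QCReport:
    """Per-stage removal counts from :func:`apply_qc`."""

    snps_removed_callrate: int
    subjects_removed_callrate: int
    snps_removed_maf: int
    snp_callrate: float
    subject_callrate: float
    maf_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["snp_callrate", "subject_callrate", "maf"],
                "removed": [
                    self.snps_removed_callrate,
                    self.subjects_removed_callrate,
                    self.snps_removed_maf,
                ],
                "threshold": [self.snp_callrate, self.subject_callrate, self.maf_min],
            }
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypePanel:
    """Read a minimal GT-only VCF into a :class:`GenotypePanel`.

    Multi-allelic records, duplicate ids and non-monotone positions are
    rejected with errors naming the offending variant.
    """
    from cyvcf2 import VCF

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # cyvcf2 warns on header-less contigs
        vcf = VCF(str(path))
        subjects = list(vcf.samples)
        rows, records = [], []
        for v in vcf:
            if len(v.ALT) != 1:
                raise VCFDialectError(
                    f"multi-allelic record not supported: {v.ID or v.CHROM + ':' + str(v.POS)}"
                )
            doses = np.full(len(subjects), np.nan)
            for i, gt in enumerate(v.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if len(alleles) == 2:
                    d = float(sum(alleles))
                    if d > 2:
                        raise VCFDialectError(f"malformed GT (allele index > 1) at {v.ID}")
                    doses[i] = d
                elif alleles:
                    raise VCFDialectError(f"half-missing GT at {v.ID} not supported")
            rows.append(doses)
            records.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
        vcf.close()
    if not rows:
        raise VCFDialectError(f"no variant records in {path}")
    variants = pd.DataFrame(records, columns=list(VARIANT_COLUMNS))
    return GenotypePanel(dosages=np.array(rows).T, variants=variants, subjects=subjects)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the minimal dialect: CHROM POS ID REF ALT . PASS . GT calls."""
    panel.validate()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.subjects) + "\n")
        for j, rec in panel.variants.iterrows():
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in panel.dosages[:, j]
            )
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Allele frequency and QC
# ---------------------------------------------------------------------------

def maf(panel: GenotypePanel, snp: int | str) -> float:
    """Minor allele frequency of one SNP over non-missing calls.

    Returns NaN (with a warning) for an all-missing column.  Invariant to
    which allele is labelled alternate: min(p, 1-p).
    """
    j = panel.snp_index(snp) if isinstance(snp, str) else int(snp)
    col = panel.dosages[:, j]
    ok = ~np.isnan(col)
    if not ok.any():
        warnings.warn(f"SNP {panel.variants['id'].iloc[j]!r} is all-missing; MAF undefined")
        return float("nan")
    p = col[ok].sum() / (2.0 * ok.sum())
    return float(min(p, 1.0 - p))


def maf_vector(panel: GenotypePanel) -> np.ndarray:
    """Vector of per-SNP MAFs (NaN where all calls are missing)."""
    d = panel.dosages
    n_called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
        p = np.where(n_called == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def apply_qc(
    panel: GenotypePanel,
    snp_callrate: float = 0.98,
    subject_callrate: float = 0.98,
    maf_min: float = 0.05,
) -> tuple[GenotypePanel, QCReport]:
    """SNP call-rate, then subject call-rate, then MAF filter, in that order.

    The MAF boundary is inclusive (MAF >= ``maf_min`` retained).  Raises if
    nothing survives.
    """
    for name, t in (("snp_callrate", snp_callrate), ("subject_callrate", subject_callrate), ("maf_min", maf_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    d = panel.dosages
    snp_cr = (~np.isnan(d)).mean(axis=0)
    keep_snp = snp_cr >= snp_callrate
    n_snp_removed = int((~keep_snp).sum())
    p1 = panel.subset(snps=keep_snp)

    subj_cr = (~np.isnan(p1.dosages)).mean(axis=1) if p1.n_snps else np.ones(p1.n_subjects)
    keep_subj = subj_cr >= subject_callrate
    n_subj_removed = int((~keep_subj).sum())
    p2 = p1.subset(subjects=keep_subj)

    mafs = maf_vector(p2) if p2.n_snps else np.array([])
    with np.errstate(invalid="ignore"):
        keep_maf = np.nan_to_num(mafs, nan=-1.0) >= maf_min
    n_maf_removed = int((~keep_maf).sum())
    p3 = p2.subset(snps=keep_maf)

    if p3.n_snps == 0 or p3.n_subjects == 0:
        raise ValueError(
            f"QC removed everything (snps: {n_snp_removed}+{n_maf_removed}, subjects: {n_subj_removed})"
        )
    report = QCReport(
        snps_removed_callrate=n_snp_removed,
        subjects_removed_callrate=n_subj_removed,
        snps_removed_maf=n_maf_removed,
        snp_callrate=snp_callrate,
        subject_callrate=subject_callrate,
        maf_min=maf_min,
    )
    return p3, report


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def compute_pcs(panel: GenotypePanel, k: int) -> np.ndarray:
    """Top-``k`` principal-component scores from standardized dosages.

    Each SNP column is centered by twice its allele frequency and scaled by
    the binomial standard deviation ``sqrt(2 p (1 - p))``; missing dosages
    contribute zero after centering.  Scores are the left singular vectors
    scaled by their singular values, with each component's sign fixed so its
    largest-magnitude SNP loading is positive.  Monomorphic SNPs are
    excluded with a warning.
    """
    if k >= min(panel.n_subjects, panel.n_snps):
        raise ValueError(
            f"k={k} must be < min(n_subjects={panel.n_subjects}, n_snps={panel.n_snps})"
        )
    d = panel.dosages
    n_called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
    poly = (p > 0.0) & (p < 1.0) & (n_called > 0)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic/all-missing SNPs from PCA")
    if poly.sum() < k + 1:
        raise ValueError("too few polymorphic SNPs for requested k")
    dp = d[:, poly]
    pp = p[poly]
    z = (dp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1.0
    return scores
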