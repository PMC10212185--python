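"""Genotype I/O, QC and per-system dosage matrices.

Dosages are minor-allele counts: 0 = major-allele homozygote, 1 =
heterozygote, 2 = minor-allele homozygote; missing calls are NaN.  Readers
normalise orientation so that after loading every variant's coded allele is
the minor one (frequency <= 0.5).  VCF is read through cyvcf2; PLINK 1
bed/bim/fam uses a small built-in 2-bit codec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import DataError, chrom_sort_key, normalize_chrom

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "GeneLocus",
    "read_genotypes",
    "write_vcf",
    "write_plink",
    "read_gene_loci",
    "qc_filter",
    "hwe_exact_p",
    "assign_snps_to_genes",
    "build_system_matrix",
    "ld_r2",
]


@dataclass(frozen=True)
class VariantRecord:
    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float = float("nan")


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(f"gene {self.gene}: start {self.start} > end {self.end}")


@dataclass
class GenotypeMatrix:
    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # N x S float, NaN = missing

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise DataError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.id: i for i, v in enumerate(self.variants)}

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
        )


# ---------------------------------------------------------------------------
# reading / writing


def _orient_minor(variants, dosages):
    """Flip columns whose coded-allele frequency exceeds 0.5; set maf."""
    out = []
    for j, v in enumerate(variants):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        freq = obs.mean() / 2.0 if obs.size else 0.0
        if freq > 0.5:
            dosages[:, j] = 2.0 - col
            freq = 1.0 - freq
        out.append(replace(v, maf=freq))
    return out, dosages


def read_genotypes(path, dialect: str) -> GenotypeMatrix:
    """Read genotypes from ``path`` in the named dialect ('vcf' or 'plink').

    For PLINK, ``path`` is the file-set prefix (with or without '.bed').
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "plink":
        return _read_plink(path)
    raise DataError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"multi-allelic site {v.CHROM}:{v.POS} skipped")
            continue
        dos = np.empty(len(sample_ids))
        for i, g in enumerate(v.genotypes):
            a = g[:-1]  # trailing element is phasing flag
            dos[i] = np.nan if any(x < 0 for x in a) else float(sum(1 for x in a if x == 1))
        variants.append(
            VariantRecord(
                id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=normalize_chrom(v.CHROM),
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
            )
        )
        cols.append(dos)
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    variants, dosages = _orient_minor(variants, dosages)
    return GenotypeMatrix(sample_ids, variants, dosages)


_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2;
# dosage counts the A1 allele.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _plink_prefix(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix == ".bed" else p


def _read_plink(path) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    n, s = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise DataError(f"{prefix}.bed: not a SNP-major PLINK 1 bed file")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * s:
        raise DataError(f"{prefix}.bed: size inconsistent with fam/bim dimensions")
    body = body.reshape(s, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((s, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    variants = [
        VariantRecord(
            id=r.id, chrom=normalize_chrom(r.chrom), pos=int(r.pos), ref=r.a2, alt=r.a1
        )
        for r in bim.itertuples()
    ]
    variants, dosages = _orient_minor(variants, dosages)
    return GenotypeMatrix(list(fam["iid"]), variants, dosages)


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a plain-text VCF 4.2 with GT fields (ALT = coded minor allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for v in gm.variants:
            if v.chrom not in seen:
                seen.append(v.chrom)
                fh.write(f"##contig=<ID={v.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j, v in enumerate(gm.variants):
            col = gm.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_STRINGS[d] for d in col
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write PLINK 1 bed/bim/fam (SNP-major; A1 = coded minor allele)."""
    prefix = _plink_prefix(prefix)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in gm.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt}\t{v.ref}\n")
    n = gm.n_samples
    bytes_per_variant = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        for j in range(gm.n_variants):
            col = gm.dosages[:, j]
            codes = np.full(bytes_per_variant * 4, 0b01, dtype=np.uint8)
            for i in range(n):
                d = col[i]
                codes[i] = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[d]
            packed = np.zeros(bytes_per_variant, dtype=np.uint8)
            for shift in range(4):
                packed |= codes[shift::4] << (2 * shift)
            fh.write(packed.tobytes())


def read_gene_loci(path, dialect: str = "tsv") -> list[GeneLocus]:
    """Read gene loci from BED (0-based half-open) or a 4-column 1-based TSV."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            if dialect == "bed":
                chrom, start, end, gene = cols[0], int(cols[1]) + 1, int(cols[2]), cols[3]
            elif dialect == "tsv":
                if cols[0] == "gene":
                    continue
                gene, chrom, start, end = cols[0], cols[1], int(cols[2]), int(cols[3])
            else:
                raise DataError(f"unknown loci dialect {dialect!r}")
            loci.append(GeneLocus(gene, normalize_chrom(chrom), start, end))
    return loci


# ---------------------------------------------------------------------------
# QC


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditional on the observed allele counts, the heterozygote count has a
    known exact distribution under HWE; the p-value sums the probabilities of
    all heterozygote counts no more likely than the observed one.
    Computed in log space, stable for thousands of samples.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise DataError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het) up to a constant: multinomial count weight x 2^het
    logp = (
        hets * np.log(2)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-10)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    control_mask: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Drop variants with MAF below ``maf_min`` or HWE exact p below ``hwe_alpha``.

    HWE is evaluated on controls (``control_mask``) when given, otherwise on
    all samples.  Retained dosage values are untouched.
    """
    keep = []
    hwe_dos = gm.dosages[control_mask] if control_mask is not None else gm.dosages
    for j in range(gm.n_variants):
        col = gm.dosages[:, j]
        obs = col[~np.isnan(col)]
        freq = obs.mean() / 2.0 if obs.size else 0.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            continue
        if hwe_alpha > 0:
            counts = _genotype_counts(hwe_dos[:, j])
            if hwe_exact_p(*counts) < hwe_alpha:
                continue
        keep.append(j)
    if not keep:
        raise DataError("QC removed every variant")
    return gm.subset_variants(keep)


# ---------------------------------------------------------------------------
# SNP-to-gene assignment and system matrices


def assign_snps_to_genes(
    variants: list[VariantRecord],
    loci: list[GeneLocus],
    window_bp: int = 10_000,
) -> dict[str, set[str]]:
    """Map each gene to the SNPs within ``window_bp`` of its body (inclusive).

    A SNP on the same chromosome with start - window <= pos <= end + window is
    assigned; one SNP may map to several genes.  Chromosome labels are
    normalised on both sides.
    """
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {v.chrom for v in variants}:
        vs = sorted(
            ((v.pos, v.id) for v in variants if v.chrom == chrom), key=lambda t: t[0]
        )
        by_chrom[normalize_chrom(chrom)] = (
            np.array([p for p, _ in vs]),
            [i for _, i in vs],
        )
    out: dict[str, set[str]] = {}
    for locus in loci:
        chrom = normalize_chrom(locus.chrom)
        entry = by_chrom.get(chrom)
        snps: set[str] = set()
        if entry is not None:
            pos, ids = entry
            lo = np.searchsorted(pos, locus.start - window_bp, side="left")
            hi = np.searchsorted(pos, locus.end + window_bp, side="right")
            snps = set(ids[lo:hi])
        out[locus.gene] = snps
    return out


def build_system_matrix(
    gm: GenotypeMatrix, snp_ids
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Mean-imputed, column-centred dosage matrix for the given SNPs.

    Columns are ordered genomically; returns (centred matrix, the column
    means that were subtracted, ordered SNP ids).
    """
    index = gm.variant_index()
    ids = [s for s in snp_ids if s in index]
    if not ids:
        raise DataError("system has no SNPs in the genotype matrix")
    ids.sort(key=lambda s: (chrom_sort_key(gm.variants[index[s]].chrom),
                            gm.variants[index[s]].pos, s))
    cols = [index[s] for s in ids]
    X = gm.dosages[:, cols].copy()
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    X -= means
    return X, means, ids


def ld_r2(gm: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of two dosage columns (pairwise complete)."""
    index = gm.variant_index()
    a = gm.dosages[:, index[snp_i]]
    b = gm.dosages[:, index[snp_j]]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn(f"r2({snp_i}, {snp_j}) undefined: zero variance")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
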