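"""PLINK 1 binary genotype I/O and phenotype tables.

Genotypes are held as an N x M ``int8`` matrix of minor-allele (A1) dosage
counts in {0, 1, 2}, with ``-1`` marking a missing call.  The on-disk .bed
codec packs four samples per byte in SNP-major order; the 2-bit codes are

    00 -> homozygous A1 (dosage 2)
    01 -> missing
    10 -> heterozygous  (dosage 1)
    11 -> homozygous A2 (dosage 0)

Phenotype and covariate tables follow the PLINK dialect: whitespace-delimited
with a header line starting ``FID IID``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit code -> A1 dosage, indexed by code value
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam triplet violates the PLINK 1 format."""


@dataclass
class GenotypeData:
    """Raw genotype panel with SNP and sample metadata.

    Parameters
    ----------
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        A1-allele dosage counts; ``-1`` codes a missing call.
    snps : DataFrame with columns chrom, snp, cm, pos, a1, a2
    samples : DataFrame with columns fid, iid (and optionally the rest of
        the .fam fields)
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise ValueError("genotype matrix must be 2-D and non-empty")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or missing (-1)")
        self.genotypes = g
        if len(self.snps) != g.shape[1]:
            raise ValueError("snp table length does not match genotype columns")
        if len(self.samples) != g.shape[0]:
            raise ValueError("sample table length does not match genotype rows")
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP identifiers")
        if self.sample_ids().duplicated().any():
            raise ValueError("duplicate sample identifiers")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def sample_ids(self) -> pd.Series:
        """FID:IID composite identifiers, aligned with genotype rows."""
        s = self.samples
        return (s["fid"].astype(str) + ":" + s["iid"].astype(str)).reset_index(drop=True)

    def take_snps(self, index: np.ndarray) -> "GenotypeData":
        """Sub-panel with the given SNP (column) indices, order preserved."""
        return GenotypeData(
            self.genotypes[:, index],
            self.snps.iloc[np.asarray(index)].reset_index(drop=True),
            self.samples.reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeData":
        """Sub-panel with the given sample (row) indices, order preserved."""
        return GenotypeData(
            self.genotypes[np.asarray(index), :],
            self.snps.reset_index(drop=True),
            self.samples.iloc[np.asarray(index)].reset_index(drop=True),
        )


def _expect_file(path: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)


def read_bim(path: str) -> pd.DataFrame:
    _expect_file(path)
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    return bim


def read_fam(path: str) -> pd.DataFrame:
    _expect_file(path)
    fam = pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                      dtype={"fid": str, "iid": str})
    return fam


def read_plink(bed_path: str, bim_path: str | None = None,
               fam_path: str | None = None) -> GenotypeData:
    """Read a PLINK 1 .bed/.bim/.fam triplet into a :class:`GenotypeData`.

    ``bed_path`` may be given without companions, in which case the .bim and
    .fam paths are derived by swapping the extension.
    """
    if bed_path.endswith(".bed"):
        prefix = bed_path[:-4]
    else:
        prefix = bed_path
        bed_path = prefix + ".bed"
    bim_path = bim_path or prefix + ".bim"
    fam_path = fam_path or prefix + ".fam"

    snps = read_bim(bim_path)
    samples = read_fam(fam_path)
    n, m = len(samples), len(snps)

    _expect_file(bed_path)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise PlinkFormatError(f"{bed_path}: bad magic bytes {header[:2]!r}")
        if header[2:3] != _BED_SNP_MAJOR:
            raise PlinkFormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
        payload = fh.read()

    bytes_per_snp = math.ceil(n / 4)
    expected = bytes_per_snp * m
    if len(payload) != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload has {len(payload)} bytes, expected "
            f"{expected} for {n} samples x {m} SNPs (truncated or corrupt)"
        )

    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack the four 2-bit fields of each byte, low bits first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    geno = _CODE_TO_DOSAGE[codes[:, :n]].T  # -> (n, m)
    return GenotypeData(np.ascontiguousarray(geno), snps, samples)


def write_plink(data: GenotypeData, prefix: str) -> None:
    """Write a panel as .bed/.bim/.fam under the given path prefix."""
    n, m = data.n_samples, data.n_snps
    bytes_per_snp = math.ceil(n / 4)
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # zero pad bits
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage % 4] = code  # -1 % 4 == 3 slots the missing code
    codes[:, :n] = lut[data.genotypes.T % 4]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())
    data.snps[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = data.samples.copy()
    for col, default in (("father", 0), ("mother", 0), ("sex", 0), ("phenotype", -9)):
        if col not in fam.columns:
            fam[col] = default
    fam[FAM_COLUMNS].to_csv(prefix + ".fam", sep="\t", header=False, index=False)


DEFAULT_MISSING_CODES = ("NA", "na", "NaN", "nan", "-9", "")


def read_pheno_table(path_or_buf, missing_codes=DEFAULT_MISSING_CODES) -> pd.DataFrame:
    """Read a PLINK-style ``FID IID value...`` table with a header line.

    Values matching ``missing_codes`` become NaN.  The returned frame is
    indexed by the FID:IID composite identifier.
    """
    df = pd.read_csv(path_or_buf, sep=r"\s+",
                     na_values=list(missing_codes), keep_default_na=False)
    fid, iid = df.columns[:2]
    df.index = df[fid].astype(str) + ":" + df[iid].astype(str)
    df = df.drop(columns=[fid, iid])
    return df.apply(pd.to_numeric, errors="coerce")
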