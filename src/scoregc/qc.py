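"""Marker quality control: missingness, MAF, Hardy-Weinberg, monomorphism.

Filters are applied in a fixed order — missingness, then minor allele
frequency, then the HWE test, then zero variance — and each dropped SNP is
attributed to the first filter it fails, so the report is deterministic.
Defaults follow common biobank practice: drop markers with >1% missing
calls, MAF < 1%, or HWE p < 1e-7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .plink import MISSING, GenotypeData


class EmptyPanelError(ValueError):
    """All SNPs were removed by quality control."""


@dataclass(frozen=True)
class QcReport:
    n_snps_in: int
    n_snps_out: int
    n_dropped_missingness: int
    n_dropped_maf: int
    n_dropped_hwe: int
    n_dropped_monomorphic: int
    max_missing_rate: float
    min_maf: float
    hwe_alpha: float

    def __post_init__(self) -> None:
        dropped = (self.n_dropped_missingness + self.n_dropped_maf
                   + self.n_dropped_hwe + self.n_dropped_monomorphic)
        if self.n_snps_out != self.n_snps_in - dropped:
            raise ValueError("QC counts do not balance")


def hwe_test_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square goodness-of-fit test of HWE.

    Observed genotype counts are compared against the expected counts
    p^2, 2pq, q^2 with the allele frequency estimated from the counts
    themselves.  A monomorphic marker returns p = 1 (the test is vacuous).
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("HWE test undefined for zero total count")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _snp_counts(genotypes: np.ndarray):
    """Per-SNP genotype counts over non-missing calls.

    Returns (n2, n1, n0, n_missing): counts of dosage 2, 1, 0 and missing.
    """
    n2 = (genotypes == 2).sum(axis=0)
    n1 = (genotypes == 1).sum(axis=0)
    n0 = (genotypes == 0).sum(axis=0)
    nm = (genotypes == MISSING).sum(axis=0)
    return n2, n1, n0, nm


def hwe_test_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Vectorised per-SNP HWE chi-square p values (monomorphic -> 1)."""
    n2, n1, n0, _ = _snp_counts(genotypes)
    n = (n2 + n1 + n0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    poly = (n > 0) & (p > 0) & (q > 0)
    pvals = np.ones(genotypes.shape[1])
    e2 = n[poly] * p[poly] ** 2
    e1 = n[poly] * 2 * p[poly] * q[poly]
    e0 = n[poly] * q[poly] ** 2
    chi2 = ((n2[poly] - e2) ** 2 / e2 + (n1[poly] - e1) ** 2 / e1
            + (n0[poly] - e0) ** 2 / e0)
    pvals[poly] = stats.chi2.sf(chi2, df=1)
    return pvals


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP frequency of the counted (A1) allele over non-missing calls."""
    n2, n1, n0, _ = _snp_counts(genotypes)
    n = (n2 + n1 + n0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, (2 * n2 + n1) / (2 * n), np.nan)


def apply_qc(data: GenotypeData, max_missing_rate: float = 0.01,
             min_maf: float = 0.01, hwe_alpha: float = 1e-7,
             exclude_regions=None) -> tuple[GenotypeData, QcReport]:
    """Filter SNPs and return the surviving panel plus an attribution report.

    ``exclude_regions`` optionally removes markers inside half-open
    (chrom, start, end) intervals (BED-style) before the statistical filters;
    such markers are not counted against any filter in the report.
    """
    if not (0 <= max_missing_rate < 1):
        raise ValueError("max_missing_rate must lie in [0, 1)")
    if not (0 <= min_maf < 0.5):
        raise ValueError("min_maf must lie in [0, 0.5)")

    if exclude_regions:
        keep_region = np.ones(data.n_snps, dtype=bool)
        chrom = data.snps["chrom"].astype(str).to_numpy()
        pos = data.snps["pos"].to_numpy()
        for c, start, end in exclude_regions:
            keep_region &= ~((chrom == str(c)) & (pos >= start) & (pos < end))
        data = data.take_snps(np.flatnonzero(keep_region))

    g = data.genotypes
    n2, n1, n0, nm = _snp_counts(g)
    n_called = n2 + n1 + n0
    miss_rate = nm / g.shape[0]
    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = hwe_test_pvalues(g)
    # variance over non-missing calls is zero iff all calls identical
    monomorphic = (n2 == n_called) | (n1 == n_called) | (n0 == n_called) | (n_called == 0)

    fail_miss = miss_rate > max_missing_rate
    fail_maf = ~fail_miss & (np.isnan(maf) | (maf < min_maf))
    fail_hwe = ~fail_miss & ~fail_maf & (hwe_p < hwe_alpha)
    fail_mono = ~fail_miss & ~fail_maf & ~fail_hwe & monomorphic

    keep = ~(fail_miss | fail_maf | fail_hwe | fail_mono)
    report = QcReport(
        n_snps_in=g.shape[1],
        n_snps_out=int(keep.sum()),
        n_dropped_missingness=int(fail_miss.sum()),
        n_dropped_maf=int(fail_maf.sum()),
        n_dropped_hwe=int(fail_hwe.sum()),
        n_dropped_monomorphic=int(fail_mono.sum()),
        max_missing_rate=max_missing_rate,
        min_maf=min_maf,
        hwe_alpha=hwe_alpha,
    )
    if report.n_snps_out == 0:
        raise EmptyPanelError("quality control removed every SNP")
    return data.take_snps(np.flatnonzero(keep)), report
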