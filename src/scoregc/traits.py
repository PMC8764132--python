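"""Phenotype pairs, the sample-overlap map, and covariate adjustment.

A :class:`TraitPair` holds the two phenotype vectors and the partial
permutation linking individuals measured on both traits.  Phenotypes enter
the moment equations only after residualization on covariates (plus an
intercept) and standardization to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .plink import GenotypeData


class EmptyCohortError(ValueError):
    """No usable samples remain for a trait."""


class CollinearityError(ValueError):
    """Covariate design is rank deficient."""


@dataclass
class TraitPair:
    """Two phenotype vectors plus the overlap map between their cohorts.

    ``overlap`` is an array of shape (n_overlap, 2): row (i, j) states that
    sample i of trait 1 and sample j of trait 2 are the same individual.
    ``sample_indices1``/``sample_indices2`` give each cohort's rows in the
    genotype panel it was built from.
    """

    y1: np.ndarray
    y2: np.ndarray
    overlap: np.ndarray
    covariates1: np.ndarray | None = None
    covariates2: np.ndarray | None = None
    sample_indices1: np.ndarray | None = None
    sample_indices2: np.ndarray | None = None
    ids1: pd.Series | None = None
    ids2: pd.Series | None = None

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=float).ravel()
        self.y2 = np.asarray(self.y2, dtype=float).ravel()
        if np.isnan(self.y1).any() or np.isnan(self.y2).any():
            raise ValueError("phenotypes must not contain missing values")
        ov = np.asarray(self.overlap, dtype=np.intp).reshape(-1, 2)
        if ov.shape[0]:
            if len(np.unique(ov[:, 0])) != ov.shape[0] or len(np.unique(ov[:, 1])) != ov.shape[0]:
                raise ValueError("overlap must be a partial permutation "
                                 "(each sample appears in at most one pair)")
            if ov[:, 0].max() >= self.n1 or ov[:, 1].max() >= self.n2:
                raise ValueError("overlap index out of range")
        self.overlap = ov

    @property
    def n1(self) -> int:
        return self.y1.size

    @property
    def n2(self) -> int:
        return self.y2.size

    @property
    def n_overlap(self) -> int:
        return self.overlap.shape[0]

    @property
    def complete_overlap(self) -> bool:
        """True when both cohorts are the same individuals (C is a bijection)."""
        return self.n_overlap == self.n1 == self.n2


def residualize(y: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """Least-squares residual of y on [1, W], centered and scaled to unit variance.

    With no covariates this reduces to centering and scaling.  Raises
    :class:`CollinearityError` when the design (including the intercept) is
    rank deficient, naming the dependent columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if covariates is None or np.size(covariates) == 0:
        resid = y - y.mean()
    else:
        w = np.asarray(covariates, dtype=float)
        if w.ndim == 1:
            w = w[:, None]
        if w.shape[0] != n:
            raise ValueError("covariate rows must align with the phenotype")
        design = np.column_stack([np.ones(n), w])
        q, r, piv = linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < design.shape[1]:
            bad = sorted(piv[rank:])
            names = ["intercept" if j == 0 else f"covariate {j - 1}" for j in bad]
            raise CollinearityError(
                "rank-deficient covariate design; dependent columns: " + ", ".join(names))
        beta = linalg.solve_triangular(r, q.T @ y)
        resid = y - design[:, piv] @ beta
    sd = resid.std()
    if sd == 0:
        raise ValueError("phenotype has zero residual variance")
    return resid / sd


def build_trait_pair(pheno_table: pd.DataFrame, covar_table: pd.DataFrame | None,
                     data1: GenotypeData, data2: GenotypeData,
                     trait1_name: str, trait2_name: str) -> TraitPair:
    """Assemble a :class:`TraitPair` by identifier intersection.

    Each trait's cohort is the set of panel samples with a non-missing
    phenotype (and complete covariates, when a covariate table is given);
    overlap pairs are computed by FID:IID intersection.
    """
    for name in (trait1_name, trait2_name):
        if name not in pheno_table.columns:
            raise KeyError(f"trait {name!r} not found in phenotype table")

    def cohort(data: GenotypeData, trait: str):
        ids = data.sample_ids()
        pheno = pheno_table[trait].reindex(ids.to_numpy())
        ok = pheno.notna().to_numpy()
        cov = None
        if covar_table is not None and covar_table.shape[1] > 0:
            cov_aligned = covar_table.reindex(ids.to_numpy())
            ok &= cov_aligned.notna().all(axis=1).to_numpy()
            cov = cov_aligned.to_numpy(dtype=float)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            raise EmptyCohortError(f"no usable samples for trait {trait!r}")
        return (pheno.to_numpy(dtype=float)[idx],
                None if cov is None else cov[idx],
                idx, ids.iloc[idx].reset_index(drop=True))

    y1, cov1, idx1, ids1 = cohort(data1, trait1_name)
    y2, cov2, idx2, ids2 = cohort(data2, trait2_name)

    pos2 = {sid: j for j, sid in enumerate(ids2)}
    overlap = [(i, pos2[sid]) for i, sid in enumerate(ids1) if sid in pos2]
    return TraitPair(
        y1=y1, y2=y2,
        overlap=np.array(overlap, dtype=np.intp).reshape(-1, 2),
        covariates1=cov1, covariates2=cov2,
        sample_indices1=idx1, sample_indices2=idx2,
        ids1=ids1, ids2=ids2,
    )
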