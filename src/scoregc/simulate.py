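"""Synthetic genotypes and trait pairs under polygenic architectures.

Genotypes are drawn per SNP as binomial(2, f) with allele frequency f
uniform on a configurable interval — i.e. linkage equilibrium.  Trait pairs
follow the generative model y_t = X_t beta_t + eps_t with per-SNP effects
drawn from a four-component causal-status mixture:

    c_m in {[1,1], [1,0], [0,1], [0,0]} with architecture-specific
    probabilities; effects at causal SNPs are (bivariate) normal with
    per-causal-SNP variance h_t^2 / (q_t M), q_t the per-trait causal
    probability, so the expected total genetic variance is exactly h_t^2.

The correlation of effect sizes at shared-causal SNPs equals the rho
parameter; the realized genome-wide genetic correlation of each replicate is
recorded from the drawn effect vectors and is the reference for bias
assessment.  Environmental noise has variance 1 - h_t^2 (unit total trait
variance in expectation) and is correlated only across overlapping
individuals.  An optional prevalence dichotomizes trait 2 by thresholding
the continuous liability at its empirical upper quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plink import GenotypeData
from .traits import TraitPair
from .operator import StandardizedOperator

ARCHITECTURES = {
    # P(c = [1,1]), P([1,0]), P([0,1]), P([0,0])
    "infinitesimal": (1.0, 0.0, 0.0, 0.0),
    "medium_polygenic": (0.1, 0.2, 0.2, 0.5),
    "low_polygenic": (0.01, 0.05, 0.05, 0.89),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Generative parameters for one simulated trait pair."""

    h1_sq: float
    h2_sq: float
    rho_param: float = 0.0
    architecture: str = "infinitesimal"
    env_corr: float = 0.0
    prevalence: float | None = None
    overlap_fraction: float = 1.0
    seed: int | None = None
    causal_probs: tuple[float, float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.causal_probs is None:
            if self.architecture not in ARCHITECTURES:
                raise ValueError(f"unknown architecture {self.architecture!r}")
            object.__setattr__(self, "causal_probs", ARCHITECTURES[self.architecture])
        elif self.architecture in ARCHITECTURES and \
                not np.allclose(self.causal_probs, ARCHITECTURES[self.architecture]):
            raise ValueError(
                f"causal_probs conflict with the {self.architecture!r} preset; "
                "use architecture='custom' for bespoke mixtures")
        probs = np.asarray(self.causal_probs, dtype=float)
        if probs.size != 4 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("causal_probs must be 4 non-negative values summing to 1")
        for h, name in ((self.h1_sq, "h1_sq"), (self.h2_sq, "h2_sq")):
            if not (0.0 <= h < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (-1.0 <= self.rho_param <= 1.0):
            raise ValueError("rho_param must lie in [-1, 1]")
        if not (-1.0 <= self.env_corr <= 1.0):
            raise ValueError("env_corr must lie in [-1, 1]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def causal_prob_trait1(self) -> float:
        return self.causal_probs[0] + self.causal_probs[1]

    @property
    def causal_prob_trait2(self) -> float:
        return self.causal_probs[0] + self.causal_probs[2]


@dataclass
class EffectSizes:
    """Drawn per-SNP effects and their causal-status labels.

    ``causal_status`` holds codes 0..3 for [1,1], [1,0], [0,1], [0,0].
    """

    beta1: np.ndarray
    beta2: np.ndarray
    causal_status: np.ndarray

    def realized_rho_g(self) -> float:
        """Genome-wide genetic correlation of the drawn effect vectors."""
        s11 = float(self.beta1 @ self.beta1)
        s22 = float(self.beta2 @ self.beta2)
        if s11 == 0.0 or s22 == 0.0:
            return float("nan")
        return float(self.beta1 @ self.beta2) / np.sqrt(s11 * s22)


def simulate_genotypes(n: int, m: int, maf_low: float = 0.05,
                       maf_high: float = 0.5,
                       seed: int | np.random.Generator | None = None) -> GenotypeData:
    """Linkage-equilibrium binomial(2, f) genotype panel, f ~ U[maf_low, maf_high]."""
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=m)
    geno = np.empty((n, m), dtype=np.int8)
    for j0 in range(0, m, 1000):  # chunked to avoid a large int64 temporary
        j1 = min(j0 + 1000, m)
        geno[:, j0:j1] = rng.binomial(2, freqs[j0:j1], size=(n, j1 - j0)).astype(np.int8)
    snps = pd.DataFrame({
        "chrom": "1", "snp": [f"snp{j}" for j in range(m)], "cm": 0.0,
        "pos": np.arange(1, m + 1), "a1": "A", "a2": "G",
    })
    samples = pd.DataFrame({"fid": [f"ind{i}" for i in range(n)],
                            "iid": [f"ind{i}" for i in range(n)]})
    return GenotypeData(geno, snps, samples)


def draw_effect_sizes(spec: ArchitectureSpec, m: int,
                      rng: np.random.Generator) -> EffectSizes:
    """Draw per-SNP effect pairs from the causal-status mixture."""
    status = rng.choice(4, size=m, p=spec.causal_probs)
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    q1, q2 = spec.causal_prob_trait1, spec.causal_prob_trait2
    v1 = spec.h1_sq / (q1 * m) if q1 > 0 else 0.0
    v2 = spec.h2_sq / (q2 * m) if q2 > 0 else 0.0

    shared = status == 0
    n_shared = int(shared.sum())
    if n_shared:
        if v1 > 0 and v2 > 0:
            cov = spec.rho_param * np.sqrt(v1 * v2)
            z1 = rng.standard_normal(n_shared)
            z2 = rng.standard_normal(n_shared)
            beta1[shared] = np.sqrt(v1) * z1
            beta2[shared] = (cov / np.sqrt(v1)) * z1 + \
                np.sqrt(max(v2 - cov * cov / v1, 0.0)) * z2
        else:
            if v1 > 0:
                beta1[shared] = rng.standard_normal(n_shared) * np.sqrt(v1)
            if v2 > 0:
                beta2[shared] = rng.standard_normal(n_shared) * np.sqrt(v2)
    only1 = status == 1
    if only1.any() and v1 > 0:
        beta1[only1] = rng.standard_normal(int(only1.sum())) * np.sqrt(v1)
    only2 = status == 2
    if only2.any() and v2 > 0:
        beta2[only2] = rng.standard_normal(int(only2.sum())) * np.sqrt(v2)
    return EffectSizes(beta1, beta2, status.astype(np.int8))


def default_cohort_size(n_total: int, overlap_fraction: float) -> int:
    """Largest per-trait cohort size n with 2n - round(overlap_fraction n) <= total."""
    n = int(n_total / (2.0 - overlap_fraction)) + 1
    while 2 * n - int(round(overlap_fraction * n)) > n_total:
        n -= 1
    if n < 1:
        raise ValueError("panel too small for any cohort")
    return n


def simulate_trait_pair(genotypes: GenotypeData, spec: ArchitectureSpec,
                        n_per_cohort: int | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[TraitPair, dict]:
    """Generate one trait pair on the panel; returns (pair, ground_truth).

    The first floor(overlap_fraction * n) panel individuals belong to both
    cohorts; the remainders are disjoint.  The ground-truth record carries
    the drawn effects' realized genome-wide genetic correlation and the
    generative parameters.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_total, m = genotypes.n_samples, genotypes.n_snps
    n = n_per_cohort if n_per_cohort is not None else \
        default_cohort_size(n_total, spec.overlap_fraction)
    n_ov = int(np.floor(spec.overlap_fraction * n))
    if 2 * n - n_ov > n_total:
        raise ValueError(
            f"panel of {n_total} samples cannot host two cohorts of {n} "
            f"with {n_ov} shared")

    effects = draw_effect_sizes(spec, m, rng)
    op = StandardizedOperator(genotypes)
    g1_all = op.matvec(effects.beta1)
    g2_all = op.matvec(effects.beta2)

    idx1 = np.arange(n)
    idx2 = np.concatenate([np.arange(n_ov), np.arange(n, 2 * n - n_ov)])

    se1 = 1.0 - spec.h1_sq
    se2 = 1.0 - spec.h2_sq
    cov_e = spec.env_corr * np.sqrt(se1 * se2)
    eps1 = np.sqrt(se1) * rng.standard_normal(n)
    eps2 = np.sqrt(se2) * rng.standard_normal(n)
    if n_ov and cov_e != 0.0:
        # re-draw the overlap part of eps2 correlated with eps1
        u = rng.standard_normal(n_ov)
        eps2[:n_ov] = (cov_e / np.sqrt(se1)) * eps1[:n_ov] + \
            np.sqrt(max(se2 - cov_e * cov_e / se1, 0.0)) * u

    y1 = g1_all[idx1] + eps1
    y2 = g2_all[idx2] + eps2

    case_count = None
    if spec.prevalence is not None:
        k = int(round(spec.prevalence * n))
        if k < 1:
            raise ValueError("prevalence too low: zero cases in this cohort")
        liability = y2
        order = np.argsort(liability)[::-1]
        y2 = np.zeros(n)
        y2[order[:k]] = 1.0
        case_count = k

    pair = TraitPair(
        y1=y1, y2=y2,
        overlap=np.column_stack([np.arange(n_ov), np.arange(n_ov)]),
        sample_indices1=idx1, sample_indices2=idx2,
        ids1=genotypes.sample_ids().iloc[idx1].reset_index(drop=True),
        ids2=genotypes.sample_ids().iloc[idx2].reset_index(drop=True),
    )
    truth = {
        "spec": spec,
        "beta1": effects.beta1,
        "beta2": effects.beta2,
        "causal_status": effects.causal_status,
        "realized_rho_g": effects.realized_rho_g(),
        "genetic_variance1": float(effects.beta1 @ effects.beta1),
        "genetic_variance2": float(effects.beta2 @ effects.beta2),
        "n_per_cohort": n,
        "n_overlap": n_ov,
        "case_count": case_count,
    }
    return pair, truth


def export_simulation(genotypes: GenotypeData, pair: TraitPair, prefix: str,
                      trait_names: tuple[str, str] = ("trait1", "trait2")) -> None:
    """Write the panel as PLINK .bed/.bim/.fam plus a phenotype table.

    Samples outside a trait's cohort get NA for that trait, so reading the
    files back reconstructs the cohorts and their overlap by identifier
    intersection.
    """
    from .plink import write_plink  # local import to avoid cycle at module load

    write_plink(genotypes, prefix)
    n_total = genotypes.n_samples
    col1 = np.full(n_total, np.nan)
    col2 = np.full(n_total, np.nan)
    col1[pair.sample_indices1] = pair.y1
    col2[pair.sample_indices2] = pair.y2
    table = pd.DataFrame({
        "FID": genotypes.samples["fid"], "IID": genotypes.samples["iid"],
        trait_names[0]: col1, trait_names[1]: col2,
    })
    table.to_csv(prefix + ".pheno", sep="\t", index=False, na_rep="NA")
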