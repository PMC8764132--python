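"""Model/Results interface tying genotype panels, trait pairs and the
method-of-moments machinery together.

Typical use::

    model = GeneticCorrelation.from_plink("panel", "panel.pheno",
                                          "height", "bmi")
    res = model.fit(b=10, n_blocks=100, seed=1)
    print(res.summary())

``fit`` residualizes both phenotypes on their covariates (plus an
intercept), standardizes them, builds the matrix-free standardized genotype
operators for each cohort, and dispatches to the randomized estimator — or,
when the two cohorts are the identical individuals, to the closed-form
complete-overlap estimator (``method='auto'``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimator import (MomFit, estimate_variance_components, score_estimate,
                        score_overlap_estimate)
from .operator import SketchConfig, StandardizedOperator
from .plink import GenotypeData, read_plink, read_pheno_table
from .qc import QcReport, apply_qc
from .traits import TraitPair, build_trait_pair, residualize

LOW_PREVALENCE_WARNING = 0.005  # binary-trait estimates get noisy below this


def _is_binary(y: np.ndarray) -> bool:
    return set(np.unique(y)).issubset({0.0, 1.0})


class GeneticCorrelation:
    """Bivariate variance-component model for a pair of traits.

    Parameters
    ----------
    data1, data2 : GenotypeData
        QC'd genotype panels for the two cohorts (pass the same object when
        both traits are measured on one panel).  The SNP sets must match.
    pair : TraitPair
        Phenotypes, covariates, cohort row indices and the overlap map.
    scale : {'empirical', 'binomial'}
        Per-SNP standardization scale.
    """

    def __init__(self, data1: GenotypeData, pair: TraitPair,
                 data2: GenotypeData | None = None,
                 scale: str = "empirical", block_size: int = 1000):
        self.data1 = data1
        self.data2 = data1 if data2 is None else data2
        if list(self.data1.snps["snp"]) != list(self.data2.snps["snp"]):
            raise ValueError("the two panels must share an identical SNP set")
        self.pair = pair
        self.scale = scale
        self.block_size = block_size
        self.qc_reports: tuple[QcReport, ...] = ()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_plink(cls, bfile: str, pheno: str, trait1: str, trait2: str,
                   covar: str | None = None, bfile2: str | None = None,
                   qc: bool = True, max_missing_rate: float = 0.01,
                   min_maf: float = 0.01, hwe_alpha: float = 1e-7,
                   exclude_regions=None, scale: str = "empirical") -> "GeneticCorrelation":
        """Build the model from PLINK binary files and phenotype tables.

        When the two cohorts live on different panels (``bfile2``), SNPs are
        filtered jointly: a marker must survive QC in both panels to be
        retained, so the model's M is common.
        """
        data1 = read_plink(bfile)
        data2 = read_plink(bfile2) if bfile2 else data1
        reports: list[QcReport] = []
        if qc:
            kw = dict(max_missing_rate=max_missing_rate, min_maf=min_maf,
                      hwe_alpha=hwe_alpha, exclude_regions=exclude_regions)
            data1, rep1 = apply_qc(data1, **kw)
            reports.append(rep1)
            if bfile2:
                data2, rep2 = apply_qc(data2, **kw)
                reports.append(rep2)
                common = set(data1.snps["snp"]) & set(data2.snps["snp"])
                keep1 = np.flatnonzero(data1.snps["snp"].isin(common))
                data1 = data1.take_snps(keep1)
                order = {s: k for k, s in enumerate(data1.snps["snp"])}
                idx2 = np.flatnonzero(data2.snps["snp"].isin(common).to_numpy())
                keys = data2.snps["snp"].iloc[idx2].map(order).to_numpy()
                data2 = data2.take_snps(idx2[np.argsort(keys)])
            else:
                data2 = data1
        pheno_table = read_pheno_table(pheno)
        covar_table = read_pheno_table(covar) if covar else None
        pair = build_trait_pair(pheno_table, covar_table, data1, data2,
                                trait1, trait2)
        model = cls(data1, pair, data2 if bfile2 else None, scale=scale)
        model.qc_reports = tuple(reports)
        return model

    @classmethod
    def from_simulation(cls, genotypes: GenotypeData, pair: TraitPair,
                        scale: str = "empirical") -> "GeneticCorrelation":
        """Wrap a simulated panel + trait pair (no QC: panels are clean)."""
        return cls(genotypes, pair, scale=scale)

    # ------------------------------------------------------------------ #
    def _operators(self) -> tuple[StandardizedOperator, StandardizedOperator]:
        op1 = StandardizedOperator(self.data1, rows=self.pair.sample_indices1,
                                   scale=self.scale, block_size=self.block_size)
        if self.data2 is self.data1 and self._same_cohorts():
            return op1, op1
        op2 = StandardizedOperator(self.data2, rows=self.pair.sample_indices2,
                                   scale=self.scale, block_size=self.block_size)
        return op1, op2

    def _same_cohorts(self) -> bool:
        """True when the two cohorts are the identical panel rows, aligned."""
        p = self.pair
        if not p.complete_overlap or self.data1 is not self.data2:
            return False
        i1 = np.arange(p.n1) if p.sample_indices1 is None else p.sample_indices1
        i2 = np.arange(p.n2) if p.sample_indices2 is None else p.sample_indices2
        return bool(np.array_equal(i1[p.overlap[:, 0]], i2[p.overlap[:, 1]]))

    def _residualized(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        notes = []
        for label, y in (("trait 1", self.pair.y1), ("trait 2", self.pair.y2)):
            if _is_binary(y):
                prev = min(y.mean(), 1 - y.mean())
                if prev < LOW_PREVALENCE_WARNING:
                    notes.append(f"{label}: prevalence {prev:.4f} below "
                                 f"{LOW_PREVALENCE_WARNING:.3f}; estimates may be noisy")
        y1 = residualize(self.pair.y1, self.pair.covariates1)
        y2 = residualize(self.pair.y2, self.pair.covariates2)
        return y1, y2, notes

    def fit(self, method: str = "auto", b: int = 10, n_blocks: int = 100,
            seed: int = 0, distribution: str = "gaussian",
            exact: bool = False) -> "GeneticCorrelationResults":
        """Estimate the variance components and the genetic correlation.

        method : {'auto', 'score', 'score-overlap'}
            'auto' selects the closed-form complete-overlap estimator when
            the two cohorts are the same individuals, else the randomized
            estimator with B sketch vectors.
        """
        if method not in ("auto", "score", "score-overlap"):
            raise ValueError(f"unknown method {method!r}")
        y1, y2, notes = self._residualized()
        same = self._same_cohorts()
        if method == "score-overlap" and not same:
            raise ValueError("score-overlap requires the two traits to be "
                             "measured on the identical sample set")
        use_overlap = same and method in ("auto", "score-overlap") and not exact

        if use_overlap:
            op1, _ = self._operators()
            # align trait 2 to cohort 1's sample order via the overlap map
            aligned = np.empty_like(y2)
            aligned[self.pair.overlap[:, 0]] = y2[self.pair.overlap[:, 1]]
            fit = score_overlap_estimate(op1, y1, aligned, n_blocks=n_blocks)
            # complete the picture with the sketched per-trait components
            cfg = SketchConfig(b=b, seed=seed, distribution=distribution)
            sg1, se1 = estimate_variance_components(op1, y1, cfg)
            cfg2 = SketchConfig(b=b, seed=seed + 1, distribution=distribution)
            sg2, se2 = estimate_variance_components(op1, aligned, cfg2)
            fit.sigma_g1_sq, fit.sigma_e1_sq = sg1, se1
            fit.sigma_g2_sq, fit.sigma_e2_sq = sg2, se2
            fit.b_used, fit.seed = b, seed
        else:
            op1, op2 = self._operators()
            cfg = SketchConfig(b=b, seed=seed, distribution=distribution)
            resid_pair = TraitPair(y1=y1, y2=y2, overlap=self.pair.overlap)
            fit = score_estimate(op1, op2, resid_pair, cfg,
                                 n_blocks=n_blocks, exact=exact)
        fit.notes = fit.notes + tuple(notes)
        return GeneticCorrelationResults(self, fit)


class GeneticCorrelationResults:
    """Estimates, uncertainty and diagnostics from a fitted model."""

    def __init__(self, model: GeneticCorrelation, fit: MomFit):
        self.model = model
        self.fit = fit

    # convenient accessors ------------------------------------------------
    @property
    def rho_g(self) -> float:
        return self.fit.rho_g

    @property
    def se(self) -> float:
        return self.fit.se_rho

    @property
    def pvalue(self) -> float:
        return self.fit.p_value

    @property
    def params(self) -> pd.Series:
        f = self.fit
        return pd.Series({
            "gamma_g": f.gamma_g, "gamma_e": f.gamma_e,
            "sigma_g1_sq": f.sigma_g1_sq, "sigma_e1_sq": f.sigma_e1_sq,
            "sigma_g2_sq": f.sigma_g2_sq, "sigma_e2_sq": f.sigma_e2_sq,
            "rho_g": f.rho_g,
        })

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for rho_g."""
        from scipy import stats
        z = stats.norm.ppf(1 - alpha / 2)
        return self.rho_g - z * self.se, self.rho_g + z * self.se

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Genetic correlation (randomized method of moments)",
            "=" * 58,
            f"method: {f.method:<22} sketch vectors B: {f.b_used}",
            f"SNPs (M): {f.m:<19} jackknife blocks: {f.n_blocks}",
            f"N1: {f.n1:<25} N2: {f.n2}",
            f"overlapping samples: {f.n_overlap}",
            "-" * 58,
            f"rho_g     {f.rho_g: .4f}   SE {f.se_rho:.4f}   p {f.p_value:.3g}",
            f"gamma_g   {f.gamma_g: .4f}   gamma_e {f.gamma_e: .4f}",
            f"trait 1:  sigma_g^2 {f.sigma_g1_sq: .4f}   sigma_e^2 {f.sigma_e1_sq: .4f}",
            f"trait 2:  sigma_g^2 {f.sigma_g2_sq: .4f}   sigma_e^2 {f.sigma_e2_sq: .4f}",
        ]
        if not f.rho_defined:
            lines.append("WARNING: rho_g undefined (non-positive genetic variance)")
        for note in f.notes:
            lines.append(f"note: {note}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<GeneticCorrelationResults rho_g={self.rho_g:.4f} "
                f"se={self.se:.4f} p={self.pvalue:.3g}>")
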