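"""Shared fixtures: random panels, trait pairs, and independent oracles.

The dense helpers here deliberately re-derive standardization and the
moment equations from their definitions (explicit matrices, generic linear
solves) so that operator/estimator tests check two independent routes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scoregc.plink import MISSING, GenotypeData
from scoregc.traits import TraitPair

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_panel(rng: np.random.Generator, n: int, m: int,
               maf_low: float = 0.1, maf_high: float = 0.5,
               missing_rate: float = 0.0) -> GenotypeData:
    """Small random panel; rejects zero-variance columns by redrawing."""
    freqs = rng.uniform(maf_low, maf_high, size=m)
    geno = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        geno[mask] = MISSING
    for j in range(m):  # ensure every SNP is polymorphic with >=2 calls
        while True:
            called = geno[:, j][geno[:, j] != MISSING]
            if called.size >= 2 and np.unique(called).size > 1:
                break
            geno[:, j] = rng.binomial(2, 0.5, size=n).astype(np.int8)
    snps = pd.DataFrame({
        "chrom": "1", "snp": [f"s{j}" for j in range(m)], "cm": 0.0,
        "pos": np.arange(1, m + 1), "a1": "A", "a2": "G"})
    samples = pd.DataFrame({"fid": [f"f{i}" for i in range(n)],
                            "iid": [f"i{i}" for i in range(n)]})
    return GenotypeData(geno, snps, samples)


def dense_standardized(geno: np.ndarray) -> np.ndarray:
    """Independent dense standardization oracle (mean-imputed missing)."""
    g = np.asarray(geno, dtype=float)
    x = np.empty_like(g)
    for j in range(g.shape[1]):
        col = g[:, j]
        obs = col != MISSING
        mu = col[obs].mean()
        sd = col[obs].std()
        x[:, j] = np.where(obs, (col - mu) / sd, 0.0)
    return x


def overlap_map(n1: int, n2: int, n_shared: int) -> np.ndarray:
    """First n_shared samples of each cohort are the same individuals."""
    return np.column_stack([np.arange(n_shared), np.arange(n_shared)])


def random_pair(rng: np.random.Generator, n1: int, n2: int,
                n_shared: int) -> TraitPair:
    """Standardized random phenotypes with the given overlap structure."""
    y1 = rng.standard_normal(n1)
    y2 = rng.standard_normal(n2)
    y1 = (y1 - y1.mean()) / y1.std()
    y2 = (y2 - y2.mean()) / y2.std()
    return TraitPair(y1=y1, y2=y2, overlap=overlap_map(n1, n2, n_shared))


def dense_mom_oracle(x1: np.ndarray, x2: np.ndarray, pair: TraitPair) -> dict:
    """Closed-form MoM solution from fully materialized matrices.

    Builds K_A, C, K_1, K_2 explicitly, forms the normal equations, and
    solves them with a generic linear solver — independent of the streaming
    implementation.
    """
    m = x1.shape[1]
    n1, n2 = x1.shape[0], x2.shape[0]
    y1, y2 = pair.y1, pair.y2
    c = np.zeros((n1, n2))
    for i, j in pair.overlap:
        c[i, j] = 1.0
    ka = x1 @ x2.T / m
    trace_cross = np.trace(ka @ ka.T)
    kc = x1 @ x2.T @ c.T / m
    trace_kc = np.trace(kc)
    n_ov = pair.n_overlap
    if n_ov == 0:
        gamma_g = (y1 @ ka @ y2) / trace_cross
        gamma_e = np.nan
    else:
        lhs = np.array([[trace_cross, trace_kc], [trace_kc, n_ov]])
        rhs = np.array([y1 @ ka @ y2, y1 @ c @ y2])
        gamma_g, gamma_e = np.linalg.solve(lhs, rhs)
    comps = {}
    for t, (x, y) in enumerate([(x1, y1), (x2, y2)], start=1):
        k = x @ x.T / m
        lhs = np.array([[np.trace(k @ k), np.trace(k)],
                        [np.trace(k), x.shape[0]]])
        rhs = np.array([y @ k @ y, y @ y])
        sg, se = np.linalg.solve(lhs, rhs)
        comps[f"sigma_g{t}_sq"] = sg
        comps[f"sigma_e{t}_sq"] = se
    sg1, sg2 = comps["sigma_g1_sq"], comps["sigma_g2_sq"]
    rho = gamma_g / np.sqrt(sg1 * sg2) if sg1 > 0 and sg2 > 0 else np.nan
    return dict(gamma_g=gamma_g, gamma_e=gamma_e, rho_g=rho,
                trace_cross=trace_cross, trace_kc=trace_kc, **comps)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
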