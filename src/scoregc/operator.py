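"""Implicit standardized-genotype linear maps and trace statistics.

The model works with column-standardized genotype matrices X (each SNP
centered and scaled over its cohort; missing calls mean-imputed, i.e.
standardized to 0) but X is never materialized beyond streaming SNP blocks.
Cross-trait traces of the form tr(K_A K_A^T), with K_A = X1 X2^T / M, are
estimated by the Hutchinson sketch

    L_B = (1/B) (1/M^2) sum_b || X1 X2^T z_b ||^2,

an unbiased randomized estimate for any sketch distribution with zero mean
and identity covariance; exact (dense Gram) routes are provided as oracles
for small panels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .plink import MISSING, GenotypeData


@dataclass(frozen=True)
class SketchConfig:
    """Randomized trace-estimator settings: B sketch vectors, seeded."""

    b: int = 10
    seed: int = 0
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("number of sketch vectors must be >= 1")
        if self.distribution not in ("gaussian", "rademacher"):
            raise ValueError("distribution must be 'gaussian' or 'rademacher'")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """An n x B sketch matrix with zero-mean, identity-covariance columns."""
        if self.distribution == "gaussian":
            return rng.standard_normal((n, self.b))
        return rng.choice([-1.0, 1.0], size=(n, self.b))


def snp_moments(data: GenotypeData, scale: str = "empirical",
                rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP means and scales over non-missing dosages.

    ``scale='empirical'`` uses the standard deviation with the 1/N divisor;
    ``scale='binomial'`` uses sqrt(2 p (1-p)) with p the sample allele
    frequency.  Raises on zero-variance SNPs (run QC first).
    """
    g = data.genotypes if rows is None else data.genotypes[rows]
    obs = g != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    if (n_obs == 0).any():
        raise ValueError("SNP with no observed calls")
    gf = np.where(obs, g, 0).astype(float)
    mu = gf.sum(axis=0) / n_obs
    if scale == "empirical":
        sq = (gf * gf).sum(axis=0) / n_obs
        var = np.maximum(sq - mu * mu, 0.0)
        s = np.sqrt(var)
    elif scale == "binomial":
        p = mu / 2.0
        s = np.sqrt(2.0 * p * (1.0 - p))
    else:
        raise ValueError("scale must be 'empirical' or 'binomial'")
    if (s <= 0).any():
        raise ValueError("zero-variance SNP encountered; apply QC before standardizing")
    return mu, s


class StandardizedOperator:
    """Matrix-free centered/scaled genotype map for one cohort.

    Represents X = (G - 1 mu^T) diag(1/s) with missing entries standardized
    to 0, exposing matvec / rmatvec / matmat products and streaming access to
    standardized SNP blocks.  ``rows`` selects the cohort's rows of the
    underlying panel; standardization moments are computed over that cohort.
    """

    def __init__(self, data: GenotypeData, rows: np.ndarray | None = None,
                 scale: str = "empirical", block_size: int = 1000):
        self.data = data
        self.rows = None if rows is None else np.asarray(rows, dtype=np.intp)
        self._g = data.genotypes if self.rows is None else \
            np.ascontiguousarray(data.genotypes[self.rows])
        self.mu, self.s = snp_moments(data, scale=scale, rows=self.rows)
        self.block_size = int(block_size)
        self._has_missing = bool((self._g == MISSING).any())

    @property
    def shape(self) -> tuple[int, int]:
        return self._g.shape

    @property
    def n(self) -> int:
        return self._g.shape[0]

    @property
    def m(self) -> int:
        return self._g.shape[1]

    def standardized_block(self, j0: int, j1: int) -> np.ndarray:
        """Dense standardized columns [j0, j1) as float64 (streaming unit)."""
        raw = self._g[:, j0:j1]
        x = raw.astype(np.float64)
        x -= self.mu[j0:j1]
        x *= 1.0 / self.s[j0:j1]
        if self._has_missing:
            x[raw == MISSING] = 0.0
        return x

    def _block_bounds(self, width: int | None = None):
        w = width or self.block_size
        return [(j, min(j + w, self.m)) for j in range(0, self.m, w)]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """X v, streaming over SNP blocks with raw-dosage products."""
        v = np.asarray(v, dtype=float)
        if v.shape[0] != self.m:
            raise ValueError(f"expected length-{self.m} vector, got {v.shape[0]}")
        out = np.zeros((self.n,) + v.shape[1:])
        for j0, j1 in self._block_bounds():
            if self._has_missing:
                out += self.standardized_block(j0, j1) @ v[j0:j1]
            else:
                u = v[j0:j1] / (self.s[j0:j1] if v.ndim == 1 else self.s[j0:j1, None])
                out += self._g[:, j0:j1] @ u
                out -= (self.mu[j0:j1] @ u)
        return out

    def rmatvec(self, w: np.ndarray) -> np.ndarray:
        """X^T w (length M per column of w)."""
        w = np.asarray(w, dtype=float)
        if w.shape[0] != self.n:
            raise ValueError(f"expected length-{self.n} vector, got {w.shape[0]}")
        out = np.empty((self.m,) + w.shape[1:])
        for j0, j1 in self._block_bounds():
            out[j0:j1] = self.standardized_block(j0, j1).T @ w
        return out

    # aliases for matrix arguments; products are identical code paths
    matmat = matvec
    rmatmat = rmatvec

    def dense(self) -> np.ndarray:
        """Fully materialized standardized matrix — small panels / tests only."""
        return self.standardized_block(0, self.m)

    def column_sq_norms(self) -> np.ndarray:
        """Per-SNP squared norms ||x_m||^2 (the diagonal of X^T X)."""
        out = np.empty(self.m)
        for j0, j1 in self._block_bounds():
            xb = self.standardized_block(j0, j1)
            out[j0:j1] = (xb * xb).sum(axis=0)
        return out


def _check_shared_m(op1: StandardizedOperator, op2: StandardizedOperator) -> int:
    if op1.m != op2.m:
        raise ValueError(f"operators must share the SNP set (M={op1.m} vs {op2.m})")
    return op1.m


def exact_trace_cross(op1: StandardizedOperator, op2: StandardizedOperator) -> float:
    """tr(K_A K_A^T) = ||X2^T X1||_F^2 / M^2 through the smaller Gram dimension.

    Deterministic oracle; cost O(N1 N2 M) or O(M^2 N) — small panels only.
    """
    m = _check_shared_m(op1, op2)
    x1, x2 = op1.dense(), op2.dense()
    if op1.n * op2.n <= m * m:
        gram = x1 @ x2.T  # N1 x N2
        total = float((gram * gram).sum())
    else:
        # cyclic identity: tr(X1 X2' X2 X1') = tr((X1'X1)(X2'X2))
        g1 = x1.T @ x1
        g2 = x2.T @ x2
        total = float((g1 * g2).sum())
    return total / (m * m)


def exact_trace_sq(op: StandardizedOperator) -> float:
    """tr(K^2) = ||X^T X||_F^2 / M^2 (dense oracle for one cohort)."""
    return exact_trace_cross(op, op)


def sketch_trace_cross(op1: StandardizedOperator, op2: StandardizedOperator,
                       cfg: SketchConfig) -> float:
    """Hutchinson estimate L_B of tr(K_A K_A^T); deterministic given the seed."""
    m = _check_shared_m(op1, op2)
    rng = np.random.default_rng(cfg.seed)
    z = cfg.draw(rng, op2.n)
    u = op1.matmat(op2.rmatmat(z))
    return float((u * u).sum()) / (cfg.b * m * m)


def jackknife_block_bounds(m: int, n_blocks: int) -> np.ndarray:
    """Bounds of contiguous, near-equal SNP blocks: array of length g+1."""
    if n_blocks < 1:
        raise ValueError("need at least one block")
    if n_blocks > m:
        raise ValueError(f"n_blocks={n_blocks} exceeds the SNP count M={m}")
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _content_key(y: np.ndarray, n: int) -> bytes:
    return hashlib.sha256(np.ascontiguousarray(np.asarray(y, dtype=float)).tobytes()
                          + n.to_bytes(8, "little")).digest()


@dataclass
class PairStatistics:
    """All moment-equation ingredients for a trait pair, with per-SNP-block
    partial sums cached for leave-one-block-out jackknifing.

    Scalar block arrays hold *unnormalized* sums (no 1/M factors): the active
    M changes under leave-one-out, so normalization happens at solve time.
    ``u_cross``, ``v1``, ``v2`` hold each block's additive contribution to the
    sketch images X1 X2^T Z, X1 X1^T Z1 and X2 X2^T Z2.
    """

    m: int
    n1: int
    n2: int
    n_overlap: int
    b: int
    block_bounds: np.ndarray
    block_sizes: np.ndarray
    cross_quad_blocks: np.ndarray   # sum_m a1_m a2_m, a_t = X_t^T y_t
    kc_blocks: np.ndarray           # sum_m sum_pairs x1_im x2_jm
    k1_blocks: np.ndarray           # sum_m ||x_1m||^2
    k2_blocks: np.ndarray
    q1_blocks: np.ndarray           # sum_m a1_m^2
    q2_blocks: np.ndarray
    u_cross: np.ndarray             # (g, n1', B) contributions to X1 X2^T Z
    v1: np.ndarray                  # (g, n1, B) contributions to X1 X1^T Z1
    v2: np.ndarray
    overlap_inner: float            # y1^T C y2
    sqnorm1: float                  # y1^T y1
    sqnorm2: float

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    # --- normalized headline statistics -----------------------------------
    @property
    def trace_cross(self) -> float:
        """L_B estimate of tr(K_A K_A^T)."""
        u = self.u_cross.sum(axis=0)
        return float((u * u).sum()) / (self.b * self.m ** 2)

    @property
    def trace_kc(self) -> float:
        return float(self.kc_blocks.sum()) / self.m

    @property
    def quad_cross(self) -> float:
        """y1^T K_A y2."""
        return float(self.cross_quad_blocks.sum()) / self.m

    def trace_k(self, trait: int) -> float:
        blocks = self.k1_blocks if trait == 1 else self.k2_blocks
        return float(blocks.sum()) / self.m

    def quad_self(self, trait: int) -> float:
        blocks = self.q1_blocks if trait == 1 else self.q2_blocks
        return float(blocks.sum()) / self.m

    def trace_k2(self, trait: int) -> float:
        v = (self.v1 if trait == 1 else self.v2).sum(axis=0)
        return float((v * v).sum()) / (self.b * self.m ** 2)

    def sq_norm(self, trait: int) -> float:
        return self.sqnorm1 if trait == 1 else self.sqnorm2


def pair_statistics(op1: StandardizedOperator, op2: StandardizedOperator,
                    pair, cfg: SketchConfig, n_blocks: int = 100) -> PairStatistics:
    """Compute every moment-equation statistic in one streaming pass.

    Phenotypes in ``pair`` must already be covariate-residualized and
    standardized.  To make the result exactly symmetric under swapping the
    two traits, the sketch is drawn in a canonical orientation fixed by an
    order-independent content hash of the two cohorts.
    """
    m = _check_shared_m(op1, op2)
    bounds = jackknife_block_bounds(m, n_blocks)
    y1 = np.asarray(pair.y1, dtype=float)
    y2 = np.asarray(pair.y2, dtype=float)
    if y1.size != op1.n or y2.size != op2.n:
        raise ValueError("phenotype lengths must match the operators' cohorts")
    overlap = np.asarray(pair.overlap, dtype=np.intp).reshape(-1, 2)

    swapped = _content_key(y2, op2.n) < _content_key(y1, op1.n)
    if swapped:
        op1, op2 = op2, op1
        y1, y2 = y2, y1
        overlap = overlap[:, ::-1]

    # one sketch per cohort side: the cross trace and trait 2 share z_cross,
    # and trait 1 shares it too when both traits sit on the same operator —
    # this coherence makes all moment systems coincide when y2 = +-y1, so
    # self-correlation comes out exactly +-1
    rng = np.random.default_rng(cfg.seed)
    z_cross = cfg.draw(rng, op2.n)
    z1 = z_cross if op1 is op2 else cfg.draw(rng, op1.n)
    z2 = z_cross

    g = len(bounds) - 1
    cross_quad = np.empty(g)
    kc = np.empty(g)
    k1 = np.empty(g)
    k2 = np.empty(g)
    q1 = np.empty(g)
    q2 = np.empty(g)
    u_cross = np.empty((g, op1.n, cfg.b))
    v1 = np.empty((g, op1.n, cfg.b))
    v2 = np.empty((g, op2.n, cfg.b))

    ov_i, ov_j = overlap[:, 0], overlap[:, 1]
    for bi in range(g):
        j0, j1 = bounds[bi], bounds[bi + 1]
        x1b = op1.standardized_block(j0, j1)
        x2b = op2.standardized_block(j0, j1)
        a1 = x1b.T @ y1
        a2 = x2b.T @ y2
        cross_quad[bi] = a1 @ a2
        q1[bi] = a1 @ a1
        q2[bi] = a2 @ a2
        k1[bi] = (x1b * x1b).sum()
        k2[bi] = (x2b * x2b).sum()
        kc[bi] = (x1b[ov_i] * x2b[ov_j]).sum() if len(ov_i) else 0.0
        u_cross[bi] = x1b @ (x2b.T @ z_cross)
        v1[bi] = x1b @ (x1b.T @ z1)
        v2[bi] = x2b @ (x2b.T @ z2)

    overlap_inner = float(y1[ov_i] @ y2[ov_j]) if len(ov_i) else 0.0

    if swapped:  # map per-trait fields back to the caller's trait order
        k1, k2 = k2, k1
        q1, q2 = q2, q1
        v1, v2 = v2, v1
        n1, n2 = op2.n, op1.n
        sq1, sq2 = float(y2 @ y2), float(y1 @ y1)
    else:
        n1, n2 = op1.n, op2.n
        sq1, sq2 = float(y1 @ y1), float(y2 @ y2)

    return PairStatistics(
        m=m, n1=n1, n2=n2, n_overlap=len(ov_i), b=cfg.b,
        block_bounds=bounds, block_sizes=np.diff(bounds).astype(float),
        cross_quad_blocks=cross_quad, kc_blocks=kc,
        k1_blocks=k1, k2_blocks=k2, q1_blocks=q1, q2_blocks=q2,
        u_cross=u_cross, v1=v1, v2=v2,
        overlap_inner=overlap_inner, sqnorm1=sq1, sqnorm2=sq2,
    )
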