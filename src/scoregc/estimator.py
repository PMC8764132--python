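"""Method-of-moments solvers for genetic covariance and correlation.

Matching the empirical second moments of a standardized trait pair to the
bivariate variance-component model leads to small linear systems.  The
cross-trait system,

    [ tr(K_A K_A^T)  tr(K_C) ] [ gamma_g ]   [ y1^T K_A y2 ]
    [ tr(K_C)        N       ] [ gamma_e ] = [ y1^T C  y2  ],

couples the genetic covariance gamma_g with the environmental covariance
gamma_e carried by the N overlapping individuals; each trait's variance
components solve the analogous single-trait system.  The genetic correlation
is the plug-in ratio rho_g = gamma_g / sqrt(sigma_g1^2 sigma_g2^2).  The
scalable estimator replaces tr(K_A K_A^T) by the Hutchinson sketch L_B; when
both traits are measured on identical samples the coefficient determinant
cancels from the ratio, giving a closed form that needs no randomization
(the complete-overlap estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import block_jackknife, jackknife_se, wald_test
from .operator import (SketchConfig, StandardizedOperator, exact_trace_sq,
                       jackknife_block_bounds, pair_statistics)


class ConditioningError(ValueError):
    """A moment system is numerically singular."""


@dataclass
class MomFit:
    """Point estimates, jackknife uncertainty and provenance of one fit.

    ``rho_g`` is reported unclamped; when either genetic variance estimate is
    non-positive the correlation is undefined (``rho_defined`` False,
    ``rho_g`` NaN) rather than silently truncated.
    """

    gamma_g: float
    gamma_e: float
    sigma_g1_sq: float
    sigma_e1_sq: float
    sigma_g2_sq: float
    sigma_e2_sq: float
    rho_g: float
    se_rho: float
    p_value: float
    rho_defined: bool
    method: str
    b_used: int
    seed: int | None
    n_blocks: int
    m: int
    n1: int
    n2: int
    n_overlap: int
    leave_one_out: np.ndarray | None = field(default=None, repr=False)
    notes: tuple[str, ...] = ()


def solve_covariance_system(trace_cross: float, trace_kc: float, n_overlap: float,
                            quad_cross: float, overlap_inner: float,
                            rtol: float = 1e-12) -> tuple[float, float]:
    """Solve the 2x2 cross-trait normal equations for (gamma_g, gamma_e).

    With no overlapping samples the system degenerates: gamma_g reduces to
    quad_cross / trace_cross and gamma_e is structurally unidentifiable
    (returned as NaN).
    """
    if n_overlap == 0:
        if trace_cross == 0:
            raise ConditioningError("zero cross-trace with no overlap")
        return quad_cross / trace_cross, float("nan")
    scale = max(abs(trace_cross), abs(trace_kc), float(n_overlap))
    det = trace_cross * n_overlap - trace_kc * trace_kc
    if scale == 0 or abs(det) < rtol * scale * scale:
        raise ConditioningError(
            f"near-singular cross-trait system (det={det:.3e}, scale={scale:.3e})")
    gamma_g = (n_overlap * quad_cross - trace_kc * overlap_inner) / det
    gamma_e = (trace_cross * overlap_inner - trace_kc * quad_cross) / det
    return gamma_g, gamma_e


def solve_variance_system(trace_k2: float, trace_k: float, n: float,
                          quad: float, sq_norm: float,
                          rtol: float = 1e-12) -> tuple[float, float]:
    """Solve the single-trait system for (sigma_g^2, sigma_e^2)."""
    scale = max(abs(trace_k2), abs(trace_k), float(n))
    det = trace_k2 * n - trace_k * trace_k
    if scale == 0 or abs(det) < rtol * scale * scale:
        raise ConditioningError(
            f"near-singular variance-component system (det={det:.3e})")
    sigma_g = (n * quad - trace_k * sq_norm) / det
    sigma_e = (trace_k2 * sq_norm - trace_k * quad) / det
    return sigma_g, sigma_e


def estimate_variance_components(op: StandardizedOperator, y: np.ndarray,
                                 cfg: SketchConfig = SketchConfig(),
                                 exact: bool = False) -> tuple[float, float]:
    """Randomized single-trait method-of-moments variance components.

    Solves [[tr(K^2)_hat, tr(K)], [tr(K), N]] (sigma_g^2, sigma_e^2)^T =
    (y^T K y, y^T y)^T with tr(K^2) estimated by the single-panel sketch
    (or computed exactly when ``exact`` is set).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != op.n:
        raise ValueError("phenotype length must match the operator's cohort")
    a = op.rmatvec(y)
    quad = float(a @ a) / op.m
    trace_k = float(op.column_sq_norms().sum()) / op.m
    if exact:
        trace_k2 = exact_trace_sq(op)
    else:
        rng = np.random.default_rng(cfg.seed)
        z = cfg.draw(rng, op.n)
        v = op.matmat(op.rmatmat(z))
        trace_k2 = float((v * v).sum()) / (cfg.b * op.m ** 2)
    return solve_variance_system(trace_k2, trace_k, op.n, quad, float(y @ y))


def _components_from_totals(*, m, cross_quad, kc, k1, k2, q1, q2, u, v1, v2,
                            b, n1, n2, n_overlap, overlap_inner,
                            sqnorm1, sqnorm2) -> dict:
    """All component estimates from (possibly leave-one-out) total sums.

    Scalar sums are unnormalized (no 1/M factors); ``m`` is the active SNP
    count, which shrinks under leave-one-block-out.
    """
    trace_cross = float((u * u).sum()) / (b * m * m)
    gamma_g, gamma_e = solve_covariance_system(
        trace_cross, kc / m, n_overlap, cross_quad / m, overlap_inner)
    sg1, se1 = solve_variance_system(
        float((v1 * v1).sum()) / (b * m * m), k1 / m, n1, q1 / m, sqnorm1)
    sg2, se2 = solve_variance_system(
        float((v2 * v2).sum()) / (b * m * m), k2 / m, n2, q2 / m, sqnorm2)
    if sg1 > 0 and sg2 > 0:
        rho = gamma_g / np.sqrt(sg1 * sg2)
    else:
        rho = float("nan")
    return dict(gamma_g=gamma_g, gamma_e=gamma_e, sigma_g1_sq=sg1,
                sigma_e1_sq=se1, sigma_g2_sq=sg2, sigma_e2_sq=se2, rho_g=rho,
                trace_cross=trace_cross)


def score_estimate(op1: StandardizedOperator, op2: StandardizedOperator,
                   pair, cfg: SketchConfig = SketchConfig(),
                   n_blocks: int = 100, exact: bool = False) -> MomFit:
    """Full randomized MoM fit of a trait pair with jackknife inference.

    Phenotypes in ``pair`` must be residualized and standardized.  With
    ``exact=True`` the sketched traces are replaced by their dense-oracle
    values (small panels only) and the jackknife recomputes them per block.
    """
    if exact:
        return _exact_mom_estimate(op1, op2, pair, n_blocks)
    stats = pair_statistics(op1, op2, pair, cfg, n_blocks)
    consts = dict(b=stats.b, n1=stats.n1, n2=stats.n2,
                  n_overlap=stats.n_overlap, overlap_inner=stats.overlap_inner,
                  sqnorm1=stats.sqnorm1, sqnorm2=stats.sqnorm2)
    partials = dict(m=stats.block_sizes,
                    cross_quad=stats.cross_quad_blocks, kc=stats.kc_blocks,
                    k1=stats.k1_blocks, k2=stats.k2_blocks,
                    q1=stats.q1_blocks, q2=stats.q2_blocks,
                    u=stats.u_cross, v1=stats.v1, v2=stats.v2)

    def rho_from(**totals):
        try:
            return _components_from_totals(**totals, **consts)["rho_g"]
        except ConditioningError:
            return float("nan")

    comp = _components_from_totals(
        **{k: v.sum(axis=0) for k, v in partials.items()}, **consts)
    jk = block_jackknife(partials, rho_from)
    notes = []
    rho_defined = np.isfinite(comp["rho_g"])
    if not rho_defined:
        notes.append("rho undefined: non-positive genetic variance estimate")
    if stats.n_overlap == 0:
        notes.append("no sample overlap: gamma_e unidentifiable")
    return MomFit(
        gamma_g=comp["gamma_g"], gamma_e=comp["gamma_e"],
        sigma_g1_sq=comp["sigma_g1_sq"], sigma_e1_sq=comp["sigma_e1_sq"],
        sigma_g2_sq=comp["sigma_g2_sq"], sigma_e2_sq=comp["sigma_e2_sq"],
        rho_g=comp["rho_g"], se_rho=jk.se,
        p_value=wald_test(comp["rho_g"], jk.se), rho_defined=bool(rho_defined),
        method="score", b_used=cfg.b, seed=cfg.seed, n_blocks=jk.n_blocks,
        m=stats.m, n1=stats.n1, n2=stats.n2, n_overlap=stats.n_overlap,
        leave_one_out=jk.leave_one_out_estimates, notes=tuple(notes),
    )


def _exact_mom_estimate(op1: StandardizedOperator, op2: StandardizedOperator,
                        pair, n_blocks: int | None) -> MomFit:
    """Deterministic MoM fit with dense-oracle traces (test-scale panels)."""
    x1, x2 = op1.dense(), op2.dense()
    y1 = np.asarray(pair.y1, dtype=float)
    y2 = np.asarray(pair.y2, dtype=float)
    overlap = np.asarray(pair.overlap, dtype=np.intp).reshape(-1, 2)
    ov_i, ov_j = overlap[:, 0], overlap[:, 1]
    n_ov = len(ov_i)
    overlap_inner = float(y1[ov_i] @ y2[ov_j]) if n_ov else 0.0
    sq1, sq2 = float(y1 @ y1), float(y2 @ y2)
    n1, n2 = op1.n, op2.n

    def fit_cols(cols: np.ndarray) -> dict:
        m = len(cols)
        a1 = x1[:, cols].T @ y1
        a2 = x2[:, cols].T @ y2
        cross = x1[:, cols] @ x2[:, cols].T  # N1 x N2
        g11 = x1[:, cols].T @ x1[:, cols]
        g22 = x2[:, cols].T @ x2[:, cols]
        trace_cross = float((cross * cross).sum()) / (m * m)
        kc = float((x1[np.ix_(ov_i, cols)] * x2[np.ix_(ov_j, cols)]).sum()) / m \
            if n_ov else 0.0
        gamma_g, gamma_e = solve_covariance_system(
            trace_cross, kc, n_ov, float(a1 @ a2) / m, overlap_inner)
        sg1, se1 = solve_variance_system(
            float((g11 * g11).sum()) / (m * m), float(np.trace(g11)) / m, n1,
            float(a1 @ a1) / m, sq1)
        sg2, se2 = solve_variance_system(
            float((g22 * g22).sum()) / (m * m), float(np.trace(g22)) / m, n2,
            float(a2 @ a2) / m, sq2)
        rho = gamma_g / np.sqrt(sg1 * sg2) if sg1 > 0 and sg2 > 0 else float("nan")
        return dict(gamma_g=gamma_g, gamma_e=gamma_e, sigma_g1_sq=sg1,
                    sigma_e1_sq=se1, sigma_g2_sq=sg2, sigma_e2_sq=se2, rho_g=rho)

    m = op1.m
    comp = fit_cols(np.arange(m))
    se = float("nan")
    loo = None
    g = 0
    if n_blocks is not None and 2 <= n_blocks <= m:
        bounds = jackknife_block_bounds(m, n_blocks)
        g = len(bounds) - 1
        loo = np.empty(g)
        all_cols = np.arange(m)
        for bi in range(g):
            keep = np.concatenate([all_cols[:bounds[bi]], all_cols[bounds[bi + 1]:]])
            try:
                loo[bi] = fit_cols(keep)["rho_g"]
            except ConditioningError:
                loo[bi] = float("nan")
        se = jackknife_se(loo)
    notes = []
    rho_defined = np.isfinite(comp["rho_g"])
    if not rho_defined:
        notes.append("rho undefined: non-positive genetic variance estimate")
    return MomFit(
        **comp, se_rho=se, p_value=wald_test(comp["rho_g"], se),
        rho_defined=bool(rho_defined), method="exact-mom", b_used=0, seed=None,
        n_blocks=g, m=m, n1=n1, n2=n2, n_overlap=n_ov,
        leave_one_out=loo, notes=tuple(notes),
    )


def score_overlap_estimate(op: StandardizedOperator, y1: np.ndarray,
                           y2: np.ndarray, n_blocks: int = 100) -> MomFit:
    """Closed-form genetic correlation for completely overlapping cohorts.

    When both traits are measured on the identical samples, every moment
    system shares the coefficient matrix [[tr(K^2), tr(K)], [tr(K), N]],
    whose determinant cancels from the plug-in ratio:

        rho = (N y1'Ky2 - tr(K) y1'y2)
              / sqrt((N y1'Ky1 - tr(K) y1'y1)(N y2'Ky2 - tr(K) y2'y2)).

    No trace of K^2 and no randomization is required; the cost is two
    operator applications per trait plus per-block scalars for the jackknife.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    if y1.size != op.n or y2.size != op.n:
        raise ValueError("both phenotypes must cover the operator's cohort "
                         "(complete overlap required)")
    n = op.n
    bounds = jackknife_block_bounds(op.m, n_blocks)
    g = len(bounds) - 1
    a12 = np.empty(g)
    a11 = np.empty(g)
    a22 = np.empty(g)
    kk = np.empty(g)
    for bi in range(g):
        xb = op.standardized_block(bounds[bi], bounds[bi + 1])
        a1 = xb.T @ y1
        a2 = xb.T @ y2
        a12[bi] = a1 @ a2
        a11[bi] = a1 @ a1
        a22[bi] = a2 @ a2
        kk[bi] = (xb * xb).sum()
    y12, y11, y22 = float(y1 @ y2), float(y1 @ y1), float(y2 @ y2)

    def rho_from(a12, a11, a22, kk):
        # the active-M normalization cancels between numerator and denominator
        num = n * a12 - kk * y12
        d1 = n * a11 - kk * y11
        d2 = n * a22 - kk * y22
        if d1 <= 0 or d2 <= 0:
            return float("nan")
        return num / np.sqrt(d1 * d2)

    jk = block_jackknife(dict(a12=a12, a11=a11, a22=a22, kk=kk), rho_from)
    rho = jk.point_estimate
    rho_defined = np.isfinite(rho)
    notes = () if rho_defined else (
        "rho undefined: non-positive denominator factor",)
    nan = float("nan")
    return MomFit(
        gamma_g=nan, gamma_e=nan, sigma_g1_sq=nan, sigma_e1_sq=nan,
        sigma_g2_sq=nan, sigma_e2_sq=nan, rho_g=rho, se_rho=jk.se,
        p_value=wald_test(rho, jk.se), rho_defined=bool(rho_defined),
        method="score-overlap", b_used=0, seed=None, n_blocks=jk.n_blocks,
        m=op.m, n1=n, n2=n, n_overlap=n,
        leave_one_out=jk.leave_one_out_estimates, notes=notes,
    )
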