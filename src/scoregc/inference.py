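"""Block-jackknife standard errors and the Wald test of zero correlation.

Every moment statistic entering the estimator decomposes additively over
contiguous SNP blocks, so deleting a block and re-solving the normal
equations is cheap given cached per-block partial sums.  The delete-one
jackknife SE over g blocks is

    SE = sqrt( (g-1)/g * sum_b (theta_(b) - mean(theta_(.)))^2 ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats


@dataclass
class JackknifeResult:
    point_estimate: float
    leave_one_out_estimates: np.ndarray
    se: float
    n_blocks: int


def jackknife_se(leave_one_out: np.ndarray) -> float:
    """Delete-one jackknife SE from the leave-one-out estimates."""
    loo = np.asarray(leave_one_out, dtype=float)
    g = loo.size
    if g < 2:
        raise ValueError("jackknife needs at least two blocks")
    if not np.isfinite(loo).all():
        return float("nan")
    if (loo == loo[0]).all():
        return 0.0
    return float(np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum()))


def block_jackknife(per_block_partials: Mapping[str, np.ndarray],
                    estimator: Callable[..., float]) -> JackknifeResult:
    """Leave-one-block-out jackknife driven by cached additive partials.

    ``per_block_partials`` maps names to arrays whose first axis indexes the
    g blocks; ``estimator`` receives the summed totals by keyword and returns
    the scalar of interest.  The full estimator is re-evaluated from
    totals-minus-block for every block; no genotype pass is needed.
    """
    partials = {k: np.asarray(v, dtype=float) for k, v in per_block_partials.items()}
    sizes = {v.shape[0] for v in partials.values()}
    if len(sizes) != 1:
        raise ValueError("all partials must share the number of blocks")
    g = sizes.pop()
    if g < 2:
        raise ValueError("jackknife needs at least two blocks")
    totals = {k: v.sum(axis=0) for k, v in partials.items()}
    point = float(estimator(**totals))
    loo = np.empty(g)
    for b in range(g):
        loo[b] = estimator(**{k: totals[k] - partials[k][b] for k in partials})
    return JackknifeResult(point, loo, jackknife_se(loo), g)


def wald_test(rho_hat: float, se: float) -> float:
    """Two-tailed p value for the null of zero genetic correlation."""
    if np.isnan(rho_hat) or np.isnan(se):
        return float("nan")
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        if rho_hat == 0:
            return 1.0
        warnings.warn("degenerate (zero) standard error; reporting p = 0")
        return 0.0
    z = abs(rho_hat) / se
    return float(2.0 * stats.norm.sf(z))
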