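"""Method-of-moments solvers, the randomized estimator and its invariances."""

import numpy as np
import pytest

from scoregc.estimator import (ConditioningError, estimate_variance_components,
                               score_estimate, score_overlap_estimate,
                               solve_covariance_system, solve_variance_system)
from scoregc.operator import SketchConfig, StandardizedOperator
from scoregc.simulate import ArchitectureSpec, simulate_genotypes, simulate_trait_pair
from scoregc.traits import TraitPair

from conftest import dense_mom_oracle, dense_standardized, make_panel, random_pair


class TestSolvers:
    def test_diagonal_system_by_hand(self):
        gamma_g, gamma_e = solve_covariance_system(1.0, 0.0, 5, 0.3, 1.0)
        assert gamma_g == pytest.approx(0.3)
        assert gamma_e == pytest.approx(0.2)

    def test_no_overlap_reduction(self):
        gamma_g, gamma_e = solve_covariance_system(2.0, 0.0, 0, 0.5, 0.0)
        assert gamma_g == pytest.approx(0.25)
        assert np.isnan(gamma_e)

    def test_random_systems_match_generic_solver(self, rng):
        for _ in range(50):
            a = rng.uniform(1.0, 5.0)
            c = rng.uniform(-0.5, 0.5)
            n = rng.integers(5, 50)
            rhs = rng.standard_normal(2)
            mine = solve_covariance_system(a, c, int(n), rhs[0], rhs[1])
            ref = np.linalg.solve(np.array([[a, c], [c, n]]), rhs)
            np.testing.assert_allclose(mine, ref, atol=1e-12)
            mine_v = solve_variance_system(a, c, int(n), rhs[0], rhs[1])
            np.testing.assert_allclose(mine_v, ref, atol=1e-12)

    def test_singular_system_rejected(self):
        with pytest.raises(ConditioningError):
            solve_covariance_system(1.0, 1.0, 1, 0.5, 0.5)
        with pytest.raises(ConditioningError):
            solve_variance_system(0.0, 0.0, 0, 0.0, 0.0)


class TestVarianceComponents:
    def test_zero_phenotype_gives_zero_components(self, rng):
        op = StandardizedOperator(make_panel(rng, 30, 20))
        sg, se = estimate_variance_components(op, np.zeros(30))
        assert sg == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_null_trait_mean_near_zero(self, rng):
        # genotypes independent of y: mean sigma_g^2 over replicates ~ 0
        data = make_panel(rng, 150, 300, maf_low=0.1)
        op = StandardizedOperator(data)
        ests = []
        for r in range(100):
            y = rng.standard_normal(150)
            y = (y - y.mean()) / y.std()
            sg, _ = estimate_variance_components(
                op, y, SketchConfig(b=10, seed=r))
            ests.append(sg)
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 3 * mc_se

    def test_heritable_trait_recovery(self, rng):
        # infinitesimal trait, h^2 = 0.5, modest panel: mean within 3 MC SE
        geno = simulate_genotypes(800, 1500, seed=rng)
        spec = ArchitectureSpec(h1_sq=0.5, h2_sq=0.5, rho_param=0.0)
        op = StandardizedOperator(geno)
        ests = []
        for r in range(25):
            pair, _ = simulate_trait_pair(geno, spec, n_per_cohort=800, rng=rng)
            y = (pair.y1 - pair.y1.mean()) / pair.y1.std()
            sg, _ = estimate_variance_components(op, y, SketchConfig(b=10, seed=r))
            ests.append(sg)
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.5) < 3 * mc_se

    def test_exact_matches_dense(self, rng):
        data = make_panel(rng, 12, 8)
        op = StandardizedOperator(data)
        y = rng.standard_normal(12)
        y = (y - y.mean()) / y.std()
        sg, se = estimate_variance_components(op, y, exact=True)
        x = dense_standardized(data.genotypes)
        k = x @ x.T / 8
        lhs = np.array([[np.trace(k @ k), np.trace(k)], [np.trace(k), 12]])
        rhs = np.array([y @ k @ y, y @ y])
        np.testing.assert_allclose([sg, se], np.linalg.solve(lhs, rhs), atol=1e-10)


def toy_instance(rng, n1, n2, m, n_shared, shared_panel=False):
    d1 = make_panel(rng, max(n1, n2) if shared_panel else n1, m)
    if shared_panel:
        d2 = d1
        op1 = StandardizedOperator(d1, rows=np.arange(n1))
        op2 = op1 if n1 == n2 else StandardizedOperator(d1, rows=np.arange(n2))
    else:
        d2 = make_panel(rng, n2, m)
        op1, op2 = StandardizedOperator(d1), StandardizedOperator(d2)
    pair = random_pair(rng, n1, n2, n_shared)
    return op1, op2, pair


class TestScoreEstimate:
    def test_self_correlation_is_exactly_one(self, rng):
        data = make_panel(rng, 15, 12)
        op = StandardizedOperator(data)
        # heritable trait: genetic signal keeps the variance estimates positive
        y = op.matvec(rng.standard_normal(12)) + 0.3 * rng.standard_normal(15)
        y = (y - y.mean()) / y.std()
        pair = TraitPair(y1=y, y2=y.copy(),
                         overlap=np.column_stack([range(15), range(15)]))
        fit = score_estimate(op, op, pair, SketchConfig(b=5, seed=3), n_blocks=4)
        assert fit.rho_g == pytest.approx(1.0, abs=1e-10)
        ov = score_overlap_estimate(op, y, y.copy(), n_blocks=4)
        assert ov.rho_g == pytest.approx(1.0, abs=1e-12)

    def test_sign_antisymmetry(self, rng):
        data = make_panel(rng, 15, 12)
        op = StandardizedOperator(data)
        y = op.matvec(rng.standard_normal(12)) + 0.3 * rng.standard_normal(15)
        y = (y - y.mean()) / y.std()
        pair = TraitPair(y1=y, y2=-y,
                         overlap=np.column_stack([range(15), range(15)]))
        fit = score_estimate(op, op, pair, SketchConfig(b=5, seed=3), n_blocks=4)
        assert fit.rho_g == pytest.approx(-1.0, abs=1e-10)

    @pytest.mark.parametrize("overlap_frac", [0.0, 0.5, 1.0])
    def test_exact_mode_equals_closed_form_oracle(self, rng, overlap_frac):
        for _ in range(8):
            n1, n2, m = 9, 8, 10
            n_shared = int(overlap_frac * min(n1, n2))
            op1, op2, pair = toy_instance(rng, n1, n2, m, n_shared)
            fit = score_estimate(op1, op2, pair, exact=True)
            oracle = dense_mom_oracle(dense_standardized(op1.data.genotypes),
                                      dense_standardized(op2.data.genotypes),
                                      pair)
            assert fit.gamma_g == pytest.approx(oracle["gamma_g"], abs=1e-10)
            assert fit.sigma_g1_sq == pytest.approx(oracle["sigma_g1_sq"], abs=1e-10)
            assert fit.sigma_g2_sq == pytest.approx(oracle["sigma_g2_sq"], abs=1e-10)
            np.testing.assert_allclose(fit.rho_g, oracle["rho_g"],
                                       atol=1e-10, equal_nan=True)
            if n_shared > 0:
                assert fit.gamma_e == pytest.approx(oracle["gamma_e"], abs=1e-10)
            else:
                assert np.isnan(fit.gamma_e)

    def test_swap_symmetry_with_sketch(self, rng):
        op1, op2, pair = toy_instance(rng, 10, 9, 12, 5)
        cfg = SketchConfig(b=4, seed=7)
        fit = score_estimate(op1, op2, pair, cfg, n_blocks=3)
        swapped = TraitPair(y1=pair.y2, y2=pair.y1,
                            overlap=pair.overlap[:, ::-1])
        fit_sw = score_estimate(op2, op1, swapped, cfg, n_blocks=3)
        np.testing.assert_allclose(fit_sw.rho_g, fit.rho_g, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(fit_sw.gamma_g, fit.gamma_g, rtol=1e-12)
        np.testing.assert_allclose(fit_sw.se_rho, fit.se_rho, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(fit_sw.sigma_g1_sq, fit.sigma_g2_sq, rtol=1e-12)

    def test_scale_invariance_through_model_standardization(self, rng):
        # rho is invariant to positive phenotype rescaling once the pipeline
        # standardizes; at the estimator level a rescaled standardized y is
        # unchanged, so test via the residualizer
        from scoregc.traits import residualize
        y = rng.standard_normal(20) * 4 + 2
        np.testing.assert_allclose(residualize(y), residualize(y * 3.5), atol=1e-10)
        np.testing.assert_allclose(residualize(y), -residualize(-y), atol=1e-10)

    def test_no_overlap_flags_gamma_e(self, rng):
        op1, op2, pair = toy_instance(rng, 10, 9, 12, 0)
        fit = score_estimate(op1, op2, pair, SketchConfig(b=4, seed=1), n_blocks=3)
        assert np.isnan(fit.gamma_e)
        assert any("unidentifiable" in note for note in fit.notes)

    def test_deterministic_given_seed(self, rng):
        op1, op2, pair = toy_instance(rng, 10, 9, 12, 5)
        cfg = SketchConfig(b=4, seed=13)
        f1 = score_estimate(op1, op2, pair, cfg, n_blocks=3)
        f2 = score_estimate(op1, op2, pair, cfg, n_blocks=3)
        np.testing.assert_equal(f1.rho_g, f2.rho_g)
        np.testing.assert_equal(f1.se_rho, f2.se_rho)
        np.testing.assert_equal(f1.gamma_g, f2.gamma_g)


class TestScoreOverlap:
    def test_equals_exact_mom_plugin(self, rng):
        for _ in range(10):
            n, m = 12, 30
            data = make_panel(rng, n, m)
            op = StandardizedOperator(data)
            pair = random_pair(rng, n, n, n)
            ov = score_overlap_estimate(op, pair.y1, pair.y2, n_blocks=5)
            x = dense_standardized(data.genotypes)
            oracle = dense_mom_oracle(x, x, pair)
            np.testing.assert_allclose(ov.rho_g, oracle["rho_g"],
                                       atol=1e-10, equal_nan=True)

    def test_score_coincides_with_overlap_on_shared_operator(self, rng):
        # sharing one sketch per cohort makes the coefficient matrices of all
        # moment systems identical, so the randomized estimator reproduces
        # the closed form exactly at any B when the cohorts are identical
        n, m = 40, 60
        data = make_panel(rng, n, m)
        op = StandardizedOperator(data)
        pair = random_pair(rng, n, n, n)
        target = score_overlap_estimate(op, pair.y1, pair.y2, n_blocks=5).rho_g
        fit = score_estimate(op, op, pair, SketchConfig(b=3, seed=5), n_blocks=5)
        assert fit.rho_g == pytest.approx(target, abs=1e-10)

    def test_large_b_score_converges_to_overlap(self, rng):
        # with independent sketches per trait the agreement is only
        # approximate and tightens as B grows
        n, m = 40, 60
        data = make_panel(rng, n, m)
        op1 = StandardizedOperator(data)
        op2 = StandardizedOperator(data)
        pair = random_pair(rng, n, n, n)
        target = score_overlap_estimate(op1, pair.y1, pair.y2, n_blocks=5).rho_g
        err = {}
        for b in (5, 2000):
            fit = score_estimate(op1, op2, pair, SketchConfig(b=b, seed=5),
                                 n_blocks=5)
            err[b] = abs(fit.rho_g - target)
        assert err[2000] < err[5]
        assert err[2000] < 0.05

    def test_cohort_mismatch_rejected(self, rng):
        op = StandardizedOperator(make_panel(rng, 10, 8))
        with pytest.raises(ValueError, match="complete overlap"):
            score_overlap_estimate(op, np.zeros(10), np.zeros(7))
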