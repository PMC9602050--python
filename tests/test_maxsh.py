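"""Tests for the MaxSH stage: loss, w estimation, alpha, UGIT weights."""

import numpy as np
import pytest
from scipy.optimize import minimize

from shaher.core import CorrelationMatrix, combo_moments, compose_ugen
from shaher.gip import gip1_weights
from shaher.maxsh import (
    SgiScreenError,
    estimate_w,
    loss_value,
    run_maxsh,
    solve_alpha,
    solve_ugit_weights,
)

from conftest import make_panel, random_panel


class TestLossValue:
    def test_zero_at_generating_w(self):
        w = np.array([0.6, 0.8, 0.9])
        assert loss_value(w, compose_ugen(w, CorrelationMatrix.identity(3))) == 0.0

    def test_zero_w_gives_sum_of_squares(self):
        ug = compose_ugen([0.6, 0.8, 0.9], CorrelationMatrix.identity(3))
        assert loss_value(np.zeros(3), ug) == pytest.approx(
            np.sum(ug.offdiag() ** 2)
        )

    def test_hand_arithmetic_example(self):
        # r = (0.48, 0.54, 0.72), w = 0.5: (0.23)^2 + (0.29)^2 + (0.47)^2
        ug = compose_ugen([0.6, 0.8, 0.9], CorrelationMatrix.identity(3))
        assert loss_value(np.full(3, 0.5), ug) == pytest.approx(0.3579)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            panel, _ = random_panel(rng)
            w = rng.uniform(-1, 1, size=panel.k)
            assert loss_value(w, panel.ugen) == pytest.approx(
                loss_value(-w, panel.ugen), rel=1e-12
            )


class TestEstimateW:
    def test_exact_generative_recovery(self):
        w = np.array([0.6, 0.8, 0.9])
        d = estimate_w(compose_ugen(w, CorrelationMatrix.identity(3)))
        assert np.max(np.abs(d.w - w)) <= 1e-6
        assert d.loss <= 1e-10
        assert np.allclose(np.diag(d.uunsh.values), 1.0)

    def test_matches_k3_closed_form(self):
        """Three consistent pairwise correlations determine w in closed form."""
        r12, r13, r23 = 0.48, 0.54, 0.72
        expected = np.array(
            [
                np.sqrt(r12 * r13 / r23),
                np.sqrt(r12 * r23 / r13),
                np.sqrt(r13 * r23 / r12),
            ]
        )
        ug = CorrelationMatrix(
            np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
        )
        d = estimate_w(ug)
        assert np.allclose(d.w, expected, atol=1e-8)
        assert np.allclose(d.w, [0.6, 0.8, 0.9], atol=1e-8)

    def test_sign_flip_recovery_and_canonicalization(self):
        w = np.array([0.6, 0.8, 0.9])
        s = np.array([1.0, -1.0, 1.0])
        base = compose_ugen(w, CorrelationMatrix.identity(3))
        flipped = CorrelationMatrix(base.values * np.outer(s, s))
        d = estimate_w(flipped)
        assert d.w.sum() >= 0.0
        assert np.allclose(np.abs(d.w), w, atol=1e-6)
        assert np.allclose(np.sign(d.w) * np.sign(d.w[0]), s * s[0])

    def test_recovers_uunsh(self):
        rng = np.random.default_rng(8)
        from shaher.simulate import gen_unsh

        w = np.array([0.8, 0.85, 0.9, 0.75])
        uunsh = gen_unsh(4, 0.3, 0.3, rng)
        d = estimate_w(compose_ugen(w, uunsh))
        # recovery is approximate: the rank-one fit absorbs part of U_unsh
        assert np.allclose(d.uunsh.values, uunsh.values, atol=0.25)
        assert np.array_equal(np.diag(d.uunsh.values), np.ones(4))
        assert d.uunsh.pd_ok

    def test_boundary_flag(self):
        with pytest.warns(RuntimeWarning, match="boundary"):
            d = estimate_w(compose_ugen([0.999999, 0.9, 0.9], CorrelationMatrix.identity(3)))
        assert d.boundary


class TestSolveAlpha:
    def test_exchangeable_panel_gives_equal_weights(self):
        panel = make_panel(np.full(4, 0.8), np.full(4, 0.5))
        alpha = solve_alpha(panel, np.full(4, 0.8))
        assert np.allclose(alpha, alpha[0])

    def test_unit_phenotypic_variance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            panel, w = random_panel(rng)
            alpha = solve_alpha(panel, w)
            assert alpha @ panel.uphen.values @ alpha == pytest.approx(1.0, abs=1e-8)

    def test_matches_numeric_ratio_maximizer(self, worked_panel, worked_w):
        """Oracle: directly maximize (k'Hw)^2 / (k'U_phen k) numerically."""
        hw = np.sqrt(worked_panel.h2) * worked_w
        up = worked_panel.uphen.values

        def neg_ratio(k):
            return -float((k @ hw) ** 2 / (k @ up @ k))

        best = None
        for seed in range(5):
            x0 = np.random.default_rng(seed).standard_normal(3)
            res = minimize(neg_ratio, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        oracle = best.x / np.sqrt(best.x @ up @ best.x)
        if oracle @ hw < 0:
            oracle = -oracle
        alpha = solve_alpha(worked_panel, worked_w)
        assert np.allclose(alpha, oracle, atol=1e-6)

    def test_optimality_over_random_directions(self):
        rng = np.random.default_rng(10)
        panel, w = random_panel(rng, k=5)
        alpha = solve_alpha(panel, w)
        best = combo_moments(alpha, panel, w).h2_shared
        directions = rng.standard_normal((2000, 5))
        for k in directions:
            k = k / np.sqrt(k @ panel.uphen.values @ k)
            assert combo_moments(k, panel, w).h2_shared <= best + 1e-9

    def test_zero_w_rejected(self, worked_panel):
        with pytest.raises(ValueError, match="shared"):
            solve_alpha(worked_panel, np.zeros(3))


class TestSolveUgitWeights:
    def test_residualization_identity(self):
        """Gamma' C_gen alpha = 0: UGITs genetically uncorrelated with SGIT."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            panel, w = random_panel(rng)
            alpha = solve_alpha(panel, w)
            c, gamma = solve_ugit_weights(panel, alpha)
            assert np.max(np.abs(gamma.T @ panel.cgen @ alpha)) <= 1e-10

    def test_fully_shared_genetics(self):
        w = np.full(4, 1.0 - 1e-9)
        panel = make_panel(w, np.full(4, 0.5))
        alpha = solve_alpha(panel, w)
        c, gamma = solve_ugit_weights(panel, alpha)
        h = np.sqrt(panel.h2)
        # c_i * (alpha' H 1) = h_i when all genetics is shared
        assert np.allclose(c * (alpha @ h), h, atol=1e-6)
        for i in range(4):
            s = combo_moments(gamma[:, i], panel, w)
            assert s.h2_total == pytest.approx(0.0, abs=1e-6)

    def test_against_brute_force_covariances(self, worked_panel, worked_w):
        alpha = solve_alpha(worked_panel, worked_w)
        c, gamma = solve_ugit_weights(worked_panel, alpha)
        cgen = worked_panel.cgen
        h2_sgit = alpha @ cgen @ alpha
        assert np.allclose(c, (cgen @ alpha) / h2_sgit, rtol=1e-12)
        assert np.allclose(gamma, np.eye(3) - np.outer(alpha, c), rtol=1e-12)
        # UGIT heritabilities from explicit covariance assembly
        for i in range(3):
            g = gamma[:, i]
            var = g @ worked_panel.uphen.values @ g
            expected_h2 = (g @ cgen @ g) / var
            assert combo_moments(g, worked_panel, worked_w).h2_total == pytest.approx(
                expected_h2, rel=1e-10
            )

    def test_unnormalized_alpha_rejected(self, worked_panel):
        with pytest.raises(ValueError, match="normalized"):
            solve_ugit_weights(worked_panel, np.ones(3))


class TestRunMaxsh:
    def test_worked_panel_end_to_end(self, worked_panel, worked_w):
        report = run_maxsh(worked_panel)
        assert np.allclose(report.decomposition.w, worked_w, atol=1e-6)
        # analytic pipeline assembled step by step
        alpha = solve_alpha(worked_panel, worked_w)
        expected = combo_moments(alpha, worked_panel, worked_w)
        assert report.sgit.q == pytest.approx(expected.q, abs=1e-6)
        assert not report.final_screen.passed  # no SGI remains among UGITs
        assert np.allclose(
            report.shared_h2 + report.unshared_h2, worked_panel.h2, atol=1e-10
        )

    def test_screen_gate_aborts(self):
        # one near-zero genetic correlation fails the screen
        ugen = CorrelationMatrix(
            np.array([[1, 0.05, 0.6], [0.05, 1, 0.6], [0.6, 0.6, 1.0]])
        )
        panel = make_panel([0.6, 0.8, 0.9], [0.5, 0.5, 0.5])
        bad = type(panel)(panel.names, panel.h2, ugen, panel.uphen)
        with pytest.raises(SgiScreenError) as err:
            run_maxsh(bad)
        assert not err.value.verdict.passed

    def test_exchangeable_symmetry_propagates(self):
        panel = make_panel(np.full(4, 0.8), np.full(4, 0.5))
        report = run_maxsh(panel, with_gip=True)
        assert np.allclose(report.weights.alpha, report.weights.alpha[0])
        assert np.allclose(report.weights.c, report.weights.c[0])
        ugit_h2 = [s.h2_total for s in report.ugits]
        assert np.allclose(ugit_h2, ugit_h2[0])
        # for an exchangeable panel GIP1 and SGIT coincide
        assert np.allclose(report.gip1, report.weights.alpha, atol=1e-8)


class TestGipBaseline:
    def test_exchangeable_equals_alpha_direction(self):
        panel = make_panel(np.full(4, 0.8), np.full(4, 0.5))
        beta = gip1_weights(panel)
        assert np.allclose(beta, beta[0])

    def test_degenerate_spectrum_error(self):
        from shaher.gip import DegenerateSpectrumError

        panel = make_panel(np.zeros(3) + 1e-12, np.full(3, 0.5))
        with pytest.raises(DegenerateSpectrumError):
            gip1_weights(panel)

    def test_matches_eigendecomposition_oracle(self, worked_panel):
        eigval, eigvec = np.linalg.eigh(worked_panel.cgen)
        v = eigvec[:, np.argmax(eigval)]
        expected = v / np.sqrt(v @ worked_panel.uphen.values @ v)
        if expected.sum() < 0:
            expected = -expected
        assert np.allclose(gip1_weights(worked_panel), expected, atol=1e-12)

    def test_never_beats_true_alpha(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            panel, w = random_panel(rng)
            alpha = solve_alpha(panel, w)
            beta = gip1_weights(panel)
            assert (
                combo_moments(beta, panel, w).h2_shared
                <= combo_moments(alpha, panel, w).h2_shared + 1e-9
            )
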