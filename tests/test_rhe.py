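"""Randomized HE regression: trace estimator and the two-moment system."""

import numpy as np
import pytest

from rhepcg.core import StandardizedDesign, standardize
from rhepcg.rhe import H2_MIN, estimate_trace_omega2, rhe_fit

from conftest import random_design


def dense_trace_omega2(Z):
    """Brute-force tr[(ZZ'/m)^2] — the oracle the randomized path must match."""
    G = Z @ Z.T / Z.shape[1]
    return float(np.trace(G @ G))


def _design_from_Z(Z, y=None):
    n, m = Z.shape
    return StandardizedDesign(
        Z=Z, y=y, X=np.ones(n), col_means=np.zeros(m), col_scales=np.ones(m)
    )


class TestTraceEstimator:
    def test_two_by_one_exact_case(self):
        """Z = (-1, 1)': G has entries +/-1, so tr(G^2) = 4 exactly."""
        Z = np.array([[-1.0], [1.0]])
        assert dense_trace_omega2(Z) == pytest.approx(4.0)
        rng = np.random.default_rng(0)
        probes = [estimate_trace_omega2(Z, 1, rng) for _ in range(10_000)]
        mean, se = np.mean(probes), np.std(probes, ddof=1) / 100
        assert abs(mean - 4.0) < 3 * se

    def test_unbiased_on_random_design(self):
        """Probe-mean converges on the dense value (Hutchinson unbiasedness)."""
        Z = random_design(50, 30, seed=11, with_y=False).Z
        exact = dense_trace_omega2(Z)
        rng = np.random.default_rng(1)
        probes = [estimate_trace_omega2(Z, 1, rng) for _ in range(1_000)]
        se = np.std(probes, ddof=1) / np.sqrt(len(probes))
        assert abs(np.mean(probes) - exact) < 3 * se
        # and a large single-call estimate is within 2%
        est = estimate_trace_omega2(Z, 5_000, np.random.default_rng(2))
        assert est == pytest.approx(exact, rel=0.02)

    def test_few_probes_are_coarse_but_sane(self):
        Z = random_design(50, 30, seed=11, with_y=False).Z
        exact = dense_trace_omega2(Z)
        est = estimate_trace_omega2(Z, 5, np.random.default_rng(3))
        assert est == pytest.approx(exact, rel=0.2)

    def test_probe_count_validated(self):
        with pytest.raises(ValueError):
            estimate_trace_omega2(np.ones((3, 2)), 0, np.random.default_rng(0))


class TestRHEFit:
    def test_matches_vectorized_least_squares_oracle(self):
        """The two-moment system is the normal-equation form of regressing
        the n^2 entries of yy' on (vec(G), vec(I)) — solve that regression
        brute force and compare, using the exact trace on both sides."""
        design = random_design(30, 12, seed=5)
        Z, y = design.Z, design.y
        n, m = Z.shape
        G = Z @ Z.T / m
        A = np.column_stack([G.ravel(), np.eye(n).ravel()])
        coef, *_ = np.linalg.lstsq(A, np.outer(y, y).ravel(), rcond=None)

        tr2 = dense_trace_omega2(Z)
        yGy = float(y @ G @ y)
        lhs = np.array([[tr2, n], [n, n]], dtype=float)
        rhs = np.array([yGy, float(y @ y)])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(sol, coef, atol=1e-8)

        # the randomized fit approaches the same solution at large S
        fit = rhe_fit(design, S=20_000, rng=np.random.default_rng(4))
        assert fit.components.sigma_g2 == pytest.approx(
            max(0.0, coef[0]), abs=0.05
        )

    def test_no_genetic_signal_clamps_h2_to_floor(self):
        """y orthogonal to every marker column: y'Gy = 0, sigma_g2 <= 0."""
        design = random_design(20, 5, seed=9)
        Z = design.Z
        # project a random vector off the column space of Z
        rng = np.random.default_rng(10)
        y = rng.standard_normal(20)
        y -= Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        y /= y.std(ddof=1)
        fit = rhe_fit(_design_from_Z(Z, y), S=5, rng=rng)
        assert fit.yT_omega_y == pytest.approx(0.0, abs=1e-16)
        assert fit.components.h2 == H2_MIN
        assert fit.clamped

    def test_recovers_simulated_heritability(self):
        from rhepcg.simulate import SimulationConfig, simulate_population

        ests = []
        for seed in range(5):
            pop = simulate_population(
                SimulationConfig(
                    n_train=400, n_cand=1, h2=0.5, n_markers=400, seed=100 + seed
                )
            )
            d = standardize(
                pop.genotypes.matrix[pop.train_idx],
                pop.phenotypes[pop.train_idx],
            )
            ests.append(
                rhe_fit(d, S=5, rng=np.random.default_rng(seed)).components.h2
            )
        assert np.mean(ests) == pytest.approx(0.5, abs=0.12)

    def test_bias_shrinks_with_training_size(self):
        """Method-of-moments consistency: |mean h2_hat - h2| shrinks with n."""
        from rhepcg.simulate import SimulationConfig, simulate_population

        biases, ses = {}, {}
        for n in (150, 600):
            ests = []
            for seed in range(30):
                pop = simulate_population(
                    SimulationConfig(
                        n_train=n, n_cand=1, h2=0.5, n_markers=300,
                        seed=1000 * n + seed,
                    )
                )
                d = standardize(
                    pop.genotypes.matrix[pop.train_idx],
                    pop.phenotypes[pop.train_idx],
                )
                ests.append(
                    rhe_fit(d, S=5, rng=np.random.default_rng(seed)).components.h2
                )
            ests = np.asarray(ests)
            biases[n] = abs(ests.mean() - 0.5)
            ses[n] = ests.std(ddof=1) / np.sqrt(ests.size)
        # allow Monte-Carlo slack: two combined standard errors of the means
        slack = 2 * np.hypot(ses[150], ses[600])
        assert biases[600] <= biases[150] + slack

    def test_degenerate_relatedness_raises(self):
        # G exactly I (Z = sqrt(n) I, m = n): tr(G^2) n == tr(G)^2 and the
        # 2x2 system is singular.  Probes of constant norm make the
        # randomized trace hit the degenerate value exactly.
        n = 6
        Z = np.sqrt(n) * np.eye(n)
        d = _design_from_Z(Z, np.arange(n, dtype=float))

        class UnitNormProbes:
            def standard_normal(self, size):
                return np.ones(size)  # ||w||^2 = n exactly

        with pytest.raises(ValueError, match="degenerate"):
            rhe_fit(d, S=3, rng=UnitNormProbes())

    def test_constant_phenotype_rejected(self, small_design):
        d = _design_from_Z(small_design.Z, np.ones(small_design.n))
        with pytest.raises(ValueError, match="constant"):
            rhe_fit(d, S=2, rng=np.random.default_rng(0))


def test_matrix_free_contract_no_grm_assembly():
    """Structural check: the RHE module never forms ZZ' or Z'Z."""
    import inspect

    import rhepcg.rhe as mod

    src = inspect.getsource(mod)
    assert "Z @ Z.T" not in src and "Z.T @ Z" not in src
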