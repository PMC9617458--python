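"""Conditional distributions, partition integrals, and the fitting loop."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from compmaxent import (
    CMEParameters,
    CompositionTable,
    ConditionalContext,
    TildeParameters,
    conditional_log_density,
    conditional_log_partition,
    conditional_log_partition_moments,
    fit,
    pseudolikelihood_objective,
    sample,
    SamplerConfig,
)

from conftest import random_table, random_tilde


def quad_log_partition(a, b, upper):
    """Independent adaptive-quadrature oracle for log Z~."""
    if upper == 0:
        return -np.inf
    fmax = max(0.0, a * upper + 0.5 * b * upper * upper)
    if b < 0 and 0 < -a / b < upper:
        fmax = max(fmax, -0.5 * a * a / b)
    val, _ = quad(
        lambda s: np.exp(a * s + 0.5 * b * s * s - fmax),
        0.0,
        upper,
        epsabs=1e-300,
        epsrel=1e-13,
        limit=200,
    )
    return fmax + np.log(val)


class TestConditionalLogPartition:
    def test_unit_integrand(self):
        assert conditional_log_partition(0.0, 0.0, 1.0) == pytest.approx(0.0)

    def test_linear_closed_form(self):
        assert conditional_log_partition(1.0, 0.0, 1.0) == pytest.approx(
            np.log(np.e - 1.0), abs=1e-12
        )

    def test_against_quadrature_example(self):
        got = conditional_log_partition(1.0, -2.0, 0.7)
        assert got == pytest.approx(quad_log_partition(1.0, -2.0, 0.7),
                                    abs=1e-10)

    @pytest.mark.parametrize("a", [-20.0, -3.0, 0.0, 1e-7, 2.5, 20.0])
    @pytest.mark.parametrize("b", [-50.0, -5.0, -0.26, -1e-8, 0.0, 0.3, 50.0])
    @pytest.mark.parametrize("upper", [1e-4, 0.3, 1.0])
    def test_against_quadrature_grid(self, a, b, upper):
        got = conditional_log_partition(a, b, upper)
        ref = quad_log_partition(a, b, upper)
        assert abs(got - ref) <= 1e-10 * max(1.0, abs(ref))

    def test_negative_upper_rejected(self):
        with pytest.raises(ValueError, match="upper"):
            conditional_log_partition(1.0, 1.0, -0.1)

    def test_zero_upper_is_empty_interval(self):
        assert conditional_log_partition(1.0, 1.0, 0.0) == -np.inf

    def test_extreme_parameters_stay_finite(self):
        # log-domain evaluation: no overflow even far outside the
        # moderate-parameter regime
        for a, b in [(600.0, -900.0), (-500.0, 400.0), (0.0, 800.0)]:
            val = conditional_log_partition(a, b, 1.0)
            assert np.isfinite(val)

    def test_moment_outputs_match_quadrature(self, rng):
        for _ in range(10):
            a = rng.uniform(-10, 10)
            b = rng.uniform(-30, 30)
            u = rng.uniform(0.05, 1.0)
            logz, es, es2 = conditional_log_partition_moments(a, b, u)
            m1 = quad(lambda s: s * np.exp(a * s + 0.5 * b * s * s - logz),
                      0, u, epsabs=1e-300, epsrel=1e-12)[0]
            m2 = quad(lambda s: s * s * np.exp(a * s + 0.5 * b * s * s - logz),
                      0, u, epsabs=1e-300, epsrel=1e-12)[0]
            assert es == pytest.approx(m1, abs=1e-9)
            assert es2 == pytest.approx(m2, abs=1e-9)


class TestConditionalLogDensity:
    def test_flat_conditional_is_uniform(self):
        t = TildeParameters(np.zeros(2), np.zeros((2, 2)), n_components=3)
        ctx = ConditionalContext(i=0, s_rest=np.array([0.4]), upper=0.6)
        for s in [0.0, 0.3, 0.6]:
            assert conditional_log_density(s, ctx, t) == pytest.approx(
                -np.log(0.6)
            )

    def test_normalizes_to_one(self, rng):
        for _ in range(5):
            t = random_tilde(rng, 3)
            rest = rng.uniform(0, 0.8)
            ctx = ConditionalContext(i=0, s_rest=np.array([rest]),
                                     upper=1.0 - rest)
            total = quad(
                lambda s: np.exp(conditional_log_density(s, ctx, t)),
                0.0,
                ctx.upper,
                epsabs=1e-12,
                epsrel=1e-10,
            )[0]
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_two_component_truncated_exponential_mean(self):
        # h~ = 2, K~ = 0, upper = 1: mean = 1/(1 - e^{-2}) - 1/2
        t = TildeParameters(np.array([2.0]), np.zeros((1, 1)), n_components=2)
        ctx = ConditionalContext(i=0, s_rest=np.zeros(0), upper=1.0)
        mean = quad(
            lambda s: s * np.exp(conditional_log_density(s, ctx, t)),
            0.0, 1.0, epsabs=1e-12, epsrel=1e-10,
        )[0]
        assert mean == pytest.approx(1.0 / (1.0 - np.exp(-2.0)) - 0.5,
                                     abs=1e-8)

    def test_outside_support_rejected(self):
        t = TildeParameters(np.zeros(2), np.zeros((2, 2)), n_components=3)
        ctx = ConditionalContext(i=0, s_rest=np.array([0.5]), upper=0.5)
        with pytest.raises(ValueError, match="outside"):
            conditional_log_density(0.7, ctx, t)


class TestPseudolikelihoodObjective:
    def test_flat_model_value(self, rng):
        table = random_table(rng, 50, 3)
        t0 = TildeParameters(np.zeros(2), np.zeros((2, 2)), n_components=3)
        uppers = table.values[:, 0] + table.values[:, 2]
        expected = -np.mean(np.log(uppers))
        assert pseudolikelihood_objective(0, t0, table) == pytest.approx(
            expected, abs=1e-12
        )

    def test_flat_model_two_components_is_zero(self, rng):
        table = random_table(rng, 30, 2)
        t0 = TildeParameters(np.zeros(1), np.zeros((1, 1)), n_components=2)
        assert pseudolikelihood_objective(0, t0, table) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_equals_average_conditional_log_density(self, rng, n):
        # the primary correctness oracle: the moment form of l_PL^i equals
        # the sample average of the conditional log-density
        table = random_table(rng, 40, n)
        tilde = random_tilde(rng, n)
        for i in range(n - 1):
            direct = np.mean([
                conditional_log_density(
                    s[i], ConditionalContext.from_sample(i, s), tilde
                )
                for s in table.values
            ])
            assert pseudolikelihood_objective(i, tilde, table) == (
                pytest.approx(direct, abs=1e-10)
            )

    def test_gradient_matches_finite_differences(self, rng):
        # analytic gradient (via conditional moments) vs central differences
        n, d = 4, 60
        table = random_table(rng, d, n)
        tilde = random_tilde(rng, n, scale=1.0)
        i = 1
        s = table.values
        x = s[:, i]
        sfree = s[:, : n - 1]
        row = tilde.K_tilde[i]
        a = tilde.h_tilde[i] + sfree @ row - row[i] * x
        upper = x + s[:, n - 1]
        _, es, es2 = conditional_log_partition_moments(a, row[i], upper)
        grad_h = np.mean(x - es)
        grad_k = (sfree * (x - es)[:, None]).mean(axis=0)
        grad_k[i] = 0.5 * np.mean(x * x - es2)

        eps = 1e-6

        def obj(ht, kt_row):
            t2 = TildeParameters(
                tilde.h_tilde.copy(), tilde.K_tilde.copy(), n_components=n
            )
            t2.h_tilde[i] = ht
            t2.K_tilde[i] = kt_row
            return pseudolikelihood_objective(i, t2, table)

        fd_h = (obj(tilde.h_tilde[i] + eps, row)
                - obj(tilde.h_tilde[i] - eps, row)) / (2 * eps)
        assert grad_h == pytest.approx(fd_h, rel=1e-6, abs=1e-8)
        for j in range(n - 1):
            rp, rm = row.copy(), row.copy()
            rp[j] += eps
            rm[j] -= eps
            fd = (obj(tilde.h_tilde[i], rp)
                  - obj(tilde.h_tilde[i], rm)) / (2 * eps)
            assert grad_k[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestFit:
    def test_flat_dirichlet_fits_near_zero(self, rng):
        table = random_table(rng, 5000, 3)
        res = fit(table)
        assert np.all(res.converged)
        assert np.max(np.abs(res.params.h)) < 0.4
        assert np.max(np.abs(res.params.K)) < 0.6

    def test_recovers_single_interaction(self, rng):
        k = np.zeros((3, 3))
        k[0, 1] = k[1, 0] = 3.0
        truth = CMEParameters(h=np.zeros(3), K=k)
        table = sample(truth, SamplerConfig(n_samples=3000, seed=42))
        res = fit(table)
        assert res.params.K[0, 1] == pytest.approx(3.0, rel=0.25)
        assert abs(res.params.K[0, 2]) < 1.0

    def test_objective_decreases_away_from_maximizer(self, rng):
        table = random_table(rng, 400, 3)
        res = fit(table)
        for i in range(2):
            base = pseudolikelihood_objective(i, res.tilde, table)
            for j in range(2):
                for d in (-0.05, 0.05):
                    t2 = TildeParameters(
                        res.tilde.h_tilde.copy(),
                        res.tilde.K_tilde.copy(),
                        n_components=3,
                    )
                    t2.K_tilde[i, j] += d
                    assert pseudolikelihood_objective(i, t2, table) < base

    def test_objective_per_node_matches_recomputation(self, rng):
        table = random_table(rng, 300, 3)
        res = fit(table)
        for i in range(2):
            assert res.objective_per_node[i] == pytest.approx(
                pseudolikelihood_objective(i, res.tilde, table), abs=1e-9
            )

    def test_reference_component_invariance(self, rng):
        # each conditional's optimum is parameterization-free, but the
        # symmetrizing refinement reconciles the per-node asymmetries in
        # a reference-dependent way, so exact invariance holds only in
        # the large-sample limit; at D = 1500 the residual dependence is
        # O(1/sqrt(D)) in the parameters
        table = random_table(rng, 1500, 3)
        base = fit(table)
        for ref in table.names:
            alt = fit(table, reference=ref)
            np.testing.assert_allclose(alt.params.K, base.params.K,
                                       atol=0.05)
            np.testing.assert_allclose(alt.params.Q, base.params.Q,
                                       atol=0.02)

    def test_recovery_error_shrinks_with_samples(self):
        # averaged over independent chains: a single draw of the small-D
        # error can beat the large-D error by chance
        k = np.zeros((3, 3))
        k[0, 1] = k[1, 0] = 3.0
        truth = CMEParameters(h=np.zeros(3), K=k)
        errs_small, errs_big = [], []
        for seed in (9, 19, 29):
            big = sample(truth, SamplerConfig(n_samples=4000, seed=seed))
            small = CompositionTable(big.values[:300], big.names)
            errs_small.append(abs(fit(small).params.K[0, 1] - 3.0))
            errs_big.append(abs(fit(big).params.K[0, 1] - 3.0))
        assert np.mean(errs_big) < np.mean(errs_small)

    def test_nonconvergence_flagged_not_fatal(self, rng):
        table = random_table(rng, 200, 3)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = fit(table, maxiter=1)
        assert not np.all(res.converged)
        assert any("convergence" in str(w.message) for w in rec)

    def test_degenerate_component_requires_ridge(self):
        v = np.column_stack([
            np.full(50, 0.2),
            np.linspace(0.1, 0.7, 50),
        ])
        v = np.column_stack([v, 1.0 - v.sum(axis=1)])
        table = CompositionTable(v, ["a", "b", "c"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="ridge"):
                fit(table)
            res = fit(table, ridge=1e-3)
        assert np.all(np.isfinite(res.params.K))

    def test_deterministic(self, rng):
        table = random_table(rng, 500, 3)
        r1 = fit(table, seed=5)
        r2 = fit(table, seed=5)
        np.testing.assert_array_equal(r1.params.K, r2.params.K)
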