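"""Polynomial chaos: basis construction, fitting, statistics, Sobol indices."""

import math

import numpy as np
import pytest

from neurouq import pce
from neurouq.distributions import (IndependentJoint, Normal, Uniform,
                                   hammersley_nodes)


@pytest.fixture
def uniform2():
    return IndependentJoint([Uniform(0, 1), Uniform(0, 1)])


class TestBasis:
    @pytest.mark.parametrize("d,p,expected", [
        (1, 0, 1),
        (2, 4, 15),          # C(6, 4)
        (11, 4, 1365),       # C(15, 4)
        (3, 3, 20),
    ])
    def test_term_count(self, d, p, expected):
        joint = IndependentJoint([Uniform(0, 1)] * d)
        basis = pce.build_basis(joint, p)
        assert basis.size == expected == math.comb(d + p, p)

    def test_orthonormality_by_quadrature(self):
        joint = IndependentJoint([Uniform(-1, 3), Normal(2, 0.5)])
        basis = pce.build_basis(joint, 3, max_univariate_order=8)
        rule = pce.quadrature_design(joint, 8, basis=basis)
        A = basis.evaluate(rule.nodes)
        G = (A * rule.weights[:, None]).T @ A
        assert np.max(np.abs(G - np.eye(basis.size))) < 1e-8

    def test_stieltjes_matches_legendre(self):
        # a uniform marginal disguised as a generic inverse-CDF distribution
        class Generic(Uniform):
            pass

        generic = Generic(0, 1)
        generic.__class__ = type("Opaque", (Uniform,), {})
        uni_closed = pce.UnivariateOrthonormal(Uniform(0, 1), 6)
        uni_stielt = pce.UnivariateOrthonormal.__new__(pce.UnivariateOrthonormal)
        uni_stielt.dist = generic
        uni_stielt.max_order = 6
        uni_stielt.shift, uni_stielt.scale = 0.0, 1.0
        uni_stielt.alpha, uni_stielt.beta = pce.UnivariateOrthonormal._stieltjes(
            generic, 7)
        x = np.linspace(0.01, 0.99, 25)
        v1 = uni_closed.values(x, 5)
        v2 = uni_stielt.values(x, 5)
        # same family up to sign per order
        for k in range(6):
            s = np.sign(v1[0, k]) * np.sign(v2[0, k]) or 1.0
            assert np.max(np.abs(v1[:, k] - s * v2[:, k])) < 1e-6

    def test_dependent_joint_rejected(self):
        from neurouq.distributions import ConditionalJoint
        joint = ConditionalJoint([Uniform(0, 1), Uniform(0, 1)])
        with pytest.raises(ValueError):
            pce.build_basis(joint, 2)


class TestCollocation:
    @pytest.mark.parametrize("d,p,n_nodes", [
        (1, 0, 4),           # 2 (1 + 1)
        (2, 4, 32),          # 2 (15 + 1)
        (11, 4, 2732),       # 2 (1365 + 1)
    ])
    def test_design_size(self, d, p, n_nodes):
        joint = IndependentJoint([Uniform(0, 1)] * d)
        basis = pce.build_basis(joint, p)
        nodes = pce.collocation_design(basis, joint)
        assert nodes.shape == (n_nodes, d)

    def test_constant_model(self, uniform2):
        basis = pce.build_basis(uniform2, 2)
        nodes = pce.collocation_design(basis, uniform2)
        e = pce.fit_collocation(nodes, np.full(nodes.shape[0], 3.0), basis)
        assert e.coefficients[0, 0] == pytest.approx(3.0, abs=1e-8)
        assert np.max(np.abs(e.coefficients[1:])) < 1e-8

    def test_polynomial_reproduced_exactly(self, uniform2):
        basis = pce.build_basis(uniform2, 2)
        nodes = pce.collocation_design(basis, uniform2)
        Y = nodes[:, 0] + nodes[:, 1]**2
        e = pce.fit_collocation(nodes, Y, basis)
        probe = np.random.default_rng(3).uniform(size=(100, 2))
        assert np.max(np.abs(e.evaluate(probe)[:, 0]
                             - (probe[:, 0] + probe[:, 1]**2))) < 1e-6

    def test_invalid_rows_dropped(self, uniform2):
        basis = pce.build_basis(uniform2, 1)
        nodes = pce.collocation_design(basis, uniform2)
        Y = np.full(nodes.shape[0], 3.0)
        valid = np.ones(nodes.shape[0], bool)
        valid[::10] = False
        with pytest.warns(UserWarning):
            e = pce.fit_collocation(nodes, Y, basis, valid=valid)
        assert e.coefficients[0, 0] == pytest.approx(3.0, abs=1e-8)

    def test_underdetermined_rejected(self, uniform2):
        basis = pce.build_basis(uniform2, 3)
        nodes = pce.collocation_design(basis, uniform2)[:5]
        with pytest.raises(ValueError, match="valid evaluations"):
            pce.fit_collocation(nodes, np.zeros(5), basis)

    def test_fixed_penalty_matches_gcv_on_clean_data(self, uniform2):
        basis = pce.build_basis(uniform2, 2)
        nodes = pce.collocation_design(basis, uniform2)
        Y = 2.0 * nodes[:, 0] - nodes[:, 1]
        e1 = pce.fit_collocation(nodes, Y, basis, regularization="gcv")
        e2 = pce.fit_collocation(nodes, Y, basis, regularization=0.0)
        assert np.max(np.abs(e1.coefficients - e2.coefficients)) < 1e-7


class TestSpectral:
    def test_weights_normalized(self):
        joint = IndependentJoint([Uniform(0, 2), Normal(0, 1), Uniform(-1, 1),
                                  Uniform(3, 4), Normal(1, 2)])
        rule = pce.quadrature_design(joint, 3)   # sparse path, d > 4
        assert rule.weights.sum() == pytest.approx(1.0, abs=1e-10)
        # the sparse rule must integrate low-degree polynomials exactly
        x = rule.nodes
        est = np.sum(rule.weights * (x[:, 0] ** 2 * x[:, 4]))
        exact = (4 / 3) * 1.0   # E[X0^2] * E[X4], X0~U(0,2), X4~N(1,2)
        assert est == pytest.approx(exact, abs=1e-8)

    def test_projection_matches_analytic_legendre(self):
        # Y = Q^2 on U(0,1): coefficients in the orthonormal shifted
        # Legendre basis are (1/3, sqrt(3)/6, sqrt(5)/30)
        joint = IndependentJoint([Uniform(0, 1)])
        basis = pce.build_basis(joint, 2, max_univariate_order=6)
        rule = pce.quadrature_design(joint, 4, basis=basis)
        e = pce.fit_spectral(rule, rule.nodes[:, 0]**2, basis)
        assert e.coefficients[:, 0] == pytest.approx(
            [1 / 3, math.sqrt(3) / 6, math.sqrt(5) / 30], abs=1e-10)

    def test_constant_model(self):
        joint = IndependentJoint([Uniform(0, 1)])
        basis = pce.build_basis(joint, 2, max_univariate_order=6)
        rule = pce.quadrature_design(joint, 4, basis=basis)
        e = pce.fit_spectral(rule, np.full(rule.nodes.shape[0], 7.0), basis)
        assert e.coefficients[0, 0] == pytest.approx(7.0)
        assert np.max(np.abs(e.coefficients[1:])) < 1e-10

    def test_invalid_evaluations_rejected(self):
        joint = IndependentJoint([Uniform(0, 1)])
        basis = pce.build_basis(joint, 2, max_univariate_order=6)
        rule = pce.quadrature_design(joint, 4, basis=basis)
        Y = np.full(rule.nodes.shape[0], 1.0)
        Y[0] = np.nan
        with pytest.raises(ValueError, match="collocation"):
            pce.fit_spectral(rule, Y, basis)


class TestStatistics:
    def test_constant_has_zero_variance(self, uniform2):
        basis = pce.build_basis(uniform2, 2)
        nodes = pce.collocation_design(basis, uniform2)
        e = pce.fit_collocation(nodes, np.full(nodes.shape[0], 3.0), basis)
        mean, var = pce.expansion_statistics(e)
        assert mean[0] == pytest.approx(3.0)
        assert var[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_identity_moments(self):
        joint = IndependentJoint([Uniform(0, 1)])
        basis = pce.build_basis(joint, 1)
        nodes = pce.collocation_design(basis, joint)
        e = pce.fit_collocation(nodes, nodes[:, 0], basis)
        mean, var = pce.expansion_statistics(e)
        assert mean[0] == pytest.approx(0.5, abs=1e-8)
        assert var[0] == pytest.approx(1 / 12, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_exactness_on_random_low_degree_polynomials(self, seed):
        # any total-degree <= p polynomial must yield exact moments,
        # checked against a high-order quadrature oracle
        rng = np.random.default_rng(seed)
        joint = IndependentJoint([Uniform(-1, 2), Normal(0.5, 1.5)])
        p = 3
        coeffs = rng.normal(size=(p + 1, p + 1))
        mask = np.add.outer(range(p + 1), range(p + 1)) > p
        coeffs[mask] = 0.0

        def poly(x, y):
            return sum(coeffs[i, j] * x**i * y**j
                       for i in range(p + 1) for j in range(p + 1))

        basis = pce.build_basis(joint, p, max_univariate_order=12)
        nodes = pce.collocation_design(basis, joint)
        e = pce.fit_collocation(nodes, poly(nodes[:, 0], nodes[:, 1]), basis)
        mean, var = pce.expansion_statistics(e)

        oracle = pce.quadrature_design(joint, 12, basis=basis)
        vals = poly(oracle.nodes[:, 0], oracle.nodes[:, 1])
        mean_o = np.sum(oracle.weights * vals)
        var_o = np.sum(oracle.weights * (vals - mean_o)**2)
        assert mean[0] == pytest.approx(mean_o, abs=1e-8 * max(1, abs(mean_o)))
        assert var[0] == pytest.approx(var_o, rel=1e-8, abs=1e-8)


class TestSobol:
    def test_additive_model(self, uniform2):
        basis = pce.build_basis(uniform2, 2)
        nodes = pce.collocation_design(basis, uniform2)
        e = pce.fit_collocation(nodes, nodes[:, 0] + 2 * nodes[:, 1], basis)
        S, ST, S_avg, ST_avg = pce.expansion_sobol(e)
        assert S[:, 0] == pytest.approx([0.2, 0.8], abs=1e-6)
        assert ST[:, 0] == pytest.approx([0.2, 0.8], abs=1e-6)
        assert S_avg == pytest.approx([0.2, 0.8], abs=1e-6)

    def test_pure_interaction(self):
        joint = IndependentJoint([Uniform(-1, 1), Uniform(-1, 1)])
        basis = pce.build_basis(joint, 2)
        nodes = pce.collocation_design(basis, joint)
        e = pce.fit_collocation(nodes, nodes[:, 0] * nodes[:, 1], basis)
        S, ST, *_ = pce.expansion_sobol(e)
        assert S[:, 0] == pytest.approx([0.0, 0.0], abs=1e-8)
        assert ST[:, 0] == pytest.approx([1.0, 1.0], abs=1e-8)

    def test_single_parameter(self):
        joint = IndependentJoint([Uniform(0, 1)])
        basis = pce.build_basis(joint, 2)
        nodes = pce.collocation_design(basis, joint)
        e = pce.fit_collocation(nodes, nodes[:, 0]**2, basis)
        S, ST, *_ = pce.expansion_sobol(e)
        assert S[0, 0] == pytest.approx(1.0) and ST[0, 0] == pytest.approx(1.0)

    def test_zero_variance_flagged_not_crashing(self, uniform2):
        basis = pce.build_basis(uniform2, 2)
        nodes = pce.collocation_design(basis, uniform2)
        Y = np.column_stack([np.full(nodes.shape[0], 1.0),
                             nodes[:, 0]])          # one dead, one live column
        e = pce.fit_collocation(nodes, Y, basis)
        S, ST, S_avg, ST_avg = pce.expansion_sobol(e)
        assert np.all(np.isnan(S[:, 0])) and np.all(np.isfinite(S[:, 1]))
        assert np.all(np.isfinite(S_avg))


class TestSurrogatePercentiles:
    def test_constant(self, uniform2):
        basis = pce.build_basis(uniform2, 1)
        nodes = pce.collocation_design(basis, uniform2)
        e = pce.fit_collocation(nodes, np.full(nodes.shape[0], 2.5), basis)
        pcts = pce.surrogate_percentiles(e, uniform2, n=500)
        assert pcts[0, 0] == pytest.approx(2.5) and pcts[1, 0] == pytest.approx(2.5)

    def test_uniform_identity_quantiles(self):
        joint = IndependentJoint([Uniform(0, 1)])
        basis = pce.build_basis(joint, 1)
        nodes = pce.collocation_design(basis, joint)
        e = pce.fit_collocation(nodes, nodes[:, 0], basis)
        pcts = pce.surrogate_percentiles(e, joint)
        assert pcts[0, 0] == pytest.approx(0.05, abs=0.01)
        assert pcts[1, 0] == pytest.approx(0.95, abs=0.01)
        assert np.all(pcts[0] <= pcts[1])
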