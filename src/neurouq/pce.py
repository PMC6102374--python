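"""Polynomial chaos expansions: orthonormal bases, fitting, statistics.

The model output Y(t) is approximated by a truncated expansion

    Y(t) ~= sum_n c_n(t) * phi_n(Q),

where the phi_n are multivariate polynomials orthonormal with respect to
the joint parameter density and the c_n are coefficients fitted either by
regression at collocation nodes (point collocation, robust to invalid
model evaluations) or by quadrature (pseudo-spectral projection, which
requires every evaluation to be valid).  Mean, variance, percentiles and
Sobol sensitivity indices then follow directly from the coefficients.

Univariate orthonormal families come from the classical three-term
recurrences (Legendre for uniform marginals, probabilists' Hermite for
normal marginals); any other marginal with an inverse CDF is handled by
the discretized Stieltjes procedure.  Internally every basis is
normalized to gamma_n = E[phi_n^2] = 1, which conditions the regression;
the gamma array is retained in the reported expansion for completeness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy import linalg

from .distributions import (Distribution, IndependentJoint, JointDistribution,
                            Normal, Uniform, hammersley_nodes)

__all__ = [
    "multi_indices",
    "OrthonormalBasis",
    "PolynomialExpansion",
    "QuadratureRule",
    "build_basis",
    "collocation_design",
    "fit_collocation",
    "quadrature_design",
    "fit_spectral",
    "expansion_statistics",
    "expansion_sobol",
    "surrogate_percentiles",
]


# ---------------------------------------------------------------------------
# univariate orthonormal polynomials
# ---------------------------------------------------------------------------

class UnivariateOrthonormal:
    """Orthonormal polynomial family for one marginal distribution.

    Stores the three-term recurrence in the monic parameterization
    (alpha_k, beta_k) together with an affine standardization of the
    variable, and evaluates the *orthonormal* polynomials by the
    normalized recurrence

        sqrt(beta_{k+1}) p_{k+1}(x) = (x - alpha_k) p_k(x)
                                      - sqrt(beta_k) p_{k-1}(x).
    """

    def __init__(self, dist: Distribution, max_order: int):
        self.dist = dist
        self.max_order = max_order
        # affine map x -> (x - shift) / scale applied before the recurrence,
        # keeping the recurrence coefficients in a well-conditioned range
        if isinstance(dist, Uniform):
            self.shift = 0.5 * (dist.lower + dist.upper)
            self.scale = 0.5 * (dist.upper - dist.lower)
            k = np.arange(max_order + 2, dtype=float)
            self.alpha = np.zeros(max_order + 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = k**2 / (4.0 * k**2 - 1.0)
            beta[0] = 1.0          # beta_0 = total mass of the measure
            self.beta = beta
        elif isinstance(dist, Normal):
            self.shift = dist.mu
            self.scale = dist.sigma
            self.alpha = np.zeros(max_order + 2)
            self.beta = np.arange(max_order + 2, dtype=float)
            self.beta[0] = 1.0
        else:
            self.shift = 0.0
            self.scale = 1.0
            self.alpha, self.beta = self._stieltjes(dist, max_order + 1)

    @staticmethod
    def _stieltjes(dist: Distribution, n: int, quad_points: int = 600):
        """Discretized Stieltjes recurrence for an arbitrary marginal.

        The measure is discretized through its inverse CDF: for any f,
        E[f(X)] = int_0^1 f(F^{-1}(u)) du, evaluated with a Gauss-Legendre
        rule in u.  Only the inverse CDF is needed, not the density.
        """
        t, w = np.polynomial.legendre.leggauss(quad_points)
        u = 0.5 * (t + 1.0)
        w = 0.5 * w
        x = np.asarray(dist.ppf(u), float)
        if not np.all(np.isfinite(x)):
            raise ValueError(
                "marginal distribution has a non-finite inverse CDF on the "
                "interior of (0, 1); cannot build an orthogonal basis")
        alpha = np.zeros(n + 1)
        beta = np.zeros(n + 1)
        beta[0] = 1.0
        p_prev = np.zeros_like(x)
        p_cur = np.ones_like(x)
        norm_cur = 1.0
        for k in range(n + 1):
            alpha[k] = np.sum(w * x * p_cur**2) / norm_cur
            if k == n:
                break
            p_next = (x - alpha[k]) * p_cur - (beta[k] if k > 0 else 0.0) * p_prev
            norm_next = np.sum(w * p_next**2)
            if norm_next <= 0:
                raise ValueError(
                    f"Stieltjes recurrence broke down at order {k + 1}; "
                    "the marginal may be (nearly) discrete")
            beta[k + 1] = norm_next / norm_cur
            p_prev, p_cur = p_cur, p_next
            norm_cur = norm_next
        return alpha, beta

    def values(self, x, order: int) -> np.ndarray:
        """Table of orthonormal polynomial values, shape (len(x), order+1)."""
        x = (np.asarray(x, float) - self.shift) / self.scale
        out = np.empty(x.shape + (order + 1,))
        out[..., 0] = 1.0
        if order >= 1:
            sqb = np.sqrt(self.beta[:order + 1])
            out[..., 1] = (x - self.alpha[0]) / sqb[1]
            for k in range(1, order):
                out[..., k + 1] = ((x - self.alpha[k]) * out[..., k]
                                   - sqb[k] * out[..., k - 1]) / sqb[k + 1]
        return out

    def gauss_rule(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        """m-point Gauss rule for the marginal (nodes in original units)."""
        if m > self.max_order + 1:
            raise ValueError("recurrence not built deep enough for this rule")
        d = self.alpha[:m].copy()
        e = np.sqrt(self.beta[1:m])
        vals, vecs = linalg.eigh_tridiagonal(d, e)
        nodes = vals * self.scale + self.shift
        weights = vecs[0, :]**2          # beta_0 = 1 (probability measure)
        return nodes, weights


# ---------------------------------------------------------------------------
# multivariate basis
# ---------------------------------------------------------------------------

def multi_indices(d: int, p: int) -> np.ndarray:
    """All multi-indices of dimension d with total degree <= p.

    Ordered graded lexicographically (by total degree, then
    lexicographic), giving a deterministic coefficient layout.  The count
    is C(d + p, p).
    """
    rows = [np.zeros(d, dtype=int)]
    for degree in range(1, p + 1):
        block = []
        for combo in combinations_with_replacement(range(d), degree):
            idx = np.zeros(d, dtype=int)
            for dim in combo:
                idx[dim] += 1
            block.append(idx)
        block.sort(key=lambda a: tuple(-a))  # lexicographic within a degree
        rows.extend(block)
    return np.array(rows, dtype=int)


@dataclass
class OrthonormalBasis:
    """Multivariate orthonormal polynomial basis of total degree <= order."""

    dim: int
    order: int
    indices: np.ndarray                       # (Np, d) multi-indices
    univariate: list[UnivariateOrthonormal]   # one family per dimension
    gamma: np.ndarray                         # E[phi_n^2]; all ones here

    @property
    def size(self) -> int:
        return self.indices.shape[0]

    def evaluate(self, nodes: np.ndarray) -> np.ndarray:
        """Design matrix of basis values at nodes, shape (n_nodes, Np)."""
        nodes = np.atleast_2d(np.asarray(nodes, float))
        tables = [self.univariate[j].values(nodes[:, j], self.order)
                  for j in range(self.dim)]
        A = np.ones((nodes.shape[0], self.size))
        for n, idx in enumerate(self.indices):
            for j in np.nonzero(idx)[0]:
                A[:, n] *= tables[j][:, idx[j]]
        return A


def build_basis(joint: JointDistribution, order: int,
                max_univariate_order: int | None = None) -> OrthonormalBasis:
    """Orthonormal basis for an independent joint, total degree <= order."""
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if joint.dependent:
        raise ValueError(
            "basis construction requires independent coordinates; map a "
            "dependent joint through the Rosenblatt transformation first")
    if not isinstance(joint, IndependentJoint):
        raise TypeError("expected an IndependentJoint")
    deep = max(order, max_univariate_order or 0) + 4
    univariate = [UnivariateOrthonormal(m, deep) for m in joint.marginals]
    indices = multi_indices(joint.dim, order)
    gamma = np.ones(indices.shape[0])
    return OrthonormalBasis(joint.dim, order, indices, univariate, gamma)


@dataclass
class PolynomialExpansion:
    """A fitted expansion: basis plus coefficient matrix (Np, n_outputs)."""

    basis: OrthonormalBasis
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        if self.coefficients.shape[0] != self.basis.size:
            raise ValueError("coefficient matrix must have one row per basis term")

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Surrogate evaluations at parameter points, shape (n_points, T)."""
        return self.basis.evaluate(points) @ self.coefficients


@dataclass
class QuadratureRule:
    nodes: np.ndarray      # (M, d)
    weights: np.ndarray    # (M,)


# ---------------------------------------------------------------------------
# point collocation
# ---------------------------------------------------------------------------

def collocation_design(basis: OrthonormalBasis,
                       joint: JointDistribution) -> np.ndarray:
    """Deterministic collocation nodes, Ns = 2(Np + 1).

    Hammersley points in the unit hypercube mapped through the joint's
    inverse Rosenblatt transformation, so any joint (including dependent
    ones, for which the basis lives on the base variables) is supported.
    """
    ns = 2 * (basis.size + 1)
    u = hammersley_nodes(ns, basis.dim)
    return np.atleast_2d(joint.rosenblatt_inverse(u))


def _gcv_ridge(A: np.ndarray, Y: np.ndarray):
    """Tikhonov regression with the penalty chosen by generalized
    cross-validation over a log grid (including zero)."""
    m = A.shape[0]
    U, s, Vt = linalg.svd(A, full_matrices=False)
    if s[0] <= 0:
        raise linalg.LinAlgError("design matrix is identically zero")
    UtY = U.T @ Y
    yy = np.sum(Y * Y)
    lams = np.concatenate(([0.0], s[0]**2 * np.logspace(-16, -2, 15)))
    best, best_lam = np.inf, 0.0
    for lam in lams:
        f = s**2 / (s**2 + lam)          # shrinkage factors
        # residual sum of squares without forming the fitted values
        rss = yy - np.sum((2 * f - f**2)[:, None] * UtY**2)
        dof = m - np.sum(f)
        if dof <= 0:
            continue
        gcv = m * max(rss, 0.0) / dof**2
        if gcv < best:
            best, best_lam = gcv, lam
    f = s / (s**2 + best_lam)
    coeff = Vt.T @ (f[:, None] * UtY)
    return coeff, best_lam


def fit_collocation(nodes: np.ndarray, values: np.ndarray,
                    basis: OrthonormalBasis,
                    valid: np.ndarray | None = None,
                    regularization="gcv") -> PolynomialExpansion:
    """Fit expansion coefficients by regularized regression.

    Invalid evaluations (``valid`` mask False, or any non-finite entry)
    are dropped from the regression; point collocation is robust to this
    as long as at least Np valid rows remain.  ``regularization`` is
    either ``"gcv"`` (Tikhonov penalty selected by generalized
    cross-validation) or a fixed non-negative penalty; large design
    matrices are fitted through the normal equations in the latter case.
    """
    nodes = np.atleast_2d(np.asarray(nodes, float))
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[:, None]
    if valid is None:
        valid = np.all(np.isfinite(values), axis=1)
    else:
        valid = np.asarray(valid, bool) & np.all(np.isfinite(values), axis=1)
    n_valid = int(valid.sum())
    if n_valid < basis.size:
        raise ValueError(
            f"only {n_valid} valid evaluations for {basis.size} basis terms; "
            "regression is underdetermined")
    if n_valid < 2 * (basis.size + 1):
        warnings.warn(
            f"{n_valid} valid evaluations is below the recommended "
            f"2(Np+1) = {2 * (basis.size + 1)}; coefficients may be noisy",
            stacklevel=2)
    if regularization == "gcv":
        A = basis.evaluate(nodes[valid])
        coeff, _ = _gcv_ridge(A, values[valid])
    else:
        lam = float(regularization)
        if lam < 0:
            raise ValueError("regularization penalty must be >= 0")
        # accumulate the normal equations in row chunks so that very
        # large designs never materialize the full design matrix
        vnodes = nodes[valid]
        vvalues = values[valid]
        G = np.zeros((basis.size, basis.size))
        rhs = np.zeros((basis.size, vvalues.shape[1]))
        chunk = max(1, int(2**24 // max(basis.size, 1)))
        for start in range(0, vnodes.shape[0], chunk):
            A_c = basis.evaluate(vnodes[start:start + chunk])
            G += A_c.T @ A_c
            rhs += A_c.T @ vvalues[start:start + chunk]
        jitter = lam if lam > 0 else 1e-12 * np.trace(G) / basis.size
        G[np.diag_indices_from(G)] += jitter
        try:
            c, low = linalg.cho_factor(G, check_finite=False)
            coeff = linalg.cho_solve((c, low), rhs, check_finite=False)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                f"collocation design is rank deficient ({n_valid} valid rows, "
                f"{basis.size} basis terms)") from err
    return PolynomialExpansion(basis, coeff)


# ---------------------------------------------------------------------------
# pseudo-spectral projection
# ---------------------------------------------------------------------------

def _tensor_rule(basis: OrthonormalBasis, points_per_dim: int) -> QuadratureRule:
    rules = [uni.gauss_rule(points_per_dim) for uni in basis.univariate]
    grids = np.meshgrid(*[r[0] for r in rules], indexing="ij")
    wgrids = np.meshgrid(*[r[1] for r in rules], indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    weights = np.ones(nodes.shape[0])
    for w in wgrids:
        weights *= w.ravel()
    return QuadratureRule(nodes, weights)


def _smolyak_rule(basis: OrthonormalBasis, level: int) -> QuadratureRule:
    """Smolyak combination of univariate Gauss rules.

    The 1-D rule at level i uses i points; the sparse grid combines all
    tensor products with d <= |i|_1 <= d + level using the standard
    combination coefficients.  Gauss rules are not nested, so duplicate
    nodes are merged by rounding.
    """
    d = basis.dim
    node_map: dict[tuple, float] = {}
    cache = {}

    def rule1d(j, m):
        if (j, m) not in cache:
            cache[(j, m)] = basis.univariate[j].gauss_rule(m)
        return cache[(j, m)]

    def levels(total, dims):
        if dims == 1:
            yield (total,)
            return
        for first in range(1, total - dims + 2):
            for rest in levels(total - first, dims - 1):
                yield (first,) + rest

    for q in range(max(d, d + level - d + 1), d + level + 1):
        coeff = (-1) ** (d + level - q) * math.comb(d - 1, d + level - q)
        if coeff == 0:
            continue
        for combo in levels(q, d):
            pts = [rule1d(j, combo[j]) for j in range(d)]
            grids = np.meshgrid(*[p[0] for p in pts], indexing="ij")
            wgrids = np.meshgrid(*[p[1] for p in pts], indexing="ij")
            nodes = np.stack([g.ravel() for g in grids], axis=1)
            weights = np.ones(nodes.shape[0]) * coeff
            for w in wgrids:
                weights *= w.ravel()
            for node, w in zip(nodes, weights):
                key = tuple(np.round(node, 12))
                node_map[key] = node_map.get(key, 0.0) + w
    nodes = np.array(sorted(node_map.keys()))
    weights = np.array([node_map[tuple(n)] for n in nodes])
    return QuadratureRule(nodes, weights)


def quadrature_design(joint: JointDistribution, order: int,
                      basis: OrthonormalBasis | None = None) -> QuadratureRule:
    """Quadrature rule exact (at least) to polynomial degree 2*order - 1.

    Gaussian tensor product for d <= 4, a sparse Smolyak-combination
    Gaussian grid for higher dimensions.  Weights are normalized so they
    integrate constants to one.
    """
    if basis is None:
        basis = build_basis(joint, 0, max_univariate_order=order + 2)
    if joint.dim <= 4:
        rule = _tensor_rule(basis, order)
    else:
        rule = _smolyak_rule(basis, order)
    total = rule.weights.sum()
    if abs(total) < 1e-8:
        raise ValueError("degenerate quadrature rule: weights sum to ~0")
    rule.weights = rule.weights / total
    return rule


def fit_spectral(rule: QuadratureRule, values: np.ndarray,
                 basis: OrthonormalBasis,
                 valid: np.ndarray | None = None) -> PolynomialExpansion:
    """Pseudo-spectral projection: c_n = sum_k w_k Y(x_k) phi_n(x_k) / gamma_n.

    Unlike point collocation, spectral projection cannot tolerate invalid
    evaluations: every quadrature node carries a fixed weight.
    """
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[:, None]
    finite = np.all(np.isfinite(values), axis=1)
    if valid is not None:
        finite &= np.asarray(valid, bool)
    if not np.all(finite):
        raise ValueError(
            f"{int((~finite).sum())} invalid evaluations: pseudo-spectral "
            "projection requires all nodes to be valid; use point "
            "collocation instead")
    A = basis.evaluate(rule.nodes)
    coeff = (A * rule.weights[:, None]).T @ values / basis.gamma[:, None]
    return PolynomialExpansion(basis, coeff)


# ---------------------------------------------------------------------------
# statistics from the expansion
# ---------------------------------------------------------------------------

def expansion_statistics(e: PolynomialExpansion):
    """Mean and variance per output point.

    mean = c_0 and variance = sum_{n>=1} gamma_n c_n^2; with the
    orthonormal basis used here gamma_n = 1.
    """
    c = e.coefficients
    mean = c[0].copy()
    var = np.sum(e.basis.gamma[1:, None] * c[1:]**2, axis=0)
    return mean, var


def expansion_sobol(e: PolynomialExpansion, var_tol: float = 1e-14):
    """First- and total-order Sobol indices from the expansion.

    S_i sums gamma_n c_n^2 over terms involving only coordinate i;
    S_Ti over all terms involving coordinate i; both normalized by the
    total variance.  Output points with (numerically) zero variance have
    undefined indices and are reported as NaN.  Also returns the
    time-averaged indices over the points where they are defined.
    """
    idx = e.basis.indices
    c2 = e.basis.gamma[:, None] * e.coefficients**2
    total = np.sum(c2[1:], axis=0)
    d = e.basis.dim
    T = c2.shape[1]
    S = np.full((d, T), np.nan)
    ST = np.full((d, T), np.nan)
    # threshold relative to the largest variance: points whose variance is
    # negligible on the output's own scale carry no meaningful indices
    tol = max(var_tol, 1e-10 * float(total.max(initial=0.0)))
    defined = total > tol
    if np.any(defined):
        for i in range(d):
            only_i = (idx[:, i] > 0) & (np.sum(idx > 0, axis=1) == 1)
            any_i = idx[:, i] > 0
            S[i, defined] = np.sum(c2[only_i], axis=0)[defined] / total[defined]
            ST[i, defined] = np.sum(c2[any_i], axis=0)[defined] / total[defined]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        S_avg = np.nanmean(S, axis=1)
        ST_avg = np.nanmean(ST, axis=1)
    return S, ST, S_avg, ST_avg


def surrogate_percentiles(e: PolynomialExpansion, joint: JointDistribution,
                          levels=(0.05, 0.95), n: int = 10**4) -> np.ndarray:
    """Empirical percentiles of the surrogate under the joint.

    The expansion is evaluated at n Hammersley points mapped through the
    joint and the percentiles are read off per output point.  Returns an
    array of shape (len(levels), T).
    """
    u = hammersley_nodes(n, joint.dim)
    q = np.atleast_2d(joint.rosenblatt_inverse(u))
    samples = e.evaluate(q)
    return np.quantile(samples, np.asarray(levels), axis=0)
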