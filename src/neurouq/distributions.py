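"""Uncertain parameters, joint distributions, low-discrepancy sampling.

A model parameter is either *fixed* (a plain number) or *uncertain* (it
carries a univariate probability distribution).  The uncertain parameters
of a model are collected, in declaration order, into a joint distribution
over which all uncertainty propagation is performed.  Joints may be fully
independent (product form) or *dependent*, specified constructively: each
coordinate's conditional distribution may depend on the values drawn for
the preceding coordinates.  The Rosenblatt transformation maps such a
joint to and from the independent unit hypercube, which is what both the
polynomial-chaos and the Saltelli samplers operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Distribution",
    "Uniform",
    "Normal",
    "PointMass",
    "ScipyDistribution",
    "uniform_pm",
    "Parameter",
    "ParameterSet",
    "JointDistribution",
    "IndependentJoint",
    "ConditionalJoint",
    "make_joint",
    "hammersley_nodes",
]

# Primes used for the radical-inverse coordinates of the Hammersley set.
_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59,
           61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113)


class Distribution:
    """Contract for a univariate distribution.

    Subclasses provide the inverse CDF (``ppf``), CDF, density, support
    bounds and the first two moments.  The inverse CDF must be monotone
    non-decreasing on [0, 1].
    """

    def ppf(self, u):
        raise NotImplementedError

    def cdf(self, x):
        raise NotImplementedError

    def pdf(self, x):
        raise NotImplementedError

    @property
    def support(self) -> tuple[float, float]:
        raise NotImplementedError

    @property
    def mean(self) -> float:
        raise NotImplementedError

    @property
    def var(self) -> float:
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator):
        return self.ppf(rng.uniform(size=n))


class ScipyDistribution(Distribution):
    """Adapter wrapping a frozen ``scipy.stats`` distribution."""

    def __init__(self, frozen):
        self._d = frozen

    def ppf(self, u):
        return self._d.ppf(u)

    def cdf(self, x):
        return self._d.cdf(x)

    def pdf(self, x):
        return self._d.pdf(x)

    @property
    def support(self):
        lo, hi = self._d.support()
        return float(lo), float(hi)

    @property
    def mean(self):
        return float(self._d.mean())

    @property
    def var(self):
        return float(self._d.var())


class Uniform(ScipyDistribution):
    """Uniform distribution on [lower, upper]."""

    def __init__(self, lower: float, upper: float):
        if not upper > lower:
            raise ValueError(f"need upper > lower, got [{lower}, {upper}]")
        self.lower = float(lower)
        self.upper = float(upper)
        super().__init__(stats.uniform(loc=lower, scale=upper - lower))

    def ppf(self, u):
        # direct affine form; avoids scipy call overhead in hot loops
        return self.lower + (self.upper - self.lower) * np.asarray(u, float)

    def cdf(self, x):
        x = np.asarray(x, float)
        return np.clip((x - self.lower) / (self.upper - self.lower), 0.0, 1.0)

    def __repr__(self):
        return f"Uniform({self.lower!r}, {self.upper!r})"


class Normal(ScipyDistribution):
    """Normal distribution with mean mu and standard deviation sigma."""

    def __init__(self, mu: float, sigma: float):
        if not sigma > 0:
            raise ValueError("sigma must be positive")
        self.mu = float(mu)
        self.sigma = float(sigma)
        super().__init__(stats.norm(loc=mu, scale=sigma))

    def __repr__(self):
        return f"Normal({self.mu!r}, {self.sigma!r})"


class PointMass(Distribution):
    """Degenerate distribution concentrated at a single value."""

    def __init__(self, value: float):
        self.value = float(value)

    def ppf(self, u):
        return np.full_like(np.asarray(u, float), self.value)

    def cdf(self, x):
        return (np.asarray(x, float) >= self.value).astype(float)

    def pdf(self, x):
        raise ValueError("point mass has no density")

    @property
    def support(self):
        return self.value, self.value

    @property
    def mean(self):
        return self.value

    @property
    def var(self):
        return 0.0

    def __repr__(self):
        return f"PointMass({self.value!r})"


def uniform_pm(center: float, fraction: float) -> Distribution:
    """Uniform distribution spanning ``center`` +/- ``fraction`` * |center|.

    The conventional way to express "a parameter is uncertain within
    +/-10% of its nominal value".  ``fraction = 0`` yields a point mass,
    i.e. the parameter is treated as fixed.  A zero center with a positive
    fraction is rejected: the interval would silently collapse to zero
    width, hiding the parameter from the analysis; supply an explicit
    interval instead.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    if fraction == 0:
        return PointMass(center)
    if center == 0:
        raise ValueError(
            "uniform_pm around 0 gives a zero-width interval; "
            "use an explicit Uniform(a, b) instead")
    half = abs(center) * fraction
    return Uniform(center - half, center + half)


@dataclass
class Parameter:
    """A named model parameter: a fixed value, a distribution, or both.

    A parameter carrying a distribution is *uncertain*; one carrying only
    a value is fixed.  An uncertain parameter may additionally declare a
    nominal value, which one-at-a-time screening uses as the fallback
    when the parameter is held fixed.
    """

    name: str
    value: float | None = None
    distribution: Distribution | None = None

    def __post_init__(self):
        if self.value is None and self.distribution is None:
            raise ValueError(
                f"parameter {self.name!r}: give a fixed value and/or a "
                "distribution")

    @property
    def uncertain(self) -> bool:
        return self.distribution is not None


class ParameterSet:
    """Ordered collection of named parameters.

    Accepts either ``Parameter`` instances or a mapping
    ``name -> value-or-Distribution``.  Declaration order defines the
    coordinate order of the joint distribution.  An optional explicit
    joint multivariate ``distribution`` overrides the product of the
    marginals (used for dependent parameters).
    """

    def __init__(self,
                 parameters: Sequence[Parameter] | Mapping[str, object],
                 distribution: "JointDistribution | None" = None):
        if isinstance(parameters, Mapping):
            params = []
            for name, spec in parameters.items():
                if isinstance(spec, Distribution):
                    params.append(Parameter(name, distribution=spec))
                else:
                    params.append(Parameter(name, value=float(spec)))
            parameters = params
        self.parameters: list[Parameter] = list(parameters)
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        self.distribution = distribution
        if distribution is not None:
            n_unc = sum(p.uncertain for p in self.parameters)
            if distribution.dim != n_unc:
                raise ValueError(
                    f"joint distribution has dimension {distribution.dim} "
                    f"but there are {n_unc} uncertain parameters")

    def __iter__(self):
        return iter(self.parameters)

    def __getitem__(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def uncertain_names(self) -> list[str]:
        return [p.name for p in self.parameters if p.uncertain]

    @property
    def fixed_values(self) -> dict[str, float]:
        return {p.name: p.value for p in self.parameters if not p.uncertain}

    def fallback_values(self) -> dict[str, float]:
        """Nominal value for every parameter, used by one-at-a-time
        screening.  An uncertain parameter falls back to its declared
        nominal value if it has one, else to its marginal mean."""
        out = {}
        for p in self.parameters:
            if p.value is not None:
                out[p.name] = p.value
            else:
                out[p.name] = p.distribution.mean
        return out

    @classmethod
    def from_config(cls, config: Mapping[str, Mapping[str, object]]) -> "ParameterSet":
        """Build a ParameterSet from a flat config mapping.

        Each entry maps a parameter name to one of::

            {"fixed": x}
            {"uniform": [a, b]}
            {"uniform_pm": [center, fraction]}
            {"normal": [mu, sigma]}
        """
        params = []
        for name, spec in config.items():
            if not isinstance(spec, Mapping) or len(spec) != 1:
                raise ValueError(f"parameter {name!r}: expected a single-key "
                                 "mapping, got {spec!r}")
            (kind, args), = spec.items()
            if kind == "fixed":
                params.append(Parameter(name, value=float(args)))
            elif kind == "uniform":
                a, b = args
                params.append(Parameter(name, distribution=Uniform(a, b)))
            elif kind == "uniform_pm":
                c, f = args
                params.append(Parameter(name, distribution=uniform_pm(c, f)))
            elif kind == "normal":
                mu, sigma = args
                params.append(Parameter(name, distribution=Normal(mu, sigma)))
            else:
                raise ValueError(f"parameter {name!r}: unknown kind {kind!r}")
        return cls(params)


class JointDistribution:
    """Contract for a d-dimensional joint distribution.

    ``rosenblatt_inverse`` maps points of the open unit hypercube to
    parameter space; ``rosenblatt_forward`` is its inverse.  Both operate
    on arrays of shape (n, d) or (d,).
    """

    dim: int
    dependent: bool = False

    def rosenblatt_inverse(self, u: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def rosenblatt_forward(self, q: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.rosenblatt_inverse(
            np.clip(rng.uniform(size=(n, self.dim)), 1e-12, 1 - 1e-12))

    def _check_u(self, u):
        u = np.atleast_2d(np.asarray(u, float))
        if u.shape[-1] != self.dim:
            raise ValueError(f"expected dimension {self.dim}, got {u.shape[-1]}")
        if np.any(u <= 0.0) or np.any(u >= 1.0):
            raise ValueError("hypercube point must lie strictly inside (0, 1)^d")
        return u


class IndependentJoint(JointDistribution):
    """Product joint of independent univariate marginals."""

    dependent = False

    def __init__(self, marginals: Sequence[Distribution]):
        if not marginals:
            raise ValueError("need at least one marginal")
        self.marginals = list(marginals)
        self.dim = len(self.marginals)

    def rosenblatt_inverse(self, u):
        squeeze = np.asarray(u).ndim == 1
        u = self._check_u(u)
        q = np.empty_like(u)
        for i, dist in enumerate(self.marginals):
            q[:, i] = dist.ppf(u[:, i])
        return q[0] if squeeze else q

    def rosenblatt_forward(self, q):
        squeeze = np.asarray(q).ndim == 1
        q = np.atleast_2d(np.asarray(q, float))
        u = np.empty_like(q)
        for i, dist in enumerate(self.marginals):
            u[:, i] = dist.cdf(q[:, i])
        return u[0] if squeeze else u

    def pdf(self, q):
        """Joint density: product of the marginal densities."""
        q = np.atleast_2d(np.asarray(q, float))
        out = np.ones(q.shape[0])
        for i, dist in enumerate(self.marginals):
            out *= dist.pdf(q[:, i])
        return out if out.size > 1 else float(out[0])


class ConditionalJoint(JointDistribution):
    """Dependent joint built coordinate-by-coordinate.

    ``coordinates`` is a sequence where entry i is either a
    ``Distribution`` (no dependence) or a callable that receives the
    values of coordinates 0..i-1 (a 1-D array) and returns the
    conditional ``Distribution`` of coordinate i.  This constructive form
    makes the Rosenblatt transformation exact: the forward map is the
    sequence of conditional CDFs, the inverse the sequence of conditional
    inverse CDFs.
    """

    dependent = True

    def __init__(self, coordinates: Sequence[Distribution | Callable]):
        if not coordinates:
            raise ValueError("need at least one coordinate")
        self.coordinates = list(coordinates)
        self.dim = len(self.coordinates)

    def _conditional(self, i: int, prev: np.ndarray) -> Distribution:
        coord = self.coordinates[i]
        if isinstance(coord, Distribution):
            return coord
        return coord(prev)

    def rosenblatt_inverse(self, u):
        squeeze = np.asarray(u).ndim == 1
        u = self._check_u(u)
        q = np.empty_like(u)
        for k in range(u.shape[0]):
            for i in range(self.dim):
                dist = self._conditional(i, q[k, :i])
                q[k, i] = dist.ppf(u[k, i])
        return q[0] if squeeze else q

    def rosenblatt_forward(self, q):
        squeeze = np.asarray(q).ndim == 1
        q = np.atleast_2d(np.asarray(q, float))
        u = np.empty_like(q)
        for k in range(q.shape[0]):
            for i in range(self.dim):
                dist = self._conditional(i, q[k, :i])
                u[k, i] = dist.cdf(q[k, i])
        return u[0] if squeeze else u


def make_joint(params: ParameterSet) -> JointDistribution:
    """Joint distribution over the uncertain parameters of ``params``.

    Returns the explicit joint if one was supplied (dependent case),
    otherwise the product of the declared marginals, in declaration
    order.  Fixed parameters are not part of the joint; they are carried
    separately and substituted at evaluation time.
    """
    if params.distribution is not None:
        return params.distribution
    marginals = [p.distribution for p in params if p.uncertain]
    if not marginals:
        raise ValueError("no uncertain parameters: nothing to quantify")
    return IndependentJoint(marginals)


def _radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    """Van der Corput radical inverse of integer indices in ``base``."""
    indices = np.asarray(indices, dtype=np.int64)
    out = np.zeros(indices.shape, float)
    inv = 1.0 / base
    work = indices.copy()
    while np.any(work > 0):
        out += (work % base) * inv
        work //= base
        inv /= base
    return out


def hammersley_nodes(n: int, d: int) -> np.ndarray:
    """The n-point Hammersley set in the open unit hypercube [0,1]^d.

    The first coordinate is the midpoint-shifted equispaced sequence
    (i + 1/2)/n; the remaining coordinates are radical-inverse (van der
    Corput) sequences in the first d-1 prime bases, indexed from 1.  The
    index offset and midpoint shift guarantee that no node touches the
    hypercube boundary, where inverse CDFs of unbounded distributions
    diverge.  Fully deterministic.
    """
    if n < 1 or d < 1:
        raise ValueError("need n >= 1 and d >= 1")
    if d - 1 > len(_PRIMES):
        raise ValueError(f"at most {len(_PRIMES) + 1} dimensions supported")
    nodes = np.empty((n, d))
    nodes[:, 0] = (np.arange(n) + 0.5) / n
    idx = np.arange(1, n + 1)
    for j in range(1, d):
        nodes[:, j] = _radical_inverse(idx, _PRIMES[j - 1])
    return nodes
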