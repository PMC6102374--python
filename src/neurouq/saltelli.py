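"""Quasi-Monte Carlo uncertainty quantification and Saltelli Sobol estimators.

The Saltelli scheme evaluates the model on a structured design of
Ns = N(d + 2) points: two independent blocks A and B of N points each,
plus d "AB_i" blocks in which column i of A is replaced by column i of B.
First-order indices use the Saltelli (2010) estimator

    S_i  = mean( f_B * (f_AB_i - f_A) ) / V,

and total-order indices the Jansen estimator

    S_Ti = mean( (f_A - f_AB_i)^2 ) / (2 V),

with V the sample variance of the pooled A and B evaluations.  Plain
uncertainty statistics (mean, variance, percentiles) use the N-point
A-block only, since the remaining rows of the design are not mutually
independent.

The base sample is a scrambled Sobol' sequence in 2d dimensions (columns
1..d feed block A, columns d+1..2d block B), mapped to parameter space
through the joint's inverse Rosenblatt transformation so that arbitrary
(including dependent) joints are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .distributions import JointDistribution

__all__ = [
    "SaltelliDesign",
    "saltelli_design",
    "mc_moments",
    "mc_percentiles",
    "impute_invalid",
    "saltelli_sobol",
]


@dataclass
class SaltelliDesign:
    """Sample matrix of shape (N(d+2), d): A-block, B-block, d AB-blocks."""

    N: int
    dim: int
    nodes: np.ndarray

    @property
    def size(self) -> int:
        return self.N * (self.dim + 2)

    def block_a(self) -> slice:
        return slice(0, self.N)

    def block_b(self) -> slice:
        return slice(self.N, 2 * self.N)

    def block_ab(self, i: int) -> slice:
        return slice((2 + i) * self.N, (3 + i) * self.N)


def saltelli_design(joint: JointDistribution, N: int,
                    seed: int = 0) -> SaltelliDesign:
    """Build the N(d+2)-row Saltelli design for ``joint``.

    Deterministic for a given seed (the Sobol' scrambling is seeded).
    """
    if N < 2:
        raise ValueError("need N >= 2 base samples")
    d = joint.dim
    with warnings.catch_warnings():
        # scipy warns when N is not a power of two; balance properties are
        # slightly degraded but the estimators remain consistent
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
        base = sampler.random(N)
    eps = 1e-12
    base = np.clip(base, eps, 1.0 - eps)
    A = base[:, :d]
    B = base[:, d:]
    blocks = [A, B]
    for i in range(d):
        ab = A.copy()
        ab[:, i] = B[:, i]
        blocks.append(ab)
    u = np.vstack(blocks)
    nodes = np.atleast_2d(joint.rosenblatt_inverse(u))
    return SaltelliDesign(N=N, dim=d, nodes=nodes)


def mc_moments(evaluations: np.ndarray, valid: np.ndarray | None = None):
    """Sample mean and (unbiased, 1/(n-1)) variance per output point.

    ``evaluations`` are the rows of the A-block (or any independent
    sample); invalid rows are excluded.
    """
    Y = np.asarray(evaluations, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if valid is None:
        valid = np.all(np.isfinite(Y), axis=1)
    else:
        valid = np.asarray(valid, bool) & np.all(np.isfinite(Y), axis=1)
    n = int(valid.sum())
    if n < 2:
        raise ValueError(f"need at least 2 valid evaluations, got {n}")
    Yv = Y[valid]
    mean = Yv.mean(axis=0)
    var = Yv.var(axis=0, ddof=1)
    return mean, var


def mc_percentiles(evaluations: np.ndarray, levels=(0.05, 0.95),
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Empirical percentiles per output point from sorted valid rows.

    Linear interpolation between order statistics.  Shape
    (len(levels), T).
    """
    Y = np.asarray(evaluations, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if valid is None:
        valid = np.all(np.isfinite(Y), axis=1)
    else:
        valid = np.asarray(valid, bool) & np.all(np.isfinite(Y), axis=1)
    if not np.any(valid):
        raise ValueError("no valid evaluations")
    return np.quantile(Y[valid], np.asarray(levels), axis=0)


def impute_invalid(evaluations: np.ndarray,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Replace invalid rows with the per-output-point mean of valid rows.

    The Saltelli estimators require a value at every design row; mean
    imputation is the standard workaround.  It biases the indices in
    proportion to the number of imputed rows, so a warning reports the
    count.
    """
    Y = np.asarray(evaluations, float).copy()
    one_d = Y.ndim == 1
    if one_d:
        Y = Y[:, None]
    if valid is None:
        valid = np.all(np.isfinite(Y), axis=1)
    else:
        valid = np.asarray(valid, bool) & np.all(np.isfinite(Y), axis=1)
    n_bad = int((~valid).sum())
    if n_bad == Y.shape[0]:
        raise ValueError("all evaluations are invalid; cannot impute")
    if n_bad:
        warnings.warn(
            f"{n_bad} invalid evaluations replaced by the mean of the "
            f"{int(valid.sum())} valid evaluations", stacklevel=2)
        Y[~valid] = Y[valid].mean(axis=0)
    return Y[:, 0] if one_d else Y


def saltelli_sobol(design: SaltelliDesign, evaluations: np.ndarray,
                   valid: np.ndarray | None = None, var_tol: float = 1e-14):
    """First- and total-order Sobol indices from a full-design evaluation.

    Invalid rows are mean-imputed first.  Returns (S, ST, S_avg, ST_avg)
    with S and ST of shape (d, T); output points with zero total variance
    get NaN indices.
    """
    Y = np.asarray(evaluations, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.size:
        raise ValueError(
            f"evaluations have {Y.shape[0]} rows but the design has "
            f"{design.size}")
    Y = impute_invalid(Y, valid)
    fA = Y[design.block_a()]
    fB = Y[design.block_b()]
    pooled = np.vstack([fA, fB])
    V = pooled.var(axis=0, ddof=1)
    d, T = design.dim, Y.shape[1]
    S = np.full((d, T), np.nan)
    ST = np.full((d, T), np.nan)
    tol = max(var_tol, 1e-10 * float(V.max(initial=0.0)))
    defined = V > tol
    for i in range(d):
        fABi = Y[design.block_ab(i)]
        Si = np.mean(fB * (fABi - fA), axis=0)
        STi = 0.5 * np.mean((fA - fABi)**2, axis=0)
        S[i, defined] = Si[defined] / V[defined]
        ST[i, defined] = STi[defined] / V[defined]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        S_avg = np.nanmean(S, axis=1)
        ST_avg = np.nanmean(ST, axis=1)
    return S, ST, S_avg, ST_avg
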