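"""Result containers, HDF5 persistence, error metric, convergence driver.

Every analyzed output (the raw model and each feature) stores the same
set of statistical metrics: the ensemble of evaluations, the output time
axis, mean, variance, the 5th/95th percentiles bounding the 90%
prediction interval, first- and total-order Sobol indices per output
point, and their time averages.  Results round-trip losslessly through a
hierarchical HDF5 file with one group per output and one dataset per
metric; undefined values (NaN) carry a companion boolean mask dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "OutputResult",
    "ResultSet",
    "save",
    "load",
    "relative_error",
    "convergence_experiment",
]

#: dataset name per stored metric (the canonical variable names)
_METRICS = ("evaluations", "time", "mean", "variance", "percentile_5",
            "percentile_95", "sobol_first", "sobol_total",
            "sobol_first_average", "sobol_total_average")


@dataclass
class OutputResult:
    """All statistical metrics of one analyzed output."""

    name: str
    evaluations: np.ndarray | None = None
    time: np.ndarray | None = None
    mean: np.ndarray | float | None = None
    variance: np.ndarray | float | None = None
    percentile_5: np.ndarray | float | None = None
    percentile_95: np.ndarray | float | None = None
    sobol_first: np.ndarray | None = None
    sobol_total: np.ndarray | None = None
    sobol_first_average: np.ndarray | None = None
    sobol_total_average: np.ndarray | None = None
    n_invalid: int = 0

    def __post_init__(self):
        p5, p95 = self.percentile_5, self.percentile_95
        if p5 is not None and p95 is not None:
            if np.any(np.asarray(p5) > np.asarray(p95) + 1e-12):
                raise ValueError(f"{self.name}: percentile_5 > percentile_95")


class ResultSet:
    """Mapping output name -> OutputResult, plus run metadata."""

    def __init__(self, outputs: dict[str, OutputResult] | None = None,
                 metadata: dict | None = None):
        self.outputs = dict(outputs or {})
        self.metadata = dict(metadata or {})

    def __getitem__(self, name: str) -> OutputResult:
        return self.outputs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.outputs

    def __iter__(self):
        return iter(self.outputs)

    def add(self, result: OutputResult):
        self.outputs[result.name] = result

    def names(self):
        return list(self.outputs)


def save(rs: ResultSet, path):
    """Persist a ResultSet to an HDF5 file (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for key, value in rs.metadata.items():
            if value is not None:
                f.attrs[key] = value
        for name, out in rs.outputs.items():
            grp = f.create_group(name)
            grp.attrs["n_invalid"] = out.n_invalid
            for metric in _METRICS:
                value = getattr(out, metric)
                if value is None:
                    continue
                arr = np.asarray(value, float)
                dset = grp.create_dataset(metric, data=arr)
                mask = ~np.isfinite(arr)
                if np.any(mask):
                    grp.create_dataset(metric + "_mask", data=mask)


def load(path) -> ResultSet:
    """Load a ResultSet written by :func:`save`.

    A file missing an expected dataset raises an error naming the first
    absent one (metrics that were ``None`` at save time stay ``None``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rs = ResultSet()
    with h5py.File(path, "r") as f:
        rs.metadata = {
            k: (v.item() if isinstance(v, np.generic)
                else np.asarray(v) if isinstance(v, np.ndarray) else v)
            for k, v in f.attrs.items()}
        for name in f:
            grp = f[name]
            out = OutputResult(name=name,
                               n_invalid=int(grp.attrs.get("n_invalid", 0)))
            for metric in _METRICS:
                if metric in grp:
                    arr = np.asarray(grp[metric])
                    setattr(out, metric,
                            float(arr) if arr.ndim == 0 else arr)
            rs.add(out)
    return rs


def require(rs: ResultSet, name: str, metric: str):
    """Fetch a metric, raising a clear error if it is absent."""
    if name not in rs:
        raise KeyError(f"result file has no output named {name!r}")
    value = getattr(rs[name], metric)
    if value is None:
        raise KeyError(f"output {name!r} is missing the dataset {metric!r}")
    return value


def relative_error(reference, estimate, time=None,
                   discard_before: float | None = None,
                   zero_tol: float = 0.0) -> float:
    """Time-averaged absolute relative error |X - X_est| / |X|.

    The average runs over the output points (uniform weight, i.e. the
    discrete form of (1/T) integral |X - X_est|/|X| dt).  If ``time`` and
    ``discard_before`` are given, points earlier than ``discard_before``
    are excluded, the convention used when an initial transient should
    not dominate the error.  Points where the reference magnitude does
    not exceed ``zero_tol`` are undefined (the relative error against a
    zero reference is meaningless) and are left out of the average.
    Scale-invariant: rescaling both inputs by the same nonzero factor
    leaves the error unchanged.  The reference must not be identically
    zero on the averaged region.
    """
    X = np.asarray(reference, float).ravel()
    Xe = np.asarray(estimate, float).ravel()
    if X.shape != Xe.shape:
        raise ValueError("reference and estimate must share a grid")
    keep = np.isfinite(X) & np.isfinite(Xe) & (np.abs(X) > zero_tol)
    if time is not None and discard_before is not None:
        t = np.asarray(time, float).ravel()
        keep &= t >= discard_before
    X, Xe = X[keep], Xe[keep]
    if X.size == 0 or np.all(X == 0):
        raise ValueError("reference is empty or identically zero on the "
                         "averaged region")
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(X - Xe) / np.abs(X)
    return float(np.mean(err[np.isfinite(err)]))


#: first-order Sobol indices below this value are indistinguishable from
#: zero (the index scale is [0, 1]); relative errors against them are
#: undefined rather than informative
SOBOL_ZERO_TOL = 1e-6


def sobol_first_error(S_ref: np.ndarray, S_est: np.ndarray, time=None,
                      discard_before: float | None = None,
                      zero_tol: float = SOBOL_ZERO_TOL) -> float:
    """Error of the first-order Sobol indices, averaged over parameters
    and time.

    Each parameter's index curve S_i(t) contributes its time-averaged
    absolute relative error against the reference, and the errors are
    averaged over parameters.  A parameter whose reference index curve
    is numerically zero throughout — never exceeding ``zero_tol`` on the
    [0, 1] index scale — has no defined relative error and is excluded
    from the average.
    """
    S_ref = np.atleast_2d(S_ref)
    S_est = np.atleast_2d(S_est)
    errs = []
    for ref_i, est_i in zip(S_ref, S_est):
        if np.nanmax(np.abs(ref_i)) <= zero_tol:
            continue        # reference index identically zero: no error defined
        errs.append(relative_error(ref_i, est_i, time=time,
                                   discard_before=discard_before))
    if not errs:
        raise ValueError("no parameter has a nonzero reference index")
    return float(np.mean(errs))


def convergence_experiment(model, parameters, pc_orders=(), mc_samples=(),
                           reference=None, reference_order: int = 6,
                           mc_reruns: int = 5, seed: int = 0,
                           discard_before: float | None = None,
                           regularization="gcv", **quantify_kwargs):
    """Error-vs-evaluations comparison of PCE and quasi-Monte Carlo.

    For each polynomial order in ``pc_orders`` and each base sample count
    in ``mc_samples``, the mean, variance and parameter-averaged
    first-order Sobol indices are compared against a converged reference
    (``reference`` ResultSet, or a PCE at ``reference_order`` computed
    here) with the time-averaged absolute relative error.  Quasi-Monte
    Carlo errors are averaged over ``mc_reruns`` re-runs with distinct
    seeds.  Returns a list of row dicts
    (method, budget, n_evaluations, error_mean, error_variance,
    error_sobol_first).
    """
    from .runner import quantify  # local import: runner depends on results

    quantify_kwargs.setdefault("save", False)
    if reference is None:
        reference = quantify(model, parameters, method="pc",
                             polynomial_order=reference_order, seed=seed,
                             regularization=regularization,
                             **quantify_kwargs)
    name = reference.metadata.get("model_name", "model")
    ref = reference[name]

    def errors(res):
        out = res[name]
        kw = dict(time=ref.time, discard_before=discard_before)
        return {
            "error_mean": relative_error(ref.mean, out.mean, **kw),
            "error_variance": relative_error(ref.variance, out.variance, **kw),
            "error_sobol_first": sobol_first_error(
                ref.sobol_first, out.sobol_first, **kw),
        }

    rows = []
    for order in pc_orders:
        try:
            res = quantify(model, parameters, method="pc",
                           polynomial_order=order, seed=seed,
                           regularization=regularization,
                           **quantify_kwargs)
        except ValueError as err:
            warnings.warn(f"pc order {order} skipped: {err}", stacklevel=2)
            continue
        n_evals = res.metadata["n_evaluations"]
        rows.append({"method": "pc", "budget": order,
                     "n_evaluations": n_evals, **errors(res)})
    for N in mc_samples:
        if N < 2:
            warnings.warn(f"mc budget {N} below minimum, skipped",
                          stacklevel=2)
            continue
        acc: dict[str, float] = {}
        for r in range(mc_reruns):
            res = quantify(model, parameters, method="mc", nr_mc_samples=N,
                           seed=seed + 1000 * r + 1, **quantify_kwargs)
            for k, v in errors(res).items():
                acc[k] = acc.get(k, 0.0) + v / mc_reruns
        n_evals = res.metadata["n_evaluations"]
        rows.append({"method": "mc", "budget": N,
                     "n_evaluations": n_evals, **acc})
    return rows
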