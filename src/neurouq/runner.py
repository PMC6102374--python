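"""Black-box model contract, ensemble evaluation, and `quantify`.

A model is any callable that accepts the uncertain parameters as named
arguments and returns ``(time, values)`` or ``(time, values, info)``.
``quantify`` propagates the parameter distributions through the model
(and through optional output features) with either polynomial chaos
expansions ("pc", the default: point collocation at order 4) or the
Saltelli quasi-Monte Carlo method ("mc"), and collects mean, variance,
the 90% prediction interval and first/total-order Sobol indices for
every output into a ResultSet.

Invalid model evaluations (exceptions, ``None`` outputs, non-finite
values) are masked, never silently dropped: point collocation excludes
them from the regression, the Saltelli estimators impute them with the
ensemble mean, and pseudo-spectral projection refuses to run with any
present.  If more than half of the evaluations are invalid the run is
aborted with guidance to narrow the parameter distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import interp1d

from . import pce, saltelli as qmc
from .distributions import (IndependentJoint, JointDistribution, Parameter,
                            ParameterSet, Uniform, hammersley_nodes,
                            make_joint)
from .features import FeatureSet
from .results import OutputResult, ResultSet, save as save_results

__all__ = [
    "Model",
    "EvaluationEnsemble",
    "evaluate_ensemble",
    "regularize",
    "quantify",
    "screen_single",
]


@dataclass
class Model:
    """The black-box model contract.

    ``run(**params)`` returns ``(time, values[, info])``; ``time`` may be
    None for models without a time axis.  ``run_batch``, if provided,
    takes a list of parameter dictionaries and returns the corresponding
    list of result tuples in order — an optimization hook for models that
    can integrate many parameter sets side by side.  ``interpolate``
    declares that the output is irregular (varying length) and must be
    interpolated to a common grid.  ``postprocess(time, values, info)``
    optionally transforms the output into regular form before the UQ;
    features always receive the raw output.  ``ignore`` skips the UQ of
    the raw output (features only).
    """

    run: Callable
    run_batch: Callable | None = None
    interpolate: bool = False
    labels: Sequence[str] = ()
    postprocess: Callable | None = None
    ignore: bool = False
    name: str | None = None

    def __post_init__(self):
        if self.name is None:
            self.name = getattr(self.run, "__name__", "model")


def _as_model(model) -> Model:
    return model if isinstance(model, Model) else Model(run=model)


class EvaluationEnsemble:
    """Model evaluations at a set of parameter nodes.

    Holds the raw per-node results (time, values, info), a validity mask,
    and — after :func:`regularize` — a common time grid and a value
    matrix with one row per node (NaN rows for invalid nodes).
    """

    def __init__(self, nodes, times, values, infos, valid,
                 first_error: str | None = None):
        self.nodes = np.atleast_2d(np.asarray(nodes, float))
        self.times = times
        self.values = values
        self.infos = infos
        self.valid = np.asarray(valid, bool)
        self.first_error = first_error
        self.grid: np.ndarray | None = None
        self.matrix: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


def _normalize_result(res):
    """Split a run() return value into (time, values, info)."""
    if res is None:
        return None, None, None
    if not isinstance(res, tuple):
        raise TypeError("model must return a tuple (time, values[, info])")
    if len(res) == 2:
        time, values = res
        info = None
    elif len(res) >= 3:
        time, values = res[0], res[1]
        info = res[2]
    else:
        raise TypeError("model must return at least (time, values)")
    return time, values, info


def _values_valid(values) -> bool:
    if values is None:
        return False
    arr = np.asarray(values, float) if not hasattr(values, "trains") else None
    if arr is None:          # structured outputs (e.g. spike-train sets)
        return True
    return bool(np.all(np.isfinite(arr)))


def evaluate_ensemble(model, nodes, fixed_params: dict | None,
                      names: Sequence[str], parallel: int = 1
                      ) -> EvaluationEnsemble:
    """Evaluate the model at every node, independently and order-stably.

    ``names`` gives the uncertain-parameter name for each node column;
    ``fixed_params`` are substituted by name.  Exceptions and missing
    outputs flag nodes invalid.  With ``parallel > 1`` evaluations are
    dispatched through joblib; results are gathered by node index, so
    the ensemble is identical to a serial run.
    """
    model = _as_model(model)
    nodes = np.atleast_2d(np.asarray(nodes, float))
    fixed_params = dict(fixed_params or {})
    param_dicts = [dict(zip(names, node)) | fixed_params for node in nodes]

    def safe_run(pd):
        try:
            return _normalize_result(model.run(**pd)), None
        except Exception as err:  # noqa: BLE001 — invalid-evaluation contract
            return (None, None, None), f"{type(err).__name__}: {err}"

    if model.run_batch is not None:
        raw = model.run_batch(param_dicts)
        results = [(_normalize_result(r), None) for r in raw]
    elif parallel > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=parallel)(
            delayed(safe_run)(pd) for pd in param_dicts)
    else:
        results = [safe_run(pd) for pd in param_dicts]

    times, values, infos, valid = [], [], [], []
    first_error = None
    for (t, v, info), err in results:
        ok = err is None and _values_valid(v)
        if err is not None and first_error is None:
            first_error = err
        times.append(t)
        values.append(v)
        infos.append(info)
        valid.append(ok)
    ens = EvaluationEnsemble(nodes, times, values, infos, valid,
                             first_error=first_error)
    if ens.n_invalid == ens.n_nodes:
        raise RuntimeError(
            "model failed on every node"
            + (f"; first error: {first_error}" if first_error else ""))
    return ens


def regularize(ensemble: EvaluationEnsemble,
               interpolate: bool = False) -> EvaluationEnsemble:
    """Bring all valid evaluations onto one common grid.

    Regular outputs (equal lengths) pass through untouched.  Irregular
    outputs require ``interpolate``; the common grid is the time axis of
    the valid evaluation with the most points, restricted to the
    intersection of all spans (no extrapolation), and each evaluation is
    interpolated onto it (piecewise cubic, linear below 4 points).
    """
    idx_valid = np.flatnonzero(ensemble.valid)
    vals = []
    for i in idx_valid:
        v = np.atleast_1d(np.asarray(ensemble.values[i], float))
        if v.ndim != 1:
            v = v.ravel()
        vals.append(v)
    lengths = {v.size for v in vals}
    if len(lengths) == 1:
        L = lengths.pop()
        grid = ensemble.times[idx_valid[0]]
        grid = None if grid is None else np.asarray(grid, float)
        matrix = np.full((ensemble.n_nodes, L), np.nan)
        for k, i in enumerate(idx_valid):
            matrix[i] = vals[k]
        ensemble.grid = grid
        ensemble.matrix = matrix
        return ensemble
    if not interpolate:
        bad = idx_valid[0]
        for k, i in enumerate(idx_valid):
            if vals[k].size != vals[0].size:
                bad = i
                break
        raise ValueError(
            f"irregular model output (node {bad} has a different length); "
            "set interpolate=True for irregular models")
    spans_lo, spans_hi, best = [], [], None
    for k, i in enumerate(idx_valid):
        t = ensemble.times[i]
        if t is None:
            raise ValueError(
                f"node {i}: interpolation requires a time axis for every "
                "valid evaluation")
        t = np.asarray(t, float)
        spans_lo.append(t[0])
        spans_hi.append(t[-1])
        if best is None or t.size > np.asarray(
                ensemble.times[idx_valid[best]], float).size:
            best = k
    lo, hi = max(spans_lo), min(spans_hi)
    base = np.asarray(ensemble.times[idx_valid[best]], float)
    grid = base[(base >= lo) & (base <= hi)]
    matrix = np.full((ensemble.n_nodes, grid.size), np.nan)
    for k, i in enumerate(idx_valid):
        t = np.asarray(ensemble.times[i], float)
        kind = "cubic" if t.size >= 4 else "linear"
        matrix[i] = interp1d(t, vals[k], kind=kind, assume_sorted=True,
                             bounds_error=False,
                             fill_value=(vals[k][0], vals[k][-1]))(grid)
    ensemble.grid = grid
    ensemble.matrix = matrix
    return ensemble


def _check_invalid(name: str, n_invalid: int, n_total: int):
    if n_invalid == 0:
        return
    if n_invalid > 0.5 * n_total:
        raise RuntimeError(
            f"{name}: {n_invalid} of {n_total} evaluations are invalid "
            "(more than half); consider redefining the problem, e.g. with "
            "narrower parameter distributions")
    warnings.warn(f"{name}: {n_invalid} of {n_total} evaluations failed to "
                  "return a valid output", stacklevel=3)


def _feature_ensembles(feature_set: FeatureSet, ensemble: EvaluationEnsemble
                       ) -> dict[str, EvaluationEnsemble]:
    """Evaluate every feature on every valid model evaluation."""
    names = feature_set.features_to_run
    per_feature = {name: ([None] * ensemble.n_nodes,
                          [None] * ensemble.n_nodes)
                   for name in names}
    for i in range(ensemble.n_nodes):
        if not ensemble.valid[i]:
            continue
        results = feature_set.calculate(ensemble.times[i],
                                        ensemble.values[i],
                                        ensemble.infos[i])
        for name, (t_f, v_f) in results.items():
            per_feature[name][0][i] = t_f
            per_feature[name][1][i] = v_f
    out = {}
    for name in names:
        times, values = per_feature[name]
        valid = [v is not None and _values_valid(v) for v in values]
        out[name] = EvaluationEnsemble(ensemble.nodes, times, values,
                                       [None] * ensemble.n_nodes, valid)
    return out


def _pc_output_result(name, ensemble, basis, regression_nodes, sample_joint,
                      regularization, nr_pc_mc_samples, levels=(0.05, 0.95)):
    expansion = pce.fit_collocation(regression_nodes, ensemble.matrix, basis,
                                    valid=ensemble.valid,
                                    regularization=regularization) \
        if ensemble._fit_mode == "collocation" else \
        pce.fit_spectral(ensemble._rule, ensemble.matrix, basis,
                         valid=ensemble.valid)
    mean, var = pce.expansion_statistics(expansion)
    S, ST, S_avg, ST_avg = pce.expansion_sobol(expansion)
    pcts = pce.surrogate_percentiles(expansion, sample_joint, levels=levels,
                                     n=nr_pc_mc_samples)
    return OutputResult(
        name=name, evaluations=ensemble.matrix, time=ensemble.grid,
        mean=mean, variance=var,
        percentile_5=np.minimum(pcts[0], pcts[1]),
        percentile_95=np.maximum(pcts[0], pcts[1]),
        sobol_first=S, sobol_total=ST,
        sobol_first_average=S_avg, sobol_total_average=ST_avg,
        n_invalid=ensemble.n_invalid)


def _mc_output_result(name, ensemble, design, levels=(0.05, 0.95)):
    A = design.block_a()
    matrix = ensemble.matrix
    mean, var = qmc.mc_moments(matrix[A], valid=ensemble.valid[A])
    pcts = qmc.mc_percentiles(matrix[A], levels=levels,
                              valid=ensemble.valid[A])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        S, ST, S_avg, ST_avg = qmc.saltelli_sobol(design, matrix,
                                                  valid=ensemble.valid)
    return OutputResult(
        name=name, evaluations=matrix, time=ensemble.grid,
        mean=mean, variance=var,
        percentile_5=pcts[0], percentile_95=pcts[1],
        sobol_first=S, sobol_total=ST,
        sobol_first_average=S_avg, sobol_total_average=ST_avg,
        n_invalid=ensemble.n_invalid)


def quantify(model, parameters, features: FeatureSet | Sequence | None = None,
             method: str = "pc", pc_method: str = "collocation",
             polynomial_order: int = 4, nr_mc_samples: int = 10000,
             nr_pc_mc_samples: int = 10**4, quadrature_order: int | None = None,
             regularization="gcv", seed: int = 0, parallel: int = 1,
             save: bool = True, output_dir: str = "data") -> ResultSet:
    """Full uncertainty quantification and sensitivity analysis.

    ``method`` selects polynomial chaos ("pc") or Saltelli quasi-Monte
    Carlo ("mc"); ``pc_method`` selects point collocation or
    pseudo-spectral projection.  The Rosenblatt transformation is applied
    automatically when the parameters carry a dependent joint
    distribution: the expansion is then built over an independent
    uniform base and nodes are mapped through the joint before the model
    sees them.  The model and all features share one node set and one
    polynomial basis; only the coefficients differ.

    Results (all Table-style metrics per output) are returned as a
    ResultSet and, when ``save`` is true, persisted to
    ``<output_dir>/<model name>.h5``.
    """
    model = _as_model(model)
    if not isinstance(parameters, ParameterSet):
        parameters = ParameterSet(parameters)
    if features is not None and not isinstance(features, FeatureSet):
        features = FeatureSet({getattr(f, "__name__", f"feature_{k}"): f
                               for k, f in enumerate(features)})
    joint = make_joint(parameters)
    names = parameters.uncertain_names
    fixed = parameters.fixed_values

    if method not in ("pc", "mc"):
        raise ValueError(f"unknown method {method!r}; expected 'pc' or 'mc'")
    if method == "pc" and pc_method not in ("collocation", "spectral"):
        raise ValueError(f"unknown pc_method {pc_method!r}; expected "
                         "'collocation' or 'spectral'")

    rs = ResultSet(metadata={
        "model_name": model.name, "method": method, "seed": seed,
        "uncertain_parameters": names,
    })

    if method == "pc":
        if joint.dependent:
            # Rosenblatt: expand over an independent uniform base
            base_joint: JointDistribution = IndependentJoint(
                [Uniform(0.0, 1.0)] * joint.dim)
            basis = pce.build_basis(base_joint, polynomial_order)
            if pc_method == "collocation":
                reg_nodes = pce.collocation_design(basis, base_joint)
                rule = None
            else:
                rule = pce.quadrature_design(
                    base_joint, quadrature_order or polynomial_order + 2,
                    basis=pce.build_basis(
                        base_joint, polynomial_order,
                        max_univariate_order=(quadrature_order
                                              or polynomial_order + 2) + 2))
                reg_nodes = rule.nodes
            u = np.clip(reg_nodes, 1e-12, 1 - 1e-12)
            model_nodes = np.atleast_2d(joint.rosenblatt_inverse(u))
            sample_joint = base_joint
        else:
            deep = (quadrature_order or polynomial_order + 2) + 2
            basis = pce.build_basis(joint, polynomial_order,
                                    max_univariate_order=deep)
            if pc_method == "collocation":
                reg_nodes = pce.collocation_design(basis, joint)
                rule = None
            else:
                rule = pce.quadrature_design(
                    joint, quadrature_order or polynomial_order + 2,
                    basis=basis)
                reg_nodes = rule.nodes
            model_nodes = reg_nodes
            sample_joint = joint
        ensemble = evaluate_ensemble(model, model_nodes, fixed, names,
                                     parallel=parallel)
        rs.metadata["pc_method"] = pc_method
        rs.metadata["polynomial_order"] = polynomial_order
        design = None
    else:
        design = qmc.saltelli_design(joint, nr_mc_samples, seed=seed)
        ensemble = evaluate_ensemble(model, design.nodes, fixed, names,
                                     parallel=parallel)
        basis = reg_nodes = rule = sample_joint = None
        rs.metadata["nr_mc_samples"] = nr_mc_samples

    rs.metadata["n_evaluations"] = ensemble.n_nodes
    _check_invalid(model.name, ensemble.n_invalid, ensemble.n_nodes)

    def analyze(name, ens):
        if ens.n_invalid == ens.n_nodes:
            warnings.warn(f"{name}: no valid evaluations; skipped",
                          stacklevel=2)
            return None
        if name != model.name:
            _check_invalid(name, ens.n_invalid, ens.n_nodes)
        if method == "pc":
            ens._fit_mode = pc_method
            ens._rule = rule
            return _pc_output_result(name, ens, basis, reg_nodes,
                                     sample_joint, regularization,
                                     nr_pc_mc_samples)
        return _mc_output_result(name, ens, design)

    if not model.ignore:
        model_ens = ensemble
        if model.postprocess is not None:
            times, values, valid = [], [], []
            for i in range(ensemble.n_nodes):
                if not ensemble.valid[i]:
                    times.append(None); values.append(None); valid.append(False)
                    continue
                try:
                    t_p, v_p = model.postprocess(ensemble.times[i],
                                                 ensemble.values[i],
                                                 ensemble.infos[i])
                    times.append(t_p); values.append(v_p)
                    valid.append(_values_valid(v_p))
                except Exception:
                    times.append(None); values.append(None); valid.append(False)
            model_ens = EvaluationEnsemble(ensemble.nodes, times, values,
                                           ensemble.infos, valid)
        regularize(model_ens, interpolate=model.interpolate)
        result = analyze(model.name, model_ens)
        if result is not None:
            rs.add(result)

    if features is not None:
        for fname, fens in _feature_ensembles(features, ensemble).items():
            try:
                regularize(fens, interpolate=True)
            except ValueError as err:
                warnings.warn(f"feature {fname}: {err}; skipped", stacklevel=2)
                continue
            try:
                result = analyze(fname, fens)
            except (ValueError, RuntimeError) as err:
                warnings.warn(f"feature {fname}: {err}; skipped", stacklevel=2)
                continue
            if result is not None:
                rs.add(result)

    if save:
        save_results(rs, f"{output_dir}/{model.name}.h5")
    return rs


def screen_single(model, parameters, **quantify_kwargs) -> dict[str, ResultSet]:
    """One-at-a-time screening: a 1-parameter UQ per uncertain parameter.

    Each uncertain parameter is analyzed alone with every other
    parameter held at its fallback value (declared nominal value, or the
    marginal mean).  A cheap way to rank parameters before a full
    analysis.  Returns a mapping parameter name -> ResultSet.
    """
    if not isinstance(parameters, ParameterSet):
        parameters = ParameterSet(parameters)
    if parameters.distribution is not None:
        raise ValueError("one-at-a-time screening requires independent "
                         "parameter distributions")
    fallback = parameters.fallback_values()
    out = {}
    for p in parameters:
        if not p.uncertain:
            continue
        params = [Parameter(q.name, value=fallback[q.name]) if q.name != p.name
                  else Parameter(p.name, distribution=p.distribution)
                  for q in parameters]
        quantify_kwargs.setdefault("save", False)
        out[p.name] = quantify(model, ParameterSet(params), **quantify_kwargs)
    return out
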