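"""Parameter estimation by derivative-free generalized pattern search.

The model is constrained by simultaneous weighted least squares against a
collection of datasets (time courses and dose-response curves, normalized
the way each is presented).  The optimizer is a generalized pattern search:
poll the 2n coordinate directions on a mesh, contract the mesh on failure,
expand on success, stop when the mesh is smaller than a tolerance or the
evaluation budget is exhausted.  Searching is done in log10 parameter space
because the rates span many decades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet


@dataclass
class FitDataset:
    """One fitting target: grid (time in s, or dose), values, weight."""

    name: str
    observable: str
    protocol: str                  # identifier understood by the simulator fn
    grid: np.ndarray
    values: np.ndarray
    weight: float = 1.0
    normalization: str = "none"    # "none" | "fraction_total" | "peak"
    source: str = ""               # provenance annotation

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) < 0):
            raise ValueError(f"dataset {self.name}: grid must be sorted")
        if self.weight <= 0:
            raise ValueError(f"dataset {self.name}: weight must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"dataset {self.name}: non-finite target values")


@dataclass
class FitResult:
    params: ParameterSet
    objective: float
    residuals: dict[str, float]
    trace: list[tuple[int, float]] = field(default_factory=list)
    n_eval: int = 0
    seed: int | None = None
    converged: bool = False

    def to_json(self, path) -> None:
        payload = {
            "objective": self.objective,
            "residuals": self.residuals,
            "n_eval": self.n_eval,
            "seed": self.seed,
            "converged": self.converged,
            "parameters": self.params.as_dict(),
            "trace": self.trace,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


PENALTY = 1.0e12


def objective(params: ParameterSet, datasets: list[FitDataset],
              simulator) -> tuple[float, dict[str, float]]:
    """Weighted sum of squared residuals across all datasets.

    ``simulator(params, dataset)`` must return model predictions on the
    dataset's grid (already in the dataset's normalization).  A simulation
    failure contributes a large penalty instead of raising, which keeps the
    direct search total.
    """
    total = 0.0
    per = {}
    for ds in datasets:
        try:
            pred = np.asarray(simulator(params, ds), dtype=float)
            if pred.shape != ds.values.shape or not np.all(np.isfinite(pred)):
                raise ValueError("bad prediction")
            r = float(np.sum((pred - ds.values) ** 2)) * ds.weight
        except Exception:
            r = PENALTY
        per[ds.name] = r
        total += r
    return total, per


def direct_search(fun, start: dict[str, float],
                  bounds: dict[str, tuple[float, float]],
                  mesh0: float = 0.1, contraction: float = 0.5,
                  expansion: float = 2.0, mesh_tol: float = 1e-4,
                  max_eval: int = 1000, log_space: bool = True,
                  callback=None) -> tuple[dict[str, float], float, list]:
    """Generalized pattern search over the named parameters.

    ``fun(candidate_dict) -> scalar``.  Returns (best parameters, best
    objective, trace).  The incumbent objective is non-increasing; the
    result is deterministic for fixed inputs.
    """
    names = list(start)
    for n in names:
        lo, hi = bounds[n]
        if not (lo <= start[n] <= hi) or lo <= 0:
            raise ValueError(f"start for {n} outside bounds or bounds <= 0")

    def enc(vals):
        return np.array([np.log10(vals[n]) if log_space else vals[n]
                         for n in names])

    def dec(x):
        return {n: (10.0 ** x[i] if log_space else x[i])
                for i, n in enumerate(names)}

    lo = enc({n: bounds[n][0] for n in names})
    hi = enc({n: bounds[n][1] for n in names})
    scale = np.maximum(np.abs(hi - lo), 1.0)
    x = np.clip(enc(start), lo, hi)
    f = fun(dec(x))
    n_eval = 1
    mesh = mesh0
    trace = [(0, f)]
    while mesh > mesh_tol and n_eval < max_eval:
        # full poll: evaluate every +/- coordinate direction, take the best
        best_c, best_f = None, f
        for i in range(len(names)):
            for sgn in (+1.0, -1.0):
                if n_eval >= max_eval:
                    break
                xc = x.copy()
                xc[i] = np.clip(xc[i] + sgn * mesh * scale[i], lo[i], hi[i])
                if xc[i] == x[i]:
                    continue
                fc = fun(dec(xc))
                n_eval += 1
                if fc < best_f:
                    best_c, best_f = xc, fc
        if best_c is not None:
            # greedy search step: keep doubling along the winning direction
            step = best_c - x
            x, f = best_c, best_f
            while n_eval < max_eval:
                xc = np.clip(x + step, lo, hi)
                if np.array_equal(xc, x):
                    break
                fc = fun(dec(xc))
                n_eval += 1
                if fc >= f:
                    break
                x, f = xc, fc
                step = step * 2.0
            trace.append((n_eval, f))
            if callback:
                callback(dec(x), f, n_eval)
            mesh = min(mesh * expansion, mesh0)
        else:
            mesh *= contraction
    return dec(x), f, trace


def fit(params: ParameterSet, datasets: list[FitDataset], simulator,
        fit_names: list[str],
        bounds: dict[str, tuple[float, float]] | None = None,
        seed: int | None = None, **search_kw) -> FitResult:
    """Constrain ``fit_names`` in ``params`` against ``datasets``."""
    start = {n: params.get(n) for n in fit_names}
    if bounds is None:
        bounds = {n: (v / 100.0, v * 100.0) for n, v in start.items()}
    for n in fit_names:
        lo, hi = bounds[n]
        if not (lo <= start[n] <= hi):
            raise ValueError(f"start value of {n} outside its bounds")

    def fun(cand):
        ps = params.with_overrides(**cand)
        val, _ = objective(ps, datasets, simulator)
        return val

    best, fbest, trace = direct_search(fun, start, bounds, **search_kw)
    fitted = params.with_overrides(**best)
    for n in fit_names:
        fitted.bounds[n] = bounds[n]
    _, per = objective(fitted, datasets, simulator)
    return FitResult(params=fitted, objective=fbest, residuals=per,
                     trace=trace, n_eval=trace[-1][0] if trace else 0,
                     seed=seed, converged=True)
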