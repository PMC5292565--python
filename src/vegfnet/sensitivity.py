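"""Global sensitivity analysis by partial rank correlation coefficients.

Parameters are perturbed jointly, each drawn uniformly from a wide
multiplicative range around its fitted value (default 0.01x to 50x), the
model is simulated for each sample, and the PRCC of each parameter against
each output metric is computed: rank-transform everything, partial out the
other parameters from both the parameter and the output by linear
regression on the ranks, and correlate the residuals.  PRCC is invariant
under monotone transforms of inputs and outputs and is the standard global
measure for monotone but nonlinear ODE models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .params import ParameterSet


@dataclass
class SensitivitySpec:
    parameters: list[str]
    low_factor: float = 0.01
    high_factor: float = 50.0
    n_samples: int = 1000
    metrics: tuple[str, ...] = ("max_pR2", "max_pERK")
    seed: int = 0

    def __post_init__(self):
        if not self.low_factor < self.high_factor:
            raise ValueError("low factor must be below high factor")
        if self.n_samples < len(self.parameters) + 2:
            raise ValueError("sample count must exceed parameter count + 2")


@dataclass
class PrccResult:
    parameters: list[str]
    metric: str
    prcc: np.ndarray
    p_value: np.ndarray
    n: int

    def ranking(self):
        """Parameters ordered by |PRCC| (descending), with sign."""
        order = np.argsort(-np.abs(self.prcc))
        return [(self.parameters[i], float(self.prcc[i]), float(self.p_value[i]))
                for i in order]

    def frame(self):
        import pandas as pd
        rows = self.ranking()
        return pd.DataFrame(rows, columns=["parameter", "prcc", "p_value"]) \
            .assign(rank=lambda d: np.arange(1, len(d) + 1))


def sample_parameters(spec: SensitivitySpec, ps: ParameterSet) -> np.ndarray:
    """Uniform Monte-Carlo design matrix (n_samples x n_parameters).

    Column j is uniform on [low_factor * v_j, high_factor * v_j] where v_j
    is the parameter's current (fitted) value.  Reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.array([ps.get(p) for p in spec.parameters])
    lo = spec.low_factor * base
    hi = spec.high_factor * base
    u = rng.random((spec.n_samples, len(base)))
    return lo + u * (hi - lo)


class ConstantColumnError(ValueError):
    """A design or output column is constant; PRCC is undefined for it."""


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def prcc(design: np.ndarray, outputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation of each design column against the output.

    Returns (prcc values, two-sided p-values).  Raises ConstantColumnError
    for degenerate columns instead of silently reporting zero.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(outputs, dtype=float).ravel()
    n, k = design.shape
    if len(y) != n:
        raise ValueError("design and outputs are misaligned")
    for j in range(k):
        if np.ptp(design[:, j]) == 0:
            raise ConstantColumnError(f"design column {j} is constant")
    if np.ptp(y) == 0:
        raise ConstantColumnError("output is constant; PRCC undefined")

    R = _rank(design)
    ry = _rank(y)
    out = np.empty(k)
    pvals = np.empty(k)
    dof = n - k - 1
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(R, j, axis=1)])
        # residualize rank(x_j) and rank(y) on the other parameters' ranks
        bx, *_ = np.linalg.lstsq(others, R[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = R[:, j] - others @ bx
        ey = ry - others @ by
        denom = np.sqrt(np.sum(ex ** 2) * np.sum(ey ** 2))
        r = float(np.sum(ex * ey) / denom) if denom > 0 else np.nan
        r = min(max(r, -1.0), 1.0)
        out[j] = r
        if dof <= 0 or abs(r) >= 1.0:
            pvals[j] = 0.0 if abs(r) >= 1.0 else np.nan
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            pvals[j] = 2.0 * stats.t.sf(abs(t), dof)
    return out, pvals


def run_prcc(spec: SensitivitySpec, ps: ParameterSet, evaluate,
             design: np.ndarray | None = None) -> dict[str, PrccResult]:
    """Sample, simulate and compute PRCC for every metric.

    ``evaluate(ps_sample) -> dict[metric, value]`` runs the model once for
    one sampled parameter set.
    """
    if design is None:
        design = sample_parameters(spec, ps)
    rows = []
    for i in range(design.shape[0]):
        sample = ps.with_overrides(
            **{p: float(design[i, j]) for j, p in enumerate(spec.parameters)})
        rows.append(evaluate(sample))
    results = {}
    for metric in spec.metrics:
        y = np.array([r[metric] for r in rows], dtype=float)
        vals, pv = prcc(design, y)
        results[metric] = PrccResult(parameters=list(spec.parameters),
                                     metric=metric, prcc=vals, p_value=pv,
                                     n=design.shape[0])
    return results


def rank_report(result: PrccResult) -> str:
    """Human-readable ranking table."""
    lines = [f"PRCC ranking for {result.metric} (n={result.n})",
             f"{'rank':>4} {'parameter':<16} {'PRCC':>8} {'p':>10}"]
    for r, (name, val, p) in enumerate(result.ranking(), start=1):
        lines.append(f"{r:>4} {name:<16} {val:>8.3f} {p:>10.2e}")
    return "\n".join(lines)
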