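"""In-silico experiments: TSP1 mechanism scans, combined surfaces, CRAC
inhibition, and therapy simulations with threshold detection.

The standard stimulation protocol is 2 nM TSP1 for 10 min followed by
50 ng/ml VEGF for 40 min; the control is the same protocol without TSP1.
Scan metrics are computed from fresh simulations at every grid point.
Threshold detection brackets the first crossing of a criterion (default:
a metric falling below 5% of control counts as *inhibited*; recovering to
50% of control counts as *recovered*) and refines it by bisection on fresh
simulations.  Both criterion levels are package definitions — the analysis
choices, not measured constants — and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .modelio import ModelDefinition
from .params import ParameterSet
from .simulate import (CompiledModel, Protocol, Trajectory, density_to_count,
                       count_to_density, tsp1_then_vegf_protocol,
                       vegf_protocol, SimulationError)

#: metrics a scan can report, as functions of a trajectory
METRICS = {
    "max_pR2": lambda tr: tr.max("pR2_frac"),
    "pR2_10min": lambda tr: tr.at("pR2_frac", _after_vegf(tr, 600.0)),
    "max_Ca": lambda tr: tr.max("Ca_c"),
    "max_Ca_rise": lambda tr: tr.max("Ca_c") - tr["Ca_c"][0],
    "end_Ca": lambda tr: tr.final("Ca_c"),
    "max_pERK": lambda tr: tr.max("pERK"),
    "pERK_10min": lambda tr: tr.at("pERK", _after_vegf(tr, 600.0)),
    "end_pERK": lambda tr: tr.final("pERK"),
}


def _after_vegf(tr: Trajectory, dt: float) -> float:
    """Time ``dt`` after the VEGF addition recorded in the trajectory."""
    return tr.diagnostics.get("vegf_time", 0.0) + dt


@dataclass
class ScanSpec:
    """One-dimensional scan of a parameter fold, ligand dose or depletion."""

    target: str                        # parameter name or "TSP1" / "CD47"
    grid: np.ndarray
    kind: str = "param"                # "param" | "tsp1_conc" | "depletion"
    metrics: tuple[str, ...] = ("max_pR2", "max_Ca", "max_pERK")
    tsp1_nM: float = 2.0
    simultaneous: bool = False
    vegf: str = "50 ng/ml"
    pre_min: float = 10.0
    vegf_min: float = 40.0

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("scan grid must be strictly increasing")
        if self.kind == "param" and np.any(g <= 0):
            raise ValueError("fold grid must be positive")
        self.grid = g


@dataclass
class ThresholdCriterion:
    """Definition of 'inhibited' / 'recovered' relative to a control value."""

    metric: str = "max_pERK"
    inhibited_below: float = 0.05      # fraction of control
    recovered_above: float = 0.50      # fraction of control
    rel_tol: float = 0.02              # bisection resolution (relative)

    def __post_init__(self):
        if not (0 < self.inhibited_below < 1 and 0 < self.recovered_above < 1):
            raise ValueError("criterion thresholds must lie in (0, 1)")


@dataclass
class ScanResult:
    spec: ScanSpec
    grid: np.ndarray
    metrics: dict[str, np.ndarray]
    control: dict[str, float]
    failures: list[tuple[float, str]] = field(default_factory=list)


class Experiment:
    """Scan/threshold driver bound to one compiled model."""

    def __init__(self, model: ModelDefinition | CompiledModel,
                 ps: ParameterSet | None = None):
        self.cm = (model if isinstance(model, CompiledModel)
                   else CompiledModel(model))
        self.ps = ps or self.cm.model.params

    # -- protocol assembly ---------------------------------------------------

    def _protocol(self, spec: ScanSpec, x: float | None) -> Protocol:
        overrides = {}
        tsp1 = spec.tsp1_nM
        if x is not None:
            if spec.kind == "param":
                overrides[spec.target] = self.ps.get(spec.target) * x
            elif spec.kind == "tsp1_conc":
                tsp1 = x
            elif spec.kind == "depletion":
                # depletion fraction x: fraction of the species removed
                scale_name = {"CD47": "cd47_scale", "NRP1": "nrp1_scale"}[spec.target]
                overrides[scale_name] = 1.0 - x
            else:
                raise ValueError(f"unknown scan kind {spec.kind!r}")
        pro = tsp1_then_vegf_protocol(
            tsp1_nM=tsp1, pre_min=spec.pre_min, vegf=spec.vegf,
            vegf_min=spec.vegf_min, simultaneous=spec.simultaneous,
            mw_kda=self.ps.get("mw_vegf_kda"))
        pro.overrides.update(overrides)
        return pro

    def _run(self, spec: ScanSpec, x: float | None) -> Trajectory:
        pro = self._protocol(spec, x)
        tr = self.cm.run_protocol(pro, self.ps)
        tr.diagnostics["vegf_time"] = (0.0 if spec.simultaneous
                                       else spec.pre_min * 60.0)
        return tr

    def control(self, spec: ScanSpec) -> dict[str, float]:
        """Metrics for the no-TSP1, unperturbed control protocol."""
        base = replace(spec, tsp1_nM=0.0)
        tr = self._run(base, None)
        return {m: METRICS[m](tr) for m in spec.metrics}

    # -- operations ----------------------------------------------------------

    def scan(self, spec: ScanSpec) -> ScanResult:
        ctrl = self.control(spec)
        out = {m: np.full(len(spec.grid), np.nan) for m in spec.metrics}
        failures = []
        for i, x in enumerate(spec.grid):
            try:
                tr = self._run(spec, float(x))
            except SimulationError as e:
                failures.append((float(x), str(e)))
                continue
            for m in spec.metrics:
                out[m][i] = METRICS[m](tr)
        return ScanResult(spec=spec, grid=spec.grid, metrics=out,
                          control=ctrl, failures=failures)

    def metric_at(self, spec: ScanSpec, x: float, metric: str) -> float:
        return METRICS[metric](self._run(spec, x))

    def find_threshold(self, spec: ScanSpec,
                       criterion: ThresholdCriterion,
                       direction: str = "inhibition",
                       scan: ScanResult | None = None) -> float | None:
        """First grid crossing of the criterion, refined by bisection.

        ``direction='inhibition'``: the metric falls below
        ``inhibited_below * control`` as the scanned value increases.
        ``direction='recovery'``: the metric rises above
        ``recovered_above * control``.  Returns None when the criterion is
        never met within the grid ("no threshold in range").
        """
        if scan is None:
            spec = replace(spec, metrics=(criterion.metric,))
            scan = self.scan(spec)
        ctrl = scan.control[criterion.metric]
        vals = scan.metrics[criterion.metric]
        if direction == "inhibition":
            level = criterion.inhibited_below * ctrl
            hit = vals < level
        elif direction == "recovery":
            level = criterion.recovered_above * ctrl
            hit = vals > level
        else:
            raise ValueError(direction)
        idx = np.flatnonzero(hit)
        if len(idx) == 0:
            return None
        i = int(idx[0])
        if i == 0:
            return float(scan.grid[0])
        lo, hi = float(scan.grid[i - 1]), float(scan.grid[i])
        # bisection on fresh simulations to the requested resolution
        while (hi - lo) > criterion.rel_tol * hi:
            mid = np.sqrt(lo * hi) if spec.kind == "param" else 0.5 * (lo + hi)
            v = self.metric_at(spec, mid, criterion.metric)
            crossed = (v < level) if direction == "inhibition" else (v > level)
            if crossed:
                hi = mid
            else:
                lo = mid
        return hi

    def surface(self, x_spec: ScanSpec, y_spec: ScanSpec,
                metric: str = "max_pERK") -> dict:
        """2-D scan: y_spec's axis varied inside x_spec's protocol."""
        Z = np.full((len(y_spec.grid), len(x_spec.grid)), np.nan)
        ctrl = self.control(replace(x_spec, metrics=(metric,)))
        for j, x in enumerate(x_spec.grid):
            for i, y in enumerate(y_spec.grid):
                spec = self._combine(x_spec, y_spec, float(x))
                try:
                    tr = self._run(spec, float(y))
                except SimulationError:
                    continue
                Z[i, j] = METRICS[metric](tr)
        return {"x": x_spec.grid, "y": y_spec.grid, "z": Z,
                "x_name": x_spec.target, "y_name": y_spec.target,
                "metric": metric, "control": ctrl[metric]}

    @staticmethod
    def _combine(x_spec: ScanSpec, y_spec: ScanSpec, x: float) -> ScanSpec:
        spec = replace(y_spec, metrics=y_spec.metrics)
        if x_spec.kind == "tsp1_conc":
            spec = replace(spec, tsp1_nM=x)
        elif x_spec.kind == "param":
            raise NotImplementedError(
                "use the param axis as the inner (y) axis")
        return spec

    # -- named studies -------------------------------------------------------

    def vegf_dose_response(self, grid_pM=None, duration_min=40.0) -> dict:
        """Peak pERK1/2 and peak pVEGFR2 per VEGF dose, with the switch dose
        (first grid dose whose pERK peak reaches 50% of the saturating
        response)."""
        grid = (np.array([0.5, 1, 2, 3.5, 5, 7.5, 10, 20, 50, 200, 1000.0])
                if grid_pM is None else np.asarray(grid_pM, float))
        perk, pr2 = [], []
        for pm in grid:
            tr = self.cm.run_protocol(
                vegf_protocol(vegf=f"{pm * 1e-3} nM",
                              duration_min=duration_min,
                              mw_kda=self.ps.get("mw_vegf_kda")), self.ps)
            perk.append(tr.max("pERK"))
            pr2.append(tr.max("pR2_frac"))
        perk = np.array(perk)
        sat = perk[-1]
        above = np.flatnonzero(perk >= 0.5 * sat) if sat > 0 else []
        switch = float(grid[above[0]]) if len(above) else None
        return {"grid_pM": grid, "max_pERK": perk, "max_pR2": np.array(pr2),
                "switch_pM": switch}

    def degradation_scan(self, grid=None, tsp1_nM=2.0, **kw) -> ScanResult:
        grid = grid if grid is not None else np.geomspace(1, 100, 25)
        return self.scan(ScanSpec("fold_deg", grid, tsp1_nM=tsp1_nM,
                                  metrics=("max_pR2", "pR2_10min", "max_Ca",
                                           "max_pERK"), **kw))

    def dephosphorylation_scan(self, grid=None, tsp1_nM=2.0, **kw) -> ScanResult:
        grid = grid if grid is not None else np.geomspace(1, 300, 25)
        return self.scan(ScanSpec("fold_dp", grid, tsp1_nM=tsp1_nM,
                                  metrics=("max_pR2", "pR2_10min", "max_Ca",
                                           "max_pERK"), **kw))

    def tsp1_dose_scan(self, grid=None, fold_deg=50.0) -> ScanResult:
        """Minimum inhibiting TSP1 concentration at a fixed degradation fold."""
        grid = grid if grid is not None else np.linspace(0.05, 3.0, 25)
        ps0 = self.ps
        self.ps = ps0.with_overrides(fold_deg=fold_deg)
        try:
            return self.scan(ScanSpec("TSP1", grid, kind="tsp1_conc",
                                      metrics=("max_pERK",)))
        finally:
            self.ps = ps0

    def crac_inhibition_study(self, amp_grid=None, tau_grid=None) -> dict:
        """Max and plateau calcium/ERK versus CRAC amplitude and time constant."""
        amp_grid = (np.linspace(0.0, 1.0, 6) if amp_grid is None
                    else np.asarray(amp_grid, float))
        tau_grid = (np.array([1.0, 2.5, 5.0, 10.0, 20.0]) if tau_grid is None
                    else np.asarray(tau_grid, float))
        out = {"amplitude": {"grid": amp_grid}, "tau": {"grid": tau_grid}}
        mets = ("max_Ca", "end_Ca", "max_pERK", "end_pERK")
        for key, grid, pname, scale in (
                ("amplitude", amp_grid, "frac_crac", 1.0),
                ("tau", tau_grid, "tau_crac", 1.0)):
            rows = {m: [] for m in mets}
            for x in grid:
                pro = vegf_protocol(duration_min=40.0,
                                    mw_kda=self.ps.get("mw_vegf_kda"))
                pro.overrides[pname] = float(x) * scale
                tr = self.cm.run_protocol(pro, self.ps)
                for m in mets:
                    tr.diagnostics["vegf_time"] = 0.0
                    rows[m].append(METRICS[m](tr))
            for m in mets:
                out[key][m] = np.array(rows[m])
        return out

    def cd47_level_scan(self, density_grid=None, fold_deg=10.0,
                        fold_dp=51.0, tsp1_nM=2.0) -> ScanResult:
        """Max pERK1/2 versus CD47 surface density (receptors/μm²)."""
        area = self.ps.get("area_um2")
        base_count = self.ps.get("CD47_0")
        grid = (np.linspace(0.0, 10.0, 11) if density_grid is None
                else np.asarray(density_grid, float))
        ps0 = self.ps
        ctrl = None
        vals = []
        self.ps = ps0.with_overrides(fold_deg=fold_deg, fold_dp=fold_dp)
        try:
            spec = ScanSpec("CD47", np.array([0.5]), kind="depletion",
                            tsp1_nM=tsp1_nM, metrics=("max_pERK",))
            ctrl = self.control(spec)
            for dens in grid:
                scale = density_to_count(dens, area) / base_count
                pro = self._protocol(replace(spec, kind="param",
                                             target="cd47_scale"), None)
                pro.overrides["cd47_scale"] = max(scale, 0.0)
                tr = self.cm.run_protocol(pro, self.ps)
                tr.diagnostics["vegf_time"] = spec.pre_min * 60.0
                vals.append(METRICS["max_pERK"](tr))
        finally:
            self.ps = ps0
        sc = ScanSpec("CD47_density", np.maximum(grid, 1e-12),
                      kind="param", metrics=("max_pERK",))
        return ScanResult(spec=sc, grid=grid,
                          metrics={"max_pERK": np.array(vals)}, control=ctrl)

    def therapy_tsp1_inhibition(self, inhibition_grid=None, fold_deg=10.0,
                                fold_dp=51.0, tsp1_nM=2.0,
                                metrics=("max_Ca_rise", "max_pERK")) -> ScanResult:
        """TSP1 inhibition therapy: scan the inhibited fraction of TSP1 with
        the combined enhanced-degradation/dephosphorylation mechanism and
        simultaneous TSP1+VEGF addition."""
        grid = (np.linspace(0.0, 0.99, 21) if inhibition_grid is None
                else np.asarray(inhibition_grid, float))
        ps0 = self.ps
        self.ps = ps0.with_overrides(fold_deg=fold_deg, fold_dp=fold_dp)
        try:
            ctrl_spec = ScanSpec("TSP1", np.array([1.0]), kind="tsp1_conc",
                                 metrics=metrics, simultaneous=True)
            ctrl = self.control(ctrl_spec)
            out = {m: [] for m in metrics}
            for inh in grid:
                tr = self._run(ctrl_spec, tsp1_nM * (1.0 - float(inh)))
                for m in metrics:
                    out[m].append(METRICS[m](tr))
        finally:
            self.ps = ps0
        sc = ScanSpec("tsp1_inhibition", np.maximum(grid, 1e-12),
                      kind="param", metrics=metrics, simultaneous=True)
        return ScanResult(spec=sc, grid=grid,
                          metrics={m: np.array(v) for m, v in out.items()},
                          control=ctrl)

    def therapy_cd47_depletion(self, depletion_grid=None, fold_deg=10.0,
                               fold_dp=51.0, tsp1_nM=2.0,
                               metrics=("max_Ca_rise", "max_pERK")) -> ScanResult:
        """CD47 depletion therapy under the combined mechanism."""
        grid = (np.linspace(0.0, 0.99, 21) if depletion_grid is None
                else np.asarray(depletion_grid, float))
        ps0 = self.ps
        self.ps = ps0.with_overrides(fold_deg=fold_deg, fold_dp=fold_dp)
        try:
            spec = ScanSpec("CD47", grid if grid[0] > 0 else grid + 0.0,
                            kind="depletion", tsp1_nM=tsp1_nM,
                            metrics=metrics, simultaneous=True)
            ctrl = self.control(spec)
            out = {m: [] for m in metrics}
            for x in grid:
                tr = self._run(spec, float(x))
                for m in metrics:
                    out[m].append(METRICS[m](tr))
        finally:
            self.ps = ps0
        sc = ScanSpec("cd47_depletion", np.maximum(grid, 1e-12),
                      kind="param", metrics=metrics, simultaneous=True)
        return ScanResult(spec=sc, grid=grid,
                          metrics={m: np.array(v) for m, v in out.items()},
                          control=ctrl)


def recovery_threshold(result: ScanResult, criterion: ThresholdCriterion) -> float | None:
    """Grid-level recovery threshold from an existing scan (no refinement)."""
    ctrl = result.control[criterion.metric]
    vals = result.metrics[criterion.metric]
    hit = vals > criterion.recovered_above * ctrl
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(result.grid[0])
    # linear interpolation between the bracketing grid points
    x0, x1 = result.grid[i - 1], result.grid[i]
    y0, y1 = vals[i - 1], vals[i]
    level = criterion.recovered_above * ctrl
    if y1 == y0:
        return float(x1)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def inhibition_threshold(result: ScanResult, criterion: ThresholdCriterion) -> float | None:
    """Grid-level inhibition threshold from an existing scan."""
    ctrl = result.control[criterion.metric]
    vals = result.metrics[criterion.metric]
    hit = vals < criterion.inhibited_below * ctrl
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(result.grid[0])
    x0, x1 = result.grid[i - 1], result.grid[i]
    y0, y1 = vals[i - 1], vals[i]
    level = criterion.inhibited_below * ctrl
    if y1 == y0:
        return float(x1)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))
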