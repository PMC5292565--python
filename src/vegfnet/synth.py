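"""Synthetic fitting/validation datasets with the statistical structure the
analysis assumes.

The twelve panel types mirror the model-parameterization targets: total and
surface VEGFR2 decay under continuous VEGF (with and without NRP1),
pVEGFR2(t), pPLCγ(t), normalized and raw cytosolic calcium, pERK1/2(t) with
and without SphK1 blockade, the VEGF surface-binding curve, and the
pVEGFR2/pERK1/2 dose-response curves.  Each panel simulates its protocol
under a given parameter set, samples the observable on the panel's grid in
the panel's presentation (fraction of the resting total, normalized to
peak, or raw), and optionally applies observation noise.

The same panel definitions drive both dataset generation and the fitting
module's simulator, so synthetic datasets and packaged fixtures share one
schema and the fitter cannot distinguish them.  The packaged CSV fixtures
are *synthetic* stand-ins produced by this module (the originals are
digitized Western-blot/flow/fluorimetry curves that ship with no deposited
data); their manifest records the emulated panel for each file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fitting import FitDataset
from .params import ParameterSet
from .simulate import CompiledModel, Protocol, vegf_protocol


@dataclass
class NoiseModel:
    """Observation noise: additive Gaussian or proportional."""

    kind: str = "additive-gaussian"     # or "proportional"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind not in ("additive-gaussian", "proportional"):
            raise ValueError(f"unknown noise model {self.kind!r}")

    def apply(self, values: np.ndarray, rng=None) -> np.ndarray:
        if self.sigma == 0:
            return np.array(values, dtype=float)
        rng = rng or np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.sigma, size=np.shape(values))
        if self.kind == "additive-gaussian":
            return values + eps
        return values * (1.0 + eps)


@dataclass
class PanelSpec:
    observable: str
    duration_min: float
    normalization: str = "none"         # "none" | "peak" | "baseline_peak"
    overrides: dict | None = None
    dose_panel: bool = False
    dose_grid_pM: tuple = ()
    vegf: str = "50 ng/ml"
    default_grid_min: tuple = ()


_TC_GRID_180 = tuple(range(0, 181, 15))
_TC_GRID_60 = tuple(range(0, 61, 5))
_TC_GRID_30 = tuple(np.arange(0, 30.5, 2.5))
_DOSES = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 200.0, 1000.0)

#: the twelve model-parameterization panels
PANELS: dict[str, PanelSpec] = {
    "r2_total": PanelSpec("R2_total_frac", 180, default_grid_min=_TC_GRID_180),
    "r2_total_no_nrp1": PanelSpec("R2_total_frac", 180,
                                  overrides={"nrp1_scale": 1e-9},
                                  default_grid_min=_TC_GRID_180),
    "r2_surface": PanelSpec("R2_surf_frac", 60, default_grid_min=_TC_GRID_60),
    "pr2": PanelSpec("pR2_frac", 60, default_grid_min=_TC_GRID_60),
    "pplcg": PanelSpec("pPLCg", 60, normalization="peak",
                       default_grid_min=_TC_GRID_60),
    "ca_norm": PanelSpec("Ca_c", 30, normalization="baseline_peak",
                         default_grid_min=_TC_GRID_30),
    "ca_raw": PanelSpec("Ca_c", 30, default_grid_min=_TC_GRID_30),
    "perk": PanelSpec("pERK", 60, normalization="peak",
                      default_grid_min=_TC_GRID_60),
    "perk_sphk1_block": PanelSpec("pERK", 60,
                                  overrides={"kserk": 0.0},
                                  default_grid_min=_TC_GRID_60),
    "vegf_binding": PanelSpec("VEGF_bound", 30, normalization="peak",
                              dose_panel=True, dose_grid_pM=_DOSES),
    "pr2_dose": PanelSpec("pR2_frac", 40, normalization="peak",
                          dose_panel=True, dose_grid_pM=_DOSES),
    "perk_dose": PanelSpec("pERK", 40, normalization="peak",
                           dose_panel=True, dose_grid_pM=_DOSES),
}


class UnknownPanelError(KeyError):
    pass


def panel_prediction(cm: CompiledModel, ps: ParameterSet, panel_name: str,
                     grid: np.ndarray) -> np.ndarray:
    """Noise-free model output for one panel on the given grid.

    For time-course panels the grid is time in minutes; for dose panels it
    is VEGF in pM (the reported value is the response maximum per dose).
    """
    try:
        panel = PANELS[panel_name]
    except KeyError:
        raise UnknownPanelError(f"unknown panel {panel_name!r}") from None
    mw = ps.get("mw_vegf_kda")
    ov = dict(panel.overrides or {})
    if panel.dose_panel:
        vals = []
        for dose_pM in grid:
            pro = vegf_protocol(vegf=f"{dose_pM * 1e-3} nM",
                                duration_min=panel.duration_min, mw_kda=mw,
                                overrides=ov)
            tr = cm.run_protocol(pro, ps)
            vals.append(tr.max(panel.observable))
        vals = np.array(vals)
    else:
        pro = vegf_protocol(vegf=panel.vegf, duration_min=panel.duration_min,
                            mw_kda=mw, overrides=ov)
        tr = cm.run_protocol(pro, ps)
        vals = np.array([tr.at(panel.observable, t * 60.0) for t in grid])
    if panel.normalization == "peak":
        peak = float(np.max(np.abs(vals)))
        if peak > 0:
            vals = vals / peak
    elif panel.normalization == "baseline_peak":
        base = vals[0]
        rng_ = float(np.max(vals) - base)
        if rng_ > 0:
            vals = (vals - base) / rng_
    return vals


def generate_datasets(cm: CompiledModel, ps: ParameterSet,
                      panels: list[str] | None = None,
                      noise: NoiseModel | None = None) -> list[FitDataset]:
    """Simulate panels under ``ps``, sample their grids, apply noise."""
    panels = panels or list(PANELS)
    noise = noise or NoiseModel(sigma=0.0)
    rng = np.random.default_rng(noise.seed)
    out = []
    for name in panels:
        if name not in PANELS:
            raise UnknownPanelError(f"unknown panel {name!r}")
        spec = PANELS[name]
        grid = np.array(spec.dose_grid_pM if spec.dose_panel
                        else spec.default_grid_min, dtype=float)
        clean = panel_prediction(cm, ps, name, grid)
        out.append(FitDataset(
            name=name, observable=spec.observable, protocol=name,
            grid=grid, values=noise.apply(clean, rng),
            normalization=spec.normalization,
            source=f"synthetic (model-generated, panel {name}, "
                   f"{noise.kind} sigma={noise.sigma})"))
    return out


def make_simulator(cm: CompiledModel):
    """Fitting-module simulator closed over a compiled model."""
    def simulator(ps: ParameterSet, ds: FitDataset) -> np.ndarray:
        return panel_prediction(cm, ps, ds.protocol, ds.grid)
    return simulator


def write_fixture_csvs(datasets: list[FitDataset], directory) -> None:
    """Write datasets + manifest in the packaged fixture schema."""
    import pandas as pd
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ds in datasets:
        fn = f"{ds.name}_synthetic.csv"
        pd.DataFrame({"grid": ds.grid, "value": ds.values}).to_csv(
            directory / fn, index=False)
        manifest.append({"file": fn, "name": ds.name,
                         "observable": ds.observable, "protocol": ds.protocol,
                         "normalization": ds.normalization,
                         "weight": ds.weight, "source": ds.source})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_fixture_csvs(directory) -> list[FitDataset]:
    import pandas as pd
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for rec in manifest:
        df = pd.read_csv(directory / rec["file"])
        out.append(FitDataset(
            name=rec["name"], observable=rec["observable"],
            protocol=rec["protocol"], grid=df["grid"].to_numpy(),
            values=df["value"].to_numpy(),
            weight=rec.get("weight", 1.0),
            normalization=rec.get("normalization", "none"),
            source=rec.get("source", "")))
    return out


def recovery_experiment(cm: CompiledModel, true_ps: ParameterSet,
                        fit_names: list[str], perturb: float = 2.0,
                        noise: NoiseModel | None = None,
                        panels: list[str] | None = None,
                        max_eval: int = 300, seed: int = 0) -> dict:
    """Parameter-recovery study: fit from a perturbed start against data
    generated from known true parameters; report per-parameter errors."""
    from .fitting import fit
    panels = panels or ["r2_total", "pr2", "ca_raw"]
    datasets = generate_datasets(cm, true_ps, panels, noise)
    start = true_ps.copy()
    rng = np.random.default_rng(seed)
    for i, n in enumerate(fit_names):
        factor = perturb if (i + rng.integers(0, 2)) % 2 else 1.0 / perturb
        start.set(n, true_ps.get(n) * factor)
    bounds = {n: (true_ps.get(n) / 100.0, true_ps.get(n) * 100.0)
              for n in fit_names}
    res = fit(start, datasets, make_simulator(cm), fit_names, bounds,
              seed=seed, max_eval=max_eval)
    report = {"objective": res.objective, "n_eval": res.n_eval,
              "parameters": {}}
    for n in fit_names:
        tv, fv = true_ps.get(n), res.params.get(n)
        report["parameters"][n] = {
            "true": tv, "start": start.get(n), "fitted": fv,
            "rel_error": abs(fv - tv) / abs(tv) if tv else np.inf}
    report["max_rel_error"] = max(p["rel_error"]
                                  for p in report["parameters"].values())
    return report
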