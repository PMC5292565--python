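"""Compile the reaction network plus the cascade/calcium closures into one
ODE system and run timed stimulation protocols.

State layout: the enumerated network species (per-cell molecule counts;
clamped ligand pools in nM), followed by the ten cascade states (μM) and the
three calcium states (μM and μM/s).  Coupling is one-way from the network:
the pVEGFR2 observable (converted to μM) drives PLCγ phosphorylation, the
cascade's IP3 drives the calcium module, and cytosolic calcium gates the
CIB1/SphK1 feedback inside the cascade.  Nothing feeds back into the
receptor network, which keeps its Jacobian block exact and cheap.

Protocols are ordered event lists (set a clamped ligand concentration, scale
or set a parameter); integration restarts at each event time.  Unless
disabled, the receptor network is pre-equilibrated without ligand so that
``t = 0`` totals (the denominators of all fraction-total observables) refer
to the resting cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from . import calcium as _cal
from . import cascade as _casc
from .modelio import ModelDefinition
from .params import ParameterSet
from .rules import ReactionNetwork

N_CASCADE = len(_casc.CASCADE_STATES)
N_CALCIUM = len(_cal.CALCIUM_STATES)

#: default solver settings (overridable per call)
DEFAULT_RTOL = 1e-7
DEFAULT_ATOL = 1e-9
EQUILIBRATION_TIME = 2.0e5  # s; ligand-free relaxation to the resting state


class SimulationError(RuntimeError):
    """Solver failure, annotated with the last successfully reached time."""

    def __init__(self, msg, last_time=None):
        self.last_time = last_time
        super().__init__(msg if last_time is None
                         else f"{msg} (last good time {last_time:.3f} s)")


class UnitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def ligand_to_nM(value: float, unit: str, mw_kda: float | None = None) -> float:
    """Convert a ligand concentration to nM.

    ``ng/ml`` requires the molar mass in kDa (1 ng/ml of a 1 kDa species is
    exactly 1 nM); the packaged VEGF molar mass is the VEGF-A165 homodimer.
    """
    if value < 0:
        raise UnitError("negative concentration")
    if unit == "nM":
        return float(value)
    if unit == "pM":
        return float(value) * 1e-3
    if unit == "ng/ml":
        if not mw_kda or mw_kda <= 0:
            raise UnitError("ng/ml conversion needs a molar mass (kDa)")
        return float(value) / mw_kda
    raise UnitError(f"unknown concentration unit {unit!r}")


def nM_to_unit(value_nM: float, unit: str, mw_kda: float | None = None) -> float:
    if unit == "nM":
        return float(value_nM)
    if unit == "pM":
        return float(value_nM) * 1e3
    if unit == "ng/ml":
        if not mw_kda or mw_kda <= 0:
            raise UnitError("ng/ml conversion needs a molar mass (kDa)")
        return float(value_nM) * mw_kda
    raise UnitError(f"unknown concentration unit {unit!r}")


def density_to_count(per_um2: float, area_um2: float) -> float:
    """Receptor surface density (molecules/μm²) to per-cell copy number."""
    return per_um2 * area_um2


def count_to_density(count: float, area_um2: float) -> float:
    return count / area_um2


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class ProtocolEvent:
    time: float                 # seconds
    action: str                 # "set_ligand" | "scale_param" | "set_param"
    target: str
    value: float
    unit: str | None = None     # for set_ligand


@dataclass
class Protocol:
    """Timed stimulation schedule with an output grid."""

    events: list[ProtocolEvent] = field(default_factory=list)
    duration: float = 3000.0    # seconds
    dt_out: float = 5.0
    equilibrate: bool = True
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("protocol event times must be non-decreasing")
        for e in self.events:
            if e.action == "scale_param" and e.value <= 0:
                raise ValueError("fold scalings must be > 0")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt_out))
        return np.linspace(0.0, self.duration, n + 1)

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        events = []
        for e in d.get("events", []):
            t = float(e.get("time_s", e.get("time_min", 0) * 60.0))
            if "set_ligand" in e:
                events.append(ProtocolEvent(t, "set_ligand", e["set_ligand"],
                                            float(e["value"]),
                                            e.get("unit", "nM")))
            elif "scale_param" in e:
                events.append(ProtocolEvent(t, "scale_param", e["scale_param"],
                                            float(e["value"])))
            elif "set_param" in e:
                events.append(ProtocolEvent(t, "set_param", e["set_param"],
                                            float(e["value"])))
            else:
                raise ValueError(f"unknown protocol event {e!r}")
        dur = float(d.get("duration_s", d.get("duration_min", 50) * 60.0))
        return cls(events=sorted(events, key=lambda e: e.time),
                   duration=dur,
                   dt_out=float(d.get("dt_out_s", 5.0)),
                   equilibrate=bool(d.get("equilibrate", True)),
                   overrides={k: float(v)
                              for k, v in (d.get("overrides") or {}).items()})

    @classmethod
    def from_yaml(cls, path) -> "Protocol":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def vegf_protocol(vegf="50 ng/ml", duration_min=40.0, mw_kda=38.4,
                  dt_out=5.0, **kw) -> Protocol:
    """Continuous VEGF exposure from t=0."""
    val, unit = _parse_conc(vegf)
    return Protocol(events=[ProtocolEvent(0.0, "set_ligand", "VEGF",
                                          ligand_to_nM(val, unit, mw_kda),
                                          "nM")],
                    duration=duration_min * 60.0, dt_out=dt_out, **kw)


def tsp1_then_vegf_protocol(tsp1_nM=2.0, pre_min=10.0, vegf="50 ng/ml",
                            vegf_min=40.0, mw_kda=38.4, dt_out=5.0,
                            simultaneous=False, **kw) -> Protocol:
    """The standard inhibition protocol: TSP1 pre-incubation, then VEGF
    (or simultaneous addition of both)."""
    val, unit = _parse_conc(vegf)
    vegf_nM = ligand_to_nM(val, unit, mw_kda)
    if simultaneous:
        ev = [ProtocolEvent(0.0, "set_ligand", "TSP1", tsp1_nM, "nM"),
              ProtocolEvent(0.0, "set_ligand", "VEGF", vegf_nM, "nM")]
        dur = vegf_min * 60.0
    else:
        ev = [ProtocolEvent(0.0, "set_ligand", "TSP1", tsp1_nM, "nM"),
              ProtocolEvent(pre_min * 60.0, "set_ligand", "VEGF", vegf_nM,
                            "nM")]
        dur = (pre_min + vegf_min) * 60.0
    return Protocol(events=ev, duration=dur, dt_out=dt_out, **kw)


def _parse_conc(text) -> tuple[float, str]:
    if isinstance(text, (int, float)):
        return float(text), "nM"
    parts = str(text).split()
    return float(parts[0]), parts[1] if len(parts) > 1 else "nM"


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    t: np.ndarray
    series: dict[str, np.ndarray]
    diagnostics: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def names(self):
        return list(self.series)

    def max(self, name: str) -> float:
        return float(np.max(self.series[name]))

    def at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.t, self.series[name]))

    def final(self, name: str) -> float:
        return float(self.series[name][-1])

    def frame(self):
        import pandas as pd
        return pd.DataFrame({"t_s": self.t, **self.series})


# ---------------------------------------------------------------------------
# the compiled model
# ---------------------------------------------------------------------------

class CompiledModel:
    """A ReactionNetwork plus the cascade/calcium closures, ready to solve."""

    def __init__(self, model: ModelDefinition,
                 network: ReactionNetwork | None = None):
        self.model = model
        self.network = network if network is not None else model.generate()
        net = self.network
        if not net.converged:
            raise SimulationError("network generation did not converge")
        n_s = net.n_species
        self.n_s = n_s
        # the cascade/calcium closures attach only when their parameters are
        # declared (a bare reaction network compiles to counts-only ODEs)
        self.has_downstream = ("kplc" in model.params
                               and "Ibar_crac" in model.params)
        self.n_small = (N_CASCADE + N_CALCIUM) if self.has_downstream else 0
        self.n_state = n_s + self.n_small

        nr = len(net.reactions)
        self._i1 = np.empty(nr, dtype=np.intp)
        self._i2 = np.full(nr, -1, dtype=np.intp)
        rows, cols, vals = [], [], []
        for j, rx in enumerate(net.reactions):
            self._i1[j] = rx.reactants[0]
            if len(rx.reactants) == 2:
                self._i2[j] = rx.reactants[1]
            stoich: dict[int, int] = {}
            for s in rx.reactants:
                stoich[s] = stoich.get(s, 0) - 1
            for s in rx.products:
                stoich[s] = stoich.get(s, 0) + 1
            for s, v in stoich.items():
                rows.append(s)
                cols.append(j)
                vals.append(float(v))
        self._S = sp.csr_matrix((vals, (rows, cols)), shape=(n_s, nr))
        self._bimol = self._i2 >= 0
        self._clamped = np.array(net.clamped, dtype=bool)
        self._free_mask = (~self._clamped).astype(float)

        self._W = net.observable_matrix()
        self._obs_names = [o.name for o in net.observables]
        if "pR2" in self._obs_names:
            self._w_pr2 = self._W[self._obs_names.index("pR2")]
        else:
            import numpy as _np
            self._w_pr2 = _np.zeros(n_s)
        self._ligand_idx = {}
        for seed in model.seeds:
            if seed.clamped and len(seed.graph.mols) == 1:
                self._ligand_idx[seed.graph.mols[0].type.name] = \
                    net.index_of(seed.graph.canonical_label())
        self._eq_cache: dict = {}

    # -- parameter plumbing --------------------------------------------------

    def rate_vector(self, ps: ParameterSet) -> np.ndarray:
        return np.array([ps.evaluate(rx.rate) * rx.factor
                         for rx in self.network.reactions])

    def initial_state(self, ps: ParameterSet) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        for i, expr in enumerate(self.network.init):
            y0[i] = ps.evaluate(expr)
        if self.has_downstream:
            cp = _casc.CascadeParams.from_parameterset(ps)
            lp = _cal.CalciumParams.from_parameterset(ps)
            y0[self.n_s:self.n_s + N_CASCADE] = _casc.rest_state(cp)
            y0[self.n_s + N_CASCADE:] = _cal.rest_state(lp)
        return y0

    # -- ODE assembly --------------------------------------------------------

    def build_ode(self, ps: ParameterSet):
        """Return (rhs, jac) callables for the full state vector."""
        k = self.rate_vector(ps)
        if np.any(k < 0):
            raise SimulationError("negative rate constant")
        if self.has_downstream:
            cp = _casc.CascadeParams.from_parameterset(ps)
            lp = _cal.CalciumParams.from_parameterset(ps)
            c2u = ps.get("count_to_uM")
        else:
            cp = lp = None
            c2u = 0.0
        n_s, n_small = self.n_s, self.n_small
        i1, i2, bimol = self._i1, self._i2, self._bimol
        S, free = self._S, self._free_mask
        w_pr2 = self._w_pr2

        def small_rhs(small: np.ndarray, pr2_uM: float) -> np.ndarray:
            casc = small[:N_CASCADE]
            cal = small[N_CASCADE:]
            dc = _casc.cascade_rhs(casc, pr2_uM, cal[0], cp)
            dl = _cal.calcium_rhs(cal, casc[1], lp)
            return np.concatenate([dc, dl])

        def rhs(t, y):
            ys = y[:n_s]
            f = k * ys[i1]
            f[bimol] *= ys[i2[bimol]]
            dnet = S @ f
            dnet *= free
            if n_small == 0:
                return dnet
            pr2_uM = max(c2u * float(w_pr2 @ ys), 0.0)
            return np.concatenate([dnet, small_rhs(y[n_s:], pr2_uM)])

        def jac(t, y):
            ys = y[:n_s]
            nr = len(k)
            v1 = k * np.where(bimol, ys[np.where(bimol, i2, 0)], 1.0)
            v2 = k * ys[i1]
            rows = np.concatenate([np.arange(nr), np.arange(nr)[bimol]])
            cols = np.concatenate([i1, i2[bimol]])
            vals = np.concatenate([v1, v2[bimol]])
            Fp = sp.csr_matrix((vals, (rows, cols)), shape=(nr, n_s))
            J = np.zeros((self.n_state, self.n_state))
            J[:n_s, :n_s] = (S @ Fp).toarray()
            J[:n_s, :n_s] *= free[:, None]
            if n_small == 0:
                return J
            # cascade/calcium own-block: finite differences (13x13, cheap)
            small = y[n_s:]
            pr2_uM = max(c2u * float(w_pr2 @ ys), 0.0)
            f0 = small_rhs(small, pr2_uM)
            eps_base = 1e-7
            for j in range(n_small):
                h = eps_base * max(abs(small[j]), 1.0)
                pert = small.copy()
                pert[j] += h
                J[n_s:, n_s + j] = (small_rhs(pert, pr2_uM) - f0) / h
            # cross-term: pPLCg depends on the pVEGFR2 observable
            plcg_free = max(cp.plcg_tot - small[0], 0.0)
            coeff = cp.kplc * plcg_free / (cp.km_plc + plcg_free) * c2u
            J[n_s, :n_s] = coeff * w_pr2
            return J

        return rhs, jac

    # -- equilibration and protocol runs -------------------------------------

    def _eq_key(self, ps: ParameterSet):
        skip = {"fold_deg", "fold_dp", "k_deg_tsp1", "k_dp_tsp1"}
        return tuple(sorted((n, v) for n, v in ps.as_dict().items()
                            if n not in skip))

    def equilibrate(self, ps: ParameterSet,
                    t_eq: float = EQUILIBRATION_TIME) -> np.ndarray:
        """Ligand-free resting state (cached per parameter values)."""
        key = self._eq_key(ps)
        hit = self._eq_cache.get(key)
        if hit is not None:
            return hit.copy()
        rhs, jac = self.build_ode(ps)
        y0 = self.initial_state(ps)
        sol = solve_ivp(rhs, (0.0, t_eq), y0, method="LSODA", jac=jac,
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise SimulationError("equilibration failed", sol.t[-1])
        yeq = sol.y[:, -1]
        yeq[np.abs(yeq) < 1e-12] = 0.0
        self._eq_cache[key] = yeq.copy()
        return yeq

    def run_protocol(self, protocol: Protocol,
                     ps: ParameterSet | None = None,
                     rtol: float = DEFAULT_RTOL,
                     atol: float = DEFAULT_ATOL,
                     method: str = "LSODA") -> Trajectory:
        """Integrate a stimulation protocol and report observables.

        Fraction-total observables are normalized to the ``t = 0`` totals
        (resting cell after ligand-free pre-equilibration).
        """
        ps = (ps or self.model.params).copy()
        if protocol.overrides:
            ps = ps.with_overrides(**protocol.overrides)
        y0 = (self.equilibrate(ps) if protocol.equilibrate
              else self.initial_state(ps))

        tgrid = protocol.time_grid
        # segment boundaries at event times
        times = sorted({0.0, protocol.duration}
                       | {e.time for e in protocol.events})
        times = [t for t in times if 0.0 <= t <= protocol.duration]
        events_at: dict[float, list[ProtocolEvent]] = {}
        for e in protocol.events:
            events_at.setdefault(e.time, []).append(e)

        y = y0.copy()
        out_t: list[np.ndarray] = []
        out_y: list[np.ndarray] = []
        nfev = 0
        cur_ps = ps
        rhs, jac = self.build_ode(cur_ps)
        mw = ps.get("mw_vegf_kda") if "mw_vegf_kda" in ps else None

        def apply_events(evs):
            nonlocal cur_ps, rhs, jac
            rebuild = False
            for e in evs:
                if e.action == "set_ligand":
                    idx = self._ligand_idx.get(e.target)
                    if idx is None:
                        raise SimulationError(
                            f"no clamped ligand species {e.target!r}")
                    y[idx] = ligand_to_nM(e.value, e.unit or "nM", mw)
                elif e.action == "scale_param":
                    cur_ps = cur_ps.scaled(e.target, e.value)
                    rebuild = True
                elif e.action == "set_param":
                    cur_ps = cur_ps.with_overrides(**{e.target: e.value})
                    rebuild = True
                else:
                    raise SimulationError(f"unknown protocol action {e.action}")
            if rebuild:
                rhs, jac = self.build_ode(cur_ps)

        for a, b in zip(times[:-1], times[1:]):
            apply_events(events_at.get(a, []))
            seg_t = tgrid[(tgrid >= a) & (tgrid <= b)]
            if len(seg_t) == 0 or seg_t[0] > a:
                seg_t = np.concatenate([[a], seg_t])
            if seg_t[-1] < b:
                seg_t = np.concatenate([seg_t, [b]])
            sol = solve_ivp(rhs, (a, b), y, method=method, jac=jac,
                            rtol=rtol, atol=atol, t_eval=seg_t)
            if not sol.success:
                raise SimulationError("solver failure", sol.t[-1]
                                      if len(sol.t) else a)
            nfev += sol.nfev
            out_t.append(sol.t)
            out_y.append(sol.y)
            y = sol.y[:, -1].copy()
        apply_events(events_at.get(times[-1], []))

        t = np.concatenate(out_t)
        Y = np.concatenate(out_y, axis=1)
        keep = np.concatenate([[True], np.diff(t) > 0])
        t, Y = t[keep], Y[:, keep]
        return self._package(t, Y, {"nfev": nfev, "rtol": rtol, "atol": atol})

    def _package(self, t, Y, diagnostics) -> Trajectory:
        series: dict[str, np.ndarray] = {}
        obs = self._W @ Y[:self.n_s]
        for name, row in zip(self._obs_names, obs):
            series[name] = row
        r2_0 = series["R2_total"][0] if "R2_total" in series else 0.0
        if r2_0 > 0:
            for name in ("R2_total", "R2_surf", "R2_endo", "pR2",
                         "pR2_surf", "pR2_endo"):
                if name in series:
                    series[name + "_frac"] = series[name] / r2_0
        if self.has_downstream:
            for i, name in enumerate(_casc.CASCADE_STATES):
                series[name] = Y[self.n_s + i]
            for i, name in enumerate(_cal.CALCIUM_STATES):
                series[name] = Y[self.n_s + N_CASCADE + i]
        return Trajectory(t=t, series=series, diagnostics=diagnostics)


def run_protocol(model, protocol: Protocol, ps: ParameterSet | None = None,
                 **kw) -> Trajectory:
    """Convenience wrapper: accepts a ModelDefinition or a CompiledModel."""
    if isinstance(model, ModelDefinition):
        model = CompiledModel(model)
    return model.run_protocol(protocol, ps, **kw)
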