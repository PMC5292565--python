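"""Calcium cycling: IP3-gated ER release, SERCA and plasma-membrane pumps,
rapid buffering, and a store-operated CRAC current.

The CRAC current relaxes toward a steady-state value that is an empirical
Hill function of ER calcium,

    dJ/dt = (I(Ca_ER) - J) / τ,      I = Ī · K^h / (K^h + Ca_ER^h),

with Hill exponent h = 4.2: the current switches on as the store empties.
Cytosolic and ER free calcium use the rapid-buffering reduction with
constant buffering factors f_cyt and f_er (fraction of incoming calcium that
stays free).  The ER leak and the resting plasma-membrane influx are derived
from the configured resting point (Ca_cyt ≈ 0.1 μM, Ca_ER ≈ 400 μM) so the
unstimulated cell sits at an exact steady state.

Units: μM and seconds; fluxes are cytosolic μM/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

#: calcium state vector layout
CALCIUM_STATES = ["Ca_c", "Ca_er", "J_crac"]


class DomainError(ValueError):
    pass


@dataclass
class CracParams:
    ibar: float          # maximal current, μM/s (scaled by the inhibition dial)
    k_crac: float        # half-activation ER calcium, μM
    hill: float          # fixed 4.2 in the packaged model
    tau: float           # activation time constant, s

    def __post_init__(self):
        if min(self.ibar, self.k_crac, self.hill, self.tau) <= 0 \
                and self.ibar != 0:
            raise DomainError("CRAC parameters must be positive")


def crac_steady_current(ca_er: float, p: CracParams) -> float:
    """Steady-state CRAC current (μM/s); strictly decreasing in Ca_ER."""
    if np.any(np.asarray(ca_er) < 0):
        raise DomainError("negative ER calcium")
    kh = p.k_crac ** p.hill
    return p.ibar * kh / (kh + np.asarray(ca_er, dtype=float) ** p.hill)


def crac_dynamics(j: float, i: float, tau: float) -> float:
    """Relaxation dJ/dt = (I - J)/τ."""
    if tau <= 0:
        raise DomainError("tau must be positive")
    return (i - j) / tau


@dataclass
class CalciumParams:
    ca_c0: float
    ca_er0: float
    f_cyt: float
    f_er: float
    vol_ratio: float        # V_cyt / V_ER
    k_ip3r: float
    k_ip3: float
    v_serca: float
    k_serca: float
    v_pmca: float
    k_pmca: float
    crac: CracParams
    k_er_leak: float = 0.0  # derived: balances SERCA at rest
    j_in0: float = 0.0      # derived: balances PMCA - CRAC at rest
    pm_enabled: bool = True

    @classmethod
    def from_parameterset(cls, ps: ParameterSet) -> "CalciumParams":
        g = ps.get
        crac = CracParams(ibar=g("Ibar_crac") * g("frac_crac"),
                          k_crac=g("K_crac"), hill=g("hill_crac"),
                          tau=g("tau_crac"))
        p = cls(ca_c0=g("Ca_c0"), ca_er0=g("Ca_er0"),
                f_cyt=g("f_cyt"), f_er=g("f_er"), vol_ratio=g("vol_ratio"),
                k_ip3r=g("k_ip3r"), k_ip3=g("K_ip3"),
                v_serca=g("v_serca"), k_serca=g("K_serca"),
                v_pmca=g("v_pmca"), k_pmca=g("K_pmca"), crac=crac)
        p.derive_rest_balance()
        return p

    def derive_rest_balance(self) -> None:
        """Fix leak/influx constants so the configured rest is a fixed point."""
        c0, e0 = self.ca_c0, self.ca_er0
        serca0 = self.v_serca * c0 ** 2 / (c0 ** 2 + self.k_serca ** 2)
        self.k_er_leak = serca0 / max(e0 - c0, 1e-9)
        pmca0 = self.v_pmca * c0 ** 2 / (c0 ** 2 + self.k_pmca ** 2)
        j_crac0 = float(crac_steady_current(e0, self.crac)) \
            if self.crac.ibar > 0 else 0.0
        self.j_in0 = max(pmca0 - j_crac0, 0.0)


def ip3r_open(ip3: float, p: CalciumParams) -> float:
    """IP3 receptor open fraction (Hill-2 in IP3)."""
    i2 = ip3 * ip3
    return i2 / (p.k_ip3 ** 2 + i2)


def calcium_rhs(state: np.ndarray, ip3: float, p: CalciumParams) -> np.ndarray:
    """Derivatives of (Ca_c, Ca_er, J_crac) given the IP3 drive (μM)."""
    ca_c, ca_er, j_crac = state
    ca_c = max(ca_c, 0.0)
    ca_er = max(ca_er, 0.0)
    j_rel = (p.k_ip3r * ip3r_open(ip3, p) + p.k_er_leak) * (ca_er - ca_c)
    j_serca = p.v_serca * ca_c ** 2 / (ca_c ** 2 + p.k_serca ** 2)
    if p.pm_enabled:
        j_pm_in = p.j_in0 + j_crac
        j_pm_out = p.v_pmca * ca_c ** 2 / (ca_c ** 2 + p.k_pmca ** 2)
    else:
        j_pm_in = j_pm_out = 0.0
    d = np.empty(3)
    d[0] = p.f_cyt * (j_rel - j_serca + j_pm_in - j_pm_out)
    d[1] = -p.f_er * p.vol_ratio * (j_rel - j_serca)
    i_ss = float(crac_steady_current(ca_er, p.crac)) if p.crac.ibar > 0 else 0.0
    d[2] = crac_dynamics(j_crac, i_ss, p.crac.tau)
    return d


def rest_state(p: CalciumParams) -> np.ndarray:
    j0 = float(crac_steady_current(p.ca_er0, p.crac)) if p.crac.ibar > 0 else 0.0
    return np.array([p.ca_c0, p.ca_er0, j0])


def total_calcium(state: np.ndarray, p: CalciumParams) -> float:
    """Conserved total (free+buffered, cyt+ER, per cytosolic volume) when the
    plasma-membrane fluxes are disabled."""
    ca_c, ca_er, _ = state
    return ca_c / p.f_cyt + ca_er / (p.f_er * p.vol_ratio)
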