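"""Coarse-grained signal transduction from pVEGFR2 to ERK1/2.

The cascade follows the receptor layer one-way: phosphorylated VEGFR2
activates PLCγ by a Michaelis–Menten catalytic step; pPLCγ proxies the
DAG/IP3 branch (IP3 production feeds the calcium module, DAG-dependent PKC
activation provides a weak trigger arm to Raf).  The dominant route to ERK
runs through a calcium-gated positive feedback loop: pERK1/2 phosphorylates
SphK1, calcium-loaded CIB1 translocates phospho-SphK1 to the plasma
membrane, membrane SphK1 produces S1P, S1P activates Ras, and Ras drives
Raf/MEK/ERK.  Because the loop gain is controlled by cytosolic calcium
(through CIB1) the model ignites abruptly once the VEGF stimulus clears a
threshold, reproducing switch-like ERK activation; breaking the loop at
SphK1 or CIB1 abolishes the ERK response while leaving the trigger arm's
small residual.

Every protein cycle conserves its total (no synthesis or degradation here);
concentrations are in μM, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

#: cascade state vector layout
CASCADE_STATES = ["pPLCg", "IP3", "PKCa", "SphK1p", "SphK1m",
                  "S1P", "RasGTP", "Rafa", "MEKa", "pERK"]


class DomainError(ValueError):
    pass


def plcg_rate(pR2: float, plcg: float, k_cat: float, km: float) -> float:
    """PLCγ phosphorylation rate by phosphorylated VEGFR2 (μM/s).

    ``rate = k_cat * [pVEGFR2] * [PLCγ] / (Km + [PLCγ])`` — catalytic in the
    receptor, saturating in free PLCγ.
    """
    if pR2 < 0 or plcg < 0:
        raise DomainError("negative input to plcg_rate")
    return k_cat * pR2 * plcg / (km + plcg)


def ras_rate(ras_gdp: float, s1p: float, k_cat: float, km: float) -> float:
    """Ras activation rate by S1P (μM/s): ``k_cat * [S1P]/([S1P]+Km)``.

    Catalytic: S1P is not consumed; the flux converts RasGDP to RasGTP.  The
    ODE system scales this flux by the remaining RasGDP fraction so the GDP
    pool cannot go negative (the printed form is recovered at the full pool).
    """
    if ras_gdp < 0 or s1p < 0:
        raise DomainError("negative input to ras_rate")
    return k_cat * s1p / (s1p + km)


@dataclass
class CascadeParams:
    plcg_tot: float
    kplc: float
    km_plc: float
    kdplc: float
    kip3: float
    kdip3: float
    pkc_tot: float
    kpkc: float
    kdpkc: float
    cib_tot: float
    kcib: float
    cib_hill: float
    s_tot: float
    kserk: float
    kdsp: float
    ktr: float
    kmoff: float
    ks1p: float
    kds1p: float
    kras: float
    km_ras: float
    kdras: float
    ras_tot: float
    raf_tot: float
    kpkcraf: float
    krasraf: float
    kdraf: float
    mek_tot: float
    kmek: float
    kdmek: float
    erk_tot: float
    kerk: float
    kderk: float
    km_erk: float

    @classmethod
    def from_parameterset(cls, ps: ParameterSet) -> "CascadeParams":
        g = ps.get
        return cls(
            plcg_tot=g("PLCg_tot"), kplc=g("kplc"), km_plc=g("Km_plc"),
            kdplc=g("kdplc"), kip3=g("kip3"), kdip3=g("kdip3"),
            pkc_tot=g("PKC_tot"), kpkc=g("kpkc"), kdpkc=g("kdpkc"),
            cib_tot=g("CIB_tot"), kcib=g("Kcib"),
            cib_hill=g("hill_cib") if "hill_cib" in ps else 2.0,
            s_tot=g("S_tot"), kserk=g("kserk"), kdsp=g("kdsp"),
            ktr=g("ktr"), kmoff=g("kmoff"),
            ks1p=g("ks1p"), kds1p=g("kds1p"),
            kras=g("kras"), km_ras=g("Km_ras"), kdras=g("kdras"),
            ras_tot=g("Ras_tot"),
            raf_tot=g("Raf_tot"), kpkcraf=g("kpkcraf"),
            krasraf=g("krasraf"), kdraf=g("kdraf"),
            mek_tot=g("MEK_tot"), kmek=g("kmek"), kdmek=g("kdmek"),
            erk_tot=g("ERK_tot"), kerk=g("kerk"), kderk=g("kderk"),
            km_erk=g("Km_erk"))


def cib1_active(ca_c: float, p: CascadeParams) -> float:
    """Calcium-loaded CIB1 (rapid-equilibrium cooperative myristoyl switch)."""
    ch = max(ca_c, 0.0) ** p.cib_hill
    kh = p.kcib ** p.cib_hill
    return p.cib_tot * ch / (kh + ch)


def cascade_rhs(state: np.ndarray, pR2_uM: float, ca_c: float,
                p: CascadeParams) -> np.ndarray:
    """Time derivatives of the cascade state (order: CASCADE_STATES)."""
    pPLCg, IP3, PKCa, Sp, Sm, S1P, RasGTP, Rafa, MEKa, pERK = state
    plcg_free = max(p.plcg_tot - pPLCg, 0.0)
    sc = max(p.s_tot - Sp - Sm, 0.0)
    d = np.empty(10)
    d[0] = plcg_rate(pR2_uM, plcg_free, p.kplc, p.km_plc) - p.kdplc * pPLCg
    d[1] = p.kip3 * pPLCg - p.kdip3 * IP3
    d[2] = p.kpkc * pPLCg * max(p.pkc_tot - PKCa, 0.0) - p.kdpkc * PKCa
    cib_a = cib1_active(ca_c, p)
    d[3] = p.kserk * pERK * sc - p.kdsp * Sp - p.ktr * cib_a * Sp \
        + p.kmoff * Sm
    d[4] = p.ktr * cib_a * Sp - p.kmoff * Sm
    d[5] = p.ks1p * Sm - p.kds1p * S1P
    ras_gdp = max(p.ras_tot - RasGTP, 0.0)
    d[6] = ras_rate(ras_gdp, max(S1P, 0.0), p.kras, p.km_ras) \
        * (ras_gdp / p.ras_tot) - p.kdras * RasGTP
    d[7] = (p.kpkcraf * PKCa + p.krasraf * RasGTP) * max(p.raf_tot - Rafa, 0.0) \
        - p.kdraf * Rafa
    d[8] = p.kmek * Rafa * max(p.mek_tot - MEKa, 0.0) - p.kdmek * MEKa
    # ERK cycle with saturable kinase/phosphatase (zero-order ultrasensitive):
    # activation is switch-like in MEK activity
    erk_u = max(p.erk_tot - pERK, 0.0)
    d[9] = p.kerk * MEKa * erk_u / (p.km_erk + erk_u) \
        - p.kderk * max(pERK, 0.0) / (p.km_erk + max(pERK, 0.0))
    return d


def sphk1_feedback_block(ps: ParameterSet) -> ParameterSet:
    """Parameter set with the SphK1 feedback arm disabled (kinase inhibition:
    pERK can no longer phosphorylate SphK1, so the loop never closes)."""
    return ps.with_overrides(kserk=0.0)


def cib1_block(ps: ParameterSet) -> ParameterSet:
    """Parameter set with CIB1 removed: no membrane translocation of
    phospho-SphK1, which suppresses ERK activation like the SphK1 block."""
    return ps.with_overrides(CIB_tot=0.0)


def rest_state(p: CascadeParams) -> np.ndarray:
    """Unstimulated fixed point: everything dephosphorylated/inactive."""
    return np.zeros(len(CASCADE_STATES))
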