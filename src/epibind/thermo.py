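"""Apparent kinetic and thermodynamic values for gas-phase complex
dissociation, and binder-group classification.

The chain converts per-charge-state dissociation midpoints into apparent
values extrapolated to a resting, neutral complex at ambient temperature
(the "m0g" reference state: mean charge, zero excess energy, gas phase):

1. Center-of-mass collision energy per charge state z at its midpoint
   voltage:  E = z·e·ΔCV50·N_A · m_gas/(m_gas + M) · n_collisions.
2. Effective internal temperature of an N-atom complex after taking up E:
   T_eff = T_source + E / ((3N − 6)·R), with N anchored at 20,000 atoms for
   an IgG1 antibody.
3. At the midpoint, half the educt survives the collision-cell residence
   time τ, so the dissociation rate constant is k = ln 2 / τ; the Eyring
   relation turns each rate into a quasi-equilibrium constant
   K = k·h/(kB·T_eff).
4. A van't Hoff regression of ln K against 1/T_eff over the charge-state
   ladder gives ΔH (slope) and ΔS (intercept); extrapolating the line to
   T_amb = 298 K gives K_D, hence ΔG = −R·T_amb·ln K_D and
   TΔS = ΔH − ΔG (both exact by construction).  An Arrhenius regression of
   ln k evaluated at T_amb gives the apparent dissociation rate constant.

The published reports that define this extrapolation give its ingredients
(the four named equations and the atom-count anchor) but not closed forms,
so this chain is the package's own documented reconstruction; absolute
rate/equilibrium values are therefore not comparable across software, while
the thermodynamic identities and orderings are.  Step 3 also accepts
externally supplied per-charge rate constants, which makes the chain exactly
invertible for simulation round trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _c
from scipy.stats import linregress

__all__ = [
    "ThermoConfig",
    "ThermoResult",
    "ChargeStatePoint",
    "com_energy",
    "effective_temperature",
    "arrhenius_vant_hoff",
    "m0g_chain",
    "classify",
    "synthesize_ladder",
    "GROUP_NAMES",
]

R_GAS = _c.R                      # 8.314... J/(mol K)
KB = _c.k
PLANCK = _c.h
E_CHARGE = _c.e
N_AVOGADRO = _c.N_A

GROUP_NAMES = {
    "I": "very strong binder",
    "II": "strong binder",
    "III": "weak/unorthodox binder",
    "IV": "non-binder",
}


@dataclass(frozen=True)
class ThermoConfig:
    """Constants of the extrapolation chain.

    ``t_source`` is the ion-source temperature (40 °C); ``n_atoms`` the
    atom-count anchor for the antibody's internal degrees of freedom;
    ``collision_gas_mass`` the collision-gas mass (argon);
    ``residence_time`` the collision-cell transit time that converts the
    midpoint condition into a rate; ``n_collisions`` a heating multiplier.
    """

    t_amb: float = 298.0
    t_source: float = 313.0
    n_atoms: int = 20000
    collision_gas_mass: float = 39.948
    residence_time: float = 1e-3
    n_collisions: int = 1

    def __post_init__(self):
        if min(self.t_amb, self.t_source, self.n_atoms,
               self.collision_gas_mass, self.residence_time,
               self.n_collisions) <= 0:
            raise ValueError("all configuration values must be positive")


@dataclass(frozen=True)
class ChargeStatePoint:
    """One rung of the ladder: charge state, its midpoint voltage, and an
    optional externally determined dissociation rate constant (1/s)."""

    z: int
    dcv50: float
    k: float | None = None


@dataclass(frozen=True)
class ThermoResult:
    """Apparent m0g values; numeric fields are None for groups III/IV."""

    group: str
    k_diss: float | None = None   # 1/s at T_amb
    k_eq: float | None = None     # dimensionless K_D
    dg: float | None = None       # kJ/mol
    dh: float | None = None       # kJ/mol
    tds: float | None = None      # kJ/mol at T_amb
    t_amb: float = 298.0

    @property
    def group_name(self) -> str:
        return GROUP_NAMES[self.group]


def com_energy(z: int, dcv: float, complex_mass: float,
               cfg: ThermoConfig = ThermoConfig()) -> float:
    """Center-of-mass collision energy (kJ/mol) taken up at voltage ``dcv``.

    ``complex_mass`` is in Da; the center-of-mass factor
    m_gas/(m_gas + M) converts laboratory-frame to internal energy.
    """
    if z < 0 or dcv < 0 or complex_mass < 0:
        raise ValueError("charge, voltage, and mass must be non-negative")
    com = cfg.collision_gas_mass / (cfg.collision_gas_mass + complex_mass)
    return z * E_CHARGE * dcv * N_AVOGADRO * com * cfg.n_collisions / 1e3


def effective_temperature(energy_kj: float,
                          cfg: ThermoConfig = ThermoConfig()) -> float:
    """Effective temperature (K) after uptake of ``energy_kj`` kJ/mol."""
    dof = 3 * cfg.n_atoms - 6
    return cfg.t_source + energy_kj * 1e3 / (dof * R_GAS)


def arrhenius_vant_hoff(temperatures, values, weights=None):
    """Linear regression of ln(value) against 1/T.

    Returns ``(energy_kj, intercept)`` where ``energy_kj`` is −slope·R in
    kJ/mol — the activation energy for rate constants (Arrhenius) or ΔH for
    equilibrium constants (van't Hoff) — and ``intercept`` is ln A or ΔS/R.
    """
    t = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) != len(v) or len(t) < 2:
        raise ValueError("need at least 2 (T, value) points")
    if np.ptp(t) <= 0:
        raise ValueError("temperatures must not be identical")
    if np.any(v <= 0):
        raise ValueError("rate/equilibrium constants must be positive")
    x, y = 1.0 / t, np.log(v)
    if weights is None:
        res = linregress(x, y)
        slope, intercept = res.slope, res.intercept
    else:
        w = np.asarray(weights, dtype=float)
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    return -slope * R_GAS / 1e3, float(intercept)


def m0g_chain(points, complex_mass: float,
              cfg: ThermoConfig = ThermoConfig()) -> ThermoResult:
    """Run the full extrapolation chain over a charge-state ladder.

    ``points`` is a sequence of :class:`ChargeStatePoint`.  With at least
    two charge states the van't Hoff step runs; a single point falls back to
    the midpoint rate alone (ΔH and TΔS stay undetermined because the
    temperature series is lost).  Group assignment is left to
    :func:`classify`, which also needs the course; here the group defaults
    to orthodox placeholders "I"/"II" by the ΔH sign rule when available.
    """
    pts = list(points)
    if not pts:
        raise ValueError("no charge-state points")
    k_mid = math.log(2.0) / cfg.residence_time
    temps, ks = [], []
    for p in pts:
        e = com_energy(p.z, p.dcv50, complex_mass, cfg)
        temps.append(effective_temperature(e, cfg))
        ks.append(p.k if p.k is not None else k_mid)
    temps = np.array(temps)
    ks = np.array(ks)
    kq = ks * PLANCK / (KB * temps)   # Eyring quasi-equilibrium constants

    if len(pts) >= 2 and np.ptp(temps) > 0:
        dh, vh_intercept = arrhenius_vant_hoff(temps, kq)
        ln_kd = vh_intercept + (-dh * 1e3 / R_GAS) / cfg.t_amb
        ea, arr_intercept = arrhenius_vant_hoff(temps, ks)
        k_diss = math.exp(arr_intercept + (-ea * 1e3 / R_GAS) / cfg.t_amb)
        kd_eq = math.exp(ln_kd)
        dg = -R_GAS * cfg.t_amb * ln_kd / 1e3
        tds = dh - dg
        group = "I" if dh > -2.0 else "II"
        return ThermoResult(group=group, k_diss=k_diss, k_eq=kd_eq,
                            dg=dg, dh=dh, tds=tds, t_amb=cfg.t_amb)
    # single-point fallback: no temperature series, no van't Hoff step
    kd_eq = float(ks[0] * PLANCK / (KB * cfg.t_amb))
    dg = -R_GAS * cfg.t_amb * math.log(kd_eq) / 1e3
    return ThermoResult(group="I", k_diss=float(ks[0]), k_eq=kd_eq,
                        dg=dg, dh=None, tds=None, t_amb=cfg.t_amb)


def classify(initial_pct: float, has_fit: bool, dh: float | None,
             zero_threshold: float = 0.5) -> str:
    """Binder group from course statistics and the apparent ΔH.

    IV — no complex signal at the lowest voltage (initial educt fraction
    zero); III — complex detected but no valid sigmoid transition; else
    I when ΔH > −2 kJ/mol, II when ΔH ≤ −2 kJ/mol.
    """
    if initial_pct <= zero_threshold:
        return "IV"
    if not has_fit or dh is None:
        return "III"
    return "I" if dh > -2.0 else "II"


def synthesize_ladder(dh_kj: float, ds_j: float, zs, dcv50s,
                      complex_mass: float,
                      cfg: ThermoConfig = ThermoConfig()):
    """Inverse chain for simulation round trips.

    Given target ΔH (kJ/mol) and ΔS (J/mol/K), charge states and their
    midpoint voltages, produce :class:`ChargeStatePoint`s whose per-charge
    rate constants place every (T_eff, K) pair exactly on the van't Hoff
    line, so :func:`m0g_chain` recovers (ΔH, ΔS) to regression precision.
    """
    pts = []
    for z, dcv in zip(zs, dcv50s):
        t = effective_temperature(com_energy(z, dcv, complex_mass, cfg), cfg)
        ln_k_eq = -dh_kj * 1e3 / (R_GAS * t) + ds_j / R_GAS
        k = math.exp(ln_k_eq) * KB * t / PLANCK
        pts.append(ChargeStatePoint(z=int(z), dcv50=float(dcv), k=k))
    return pts
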