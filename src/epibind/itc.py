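"""Single-site (independent binding) analysis of isothermal titration
calorimetry data.

A ligand at syringe concentration ``L_s`` is injected stepwise into a cell of
fixed volume ``V0`` holding the macromolecule at ``M_0``.  Binding to ``n``
independent, identical sites with association constant ``K_A`` and molar
enthalpy ``ΔH`` produces, per injection, the heat of the change in bound
ligand.  The bound fraction Θ of sites solves the Wiseman quadratic

    Θ² − Θ(1 + L/(nM) + 1/(n·K_A·M)) + L/(nM) = 0      (smaller root)

and the cell contents are diluted by the perfusion (overflow) factor
``1 − dV/V0`` at each injection, which also expels a share of already-formed
complex.  Fitting the injection heats returns (K_A, ΔH, n); ΔG = −RT ln K_A
(K_A referenced to 1 M) and TΔS = ΔH − ΔG follow exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from scipy.constants import R as R_GAS  # J/(mol K)

__all__ = [
    "Titration",
    "ItcFit",
    "NotBindingError",
    "predicted_heats",
    "fit_independent",
    "read_titration_csv",
    "write_titration_csv",
]


class NotBindingError(ValueError):
    """Titration heats are flat at the noise floor; no binding to fit."""


@dataclass(frozen=True)
class Titration:
    """An integrated-heat titration (volumes in µL, concentrations in µM,
    heats in µJ)."""

    cell_volume: float           # µL
    cell_conc: float             # µM macromolecule in the cell
    syringe_conc: float          # µM ligand in the syringe
    injections: tuple            # ((volume µL, heat µJ), ...)
    temperature: float = 298.0   # K
    label: str = ""

    def __post_init__(self):
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if any(v <= 0 for v, _ in self.injections):
            raise ValueError("injection volumes must be positive")

    @property
    def volumes(self):
        return np.array([v for v, _ in self.injections], dtype=float)

    @property
    def heats(self):
        return np.array([q for _, q in self.injections], dtype=float)

    def molar_ratios(self):
        """Cumulative ligand:macromolecule molar ratio in the cell after each
        injection (perfusion dilution applied to both species)."""
        _, m, l = _cell_concentrations(self)
        return l / m


def _cell_concentrations(t: Titration):
    """Per-injection (dilution factor, M_t, L_t) arrays in M."""
    v0 = t.cell_volume
    m = t.cell_conc * 1e-6
    l = 0.0
    fs, ms, ls = [], [], []
    for dv in t.volumes:
        f = 1.0 - dv / v0
        m *= f
        l = l * f + t.syringe_conc * 1e-6 * (dv / v0)
        fs.append(f)
        ms.append(m)
        ls.append(l)
    return np.array(fs), np.array(ms), np.array(ls)


def _theta(ka: float, n: float, m: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Bound-site fraction from the single-site quadratic (smaller root)."""
    b = 1.0 + l / (n * m) + 1.0 / (n * ka * m)
    disc = b * b - 4.0 * l / (n * m)
    if np.any(disc < -1e-12):
        raise ValueError("non-physical quadratic discriminant (inconsistent inputs)")
    theta = (b - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    if np.any((theta < -1e-9) | (theta > 1.0 + 1e-9)):
        raise ValueError("bound fraction outside [0, 1]; inconsistent inputs")
    return np.clip(theta, 0.0, 1.0)


def predicted_heats(ka: float, dh_kj: float, n: float, t: Titration) -> np.ndarray:
    """Model injection heats (µJ) for parameters (K_A [1/M], ΔH [kJ/mol], n).

    The heat of injection i is the change in cell heat content
    ``Q_i = V0 · n · M_i · Θ_i · ΔH`` corrected for the complex expelled by
    the overflow of injection i.
    """
    if ka <= 0 or n <= 0:
        raise ValueError("K_A and n must be positive")
    fs, ms, ls = _cell_concentrations(t)
    theta = _theta(ka, n, ms, ls)
    v0_l = t.cell_volume * 1e-6            # µL -> L
    q_cell = v0_l * n * ms * theta * dh_kj * 1e3   # J
    heats = np.empty(len(q_cell))
    prev = 0.0
    for i, (f, q) in enumerate(zip(fs, q_cell)):
        heats[i] = q - prev * f
        prev = q
    return heats * 1e6                      # J -> µJ


@dataclass(frozen=True)
class ItcFit:
    """Fitted single-site parameters with their exactly derived quantities."""

    ka: float            # 1/M
    dh: float            # kJ/mol
    n_sites: float
    temperature: float   # K
    residual_ss: float = float("nan")
    covariance: np.ndarray | None = None

    @property
    def kd(self) -> float:
        return 1.0 / self.ka

    @property
    def dg(self) -> float:
        """ΔG = −RT ln K_A (kJ/mol), K_A referenced to 1 M."""
        return -R_GAS * self.temperature * np.log(self.ka) / 1e3

    @property
    def tds(self) -> float:
        """TΔS = ΔH − ΔG (kJ/mol)."""
        return self.dh - self.dg


def fit_independent(t: Titration, *, fit_n: bool = True, n_fixed: float = 2.0,
                    skip_first: bool = True, flat_heat_uj: float = 0.5,
                    p0=None) -> ItcFit:
    """Least-squares single-site fit of a titration.

    The first injection is excluded by default (diffusion across the syringe
    tip corrupts it in practice).  Flat heat traces — every |heat| below
    ``flat_heat_uj`` — are refused as non-binding.  With ``fit_n`` false the
    stoichiometry is pinned at ``n_fixed`` (two Fab arms per antibody).
    """
    if len(t.injections) == 0:
        raise ValueError("empty titration; nothing to fit")
    if len(t.injections) < 5:
        raise ValueError("need at least 5 injections to fit")
    heats = t.heats
    if np.max(np.abs(heats)) < flat_heat_uj:
        raise NotBindingError(
            f"all injection heats below {flat_heat_uj} µJ; not binding"
        )
    idx = np.arange(len(heats))
    if skip_first:
        idx = idx[1:]

    def model(_i, log10_ka, dh, n):
        return predicted_heats(10.0 ** log10_ka, dh, n, t)[idx]

    total_q = float(np.sum(heats))  # µJ
    lig_moles = t.syringe_conc * 1e-6 * np.sum(t.volumes) * 1e-6  # mol
    dh_guess = float(np.clip(total_q * 1e-6 / max(lig_moles, 1e-30) / 1e3,
                             -500, 500))
    if abs(dh_guess) < 1e-6:
        dh_guess = -10.0
    n_guess = n_fixed if not fit_n else 1.0
    starts = ([p0] if p0 is not None
              else [[lk, dh_guess, n_guess] for lk in (5.0, 6.0, 7.0)])

    best = None
    if fit_n:
        bounds = ([0.0, -1e3, 1e-2], [14.0, 1e3, 10.0])
        for start in starts:
            try:
                popt, pcov = curve_fit(model, idx, heats[idx], p0=start,
                                       bounds=bounds, maxfev=50000)
            except (RuntimeError, ValueError):
                continue
            ss = float(np.sum((heats[idx] - model(idx, *popt)) ** 2))
            if best is None or ss < best[2]:
                best = (popt, pcov, ss)
        if best is None:
            raise RuntimeError("single-site fit did not converge")
        (log_ka, dh, n), pcov = best[0], best[1]
    else:
        def model2(_i, log10_ka, dh):
            return model(_i, log10_ka, dh, n_fixed)
        bounds = ([0.0, -1e3], [14.0, 1e3])
        for start in starts:
            try:
                popt, pcov = curve_fit(model2, idx, heats[idx], p0=start[:2],
                                       bounds=bounds, maxfev=50000)
            except (RuntimeError, ValueError):
                continue
            ss = float(np.sum((heats[idx] - model2(idx, *popt)) ** 2))
            if best is None or ss < best[2]:
                best = (popt, pcov, ss)
        if best is None:
            raise RuntimeError("single-site fit did not converge")
        (log_ka, dh), pcov = best[0], best[1]
        n = n_fixed
    ka = 10.0 ** float(log_ka)
    resid = heats[idx] - predicted_heats(ka, float(dh), float(n), t)[idx]
    return ItcFit(ka=ka, dh=float(dh), n_sites=float(n),
                  temperature=t.temperature,
                  residual_ss=float(np.sum(resid ** 2)), covariance=pcov)


def read_titration_csv(path, cell_volume: float, cell_conc: float,
                       syringe_conc: float, temperature: float = 298.0,
                       label: str = "") -> Titration:
    """Read a titration from CSV columns injection_index, volume_uL, heat_uJ."""
    df = pd.read_csv(path)
    df = df.sort_values(df.columns[0])
    inj = tuple(zip(df["volume_uL"].astype(float), df["heat_uJ"].astype(float)))
    return Titration(cell_volume=cell_volume, cell_conc=cell_conc,
                     syringe_conc=syringe_conc, injections=inj,
                     temperature=temperature, label=label)


def write_titration_csv(t: Titration, path) -> None:
    df = pd.DataFrame({
        "injection_index": np.arange(1, len(t.injections) + 1),
        "volume_uL": t.volumes,
        "heat_uJ": t.heats,
    })
    df.to_csv(path, index=False)
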