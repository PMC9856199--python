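"""Synthetic breakdown-series and titration generators with known ground truth.

These stand in for deposited raw data: multiply charged antibody and
antibody-peptide complex envelopes between m/z 5000 and 7000, released
peptide ions at 2+/3+ (with optional sodiated satellites), educt decay
governed by a Boltzmann sigmoid over a 13-step collision-voltage schedule,
and Wiseman single-site titration heats.  Everything is deterministic given
the recipe seed.

Rendering choices that make the generator exactly invertible by the
processing chain (documented in the methods note): every peak shares one
Gaussian m/z width, peak centers are quantized to the m/z grid, and species
intensities are bookkept as peak apex heights, so iterated Savitzky-Golay
smoothing attenuates every species by one common factor and height ratios
survive the full pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import itc as _itc
from .boltzmann import boltzmann_value
from .peptides import mz as _mz
from .reference import ANTIBODY_MASS_AVG, CV_STEPS
from .spectra import NA_MASS_SHIFT, Spectrum, SpectrumSeries

__all__ = ["SimulationRecipe", "simulate_series", "ground_truth_course",
           "simulate_itc"]

DEFAULT_EDUCT_PARAMS = (77.36, 36.24, 30.0, 15.2)  # wild-type course shape


@dataclass(frozen=True)
class SimulationRecipe:
    """Ground-truth description of one synthetic breakdown series.

    ``educt_params`` are the Boltzmann parameters (A1 %, A2 %, x0 V, dx V)
    of the educt course; ``occupancy_split`` is the educt share carried by
    the singly occupied complex (the remainder is doubly occupied);
    ``release_response`` scales the released-peptide signal relative to the
    dissociated educt; ``noise_sd`` is additive Gaussian noise relative to
    ``total_intensity``.
    """

    antibody_mass: float = ANTIBODY_MASS_AVG
    peptide_mass: float = 1813.907
    charge_states: tuple = (23, 27)          # inclusive range
    envelope_center: float = 25.0            # mean charge
    envelope_width: float = 1.2              # charge units
    total_intensity: float = 1000.0
    educt_params: tuple = DEFAULT_EDUCT_PARAMS
    occupancy_split: float = 0.7
    cv_steps: tuple = CV_STEPS
    noise_sd: float = 0.0
    na_adduct_fraction: float = 0.0
    release_response: float = 0.8
    peak_width_mz: float = 3.0
    fragment_level: float = 0.0              # broadband m/z 1200-2300 signal
    grid_start: float = 400.0
    grid_stop: float = 8000.0
    grid_step: float = 0.25
    seed: int = 0

    def __post_init__(self):
        a1, a2, x0, dx = self.educt_params
        if not (0.0 <= a2 <= a1 <= 100.0):
            raise ValueError("educt params must satisfy 0 <= A2 <= A1 <= 100")
        if dx <= 0:
            raise ValueError("course constant dx must be positive")
        if any(b <= a for a, b in zip(self.cv_steps, self.cv_steps[1:])):
            raise ValueError("cv_steps must be strictly increasing")
        if not (0.0 <= self.na_adduct_fraction <= 1.0):
            raise ValueError("na_adduct_fraction must lie in [0, 1]")
        if not (0.0 <= self.occupancy_split <= 1.0):
            raise ValueError("occupancy_split must lie in [0, 1]")
        if self.total_intensity < 0 or self.peak_width_mz <= 0:
            raise ValueError("intensity must be >= 0 and peak width positive")

    @property
    def charges(self):
        lo, hi = self.charge_states
        return range(int(lo), int(hi) + 1)


def ground_truth_course(recipe: SimulationRecipe) -> np.ndarray:
    """Noise-free educt fractions (%) at the recipe's voltage steps."""
    a1, a2, x0, dx = recipe.educt_params
    return boltzmann_value(np.array(recipe.cv_steps, dtype=float), a1, a2, x0, dx)


def species_heights(recipe: SimulationRecipe) -> list:
    """Per-step ground-truth apex heights of every species (no noise).

    The educt carries fraction f of the total, split between the singly and
    doubly occupied complex; the released-peptide signal grows with the
    cumulatively dissociated educt; the free antibody takes up the balance,
    so the species heights sum to ``total_intensity`` at every step.
    """
    t = recipe.total_intensity
    f = ground_truth_course(recipe) / 100.0
    f0 = f[0]
    out = []
    for fi in f:
        educt = fi * t
        pep = min(recipe.release_response * (f0 - fi) * t, max(t - educt, 0.0))
        out.append({
            "complex1": recipe.occupancy_split * educt,
            "complex2": (1.0 - recipe.occupancy_split) * educt,
            "peptide": pep,
            "antibody": max(t - educt - pep, 0.0),
        })
    return out


def _render(grid, center, sigma, apex, out):
    """Add a Gaussian peak, apex snapped to the nearest grid point."""
    if apex <= 0:
        return
    step = grid[1] - grid[0]
    c = grid[0] + round((center - grid[0]) / step) * step
    lo = np.searchsorted(grid, c - 6 * sigma)
    hi = np.searchsorted(grid, c + 6 * sigma)
    out[lo:hi] += apex * np.exp(-0.5 * ((grid[lo:hi] - c) / sigma) ** 2)


def simulate_series(recipe: SimulationRecipe) -> SpectrumSeries:
    """Render the full synthetic series: one profile spectrum per step."""
    rng = np.random.default_rng(recipe.seed)
    grid = np.arange(recipe.grid_start, recipe.grid_stop + recipe.grid_step / 2,
                     recipe.grid_step)
    masses = {
        "antibody": recipe.antibody_mass,
        "complex1": recipe.antibody_mass + recipe.peptide_mass,
        "complex2": recipe.antibody_mass + 2 * recipe.peptide_mass,
    }
    # charge-envelope weight, apex-normalized at the envelope center
    def zweight(z):
        return np.exp(-0.5 * ((z - recipe.envelope_center) /
                              recipe.envelope_width) ** 2)

    steps = []
    for heights, dcv in zip(species_heights(recipe), recipe.cv_steps):
        y = np.zeros(len(grid))
        for name, mass in masses.items():
            for z in recipe.charges:
                _render(grid, _mz(mass, z), recipe.peak_width_mz,
                        heights[name] * zweight(z), y)
        pep = heights["peptide"]
        if pep > 0:
            _render(grid, _mz(recipe.peptide_mass, 2), recipe.peak_width_mz,
                    pep, y)
            _render(grid, _mz(recipe.peptide_mass, 3), recipe.peak_width_mz,
                    0.6 * pep, y)
            if recipe.na_adduct_fraction > 0:
                _render(grid, _mz(recipe.peptide_mass + NA_MASS_SHIFT, 2),
                        recipe.peak_width_mz,
                        recipe.na_adduct_fraction * pep, y)
        if recipe.fragment_level > 0:
            band = (grid >= 1200) & (grid <= 2300)
            y[band] += recipe.fragment_level * recipe.total_intensity
        if recipe.noise_sd > 0:
            y = y + rng.normal(0.0, recipe.noise_sd * recipe.total_intensity,
                               size=len(grid))
            y = np.clip(y, 0.0, None)
        steps.append((float(dcv), Spectrum(grid, y)))
    return SpectrumSeries(steps=tuple(steps), label="synthetic")


def simulate_itc(ka: float, dh_kj: float, n_sites: float, cell_conc: float,
                 syringe_conc: float, cell_volume: float, injection_volumes,
                 noise_sd: float = 0.0, seed: int = 0,
                 temperature: float = 298.0) -> _itc.Titration:
    """Synthetic single-site titration (µL / µM / µJ conventions).

    Heats follow the Wiseman isotherm with perfusion dilution; ``noise_sd``
    is the per-injection additive heat noise in µJ.
    """
    if ka <= 0 or n_sites <= 0:
        raise ValueError("K_A and n must be positive")
    if cell_conc <= 0 or syringe_conc <= 0 or cell_volume <= 0:
        raise ValueError("concentrations and volumes must be positive")
    volumes = tuple(float(v) for v in injection_volumes)
    blank = _itc.Titration(
        cell_volume=cell_volume, cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injections=tuple((v, 0.0) for v in volumes),
        temperature=temperature, label="synthetic",
    )
    if not volumes:
        return blank
    heats = _itc.predicted_heats(ka, dh_kj, n_sites, blank)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    return replace(blank, injections=tuple(zip(volumes, heats)))
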