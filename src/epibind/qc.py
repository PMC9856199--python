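"""Measurement-series acceptance gate: four quality criteria, pass on 3 of 4.

A breakdown series enters kinetic/thermodynamic analysis only when at least
three of these hold: (i) free antibody and the two complex stoichiometries
are resolved in at least five charge states (valley between adjacent species
signals at most 50% of the smaller apex); (ii) the sodiated released-peptide
2+ signal at the final voltage step stays at or below 35% of the protonated
2+ signal; (iii) the Boltzmann fit used every course point (no outliers were
excluded); (iv) the fit's R² is at least 0.99.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .boltzmann import BoltzmannFit
from .peptides import mz as _mz
from .spectra import NA_MASS_SHIFT, Spectrum, read_height

__all__ = [
    "QcReport",
    "criterion_resolution",
    "criterion_sodium",
    "criterion_outliers",
    "criterion_r2",
    "evaluate",
]

SODIUM_RATIO_LIMIT = 0.35
R2_LIMIT = 0.99
VALLEY_LIMIT = 0.50
MIN_RESOLVED_CHARGES = 5


@dataclass(frozen=True)
class QcReport:
    criterion_resolution: bool
    criterion_sodium: bool
    criterion_outliers: bool
    criterion_r2: bool
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        flags = (self.criterion_resolution, self.criterion_sodium,
                 self.criterion_outliers, self.criterion_r2)
        return sum(flags) >= 3

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["passed"] = self.passed
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _valley_resolved(spectrum: Spectrum, mz_a: float, mz_b: float,
                     tolerance: float) -> bool:
    """Valley between two peaks at most ``VALLEY_LIMIT`` of the smaller apex."""
    lo_c, hi_c = sorted((mz_a, mz_b))
    a = _window_max(spectrum, lo_c, tolerance)
    b = _window_max(spectrum, hi_c, tolerance)
    if a is None or b is None:
        return False
    mask = (spectrum.mz >= lo_c) & (spectrum.mz <= hi_c)
    if not mask.any():
        return False
    valley = float(spectrum.intensity[mask].min())
    smaller = min(a, b)
    if smaller <= 0:
        return False
    return valley <= VALLEY_LIMIT * smaller + 1e-12


def _window_max(spectrum: Spectrum, center: float, tolerance: float):
    mask = (spectrum.mz >= center - tolerance) & (spectrum.mz <= center + tolerance)
    if not mask.any():
        return None
    return float(spectrum.intensity[mask].max())


def criterion_resolution(spectrum: Spectrum, antibody_mass: float,
                         peptide_mass: float, charges,
                         tolerance: float = 5.0) -> bool:
    """Species differentiation at the lowest voltage step.

    A charge state counts as resolved when both adjacent species pairs
    (antibody/complex1 and complex1/complex2 at that charge) show a valley
    at most 50% of the smaller apex; at least five charge states must
    resolve (boundary inclusive).
    """
    resolved = 0
    m0, m1, m2 = (antibody_mass, antibody_mass + peptide_mass,
                  antibody_mass + 2 * peptide_mass)
    for z in charges:
        pair1 = _valley_resolved(spectrum, _mz(m0, z), _mz(m1, z), tolerance)
        pair2 = _valley_resolved(spectrum, _mz(m1, z), _mz(m2, z), tolerance)
        if pair1 and pair2:
            resolved += 1
    return resolved >= MIN_RESOLVED_CHARGES


def criterion_sodium(spectrum: Spectrum, peptide_mass: float,
                     background: float = 0.0, tolerance: float = 0.5) -> bool:
    """Sodium-adduct check at the final (highest) voltage step.

    Passes when the sodiated 2+ peptide signal is at most 35% of the
    protonated 2+ signal.  When no protonated peptide rises above background
    (a non-binder series releases nothing) the criterion is undecidable and
    recorded as a pass with a warning.
    """
    prot = read_height(spectrum, peptide_mass, 2, tolerance)
    sodi = read_height(spectrum, peptide_mass + NA_MASS_SHIFT, 2, tolerance)
    if prot is None or prot <= background * (1 + 1e-9) or prot <= 0:
        warnings.warn(
            "no protonated 2+ peptide signal above background; sodium "
            "criterion undecidable, recording pass", stacklevel=2,
        )
        return True
    if sodi is None:
        return True
    return sodi <= SODIUM_RATIO_LIMIT * prot + 1e-12


def criterion_outliers(fit: BoltzmannFit) -> bool:
    """True iff the Boltzmann fit used every course point."""
    return len(fit.excluded_points) == 0


def criterion_r2(fit: BoltzmannFit) -> bool:
    """True iff the fit's R² is at least 0.99 (boundary inclusive)."""
    return fit.r2 >= R2_LIMIT


def evaluate(*, resolution: bool, sodium: bool, outliers: bool,
             r2: bool, details=None) -> QcReport:
    """Assemble the 3-of-4 gate from the four criterion outcomes."""
    return QcReport(
        criterion_resolution=bool(resolution),
        criterion_sodium=bool(sodium),
        criterion_outliers=bool(outliers),
        criterion_r2=bool(r2),
        details=details or {},
    )
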