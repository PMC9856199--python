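"""Spectrum processing for breakdown-curve series.

The processing chain mirrors standard native-MS practice for stepped
collision-voltage experiments on intact immune complexes: scans within one
voltage step are averaged; the averaged spectrum is smoothed by repeated
Savitzky-Golay passes; apex heights of every molecular species (free
antibody, complex with one and two bound peptides, released peptide, and
optionally antibody fragments) are read per charge state; a Gaussian is
fitted over each species' charge-state envelope (imputing flanking charge
states at background level when fewer than five points were measured); and
the normalized educt fraction

    100 * (complex1 + complex2) / sum over species

is tracked against the voltage schedule to form the breakdown course.
A zero-charge deconvolution of consecutive multiply charged peaks gives
intact-protein masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .peptides import PROTON_MASS, mz as _mz

__all__ = [
    "Spectrum",
    "SpectrumSeries",
    "SpeciesEnvelope",
    "EductCourse",
    "PeakCollisionWarning",
    "combine_scans",
    "smooth",
    "estimate_background",
    "read_height",
    "read_species_heights",
    "fit_envelope",
    "normalized_educt",
    "deconvolute_mass",
    "process_series",
    "aggregate_courses",
    "ProcessResult",
]

HEAVY_SPECIES = ("antibody", "complex1", "complex2")


class PeakCollisionWarning(UserWarning):
    """Two expected species peaks fall within one reading tolerance."""


@dataclass(frozen=True)
class Spectrum:
    """A centroid-free profile spectrum: strictly increasing m/z grid."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")


@dataclass(frozen=True)
class SpectrumSeries:
    """One averaged spectrum per collision-voltage step, in step order."""

    steps: tuple  # ((dcv, Spectrum), ...)
    label: str = ""
    replicate: int = 0

    def __post_init__(self):
        dcv = [s[0] for s in self.steps]
        if any(b <= a for a, b in zip(dcv, dcv[1:])):
            raise ValueError("voltage steps must be strictly increasing")

    @property
    def dcv(self):
        return np.array([s[0] for s in self.steps], dtype=float)


@dataclass
class SpeciesEnvelope:
    """Charge-state envelope of one molecular species with its Gaussian fit."""

    species: str
    points: dict                      # z -> apex intensity (incl. imputed)
    apex_height: float
    center_charge: float | None      # the species' mean charge; None = non-detect
    width: float | None
    imputed: frozenset = frozenset()
    background: float = 0.0

    @property
    def detected(self) -> bool:
        return self.center_charge is not None


@dataclass(frozen=True)
class EductCourse:
    """Normalized educt fraction (%) vs voltage, with replicate statistics."""

    dcv: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("dcv", "mean", "sd", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.dcv) == len(self.mean) == len(self.sd) == len(self.n)):
            raise ValueError("course arrays must share one length per voltage step")
        if np.any((self.mean < -1e-9) | (self.mean > 100 + 1e-9)):
            raise ValueError("educt fractions must lie in [0, 100] percent")


def combine_scans(scans) -> Spectrum:
    """Average a list of scans into one spectrum (pointwise mean intensity).

    Scans on mismatched m/z grids are resampled onto the first scan's grid by
    linear interpolation before averaging.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("cannot combine an empty scan list")
    grid = scans[0].mz
    stack = []
    for s in scans:
        if s.mz.shape == grid.shape and np.array_equal(s.mz, grid):
            stack.append(s.intensity)
        else:
            stack.append(np.interp(grid, s.mz, s.intensity))
    return Spectrum(grid, np.mean(stack, axis=0))


def smooth(spectrum: Spectrum, window: int = 10, passes: int = 20,
           polyorder: int = 2) -> Spectrum:
    """Iterated Savitzky-Golay smoothing (default: 20 passes, window 10).

    Symmetric SG kernels need an odd length, so an even ``window`` is widened
    by one point (10 -> 11).
    """
    if passes < 0:
        raise ValueError("passes must be non-negative")
    w = window + 1 if window % 2 == 0 else window
    if w <= polyorder:
        raise ValueError(f"window {window} must exceed polyorder {polyorder}")
    if len(spectrum.mz) < w:
        raise ValueError(
            f"spectrum has {len(spectrum.mz)} points, shorter than window {w}"
        )
    y = spectrum.intensity
    for _ in range(passes):
        y = savgol_filter(y, w, polyorder)
    return Spectrum(spectrum.mz, y)


def estimate_background(spectrum: Spectrum, windows=((4400.0, 4700.0),)) -> float:
    """Median intensity over signal-free m/z windows.

    Falls back to the overall median if no grid point lies in any window.
    """
    mask = np.zeros(len(spectrum.mz), dtype=bool)
    for lo, hi in windows:
        mask |= (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if not mask.any():
        return float(np.median(spectrum.intensity))
    return float(np.median(spectrum.intensity[mask]))


def read_height(spectrum: Spectrum, species_mass: float, z: int,
                tolerance: float) -> float | None:
    """Maximum smoothed intensity within ``mz(species_mass, z) ± tolerance``.

    Returns ``None`` when the window falls outside the recorded m/z range
    (flagged missing; a candidate for envelope imputation).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    center = _mz(species_mass, z)
    lo, hi = center - tolerance, center + tolerance
    if hi < spectrum.mz[0] or lo > spectrum.mz[-1]:
        return None
    mask = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if not mask.any():
        return None
    return float(spectrum.intensity[mask].max())


def read_species_heights(spectrum: Spectrum, species_masses: dict, z: int,
                         tolerance: float) -> dict:
    """Read apex heights for several species at one charge state.

    Warns (:class:`PeakCollisionWarning`) when two expected species positions
    fall within one tolerance of each other — the taller apex then dominates
    both readings.
    """
    centers = {name: _mz(m, z) for name, m in species_masses.items()}
    names = list(centers)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if abs(centers[a] - centers[b]) < tolerance:
                warnings.warn(
                    f"species {a!r} and {b!r} closer than {tolerance} Th at "
                    f"charge {z}+ (Δ={abs(centers[a] - centers[b]):.3f} Th)",
                    PeakCollisionWarning, stacklevel=2,
                )
    return {
        name: read_height(spectrum, m, z, tolerance)
        for name, m in species_masses.items()
    }


def _gaussian(z, h, c, w):
    return h * np.exp(-0.5 * ((z - c) / w) ** 2)


def fit_envelope(points: dict, background: float, species: str = "",
                 min_points: int = 5) -> SpeciesEnvelope:
    """Gaussian fit of a charge-state envelope, imputing to ``min_points``.

    When fewer than five charge states were measured, flanking charge states
    are appended at background intensity, alternating below and above the
    measured range (starting below), until five points exist — the fit needs
    that many.  If every measured point sits at (or below) background the
    species is a non-detect: apex = background, center undefined.
    """
    measured = {int(z): float(i) for z, i in points.items() if i is not None}
    if not measured:
        raise ValueError("need at least one measured envelope point")
    imputed = set()
    lo, hi = min(measured), max(measured)
    side_low = True
    while len(measured) + len(imputed) < min_points:
        if side_low:
            lo -= 1
            imputed.add(lo)
        else:
            hi += 1
            imputed.add(hi)
        side_low = not side_low
    full = dict(measured)
    full.update({z: background for z in imputed})

    zs = np.array(sorted(full), dtype=float)
    ys = np.array([full[int(z)] for z in zs], dtype=float)
    if np.all(ys <= background + 1e-12):
        return SpeciesEnvelope(
            species=species, points=full, apex_height=float(background),
            center_charge=None, width=None, imputed=frozenset(imputed),
            background=background,
        )
    zmax = float(zs[np.argmax(ys)])
    p0 = [float(ys.max()), zmax, max(1.0, np.ptp(zs) / 4.0)]
    try:
        popt, _ = curve_fit(
            _gaussian, zs, ys - background, p0=[p0[0] - background, p0[1], p0[2]],
            maxfev=20000,
        )
        h, c, w = float(popt[0]) + background, float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        # degenerate envelope: fall back to the tallest measured point
        h, c, w = float(ys.max()), zmax, float("nan")
    if not (zs.min() - 2.0 <= c <= zs.max() + 2.0):
        # fit ran away: report the tallest point instead of an absurd center
        h, c, w = float(ys.max()), zmax, float("nan")
    return SpeciesEnvelope(
        species=species, points=full, apex_height=h, center_charge=c,
        width=w, imputed=frozenset(imputed), background=background,
    )


def normalized_educt(heights: dict, include=("antibody", "complex1",
                                             "complex2", "peptide")) -> float:
    """Normalized educt fraction (%): (complex1 + complex2) / Σ species.

    ``heights`` maps species name to apex height.  ``include`` fixes the
    denominator set; antibody fragments join it only when explicitly listed.
    """
    for needed in HEAVY_SPECIES:
        if needed not in heights:
            raise ValueError(f"missing species {needed!r}")
    denom = sum(float(heights[s]) for s in include if s in heights)
    if denom <= 0:
        raise ValueError("zero total species intensity; cannot normalize")
    num = float(heights["complex1"]) + float(heights["complex2"])
    return 100.0 * num / denom


def deconvolute_mass(peaks, tolerance_da: float = 5.0):
    """Zero-charge mass from consecutive multiply charged peaks.

    ``peaks`` is a list of ``(m/z, z)`` with ``z`` possibly ``None``; unknown
    charges are inferred from adjacent-peak spacing (for neighbours
    m1 > m2 carrying z and z+1: z = (m2 - proton)/(m1 - m2)).  Returns
    ``(mass, sd)`` over the per-peak masses; inconsistent assignments (the
    per-peak masses disagreeing by more than ``tolerance_da``) are rejected.
    """
    peaks = sorted(((float(m), z) for m, z in peaks), reverse=True)
    if len(peaks) < 2 and peaks and peaks[0][1] is None:
        raise ValueError("need at least 2 consecutive peaks to infer charge")
    if not peaks:
        raise ValueError("no peaks given")

    charges = [z for _, z in peaks]
    if any(z is None for z in charges):
        charges = []
        for i in range(len(peaks) - 1):
            m1, m2 = peaks[i][0], peaks[i + 1][0]
            zf = (m2 - PROTON_MASS) / (m1 - m2)
            charges.append(int(round(zf)))
        charges.append(charges[-1] + 1)
        # known charges, where present, must agree with the inference
        for (mz_, z), zi in zip(peaks, charges):
            if z is not None and z != zi:
                raise ValueError(
                    f"assigned charge {z} at m/z {mz_:.2f} conflicts with "
                    f"spacing-inferred charge {zi}"
                )
    diffs = np.diff(charges)
    if np.any(diffs != 1):
        raise ValueError(
            f"inferred charges {charges} are not consecutive; peaks likely "
            "mix species"
        )
    masses = np.array([z * (m - PROTON_MASS) for (m, _), z in zip(peaks, charges)])
    if np.ptp(masses) > tolerance_da * max(1.0, np.mean(masses) / 1e5):
        raise ValueError(
            f"per-peak masses spread over {np.ptp(masses):.2f} Da; "
            "inconsistent charge assignment or interleaved species"
        )
    return float(masses.mean()), float(masses.std(ddof=0))


@dataclass
class ProcessResult:
    """Everything the downstream QC / fitting stages need from one series."""

    dcv: np.ndarray
    envelopes: list            # per step: dict species -> SpeciesEnvelope
    heights: list              # per step: dict species -> apex height
    educt: np.ndarray          # per step: normalized educt fraction (%)
    per_charge: dict           # z -> np.ndarray of per-step educt fractions
    peptide_heights: list      # per step: dict like {"2+": h, "3+": h, "na2+": h}
    background: np.ndarray     # per step

    def course(self) -> EductCourse:
        n = len(self.dcv)
        return EductCourse(self.dcv, self.educt, np.zeros(n), np.ones(n))


NA_MASS_SHIFT = 21.981943  # Na+ replacing H+ on the released peptide (Da)


def process_series(series: SpectrumSeries, antibody_mass: float,
                   peptide_mass: float, charges=range(23, 28), *,
                   tol_heavy: float = 5.0, tol_peptide: float = 0.5,
                   window: int = 10, passes: int = 20, polyorder: int = 2,
                   background_windows=((4400.0, 4700.0),),
                   include=("antibody", "complex1", "complex2", "peptide"),
                   ) -> ProcessResult:
    """Run the full per-step chain: smooth, read, fit envelopes, normalize.

    Species m/z positions are predicted from the antibody mass plus 0/1/2
    peptide masses over the given charge range; the released peptide is read
    at 2+ and 3+ (plus its sodiated 2+ satellite, for quality control).
    """
    species_masses = {
        "antibody": antibody_mass,
        "complex1": antibody_mass + peptide_mass,
        "complex2": antibody_mass + 2 * peptide_mass,
    }
    dcv, env_steps, height_steps, educt_steps = [], [], [], []
    pep_steps, bg_steps = [], []
    per_charge_rows = {int(z): [] for z in charges}
    for v, spec in series.steps:
        sm = smooth(spec, window=window, passes=passes, polyorder=polyorder)
        bg = estimate_background(sm, background_windows)
        by_z = {}
        for z in charges:
            by_z[int(z)] = read_species_heights(sm, species_masses, int(z), tol_heavy)
        envs = {}
        for name in species_masses:
            pts = {z: by_z[z][name] for z in by_z}
            envs[name] = fit_envelope(pts, bg, species=name)
        pep = {
            "2+": read_height(sm, peptide_mass, 2, tol_peptide),
            "3+": read_height(sm, peptide_mass, 3, tol_peptide),
            "na2+": read_height(sm, peptide_mass + NA_MASS_SHIFT, 2, tol_peptide),
        }
        heights = {name: envs[name].apex_height for name in envs}
        heights["peptide"] = max(
            (h for h in (pep["2+"], pep["3+"]) if h is not None), default=bg
        )
        try:
            educt_steps.append(normalized_educt(heights, include=include))
        except ValueError:
            # zero total signal (empty or fully suppressed step): the educt
            # fraction is zero by convention so non-binder series flow through
            educt_steps.append(0.0)
        # per-charge courses use the three heavy species read at that charge
        # (the released peptide carries its own, unrelated charge states)
        for z in per_charge_rows:
            row = by_z[z]
            vals = {k: (row[k] if row[k] is not None else bg) for k in row}
            denom = vals["antibody"] + vals["complex1"] + vals["complex2"]
            num = vals["complex1"] + vals["complex2"]
            per_charge_rows[z].append(100.0 * num / denom if denom > 0 else 0.0)
        dcv.append(v)
        env_steps.append(envs)
        height_steps.append(heights)
        pep_steps.append(pep)
        bg_steps.append(bg)
    return ProcessResult(
        dcv=np.array(dcv, dtype=float),
        envelopes=env_steps,
        heights=height_steps,
        educt=np.array(educt_steps, dtype=float),
        per_charge={z: np.array(rows) for z, rows in per_charge_rows.items()},
        peptide_heights=pep_steps,
        background=np.array(bg_steps, dtype=float),
    )


def aggregate_courses(results) -> EductCourse:
    """Combine replicate :class:`ProcessResult`s into a mean ± SD course."""
    results = list(results)
    if not results:
        raise ValueError("no replicate results to aggregate")
    dcv = results[0].dcv
    for r in results[1:]:
        if not np.array_equal(r.dcv, dcv):
            raise ValueError("replicates must share one voltage schedule")
    stack = np.vstack([r.educt for r in results])
    sd = stack.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(len(dcv))
    return EductCourse(dcv, stack.mean(axis=0), sd,
                       np.full(len(dcv), len(results)))
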