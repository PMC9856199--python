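"""Boltzmann sigmoid fitting of educt breakdown courses.

The normalized educt fraction y(x) of an antibody-peptide complex as a
function of the collision-cell voltage difference x follows a falling
sigmoid::

    y(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx))

with initial plateau A1, final plateau A2, midpoint x0 (the dissociation
midpoint voltage, "ΔCV50") and course constant dx.  The tangent slope at the
midpoint is -(A1 - A2)/(4 dx).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BoltzmannFit",
    "NoTransitionError",
    "FitError",
    "boltzmann_value",
    "fit",
    "tangent_slope",
    "tangent_line",
]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


class NoTransitionError(ValueError):
    """Course is too flat to carry a dissociation transition (fit refused)."""


def boltzmann_value(x, a1: float, a2: float, x0: float, dx: float):
    """Evaluate the Boltzmann sigmoid at voltage(s) ``x``."""
    if dx == 0:
        raise ValueError("course constant dx must be nonzero")
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates to the A2 plateau
        out = a2 + (a1 - a2) / (1.0 + np.exp((x - x0) / dx))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted sigmoid parameters and derived course characteristics.

    ``data_initial`` / ``data_final`` are the course means at the first and
    last voltage step (how the published "initial/final" columns are
    defined), while ``a1`` / ``a2`` are the fit asymptotes; both are kept.
    """

    a1: float
    a2: float
    x0: float
    dx: float
    r2: float
    data_initial: float
    data_final: float
    excluded_points: tuple = ()
    covariance: np.ndarray | None = None

    @property
    def slope(self) -> float:
        """Tangent slope at the midpoint, -(A1 - A2)/(4 dx) (%/V)."""
        return -(self.a1 - self.a2) / (4.0 * self.dx)

    def __call__(self, x):
        return boltzmann_value(x, self.a1, self.a2, self.x0, self.dx)


def tangent_slope(fit_or_a1, a2: float | None = None, dx: float | None = None) -> float:
    """Midpoint tangent slope -(A1 - A2)/(4 dx) (%/V).

    Accepts either a :class:`BoltzmannFit` or the raw ``(a1, a2, dx)`` triple
    (useful when only published course parameters are at hand).
    """
    if isinstance(fit_or_a1, BoltzmannFit):
        return fit_or_a1.slope
    return -(fit_or_a1 - a2) / (4.0 * dx)


def tangent_line(fit: BoltzmannFit):
    """The tangent at the midpoint as ``(slope, intercept)`` of y = s·x + b."""
    s = fit.slope
    y0 = (fit.a1 + fit.a2) / 2.0
    return s, y0 - s * fit.x0


def fit(dcv, fractions, sd=None, *, weighted: bool = False,
        exclude=(), flat_range: float = 10.0,
        bounded: bool = True) -> BoltzmannFit:
    """Least-squares Boltzmann fit of an educt course.

    Parameters
    ----------
    dcv, fractions:
        Voltage steps (V) and normalized educt fractions (%), replicate means.
    sd:
        Optional per-point standard deviations; used only if ``weighted``.
    weighted:
        Weight residuals by 1/SD² (default off: the fit runs on the means).
    exclude:
        Indices of course points to mask; recorded on the result (quality
        gating elsewhere checks that this stays empty).
    flat_range:
        Dynamic-range floor in percentage points below which the course is
        declared transition-free and the fit refused.
    bounded:
        Constrain the parameters to their identifiable region (plateaus in
        [0, 100]%, midpoint inside the scanned voltage window, course
        constant within half the window span) and take the best of a few
        starts.  Without these constraints the sigmoid can degenerate to a
        straight line (dx and x0 unbounded) on noisy courses.
    """
    x = np.asarray(dcv, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dcv and fractions must be 1-D arrays of equal length")
    keep = np.ones(len(x), dtype=bool)
    for i in exclude:
        keep[i] = False
    xk, yk = x[keep], y[keep]
    if len(xk) < 5:
        raise ValueError(f"need at least 5 course points, got {len(xk)}")
    if np.ptp(yk) < flat_range:
        raise NoTransitionError(
            f"course dynamic range {np.ptp(yk):.2f} percentage points is below "
            f"{flat_range:g}; no dissociation transition to fit"
        )

    span = float(np.ptp(xk))
    mid = (float(yk.max()) + float(yk.min())) / 2.0
    # first crossing of the midlevel, by linear interpolation
    x0_0 = float(xk[-1])
    for i in range(len(xk) - 1):
        y0_, y1_ = yk[i], yk[i + 1]
        if (y0_ - mid) * (y1_ - mid) <= 0 and y0_ != y1_:
            t = (mid - y0_) / (y1_ - y0_)
            x0_0 = float(xk[i] + t * (xk[i + 1] - xk[i]))
            break

    sigma = None
    if weighted and sd is not None:
        sigma = np.asarray(sd, dtype=float)[keep]
        sigma = np.where(sigma <= 0, np.nanmax(sigma[sigma > 0], initial=1.0), sigma)

    if bounded:
        a1_0 = min(float(yk.max()), 100.0)
        a2_0 = max(float(yk.min()), 0.0)
        dx_max = max(span / 2.0, 1.0)
        x0_0 = min(max(x0_0, float(xk[0])), float(xk[-1]))
        bounds = ([0.0, 0.0, float(xk[0]), 0.5],
                  [100.0, 100.0, float(xk[-1]), dx_max])
        starts = [
            [a1_0, a2_0, x0_0, span / 10.0],
            [a1_0, a2_0, x0_0, dx_max / 2.0],
            [a1_0, a2_0, float(np.median(xk)), span / 10.0],
        ]
    else:
        bounds = (-np.inf, np.inf)
        starts = [[float(yk.max()), float(yk.min()), x0_0, span / 10.0]]

    best = None
    last_err = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                boltzmann_value, xk, yk, p0=p0, bounds=bounds,
                sigma=sigma, absolute_sigma=False, maxfev=20000,
            )
        except RuntimeError as err:
            last_err = err
            continue
        ss = float(np.sum((yk - boltzmann_value(xk, *popt)) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise FitError(f"Boltzmann fit did not converge: {last_err}")
    popt, pcov, _ = best
    a1, a2, x0, dx = (float(v) for v in popt)
    if dx < 0:  # the sigmoid is symmetric under (dx, A1<->A2) sign flips
        a1, a2, dx = a2, a1, -dx
    resid = yk - boltzmann_value(xk, a1, a2, x0, dx)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((yk - yk.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return BoltzmannFit(
        a1=a1, a2=a2, x0=x0, dx=dx, r2=r2,
        data_initial=float(y[0]), data_final=float(y[-1]),
        excluded_points=tuple(int(i) for i in exclude),
        covariance=pcov,
    )
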