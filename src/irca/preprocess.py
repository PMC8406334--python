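"""Per-spectrum corrections and cross-ramanome standardization.

Raw single-cell Raman spectra carry an instrument background (acquired
from the liquid around the cell) and a broad fluorescence baseline.
Background subtraction removes the former; an iterative polynomial fit
(ModPoly-style: fit, clamp the signal to the fit from above, refit)
removes the latter.

Because ramanomes acquired in different batches may differ in spectral
range and resolution, every ramanome is standardized in three steps
before any comparison or correlation:

  i.   crop to the biomolecular fingerprint region (600-1800 cm^-1),
  ii.  resample to a 1 cm^-1 grid by linear interpolation,
  iii. normalize each spectrum by its integrated area.

After step iii every cell's spectrum integrates (trapezoidally) to 1, so
per-cell acquisition-intensity differences cancel and intensities are
comparable across cells and ramanomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from irca.core import (
    AxisMismatchError,
    DegenerateInputError,
    IrcaError,
    Ramanome,
    SpectralAxis,
    Spectrum,
)

__all__ = [
    "PreprocessParams", "subtract_background", "correct_baseline",
    "resample", "crop_fingerprint", "normalize_area", "trapezoid_area",
    "standardize_ramanome",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of baseline correction and standardization.

    poly_degree: degree of the baseline polynomial (7 is a common choice
    for cellular Raman spectra with broad fluorescence).
    fingerprint: retained wavenumber window in cm^-1.
    target_step: grid step of the standardized axis in cm^-1.
    """

    poly_degree: int = 7
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    fingerprint: tuple[float, float] = (600.0, 1800.0)
    target_step: float = 1.0

    def __post_init__(self) -> None:
        if self.poly_degree < 0:
            raise ValueError("poly_degree must be >= 0")
        lo, hi = self.fingerprint
        if not lo < hi:
            raise ValueError("fingerprint window must satisfy lo < hi")
        if self.target_step <= 0:
            raise ValueError("target_step must be > 0")


def subtract_background(s: Spectrum, backgrounds: list[Spectrum]) -> Spectrum:
    """Subtract the mean of the background spectra from ``s``.

    Backgrounds are typically several spectra of the medium around the
    cell; all must share ``s``'s axis.
    """
    if not backgrounds:
        raise IrcaError("need at least one background spectrum")
    for b in backgrounds:
        if not np.array_equal(b.axis.wavenumbers, s.axis.wavenumbers):
            raise AxisMismatchError("background axis differs from spectrum axis")
    mean_bg = np.mean([b.intensities for b in backgrounds], axis=0)
    return Spectrum(s.axis, s.intensities - mean_bg)


def correct_baseline(s: Spectrum,
                     p: PreprocessParams = PreprocessParams(),
                     ) -> tuple[Spectrum, Spectrum]:
    """Iterative polynomial baseline fit; returns (corrected, baseline).

    Fits a degree-``p.poly_degree`` polynomial to the working signal,
    replaces every point lying above the fit by the fit, and repeats
    until the fit changes by less than ``p.baseline_tol`` (max absolute
    change) or ``p.baseline_max_iter`` iterations. Peaks, which sit above
    the smooth baseline, are thereby excluded from the fit while the
    broad background is tracked.
    """
    n = len(s)
    if n <= p.poly_degree + 1:
        raise DegenerateInputError(
            f"baseline fit of degree {p.poly_degree} needs more than "
            f"{p.poly_degree + 1} points, got {n}"
        )
    # scale x to [-1, 1] for numerical conditioning
    w = s.axis.wavenumbers
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    work = s.intensities.copy()
    prev_fit = np.full(n, np.inf)
    fit = work
    for _ in range(p.baseline_max_iter):
        coef = np.polynomial.polynomial.polyfit(x, work, p.poly_degree)
        fit = np.polynomial.polynomial.polyval(x, coef)
        if np.max(np.abs(fit - prev_fit)) < p.baseline_tol:
            break
        prev_fit = fit
        work = np.minimum(work, fit)
    else:
        warnings.warn(
            f"baseline fit did not converge in {p.baseline_max_iter} "
            "iterations; returning last iterate",
            stacklevel=2,
        )
    baseline = Spectrum(s.axis, fit)
    return Spectrum(s.axis, s.intensities - fit), baseline


def resample(s: Spectrum, target: SpectralAxis) -> Spectrum:
    """Linear interpolation of ``s`` onto ``target``; no extrapolation."""
    if target.lo < s.axis.lo or target.hi > s.axis.hi:
        raise IrcaError(
            f"target axis [{target.lo}, {target.hi}] extends beyond source "
            f"range [{s.axis.lo}, {s.axis.hi}]; extrapolation refused"
        )
    y = np.interp(target.wavenumbers, s.axis.wavenumbers, s.intensities)
    return Spectrum(target, y)


def crop_fingerprint(s: Spectrum, lo: float = 600.0, hi: float = 1800.0) -> Spectrum:
    """Keep only grid points inside the closed interval [lo, hi]."""
    mask = (s.axis.wavenumbers >= lo) & (s.axis.wavenumbers <= hi)
    if mask.sum() < 2:
        raise IrcaError(
            f"crop window [{lo}, {hi}] leaves {int(mask.sum())} points of "
            f"axis [{s.axis.lo}, {s.axis.hi}]"
        )
    return Spectrum(SpectralAxis(s.axis.wavenumbers[mask]),
                    s.intensities[mask])


def trapezoid_area(s: Spectrum) -> float:
    """Trapezoidal integral of the spectrum over its axis."""
    return float(np.trapezoid(s.intensities, s.axis.wavenumbers))


def normalize_area(s: Spectrum) -> Spectrum:
    """Divide by the trapezoidal area so the spectrum integrates to 1."""
    area = trapezoid_area(s)
    if not area > 0:
        raise IrcaError(f"cannot area-normalize: area = {area}")
    return Spectrum(s.axis, s.intensities / area)


def _standard_axis(p: PreprocessParams) -> SpectralAxis:
    lo, hi = p.fingerprint
    n = int(round((hi - lo) / p.target_step)) + 1
    return SpectralAxis(lo + p.target_step * np.arange(n))


def standardize_ramanome(r: Ramanome,
                         p: PreprocessParams = PreprocessParams(),
                         ) -> Ramanome:
    """Apply crop -> resample -> area-normalize to every cell.

    The output axis depends only on ``p``, so any two ramanomes
    standardized with the same parameters are directly comparable.
    Idempotent: standardizing twice equals standardizing once.
    """
    target = _standard_axis(p)
    if target.lo < r.axis.lo or target.hi > r.axis.hi:
        raise IrcaError(
            f"ramanome axis [{r.axis.lo}, {r.axis.hi}] does not cover the "
            f"fingerprint window {p.fingerprint}"
        )
    # crop with a one-native-step pad so the window endpoints remain
    # interpolable when the native grid does not hit them exactly
    pad = float(np.max(np.diff(r.axis.wavenumbers)))
    rows = []
    for i in range(r.n_cells):
        s = r.spectrum(i)
        s = crop_fingerprint(s, p.fingerprint[0] - pad, p.fingerprint[1] + pad)
        s = resample(s, target)
        s = normalize_area(s)
        rows.append(s.intensities)
    return Ramanome(target, np.vstack(rows), list(r.cells), dict(r.meta))
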