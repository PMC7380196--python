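"""1-D spectrum handling: Lorentzian deconvolution and peak integrals.

Two overlapping 19F resonances report on the active and inactive protein
states; their relative areas are direct population estimates for states in
slow exchange.  This module deconvolves such spectra with a sum of
Lorentzians plus a constant baseline, integrates peaks over ppm windows,
and converts areas to populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import argrelmax

__all__ = [
    "Spectrum1D",
    "LorentzianPeak",
    "DeconvolutionResult",
    "fit_lorentzians",
    "populations_from_integrals",
    "peak_integral",
]


@dataclass(frozen=True)
class Spectrum1D:
    """A 1-D spectrum: ppm axis, intensities, and the field it was taken at.

    The ppm axis follows NMR convention (chemical shifts may be negative and
    are conventionally plotted decreasing to the right); internally only
    strict monotonicity is required.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    spectrometer_freq: float  # MHz

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)
        if ppm.ndim != 1 or len(ppm) != len(inten):
            raise ValueError("ppm and intensity must be 1-D and equal length")
        d = np.diff(ppm)
        if len(d) == 0 or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    def ascending(self) -> "Spectrum1D":
        """Copy with the ppm axis sorted ascending (for quadrature)."""
        if self.ppm[1] > self.ppm[0]:
            return self
        return Spectrum1D(self.ppm[::-1].copy(), self.intensity[::-1].copy(),
                          self.spectrometer_freq)


@dataclass(frozen=True)
class LorentzianPeak:
    """One deconvolved Lorentzian line.

    ``center`` is in ppm; ``fwhm`` in Hz (linewidths are field-dependent, so
    Hz is the physically meaningful unit); ``amplitude`` is peak height in
    the spectrum's intensity units; ``area`` = amplitude * pi * fwhm / 2
    (a.u. * Hz), the analytic integral of the amplitude-parameterised line.
    """

    center: float
    fwhm: float
    amplitude: float
    area: float

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if not math.isclose(self.area, self.amplitude * math.pi * self.fwhm / 2.0,
                            rel_tol=1e-6, abs_tol=1e-12):
            raise ValueError("area inconsistent with amplitude*pi*fwhm/2")

    @classmethod
    def from_fit(cls, center: float, fwhm: float, amplitude: float) -> "LorentzianPeak":
        return cls(center=center, fwhm=fwhm, amplitude=amplitude,
                   area=amplitude * math.pi * fwhm / 2.0)


@dataclass(frozen=True)
class DeconvolutionResult:
    """Peaks (sorted by descending ppm), baseline, and convergence info."""

    peaks: tuple[LorentzianPeak, ...]
    baseline: float
    converged: bool
    cost: float
    message: str = ""
    diagnostics: dict = field(default_factory=dict, compare=False)


def _lorentz(ppm, center, hwhm_ppm, amplitude):
    return amplitude * hwhm_ppm**2 / ((ppm - center) ** 2 + hwhm_ppm**2)


def _initial_guesses(spec: Spectrum1D, n_peaks: int) -> list[tuple[float, float, float]]:
    """Crude initialisation from the n highest local maxima of the smoothed
    signal, with a width guess from the axis span.

    Smoothing (moving average over ~1% of the axis) keeps noise spikes from
    masquerading as peaks."""
    s = spec.ascending()
    base = float(np.median(s.intensity))
    y = s.intensity - base
    win = max(3, len(y) // 100)
    kernel = np.ones(win) / win
    smooth = np.convolve(y, kernel, mode="same")
    order = max(3, len(y) // 50)
    maxima = argrelmax(smooth, order=order)[0]
    if len(maxima) < n_peaks:
        maxima = np.argsort(smooth)[-n_peaks:]
    maxima = sorted(maxima, key=lambda i: smooth[i], reverse=True)[:n_peaks]
    width0 = (s.ppm[-1] - s.ppm[0]) / 20.0
    return [(float(s.ppm[i]), width0, float(max(y[i], 1e-12))) for i in maxima]


def fit_lorentzians(
    spectrum: Spectrum1D,
    n_peaks: int,
    init: list[tuple[float, float, float]] | None = None,
) -> DeconvolutionResult:
    """Least-squares deconvolution into ``n_peaks`` Lorentzians + constant
    baseline.

    ``init`` entries are (center_ppm, hwhm_ppm, amplitude) guesses; when
    omitted they come from the highest local maxima.  If two requested peaks
    initialise onto the same maximum the second is displaced by one width so
    overlapped doublets still separate.  Non-convergence is flagged on the
    result, never silent.
    """
    if n_peaks not in (1, 2):
        raise ValueError("n_peaks must be 1 or 2")
    s = spectrum.ascending()
    if init is None:
        init = _initial_guesses(s, n_peaks)
    elif n_peaks == 2 and abs(init[0][0] - init[1][0]) < 2 * max(init[0][1],
                                                                 init[1][1]):
        # merged user guesses: re-initialise from the two highest maxima
        init = _initial_guesses(s, n_peaks)

    span = s.ppm[-1] - s.ppm[0]
    x0 = [float(np.median(s.intensity))]
    lo = [-np.inf]
    hi = [np.inf]
    for c, w, a in init:
        x0 += [c, max(w, span / 500.0), max(a, 1e-12)]
        lo += [s.ppm[0], span / 1e4, 0.0]
        hi += [s.ppm[-1], span, np.inf]

    def resid(x):
        model = np.full_like(s.intensity, x[0])
        for j in range(n_peaks):
            c, w, a = x[1 + 3 * j : 4 + 3 * j]
            model += _lorentz(s.ppm, c, w, a)
        return model - s.intensity

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    peaks = []
    for j in range(n_peaks):
        c, w, a = sol.x[1 + 3 * j : 4 + 3 * j]
        fwhm_hz = 2.0 * w * s.spectrometer_freq  # ppm halfwidth -> Hz fullwidth
        peaks.append(LorentzianPeak.from_fit(center=float(c), fwhm=float(fwhm_hz),
                                             amplitude=float(a)))
    peaks.sort(key=lambda p: p.center, reverse=True)
    return DeconvolutionResult(
        peaks=tuple(peaks),
        baseline=float(sol.x[0]),
        converged=bool(sol.success),
        cost=float(sol.cost),
        message=sol.message,
        diagnostics={"nfev": sol.nfev, "optimality": sol.optimality},
    )


def populations_from_integrals(area_a: float, area_b: float) -> tuple[float, float]:
    """Fractional populations from two peak areas (slow-exchange limit)."""
    if area_a < 0 or area_b < 0:
        raise ValueError("areas must be non-negative")
    total = area_a + area_b
    if total == 0:
        raise ValueError("both areas are zero; populations undefined")
    return area_a / total, area_b / total


def peak_integral(
    spectrum: Spectrum1D,
    window: tuple[float, float],
    baseline_regions: list[tuple[float, float]] | None = None,
) -> float:
    """Trapezoidal integral of the spectrum over a ppm window.

    The baseline, estimated as the median intensity over ``baseline_regions``
    (default: the outer 10% of the axis at each end), is subtracted first.
    Returned area is in intensity * ppm units.
    """
    s = spectrum.ascending()
    lo, hi = min(window), max(window)
    if hi < s.ppm[0] or lo > s.ppm[-1]:
        raise ValueError("window lies outside the spectrum axis")
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 points")

    if baseline_regions is None:
        span = s.ppm[-1] - s.ppm[0]
        baseline_regions = [
            (s.ppm[0], s.ppm[0] + 0.1 * span),
            (s.ppm[-1] - 0.1 * span, s.ppm[-1]),
        ]
    base_mask = np.zeros_like(mask)
    for b_lo, b_hi in baseline_regions:
        base_mask |= (s.ppm >= min(b_lo, b_hi)) & (s.ppm <= max(b_lo, b_hi))
    baseline = float(np.median(s.intensity[base_mask])) if base_mask.any() else 0.0

    return float(np.trapezoid(s.intensity[mask] - baseline, s.ppm[mask]))
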