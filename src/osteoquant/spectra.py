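"""Raman spectral processing for bone matrix composition.

Turns a raw bone Raman spectrum into the three compositional quality
parameters used in bone-quality studies:

* mineral-to-matrix ratio (MMR): area of the ν1-PO4 band over the Amide I
  band — a proxy for the degree of tissue mineralization;
* type B carbonate substitution: ν1-CO3 over ν1-PO4 band areas — the
  extent of carbonate replacing phosphate in the apatite lattice;
* crystallinity: the reciprocal of the full width at half maximum of a
  Gaussian fitted to the ν1-PO4 band — narrower bands mean more ordered
  or larger mineral crystals.

The processing chain is raw → baseline-corrected → despiked → smoothed,
after which band areas and the phosphate Gaussian fit are evaluated.
Band areas are defined operationally throughout the package: the
trapezoidal integral of the smoothed intensity inside the band window,
after subtracting the straight line through the window endpoints.  The
synthetic generator realizes ground-truth areas under this same
definition, so generator → analyzer roundtrips are exact by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "SpectrumState",
    "RamanSpectrum",
    "BandDefinition",
    "RamanParameters",
    "DEFAULT_BANDS",
    "GridMismatchError",
    "BaselineFitError",
    "BandRangeError",
    "GaussianFitError",
    "average_accumulations",
    "correct_baseline",
    "remove_cosmic_rays",
    "smooth",
    "band_area",
    "fit_phosphate_gaussian",
    "compute_raman_parameters",
    "average_per_specimen",
]


class SpectrumState(enum.IntEnum):
    """Processing state; transitions are forward-only."""

    RAW = 0
    BASELINED = 1
    DESPIKED = 2
    SMOOTHED = 3


class GridMismatchError(ValueError):
    pass


class BaselineFitError(RuntimeError):
    pass


class BandRangeError(ValueError):
    pass


class GaussianFitError(RuntimeError):
    """Gaussian fit failed to converge; carries the initial guesses used."""

    def __init__(self, message: str, p0: tuple[float, float, float]):
        super().__init__(f"{message} (initial guesses amp={p0[0]:.4g}, "
                         f"center={p0[1]:.4g}, sigma={p0[2]:.4g})")
        self.p0 = p0


@dataclass(frozen=True)
class RamanSpectrum:
    """A single Raman spectrum with its processing state.

    wavenumber : strictly increasing grid in cm^-1 (length >= 64)
    intensity  : arbitrary counts, same length
    state      : position in the raw -> baselined -> despiked -> smoothed chain
    meta       : sample id, group, region tag, lacunar distance, ...
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    state: SpectrumState = SpectrumState.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.wavenumber, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if w.ndim != 1 or i.ndim != 1 or w.size != i.size:
            raise ValueError("wavenumber and intensity must be 1-D and equal length")
        if w.size < 64:
            raise ValueError(f"spectrum too short ({w.size} points; need >= 64)")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "wavenumber", w)
        object.__setattr__(self, "intensity", i)

    def __len__(self) -> int:
        return self.wavenumber.size

    def _advance(self, intensity: np.ndarray, state: SpectrumState) -> "RamanSpectrum":
        if state < self.state:
            raise ValueError(
                f"state may only advance forward (have {self.state.name}, "
                f"requested {state.name})")
        return replace(self, intensity=intensity, state=state)


@dataclass(frozen=True)
class BandDefinition:
    """A named integration/fit window in cm^-1."""

    name: str
    window: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"band {self.name}: window low must be < high")

    def slice(self, wavenumber: np.ndarray) -> np.ndarray:
        lo, hi = self.window
        return (wavenumber >= lo) & (wavenumber <= hi)


#: Default windows (bone Raman literature conventions): nu1 phosphate at
#: ~959 cm^-1, nu1 carbonate at ~1070 cm^-1, Amide I at ~1665 cm^-1.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "nu1_phosphate": BandDefinition("nu1_phosphate", (930.0, 980.0)),
    "nu1_carbonate": BandDefinition("nu1_carbonate", (1050.0, 1100.0)),
    "amide_I": BandDefinition("amide_I", (1620.0, 1700.0)),
}


@dataclass(frozen=True)
class RamanParameters:
    """The three compositional parameters plus the raw phosphate width.

    crystallinity is defined as 1 / fwhm_phosphate (units: cm).
    """

    mmr: float
    carbonate_substitution: float
    crystallinity: float
    fwhm_phosphate: float


def average_accumulations(spectra: Sequence[RamanSpectrum]) -> RamanSpectrum:
    """Pointwise mean of repeated raw accumulations on a shared grid."""
    if len(spectra) == 0:
        raise ValueError("cannot average an empty list of accumulations")
    first = spectra[0]
    for s in spectra[1:]:
        if s.wavenumber.shape != first.wavenumber.shape or not np.array_equal(
                s.wavenumber, first.wavenumber):
            raise GridMismatchError("accumulations are not on a shared wavenumber grid")
        if s.state != SpectrumState.RAW:
            raise ValueError("only raw spectra can be averaged as accumulations")
    if first.state != SpectrumState.RAW:
        raise ValueError("only raw spectra can be averaged as accumulations")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    return replace(first, intensity=mean)


def correct_baseline(s: RamanSpectrum, order: int = 11, *,
                     max_iter: int = 20, rtol: float = 1e-4,
                     exclusion_k: float = 2.0) -> RamanSpectrum:
    """Subtract a polynomial background estimated with iterative peak exclusion.

    A polynomial of the given order is least-squares fitted to the spectrum,
    points lying more than ``exclusion_k`` robust standard deviations above
    the fit are dropped, and the fit repeats until the baseline stabilises
    (relative change < ``rtol``) or ``max_iter`` passes.  Direct least
    squares through the peaks would pull the baseline up into the bands;
    excluding high outliers recovers the background they sit on.
    """
    if s.state != SpectrumState.RAW:
        raise ValueError("baseline correction expects a raw spectrum")
    if order < 1:
        raise ValueError("polynomial order must be >= 1")
    n = len(s)
    if n <= order + 1:
        raise ValueError(f"spectrum length {n} too short for order {order}")

    # fit in a [-1, 1] scaled domain: raw wavenumbers at order 11 would be
    # catastrophically ill-conditioned
    x = np.interp(s.wavenumber, (s.wavenumber[0], s.wavenumber[-1]), (-1.0, 1.0))
    y = s.intensity
    scale = float(np.ptp(y)) or 1.0
    keep = np.ones(n, dtype=bool)
    baseline = np.zeros(n)
    for _ in range(max_iter):
        if keep.sum() <= order + 1:
            raise BaselineFitError(
                f"baseline fit of order {order} is rank deficient "
                f"({keep.sum()} points retained)")
        try:
            coef = npoly.polyfit(x[keep], y[keep], order)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise BaselineFitError(f"baseline fit of order {order} failed") from exc
        new_baseline = npoly.polyval(x, coef)
        resid = y - new_baseline
        # robust sigma of retained residuals; floor avoids a degenerate
        # threshold on noiseless synthetic input
        sigma = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
        sigma = max(sigma, 1e-9 * scale)
        new_keep = resid <= exclusion_k * sigma
        converged = np.max(np.abs(new_baseline - baseline)) < rtol * scale
        baseline = new_baseline
        if converged and np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return s._advance(y - baseline, SpectrumState.BASELINED)


def remove_cosmic_rays(s: RamanSpectrum, *, k: float = 8.0,
                       max_width: int = 2) -> RamanSpectrum:
    """Replace narrow cosmic-ray spikes by linear interpolation.

    Candidate points are flagged where the absolute second difference
    exceeds ``k`` times the median absolute second difference.  Flagged
    points are grouped into runs: a 1-point spike perturbs the second
    difference at three consecutive positions and a 2-point spike at four,
    so only runs of at most ``2 * max_width`` flagged positions are treated
    as spike candidates — genuine bands (>= 3 points wide) produce longer
    runs of high curvature and pass through untouched.  Within a candidate
    run only the points that deviate strongly from the chord joining the
    run's flanking good points are replaced, so neighbours of a spike are
    left bit-identical.
    """
    if s.state != SpectrumState.BASELINED:
        raise ValueError("despiking expects a baseline-corrected spectrum")
    y = s.intensity
    n = y.size
    d2 = np.zeros(n)
    d2[1:-1] = y[2:] - 2.0 * y[1:-1] + y[:-2]
    mad = np.median(np.abs(d2[1:-1]))
    if mad == 0.0:
        mad = 1e-12 * (float(np.max(np.abs(d2))) or 1.0)
    flagged = np.abs(d2) > k * mad

    out = y.copy()
    changed = False
    idx = np.flatnonzero(flagged)
    if idx.size:
        # split flagged indices into consecutive runs
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            if run.size > 2 * max_width:
                continue  # broad curvature: a real band, not a spike
            lo = max(run[0] - 1, 0)
            hi = min(run[-1] + 1, n - 1)
            chord = np.interp(s.wavenumber[lo:hi + 1],
                              [s.wavenumber[lo], s.wavenumber[hi]],
                              [y[lo], y[hi]])
            dev = np.abs(y[lo:hi + 1] - chord)
            spike_points = lo + np.flatnonzero(dev > k * mad)
            for p in spike_points:
                if 0 < p < n - 1:
                    out[p] = np.interp(s.wavenumber[p],
                                       [s.wavenumber[lo], s.wavenumber[hi]],
                                       [y[lo], y[hi]])
                    changed = True
    if not changed:
        out = y
    return s._advance(out, SpectrumState.DESPIKED)


#: Smoothing strategies.  The instrument-software notion of a "modified"
#: Savitzky-Golay filter is not a single well-defined algorithm; the package
#: ships the standard filter and keeps the strategy switchable so variants
#: can be registered without touching the pipeline.
_SMOOTHERS = {
    "savgol": lambda y, window, polyorder: savgol_filter(
        y, window_length=window, polyorder=polyorder, mode="interp"),
}


def smooth(s: RamanSpectrum, window: int = 11, polyorder: int = 4,
           *, strategy: str = "savgol") -> RamanSpectrum:
    """Savitzky-Golay smoothing (local polynomial least squares)."""
    if s.state != SpectrumState.DESPIKED:
        raise ValueError("smoothing expects a despiked spectrum")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window >= len(s):
        raise ValueError(f"window {window} must be smaller than spectrum length {len(s)}")
    try:
        smoother = _SMOOTHERS[strategy]
    except KeyError:
        raise ValueError(f"unknown smoothing strategy {strategy!r}") from None
    return s._advance(smoother(s.intensity, window, polyorder),
                      SpectrumState.SMOOTHED)


def _windowed_area(x: np.ndarray, y: np.ndarray, anchor: int = 12) -> float:
    """Trapezoid area above the chord through the window endpoints.

    Each chord endpoint is anchored on the mean of up to ``anchor``
    outermost points, capped at a quarter of the window per side (for a
    locally linear background the mean sits exactly on the line, so clean
    linear data still integrate to zero) — a single noisy endpoint sample
    would otherwise project its noise across the whole window width, and
    the chord level error is the variance floor of small-band areas.
    """
    k = min(anchor, x.size // 4) or 1
    xa, ya = float(np.mean(x[:k])), float(np.mean(y[:k]))
    xb, yb = float(np.mean(x[-k:])), float(np.mean(y[-k:]))
    chord = ya + (yb - ya) * (x - xa) / (xb - xa)
    return float(np.trapezoid(y - chord, x))


def band_area(s: RamanSpectrum, band: BandDefinition) -> float:
    """Band area: windowed trapezoid minus the endpoint chord, floored at 0.

    Subtracting the straight line through the window endpoints decouples
    the band from any residual background and makes the area robust to the
    exact window placement.
    """
    if s.state != SpectrumState.SMOOTHED:
        raise ValueError("band areas are computed on smoothed spectra")
    lo, hi = band.window
    if lo < s.wavenumber[0] or hi > s.wavenumber[-1]:
        raise BandRangeError(
            f"band {band.name} window {band.window} outside spectrum range "
            f"({s.wavenumber[0]:.1f}, {s.wavenumber[-1]:.1f})")
    m = band.slice(s.wavenumber)
    if m.sum() < 3:
        raise BandRangeError(f"band {band.name} covers fewer than 3 grid points")
    return max(_windowed_area(s.wavenumber[m], s.intensity[m]), 0.0)


def _gaussian(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _gaussian_linear(x, amp, center, sigma, b0, b1):
    return _gaussian(x, amp, center, sigma) + b0 + b1 * (x - x[0])


FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # fwhm = factor * sigma


def fit_phosphate_gaussian(s: RamanSpectrum, band: BandDefinition,
                           ) -> tuple[float, float, float]:
    """Least-squares Gaussian fit inside a band window.

    The model is a Gaussian plus a linear background term so residual
    off-peak background cannot bias the fitted width; the returned values
    describe the Gaussian part only.  Returns (amplitude, center cm^-1,
    fwhm cm^-1).  Initialisation: amplitude at the window maximum, center
    at its argmax, sigma at one sixth of the window span; deterministic.
    """
    if s.state != SpectrumState.SMOOTHED:
        raise ValueError("Gaussian fits are computed on smoothed spectra")
    m = band.slice(s.wavenumber)
    x, y = s.wavenumber[m], s.intensity[m]
    if x.size < 7:
        raise BandRangeError(f"band {band.name} covers too few points for a fit")
    i0 = int(np.argmax(y))
    p0 = (float(y[i0]), float(x[i0]), float((x[-1] - x[0]) / 6.0))
    try:
        popt, _ = curve_fit(_gaussian_linear, x, y, p0=p0 + (0.0, 0.0),
                            xtol=1e-8, ftol=1e-8, maxfev=10000)
    except RuntimeError as exc:
        raise GaussianFitError(f"Gaussian fit in band {band.name} did not converge",
                               p0) from exc
    amp, center, sigma = popt[:3]
    sigma = abs(float(sigma))
    if sigma <= 0 or not np.isfinite(sigma):
        raise GaussianFitError(f"Gaussian fit in band {band.name} degenerate", p0)
    return float(amp), float(center), FWHM_FACTOR * sigma


def compute_raman_parameters(s: RamanSpectrum,
                             bands: dict[str, BandDefinition] | None = None,
                             ) -> RamanParameters:
    """MMR, type B carbonate substitution, and crystallinity of one spectrum."""
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    for required in ("nu1_phosphate", "nu1_carbonate", "amide_I"):
        if required not in bands:
            raise ValueError(f"band definition {required!r} missing")
    a_po4 = band_area(s, bands["nu1_phosphate"])
    a_co3 = band_area(s, bands["nu1_carbonate"])
    a_amide = band_area(s, bands["amide_I"])
    if a_po4 <= 0 or a_amide <= 0:
        raise ZeroDivisionError(
            "zero phosphate or Amide I band area; ratios undefined")
    _, _, fwhm = fit_phosphate_gaussian(s, bands["nu1_phosphate"])
    return RamanParameters(
        mmr=a_po4 / a_amide,
        carbonate_substitution=a_co3 / a_po4,
        crystallinity=1.0 / fwhm,
        fwhm_phosphate=fwhm,
    )


def process_spectrum(s: RamanSpectrum,
                     bands: dict[str, BandDefinition] | None = None,
                     *, baseline_order: int = 11, smooth_window: int = 11,
                     smooth_polyorder: int = 4) -> RamanParameters:
    """Full raw → parameters chain with the default pipeline settings."""
    s = correct_baseline(s, order=baseline_order)
    s = remove_cosmic_rays(s)
    s = smooth(s, window=smooth_window, polyorder=smooth_polyorder)
    return compute_raman_parameters(s, bands)


def average_per_specimen(values: Sequence[RamanParameters]) -> RamanParameters:
    """Average parameter values (not spectra) across a specimen's points.

    Periosteal measurements are taken at several locations per specimen and
    reduced to one value per parameter per specimen by averaging the
    computed parameters.
    """
    if not values:
        raise ValueError("no parameter sets to average")
    fwhm = float(np.mean([v.fwhm_phosphate for v in values]))
    return RamanParameters(
        mmr=float(np.mean([v.mmr for v in values])),
        carbonate_substitution=float(np.mean([v.carbonate_substitution
                                              for v in values])),
        crystallinity=float(np.mean([v.crystallinity for v in values])),
        fwhm_phosphate=fwhm,
    )
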