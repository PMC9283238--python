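"""Quantitative backscattered-electron imaging (qBEI) and the BMDD.

Backscatter gray levels scale with mean atomic number, so an 8-bit BSE
image of embedded bone calibrated against carbon (Z=6) and aluminum
(Z=13) standards maps each pixel to a local calcium content in weight
percent.  The bone mineral density distribution (BMDD) is the normalized
histogram of calcium content over a region of interest, summarized by

* ``ca_mean``  — frequency-weighted mean calcium content (wt%),
* ``ca_peak``  — calcium content of the most frequent bin (wt%),
* ``ca_width`` — full width at half maximum of the distribution (wt%),
  a measure of mineralization heterogeneity.

The gray→calcium map is affine and anchored, by convention, at the carbon
standard gray level (0 wt% Ca) and at the aluminum standard gray level
(39.86 wt% Ca, the calcium mass fraction of pure hydroxyapatite).  Both
anchors are configurable; the same map must be used for synthesis and
analysis for roundtrips to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BSEImage",
    "GrayCalibration",
    "StandardsReport",
    "BMDDMetrics",
    "check_standards",
    "gray_to_calcium",
    "compute_bmdd",
]

#: calcium mass fraction of stoichiometric hydroxyapatite, wt%
HYDROXYAPATITE_CA_WT = 39.86

MIN_ROI_PIXELS = 1000


@dataclass(frozen=True)
class GrayCalibration:
    """Affine gray-level → calcium wt% calibration from two standards.

    gray_carbon / gray_aluminum are the target gray levels of the carbon
    and aluminum standards (25 and 225 in the reference protocol, each
    accepted within ±1), anchored at ca_carbon and ca_aluminum wt%.
    """

    gray_carbon: float = 25.0
    gray_aluminum: float = 225.0
    tolerance: float = 1.0
    ca_carbon: float = 0.0
    ca_aluminum: float = HYDROXYAPATITE_CA_WT

    def __post_init__(self):
        if not self.gray_aluminum > self.gray_carbon:
            raise ValueError("aluminum gray level must exceed carbon gray level")
        if not self.ca_aluminum > self.ca_carbon:
            raise ValueError("calcium anchors must be increasing")

    @property
    def slope(self) -> float:
        """wt% Ca per gray step."""
        return (self.ca_aluminum - self.ca_carbon) / \
            (self.gray_aluminum - self.gray_carbon)

    @property
    def intercept(self) -> float:
        return self.ca_carbon - self.slope * self.gray_carbon

    def calcium_to_gray(self, ca: np.ndarray | float) -> np.ndarray | float:
        """Inverse map (continuous; no quantization)."""
        return (np.asarray(ca, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class BSEImage:
    """8-bit grayscale BSE image with an ROI mask and metadata."""

    pixels: np.ndarray
    roi_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        roi = np.asarray(self.roi_mask, dtype=bool)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.shape != roi.shape:
            raise ValueError("ROI mask shape must match the image shape")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "roi_mask", roi)

    @property
    def roi_pixels(self) -> np.ndarray:
        return self.pixels[self.roi_mask]


@dataclass(frozen=True)
class StandardsReport:
    measured_carbon: float
    measured_aluminum: float
    carbon_ok: bool
    aluminum_ok: bool

    @property
    def accepted(self) -> bool:
        return self.carbon_ok and self.aluminum_ok


@dataclass(frozen=True)
class BMDDMetrics:
    """Summary of a bone mineral density distribution.

    bin_centers_wt / frequency carry the full normalized histogram
    (one bin per 8-bit gray step mapped through the calibration).
    """

    bin_centers_wt: np.ndarray
    frequency: np.ndarray
    ca_mean: float
    ca_peak: float
    ca_width: float
    degenerate: bool = False


def check_standards(measured_c: float, measured_al: float,
                    cal: GrayCalibration) -> StandardsReport:
    """Accept a session's brightness/contrast setting iff both standards hit
    their target gray levels within the calibration tolerance."""
    for v, name in ((measured_c, "carbon"), (measured_al, "aluminum")):
        if not 0 <= v <= 255:
            raise ValueError(f"measured {name} gray level {v} outside [0, 255]")
    return StandardsReport(
        measured_carbon=measured_c,
        measured_aluminum=measured_al,
        carbon_ok=abs(measured_c - cal.gray_carbon) <= cal.tolerance,
        aluminum_ok=abs(measured_al - cal.gray_aluminum) <= cal.tolerance,
    )


def gray_to_calcium(g: np.ndarray | float, cal: GrayCalibration,
                    ) -> np.ndarray | float:
    """Affine gray → calcium wt% map; strictly increasing in g."""
    garr = np.asarray(g, dtype=float)
    if np.any((garr < 0) | (garr > 255)):
        raise ValueError("gray level outside [0, 255]")
    out = cal.slope * garr + cal.intercept
    return float(out) if np.isscalar(g) else out


def _fwhm_linear(x: np.ndarray, f: np.ndarray, bin_width: float,
                 ) -> tuple[float, bool]:
    """FWHM of a histogram curve by linear interpolation at half maximum."""
    i_peak = int(np.argmax(f))
    half = f[i_peak] / 2.0
    above = f >= half
    if above.sum() <= 1:
        return bin_width, True
    lo = int(np.argmax(above))                 # first bin at/above half max
    hi = len(f) - 1 - int(np.argmax(above[::-1]))  # last bin at/above half max
    # interpolate the crossings just outside [lo, hi]
    if lo > 0:
        x_left = x[lo - 1] + (half - f[lo - 1]) / (f[lo] - f[lo - 1]) * \
            (x[lo] - x[lo - 1])
    else:
        x_left = x[0] - 0.5 * bin_width
    if hi < len(f) - 1:
        x_right = x[hi] + (f[hi] - half) / (f[hi] - f[hi + 1]) * \
            (x[hi + 1] - x[hi])
    else:
        x_right = x[-1] + 0.5 * bin_width
    return float(x_right - x_left), False


def compute_bmdd(img: BSEImage, cal: GrayCalibration, *,
                 peak_smooth_bins: int = 3) -> BMDDMetrics:
    """BMDD metrics over the ROI of a calibrated BSE image.

    The histogram has one bin per 8-bit gray step mapped through the
    calibration (no re-binning), normalized to unit mass.  ``ca_peak`` and
    the half-maximum crossings are evaluated on a light moving-average of
    the histogram (``peak_smooth_bins`` bins, default 3) so that counting
    noise in a single bin cannot masquerade as the mode; ``ca_mean`` uses
    the raw frequencies.  A single-gray-level ROI is flagged degenerate and
    its width reported as one bin.
    """
    roi = img.roi_pixels
    if roi.size < MIN_ROI_PIXELS:
        raise ValueError(
            f"ROI has {roi.size} pixels; need >= {MIN_ROI_PIXELS} for BMDD metrics")
    counts = np.bincount(roi, minlength=256).astype(float)
    freq = counts / counts.sum()
    centers = gray_to_calcium(np.arange(256, dtype=float), cal)
    bin_width = cal.slope  # wt% per gray step

    ca_mean = float(np.sum(freq * centers))

    if np.count_nonzero(counts) == 1:
        only = centers[int(np.argmax(counts))]
        return BMDDMetrics(bin_centers_wt=centers, frequency=freq,
                           ca_mean=ca_mean, ca_peak=float(only),
                           ca_width=float(bin_width), degenerate=True)

    if peak_smooth_bins > 1:
        kernel = np.ones(peak_smooth_bins) / peak_smooth_bins
        smoothed = np.convolve(freq, kernel, mode="same")
    else:
        smoothed = freq
    ca_peak = float(centers[int(np.argmax(smoothed))])
    ca_width, degenerate = _fwhm_linear(centers, smoothed, bin_width)
    return BMDDMetrics(bin_centers_wt=centers, frequency=freq,
                       ca_mean=ca_mean, ca_peak=ca_peak,
                       ca_width=ca_width, degenerate=degenerate)
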