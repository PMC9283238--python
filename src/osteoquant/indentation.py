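"""Oliver-Pharr analysis of load-controlled nanoindentation curves.

An indent is driven in load control to a programmed peak (1000 μN in the
reference protocol), held to let creep settle, and unloaded.  The analysis
chain is

1. segment the record into loading / hold / unloading branches,
2. fit the Oliver-Pharr power law ``P = alpha * (h - h_f)**m`` to the
   95%–40% region of the unloading branch and take ``S = dP/dh`` at the
   maximum depth,
3. contact depth ``h_c = h_max - eps * P_max / S``,
4. spherical contact area ``A = pi * (2 R h_c - h_c^2)``,
5. reduced modulus ``E_r = (1/beta) * (sqrt(pi)/2) * S / sqrt(A)`` and
   hardness ``H = P_max / A``.

Internal units: load μN, displacement nm, time s; areas μm², moduli GPa
(1 μN/μm² = 1 MPa).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IndentCurve",
    "ProbeGeometry",
    "IndentResult",
    "SegmentationError",
    "InsufficientDataError",
    "segment_curve",
    "unloading_stiffness",
    "contact_area",
    "reduced_modulus",
    "hardness",
    "analyze_indent",
]

NM_PER_UM = 1000.0
MPA_PER_GPA = 1000.0  # 1 μN/μm² = 1 MPa


class SegmentationError(RuntimeError):
    pass


class InsufficientDataError(RuntimeError):
    pass


class StiffnessStrategy(str, enum.Enum):
    """How the 95%–40% unloading "slope" is turned into S."""

    POWER_LAW = "power_law"   # dP/dh of the fitted power law at h_max
    SECANT = "secant"         # chord slope between the range endpoints


@dataclass(frozen=True)
class ProbeGeometry:
    """Spherical indenter probe.

    radius_um : probe radius R in μm (1.03 for the reference diamond probe)
    beta      : dimensionless geometric factor (1 for axisymmetric probes)
    epsilon   : intercept factor in the contact-depth correction
                (0.75 for spherical/paraboloid contact)
    """

    radius_um: float = 1.03
    beta: float = 1.0
    epsilon: float = 0.75
    shape: str = "sphere"

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("probe radius must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


@dataclass(frozen=True)
class IndentCurve:
    """A load-displacement-time record with optional segment boundaries.

    time_s    : strictly increasing, s
    load_uN   : μN
    disp_nm   : nm
    load_end  : index of the last loading sample (start of the hold)
    hold_end  : index of the last hold sample (start of the unloading)
    """

    time_s: np.ndarray
    load_uN: np.ndarray
    disp_nm: np.ndarray
    load_end: int | None = None
    hold_end: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.load_uN, dtype=float)
        h = np.asarray(self.disp_nm, dtype=float)
        if not (t.size == p.size == h.size):
            raise ValueError("time, load and displacement must be equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "load_uN", p)
        object.__setattr__(self, "disp_nm", h)
        if self.load_end is not None and self.hold_end is not None:
            if not 0 < self.load_end < self.hold_end < t.size - 1:
                raise ValueError("segment boundaries must satisfy "
                                 "load < hold < unload ordering")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def segmented(self) -> bool:
        return self.load_end is not None and self.hold_end is not None


@dataclass(frozen=True)
class IndentResult:
    """Oliver-Pharr outputs for one indent.  H * A == Pmax by construction."""

    S_uN_per_nm: float
    hc_nm: float
    A_um2: float
    Er_GPa: float
    H_GPa: float
    Pmax_uN: float
    hmax_nm: float
    m_exponent: float
    fit_warning: bool = False


def _refine_corner(p: np.ndarray, boundary: int, level: float, side: str,
                   window: int = 20, clamp: int = 12) -> int:
    """Move a threshold-crossing boundary to the ramp/plateau intersection.

    A threshold crossing systematically lands where the load passes
    ``(1 - tol) * plateau``, not at the corner itself; intersecting a line
    fitted to the adjacent ramp with the plateau level removes that offset
    exactly on piecewise-linear profiles and to a fraction of a sample
    under noise.
    """
    n = p.size
    # fit only samples clearly below the plateau, so a misplaced raw
    # boundary cannot mix plateau samples into the ramp fit
    ramp_level = 0.97 * level
    if side == "load":
        lo = max(boundary - 2 * window, 0)
        idx = lo + np.flatnonzero(p[lo:boundary] < ramp_level)
        idx = idx[-window:]
    else:
        hi = min(boundary + 2 * window, n)
        idx = boundary + np.flatnonzero(p[boundary:hi] < ramp_level)
        idx = idx[:window]
    if idx.size < 5:
        return boundary
    slope, intercept = np.polyfit(idx, p[idx], 1)
    sign = 1.0 if side == "load" else -1.0
    if slope * sign <= 0:
        return boundary
    corner = int(round((level - intercept) / slope))
    corner = max(boundary - clamp, min(boundary + clamp, corner))
    return max(1, min(n - 2, corner))


def segment_curve(c: IndentCurve, hold_tolerance: float = 0.01,
                  min_hold_points: int = 3, max_gap: int = 15) -> IndentCurve:
    """Locate the load/hold/unload boundaries of a load-controlled indent.

    The hold is the region where the load sits within ``hold_tolerance``
    of the plateau level: the loading branch ends where the load first
    reaches it and the hold ends just before the load falls back out of
    it.  Robustness choices: thresholding is applied to a 9-sample running
    median of the load (a running median over a monotone ramp returns the
    center sample, so clean profiles are untouched); the plateau level is
    the median of the near-peak samples rather than the noisy maximum;
    mask gaps of up to ``max_gap`` samples inside the plateau are bridged
    so noise dips cannot end the hold early; and both boundaries are
    refined to the intersection of the adjacent ramp with the plateau
    level, which is exact for trapezoidal profiles.
    """
    if len(c) < 30:
        raise SegmentationError(f"curve too short to segment ({len(c)} points)")
    p = c.load_uN
    if float(np.max(p)) <= 0:
        raise SegmentationError("non-positive peak load")
    from scipy.ndimage import median_filter
    pf = median_filter(p, size=9, mode="nearest")
    coarse = pf >= (1.0 - 2.0 * hold_tolerance) * float(np.max(pf))
    plateau = float(np.median(pf[coarse]))
    near = pf >= (1.0 - hold_tolerance) * plateau
    idx = np.flatnonzero(near)
    if idx.size == 0:
        raise SegmentationError("no samples near the peak load")
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    merged: list[np.ndarray] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] <= max_gap + 1:
            merged[-1] = np.concatenate(
                [merged[-1], np.arange(merged[-1][-1] + 1, run[-1] + 1)])
        else:
            merged.append(run)
    candidates = [r for r in merged
                  if r.size >= min_hold_points and 0 < r[0] and
                  r[-1] < len(c) - 1]
    if not candidates:
        raise SegmentationError(
            f"no hold plateau detected at tolerance {hold_tolerance}")
    best = max(candidates, key=len)
    load_end = _refine_corner(p, int(best[0]), plateau, "load")
    hold_end = _refine_corner(p, int(best[-1]), plateau, "hold")
    if hold_end <= load_end:
        load_end, hold_end = int(best[0]), int(best[-1])
    return replace(c, load_end=load_end, hold_end=hold_end)


def _power_law_inverse(p_over_pmax, h_f, h_peak, m):
    # displacement as a function of load, normalized by the peak load:
    # h = h_f + (h_peak - h_f) * (P/Pmax)**(1/m), i.e. P = alpha*(h-h_f)**m
    # with alpha = Pmax/(h_peak - h_f)**m.  This parametrization decouples
    # the scale from the exponent and keeps the fit well conditioned.
    return h_f + (h_peak - h_f) * p_over_pmax ** (1.0 / m)


def unloading_stiffness(c: IndentCurve, upper: float = 0.95, lower: float = 0.40,
                        *, strategy: StiffnessStrategy = StiffnessStrategy.POWER_LAW,
                        ) -> tuple[float, float, float, float, bool]:
    """Stiffness from the 95%–40% region of the unloading branch.

    Fits the Oliver-Pharr power law ``P = alpha * (h - h_f)**m`` to the
    unloading samples with ``lower*Pmax <= P <= upper*Pmax`` and evaluates
    ``S = dP/dh`` at the maximum depth.  The least-squares fit is cast as
    ``h(P) = h_f + (P/alpha)**(1/m)`` because in load control the load is
    the clean programmed variable and the measurement noise lives in the
    displacement; regressing the noisy variable on the clean one avoids
    the attenuation bias of the transposed fit.  The maximum depth is
    taken from the fitted curve at P_max, which coincides with the
    measured value on noiseless data.  Returns ``(S [μN/nm], h_max [nm],
    P_max [μN], m, fit_warning)``; the warning flags a fitted exponent
    outside the physically expected [1, 3] range.
    """
    if not c.segmented:
        raise ValueError("curve must be segmented before stiffness analysis")
    unload = slice(c.hold_end, len(c))
    p_u = c.load_uN[unload]
    h_u = c.disp_nm[unload]
    pmax = float(np.max(c.load_uN))
    hmax = float(h_u[0])
    if float(np.min(p_u)) > lower * pmax:
        raise InsufficientDataError(
            f"unloading branch does not span below {lower:.0%} of Pmax")
    m_range = (p_u >= lower * pmax) & (p_u <= upper * pmax)
    if m_range.sum() < 8:
        raise InsufficientDataError(
            f"only {int(m_range.sum())} unloading points in the "
            f"{upper:.0%}-{lower:.0%} load range (need >= 8)")
    x, y = h_u[m_range], p_u[m_range]

    if strategy is StiffnessStrategy.SECANT:
        # chord through the extreme points of the fit range
        i_hi, i_lo = int(np.argmax(y)), int(np.argmin(y))
        S = (y[i_hi] - y[i_lo]) / (x[i_hi] - x[i_lo])
        return float(S), hmax, pmax, 1.0, False

    h_min = float(np.min(x))
    h_f0 = h_min - 0.5 * (hmax - h_min)
    p0 = (h_f0, hmax, 1.5)
    bounds = ([-np.inf, h_min, 0.5], [h_min, np.inf, 5.0])
    popt, _ = curve_fit(_power_law_inverse, y / pmax, x, p0=p0,
                        bounds=bounds, maxfev=20000)
    h_f, h_peak, m = (float(v) for v in popt)
    hmax = h_peak
    S = m * pmax / (h_peak - h_f)
    if S <= 0 or not np.isfinite(S):
        raise InsufficientDataError("non-positive fitted unloading stiffness")
    return S, hmax, pmax, m, not (1.0 <= m <= 3.0)


def contact_area(hc_nm: float, probe: ProbeGeometry) -> float:
    """Projected contact area of a sphere at contact depth hc, in μm²."""
    hc_um = hc_nm / NM_PER_UM
    if hc_um <= 0:
        raise ValueError("contact depth must be positive")
    if hc_um >= 2.0 * probe.radius_um:
        raise ValueError(
            f"contact depth {hc_um:.3f} μm exceeds the probe diameter "
            f"{2 * probe.radius_um:.3f} μm")
    return float(np.pi * (2.0 * probe.radius_um * hc_um - hc_um ** 2))


def reduced_modulus(S_uN_per_nm: float, A_um2: float,
                    probe: ProbeGeometry) -> float:
    """Reduced elastic modulus E_r = (1/beta) (sqrt(pi)/2) S / sqrt(A), GPa."""
    if S_uN_per_nm <= 0 or A_um2 <= 0:
        raise ValueError("stiffness and contact area must be positive")
    S_uN_per_um = S_uN_per_nm * NM_PER_UM
    er_mpa = (1.0 / probe.beta) * (np.sqrt(np.pi) / 2.0) * \
        S_uN_per_um / np.sqrt(A_um2)
    return float(er_mpa / MPA_PER_GPA)


def hardness(Pmax_uN: float, A_um2: float) -> float:
    """Hardness H = Pmax / A, converted to GPa."""
    if Pmax_uN <= 0:
        raise ValueError("peak load must be positive")
    if A_um2 <= 0:
        raise ValueError("contact area must be positive")
    return float(Pmax_uN / A_um2 / MPA_PER_GPA)


def analyze_indent(c: IndentCurve, probe: ProbeGeometry | None = None,
                   *, upper: float = 0.95, lower: float = 0.40,
                   strategy: StiffnessStrategy = StiffnessStrategy.POWER_LAW,
                   ) -> IndentResult:
    """Full Oliver-Pharr chain on one (segmented or raw) indent curve."""
    probe = probe or ProbeGeometry()
    if not c.segmented:
        c = segment_curve(c)
    try:
        S, hmax, pmax, m, warn = unloading_stiffness(
            c, upper=upper, lower=lower, strategy=strategy)
    except (InsufficientDataError, RuntimeError) as exc:
        raise type(exc)(f"unloading-stiffness stage: {exc}") from exc
    hc = hmax - probe.epsilon * pmax / S
    if hc <= 0:
        raise ValueError("contact-depth stage: non-positive contact depth")
    try:
        A = contact_area(hc, probe)
        Er = reduced_modulus(S, A, probe)
        H = hardness(pmax, A)
    except ValueError as exc:
        raise ValueError(f"contact-mechanics stage: {exc}") from exc
    return IndentResult(S_uN_per_nm=S, hc_nm=hc, A_um2=A, Er_GPa=Er, H_GPa=H,
                        Pmax_uN=pmax, hmax_nm=hmax, m_exponent=m,
                        fit_warning=warn)
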