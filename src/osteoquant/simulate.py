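"""Synthetic bone-quality data with known ground truth.

Forward models for the three instrument layers, each built as the exact
inverse of the corresponding analyzer so that roundtrip recovery can be
scored against known truth:

* Raman spectra — Gaussian bands at the ν1-PO4 (959 cm^-1),
  ν1-CO3 (1070 cm^-1) and Amide I (1665 cm^-1) positions on an
  800–1800 cm^-1 grid, a smooth polynomial fluorescence-like baseline,
  optional cosmic-ray spikes, multiplicative Gaussian noise.  Band
  amplitudes are scaled so that the *windowed, endpoint-corrected* band
  area (the analyzer's operational area definition) matches the requested
  truth exactly.
* Indentation curves — Hertzian spherical loading
  ``P = (4/3) E_r sqrt(R) h^{3/2}`` to the programmed peak, a hold with
  logarithmic creep, and a power-law unload whose stiffness at maximum
  depth and residual depth are constructed so that the Oliver-Pharr chain
  returns the requested (E_r, H) in the noiseless limit.
* BSE images — a Gaussian calcium field quantized to 8-bit gray through
  the gray calibration, with a horizontal "new bone" ROI band.

``generate_study`` assembles a full three-group design (CTRL, CKD,
CKD_KP; periosteal points per animal plus perilacunar points at fixed
distances from the lacunar wall) either as raw on-disk signals or as
measurement-level parameter tables for statistical studies at scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .indentation import IndentCurve, ProbeGeometry, NM_PER_UM, MPA_PER_GPA
from .qbei import BSEImage, GrayCalibration
from .spectra import (BandDefinition, DEFAULT_BANDS, FWHM_FACTOR,
                      RamanSpectrum, SpectrumState, _windowed_area)

__all__ = [
    "BAND_CENTERS",
    "generate_spectrum",
    "generate_indent_curve",
    "generate_bse_image",
    "GroupTruth",
    "StudyConfig",
    "StudyTables",
    "generate_study_tables",
    "generate_study",
]

#: band center positions, cm^-1
BAND_CENTERS = {"nu1_phosphate": 959.0, "nu1_carbonate": 1070.0,
                "amide_I": 1665.0}
#: fixed shape widths of the non-phosphate bands, cm^-1 (fwhm)
FIXED_FWHM = {"nu1_carbonate": 20.0, "amide_I": 45.0}

GRID = np.arange(800.0, 1801.0, 1.0)


class ConfigError(ValueError):
    pass


def _gauss(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _unit_windowed_area(center: float, sigma: float,
                        band: BandDefinition, grid: np.ndarray) -> float:
    """Windowed endpoint-corrected area of a unit-amplitude Gaussian."""
    m = band.slice(grid)
    return _windowed_area(grid[m], _gauss(grid[m], 1.0, center, sigma))


def generate_spectrum(truth: tuple[float, float, float], noise: float = 0.0,
                      seed: int = 0, *,
                      base_area: float = 1000.0,
                      baseline_coeffs: tuple[float, ...] | None = None,
                      n_spikes: int = 0, spike_amplitude: float = 50.0,
                      bands: dict[str, BandDefinition] | None = None,
                      grid: np.ndarray | None = None,
                      meta: dict | None = None) -> RamanSpectrum:
    """Synthesize a bone Raman spectrum realizing (mmr, carbonate, fwhm).

    truth : (mmr, carbonate_substitution, fwhm_phosphate cm^-1); the
        Amide I band area is anchored at ``base_area`` (counts·cm^-1), the
        phosphate area is ``mmr * base_area`` and the carbonate area
        ``carbonate * mmr * base_area``, all under the analyzer's windowed
        area definition, so the matrix band stays fixed while mineral
        truth scales the mineral bands.
    noise : multiplicative Gaussian noise fraction on the total signal.
    baseline_coeffs : polynomial coefficients (low order first) in the
        scaled variable u = (w - 800)/1000; None selects a gentle cubic.
    n_spikes : cosmic-ray spikes of ``spike_amplitude`` times the local
        intensity scale injected at random grid points.
    """
    mmr, carbonate, fwhm = truth
    if mmr <= 0 or carbonate <= 0:
        raise ConfigError("mmr and carbonate truth must be positive")
    if not 5.0 < fwhm < 60.0:
        raise ConfigError(f"phosphate fwhm {fwhm} outside the supported (5, 60)")
    grid = GRID if grid is None else np.asarray(grid, dtype=float)
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    rng = np.random.default_rng(seed)

    areas = {"nu1_phosphate": mmr * base_area,
             "nu1_carbonate": carbonate * mmr * base_area,
             "amide_I": base_area}
    sigmas = {"nu1_phosphate": fwhm / FWHM_FACTOR,
              "nu1_carbonate": FIXED_FWHM["nu1_carbonate"] / FWHM_FACTOR,
              "amide_I": FIXED_FWHM["amide_I"] / FWHM_FACTOR}
    signal = np.zeros_like(grid)
    amplitudes = {}
    for name, area in areas.items():
        center = BAND_CENTERS[name]
        unit = _unit_windowed_area(center, sigmas[name], bands[name], grid)
        if unit <= 0:
            raise ConfigError(f"band {name} does not fit its window")
        amplitudes[name] = area / unit
        signal += _gauss(grid, amplitudes[name], center, sigmas[name])

    if baseline_coeffs is None:
        # fluorescence background scales with the organic matrix (the main
        # autofluorescence source), not with the mineral bands: the default
        # is a gentle cubic at roughly twice the Amide I band height, the
        # level of a photobleached 785-nm bone measurement
        a = amplitudes["amide_I"] or 1.0
        baseline_coeffs = (2.0 * a, 0.4 * a, -0.3 * a, 0.15 * a)
    u = (grid - grid[0]) / 1000.0
    baseline = np.polynomial.polynomial.polyval(u, baseline_coeffs)
    if np.any(signal + baseline < 0):
        raise ConfigError("requested truth/baseline yields negative intensities")

    y = signal + baseline
    if noise > 0:
        y = y * (1.0 + noise * rng.standard_normal(grid.size))
    if n_spikes > 0:
        pos = rng.choice(np.arange(5, grid.size - 5), size=n_spikes,
                         replace=False)
        y[pos] += spike_amplitude * np.median(np.abs(y))
    y = np.clip(y, 0.0, None)
    return RamanSpectrum(wavenumber=grid, intensity=y,
                         state=SpectrumState.RAW, meta=dict(meta or {}))


def generate_indent_curve(Er_true: float, H_true: float,
                          probe: ProbeGeometry | None = None,
                          noise: float = 0.0, seed: int = 0, *,
                          Pmax_uN: float = 1000.0, m_exponent: float = 1.5,
                          t_load_s: float = 10.0, t_hold_s: float = 45.0,
                          t_unload_s: float = 10.0, sample_hz: float = 100.0,
                          meta: dict | None = None) -> IndentCurve:
    """Synthesize a load-controlled indent whose Oliver-Pharr analysis
    returns (Er_true [GPa], H_true [GPa]) in the noiseless limit.

    The target contact area follows from hardness (A = Pmax / H), the
    target stiffness from the reduced-modulus relation inverted, the
    maximum depth from the contact-depth correction, and the unloading
    power law (exponent ``m_exponent``) is anchored to pass through
    (h_max, Pmax) with slope S there.  ``noise`` adds Gaussian
    displacement noise of that fraction of the maximum depth.
    """
    probe = probe or ProbeGeometry()
    if Er_true <= 0 or H_true <= 0:
        raise ConfigError("material properties must be positive")
    R = probe.radius_um
    er_u = Er_true * MPA_PER_GPA       # μN/μm²
    h_u = H_true * MPA_PER_GPA

    A = Pmax_uN / h_u                  # μm²
    if A / math.pi >= R ** 2:
        raise ConfigError(
            f"hardness {H_true} GPa needs contact area {A:.2f} μm², beyond "
            f"the {R}-μm probe's hemispherical capacity")
    hc = R - math.sqrt(R ** 2 - A / math.pi)          # μm
    S_um = probe.beta * er_u * 2.0 / math.sqrt(math.pi) * math.sqrt(A)
    hmax = hc + probe.epsilon * Pmax_uN / S_um        # μm
    h_f = hmax - m_exponent * Pmax_uN / S_um
    if h_f < 0:
        raise ConfigError("inconsistent (Er, H): negative residual depth")
    alpha = Pmax_uN / (hmax - h_f) ** m_exponent

    h_hertz = (3.0 * Pmax_uN / (4.0 * er_u * math.sqrt(R))) ** (2.0 / 3.0)
    if h_hertz >= 2.0 * R:
        raise ConfigError("Hertzian depth at peak load exceeds probe diameter")

    dt = 1.0 / sample_hz
    t_load = np.arange(0.0, t_load_s, dt)
    t_hold = np.arange(t_load_s, t_load_s + t_hold_s, dt)
    t_unld = np.arange(t_load_s + t_hold_s,
                       t_load_s + t_hold_s + t_unload_s + dt / 2, dt)

    p_load = Pmax_uN * t_load / t_load_s
    h_load = (3.0 * p_load / (4.0 * er_u * math.sqrt(R))) ** (2.0 / 3.0)

    # logarithmic creep bridging the elastic Hertz depth to hmax
    tau = t_hold_s / 9.0
    frac = np.log1p((t_hold - t_load_s) / tau) / np.log1p(t_hold_s / tau)
    h_hold = h_hertz + (hmax - h_hertz) * frac
    p_hold = np.full_like(t_hold, Pmax_uN)

    p_unld = Pmax_uN * (1.0 - (t_unld - t_unld[0]) / t_unload_s)
    p_unld = np.clip(p_unld, 0.0, None)
    h_unld = h_f + (p_unld / alpha) ** (1.0 / m_exponent)

    t = np.concatenate([t_load, t_hold, t_unld])
    p = np.concatenate([p_load, p_hold, p_unld])
    h = np.concatenate([h_load, h_hold, h_unld]) * NM_PER_UM
    if noise > 0:
        rng = np.random.default_rng(seed)
        h = h + noise * hmax * NM_PER_UM * rng.standard_normal(t.size)
    return IndentCurve(time_s=t, load_uN=p, disp_nm=h, meta=dict(meta or {}))


def generate_bse_image(ca_mean: float, ca_sd: float,
                       cal: GrayCalibration | None = None,
                       shape: tuple[int, int] = (360, 480), seed: int = 0, *,
                       roi_band: tuple[float, float] = (0.2, 0.8),
                       max_clip_fraction: float = 0.001,
                       meta: dict | None = None) -> BSEImage:
    """Synthesize a calibrated BSE image of a Gaussian calcium field.

    The ROI mask marks a horizontal band of rows (fractions ``roi_band``
    of the image height) standing in for the fluorochrome-bounded newly
    formed bone; pixels outside the band are set near the carbon level.
    A configuration raising more than ``max_clip_fraction`` of pixels out
    of the 8-bit range is rejected.
    """
    cal = cal or GrayCalibration()
    rng = np.random.default_rng(seed)
    ca = rng.normal(ca_mean, ca_sd, size=shape) if ca_sd > 0 \
        else np.full(shape, float(ca_mean))
    gray = np.rint(cal.calcium_to_gray(ca))
    clipped = np.mean((gray < 0) | (gray > 255))
    if clipped > max_clip_fraction:
        raise ConfigError(
            f"{clipped:.2%} of pixels clip outside 8-bit range for "
            f"ca_mean={ca_mean}, ca_sd={ca_sd}")
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    rows = np.arange(shape[0])
    lo, hi = int(roi_band[0] * shape[0]), int(roi_band[1] * shape[0])
    mask = np.zeros(shape, dtype=bool)
    mask[lo:hi, :] = True
    background = int(round(cal.gray_carbon))
    gray[~mask] = background
    return BSEImage(pixels=gray, roi_mask=mask, meta=dict(meta or {}))


# --------------------------------------------------------------------------
# study-level design


PARAMS = ("mmr", "carbonate", "crystallinity", "Er", "H")


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth means and SDs of one animal group.

    ``means``/``sds`` cover mmr, carbonate, crystallinity (cm; reciprocal
    phosphate fwhm), Er and H (GPa) and ca_mean (wt%).
    ``perilacunar_offsets[param][distance]`` shifts the perilacunar mean
    of a parameter at one lacunar distance (additive, same units) —
    spatial effects are piecewise per distance, not parametric in it.
    """

    means: dict[str, float]
    sds: dict[str, float]
    perilacunar_offsets: dict[str, dict[float, float]] = field(
        default_factory=dict)

    def __post_init__(self):
        for p in PARAMS + ("ca_mean",):
            if p not in self.means or p not in self.sds:
                raise ConfigError(f"group truth missing parameter {p!r}")
            if self.sds[p] < 0:
                raise ConfigError(f"negative SD for {p!r}")

    def mean_at(self, param: str, distance: float | None) -> float:
        base = self.means[param]
        if distance is None:
            return base
        return base + self.perilacunar_offsets.get(param, {}).get(
            float(distance), 0.0)


def _default_groups() -> dict[str, GroupTruth]:
    """Defaults emulate the study's qualitative findings on realistic
    hydrated rat cortical bone values: CKD lowers carbonate substitution
    and reduced modulus; calcimimetic treatment (CKD_KP) keeps carbonate
    low, raises crystallinity, restores periosteal modulus, and raises
    perilacunar MMR/Er/H toward control in a distance-dependent way."""
    ctrl = dict(mmr=2.5, carbonate=0.17, crystallinity=1 / 17.0,
                Er=20.0, H=0.7, ca_mean=22.5)
    sds = dict(mmr=0.25, carbonate=0.015, crystallinity=0.002,
               Er=2.5, H=0.1, ca_mean=0.8)
    ckd = dict(ctrl, carbonate=0.155, Er=16.25, H=0.65)
    kp = dict(ctrl, carbonate=0.155, crystallinity=1 / 17.0 + 0.002,
              Er=19.0, H=0.7)
    kp_off = {"mmr": {1.0: 0.3, 3.0: 0.3, 5.0: 0.3, 7.0: 0.0},
              "Er": {1.0: -1.0, 3.0: 0.0, 5.0: 0.0, 7.0: 0.0}}
    ckd_off = {"H": {1.0: -0.05, 3.0: -0.05, 5.0: -0.05, 7.0: 0.0}}
    return {
        "CTRL": GroupTruth(means=ctrl, sds=dict(sds)),
        "CKD": GroupTruth(means=ckd, sds=dict(sds),
                          perilacunar_offsets=ckd_off),
        "CKD_KP": GroupTruth(means=kp, sds=dict(sds),
                             perilacunar_offsets=kp_off),
    }


def default_group_truths() -> dict[str, GroupTruth]:
    """The default three-group ground truth (see ``_default_groups``)."""
    return _default_groups()


def null_group_truths() -> dict[str, GroupTruth]:
    """All three groups share the CTRL truth: zero effects everywhere.

    Used for soundness checks — any significant shift the pipeline calls
    on a null study is a false positive.
    """
    ctrl = _default_groups()["CTRL"]
    return {name: GroupTruth(means=dict(ctrl.means), sds=dict(ctrl.sds))
            for name in ("CTRL", "CKD", "CKD_KP")}


@dataclass(frozen=True)
class StudyConfig:
    """Design of the three-group colocalized study.

    The default counts reproduce the reference design: 12 animals per
    group measured at 8 periosteal points each, and a 6-animal subset per
    group measured around 6 lacunae in 4 directions at 1/3/5/7 μm from
    the lacunar wall — 6 x 6 x 4 = 144 perilacunar points per group per
    distance.
    """

    groups: dict[str, GroupTruth] = field(default_factory=_default_groups)
    n_periosteal_animals: int = 12
    n_perilacunar_animals: int = 6
    periosteal_points: int = 8
    lacunae_per_animal: int = 6
    directions: int = 4
    distances_um: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    raman_noise: float = 0.01
    indent_noise: float = 0.005
    ca_within_sd: float = 2.0
    accumulations: int = 8
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.distances_um) or \
                list(self.distances_um) != sorted(self.distances_um):
            raise ConfigError("distances must be positive and ascending")

    @property
    def perilacunar_points_per_group_per_distance(self) -> int:
        return self.n_perilacunar_animals * self.lacunae_per_animal * \
            self.directions


@dataclass(frozen=True)
class StudyTables:
    """Measurement-level ground-truth parameter tables of one study draw."""

    periosteal: pd.DataFrame   # group, animal, point, param columns
    perilacunar: pd.DataFrame  # group, animal, lacuna, direction, distance_um, params
    qbei: pd.DataFrame         # group, animal, ca_mean (image-level target)


def _draw(rng: np.random.Generator, mean: float, sd: float, n: int,
          lo: float | None = None, hi: float | None = None) -> np.ndarray:
    v = rng.normal(mean, sd, size=n)
    return np.clip(v, lo, hi)


#: physically measurable ranges for sampled measurement targets.  A
#: spherical probe driven to Pmax cannot register a hardness below
#: Pmax / (pi R^2), and the spectrum model supports phosphate fwhm in
#: (5, 60) cm^-1, i.e. crystallinity in (1/60, 1/5) cm.  Tail draws are
#: truncated to these ranges (a fraction of a percent at the defaults).
def _param_bounds(probe: ProbeGeometry, pmax_uN: float) -> dict:
    h_floor = 1.1 * pmax_uN / (math.pi * probe.radius_um ** 2) / MPA_PER_GPA
    return {"mmr": (0.05, None), "carbonate": (0.005, None),
            "crystallinity": (1.0 / 55.0, 1.0 / 6.0),
            "Er": (1.0, None), "H": (h_floor, None),
            "ca_mean": (1.0, None)}


def generate_study_tables(cfg: StudyConfig) -> StudyTables:
    """Sample per-measurement ground-truth parameter values for a study.

    Values are drawn independently per measurement from the group (and,
    for perilacunar points, distance-offset) means — the pooled-points
    view that the distribution-shift layer analyzes.  Raw-signal synthesis
    adds instrument noise on top of these targets but no group effect.
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = _param_bounds(ProbeGeometry(), 1000.0)
    peri_rows, lac_rows, qbei_rows = [], [], []
    for group in cfg.groups:
        truth = cfg.groups[group]
        for a in range(cfg.n_periosteal_animals):
            for pt in range(cfg.periosteal_points):
                row = {"group": group, "animal": f"{group}_{a:02d}",
                       "point": pt}
                for p in PARAMS:
                    row[p] = float(_draw(rng, truth.means[p], truth.sds[p],
                                         1, *bounds[p])[0])
                peri_rows.append(row)
        for a in range(cfg.n_perilacunar_animals):
            animal = f"{group}_L{a:02d}"
            for lac in range(cfg.lacunae_per_animal):
                for d in range(cfg.directions):
                    for dist in cfg.distances_um:
                        row = {"group": group, "animal": animal,
                               "lacuna": lac, "direction": d,
                               "distance_um": float(dist)}
                        for p in PARAMS:
                            row[p] = float(_draw(
                                rng, truth.mean_at(p, dist), truth.sds[p],
                                1, *bounds[p])[0])
                        lac_rows.append(row)
            qbei_rows.append({
                "group": group, "animal": animal,
                "ca_mean": float(_draw(rng, truth.means["ca_mean"],
                                       truth.sds["ca_mean"], 1,
                                       *bounds["ca_mean"])[0])})
    return StudyTables(periosteal=pd.DataFrame(peri_rows),
                       perilacunar=pd.DataFrame(lac_rows),
                       qbei=pd.DataFrame(qbei_rows))


def generate_study(cfg: StudyConfig, out_dir: str | Path, *,
                   image_shape: tuple[int, int] = (360, 480),
                   ) -> tuple[pd.DataFrame, StudyTables]:
    """Write a full raw synthetic study to disk; returns (manifest, truth).

    Layout: ``spectra/*.txt`` (multi-accumulation two-column text),
    ``indents/*.tsv``, ``images/*.png`` with ``*_mask.png``,
    ``manifest.csv`` and ``truth.csv`` (the measurement-level ground truth
    for recovery scoring; the default group means are modelling
    conventions, not measured study values).
    """
    from .io import write_bse_image, write_indent_file, write_spectrum_file

    out = Path(out_dir)
    for sub in ("spectra", "indents", "images"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    tables = generate_study_tables(cfg)
    cal = GrayCalibration()
    seq = np.random.SeedSequence(cfg.seed)
    manifest = []

    def spectrum_seeds(n):
        return [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq.spawn(n)]

    all_points = pd.concat([
        tables.periosteal.assign(region="periosteal", distance_um=np.nan,
                                 lacuna=-1, direction=-1),
        tables.perilacunar.assign(region="perilacunar", point=-1),
    ], ignore_index=True)
    seeds = spectrum_seeds(2 * len(all_points) + len(tables.qbei))

    for i, row in all_points.iterrows():
        tag = (f"{row.group}_{row.animal}_{row.region[:4]}_"
               f"{int(row.point) if row.region == 'periosteal' else int(row.lacuna)}_"
               f"{int(row.direction)}_"
               f"{'' if np.isnan(row.distance_um) else int(row.distance_um)}"
               ).replace("-1", "x")
        fwhm = 1.0 / row.crystallinity
        accs = [generate_spectrum((row.mmr, row.carbonate, fwhm),
                                  noise=cfg.raman_noise,
                                  seed=seeds[2 * i] + k)
                for k in range(cfg.accumulations)]
        spath = out / "spectra" / f"{tag}.txt"
        write_spectrum_file(spath, accs)
        manifest.append({"path": str(spath.relative_to(out)),
                         "kind": "spectrum", "sample": row.animal,
                         "group": row.group, "region": row.region,
                         "distance_um": row.distance_um,
                         "calibration": ""})
        curve = generate_indent_curve(row.Er, row.H, noise=cfg.indent_noise,
                                      seed=seeds[2 * i + 1])
        cpath = out / "indents" / f"{tag}.tsv"
        write_indent_file(cpath, curve)
        manifest.append({"path": str(cpath.relative_to(out)),
                         "kind": "indent", "sample": row.animal,
                         "group": row.group, "region": row.region,
                         "distance_um": row.distance_um,
                         "calibration": ""})

    for j, row in tables.qbei.iterrows():
        img = generate_bse_image(row.ca_mean, cfg.ca_within_sd, cal,
                                 shape=image_shape,
                                 seed=seeds[2 * len(all_points) + j])
        ipath = out / "images" / f"{row.animal}.png"
        write_bse_image(ipath, img)
        manifest.append({"path": str(ipath.relative_to(out)),
                         "kind": "image", "sample": row.animal,
                         "group": row.group, "region": "periosteal",
                         "distance_um": np.nan,
                         "calibration": "carbon25_aluminum225"})

    mdf = pd.DataFrame(manifest)
    mdf.to_csv(out / "manifest.csv", index=False)
    truth = all_points.assign(fwhm=1.0 / all_points.crystallinity)
    truth.to_csv(out / "truth.csv", index=False)
    tables.qbei.to_csv(out / "truth_qbei.csv", index=False)
    return mdf, tables
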