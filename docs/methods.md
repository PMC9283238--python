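# Methods

This note records the models, conventions, numerical choices and known
limitations behind `osteoquant`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Raman processing

**Model.** A bone Raman spectrum on an 800–1800 cm⁻¹ grid carries three
analysis bands — ν1-PO4 at ~959 cm⁻¹ (default window 930–980), ν1-CO3 at
~1070 cm⁻¹ (1050–1100) and Amide I at ~1665 cm⁻¹ (1620–1700) — on top of
a smooth fluorescence background.  The windows are the standard
bone-Raman literature choices and are configurable.

**Processing chain** (states enforce forward-only order):

1. *Accumulation averaging.*  Repeated accumulations of one measurement
   are averaged pointwise on their shared grid before any correction —
   the same order as the instrument protocol (eight accumulations in the
   reference design).
2. *Baseline.*  An 11th-order polynomial is least-squares fitted on a
   [−1, 1]-scaled wavenumber domain (raw wavenumbers at order 11 are
   numerically hopeless) with iterative peak exclusion: points more than
   2 robust standard deviations (1.4826·MAD, floored at 10⁻⁹ of the
   intensity range so noiseless input cannot degenerate) above the fit
   are dropped and the fit repeated, up to 20 passes or convergence at
   10⁻⁴ relative change.  Direct least squares through the bands would
   pull the background up into them; one-sided exclusion recovers the
   background they sit on.
3. *Cosmic-ray removal.*  Candidate points have |second difference| >
   8 × median |second difference|.  A one-point spike perturbs the second
   difference at three consecutive positions and a two-point spike at
   four, so only candidate runs of ≤ 4 positions are treated as spikes;
   genuine bands (≥ 3 points wide) produce much longer curvature runs and
   pass untouched.  Within a candidate run, only points deviating
   strongly from the chord across the run are replaced by linear
   interpolation, leaving spike neighbours bit-identical.  The operation
   is idempotent.
4. *Smoothing.*  Standard Savitzky–Golay (window 11, polyorder 4),
   behind a named strategy switch: the notion of a "modified" SG filter
   with likelihood-based feature preservation is not a single
   well-defined algorithm, so the package ships the standard filter and
   keeps the slot open.

**Band areas — the operational definition.**  A band area is the
trapezoidal integral of the smoothed intensity inside the band window
minus a linear background chord.  Each chord endpoint is anchored on the
mean of up to 12 outermost window points (capped at a quarter of the
window per side).  Two reasons: a chord through *single* endpoint samples
projects that sample's noise across the whole window width — for weak
bands (carbonate at low substitution over a realistic background) this
chord noise, not the integration noise, dominates the area error; and for
a locally linear background the anchored chord is exact, so linear
residual background still cancels.  The synthetic generator realizes
ground-truth areas under this *same* definition (it rescales each
Gaussian's amplitude so its windowed, chord-corrected area equals the
requested truth), which makes noiseless generator → analyzer roundtrips
exact by construction rather than approximately true.  The alternative —
defining truth as the analytic Gaussian integral — is irreconcilable with
sub-percent roundtrips for broad bands in finite windows.

**Phosphate Gaussian fit.**  Crystallinity is 1/FWHM of a Gaussian
fitted in the phosphate window.  The fit model is Gaussian **plus a
linear term**, so residual background level/tilt cannot bias the fitted
width (a pure-Gaussian fit after chord subtraction showed a systematic
−1% width bias).  Initialisation is deterministic: amplitude and center
at the window maximum, σ at a sixth of the window span; `crystallinity ·
fwhm = 1` holds exactly by construction.

**Error budget at 1% multiplicative noise.**  Multiplicative noise
scales with *total* intensity, so the fluorescence level under a weak
band sets its noise floor: the area error of the windowed estimator is
≈ ν·B·√(W + W²/(2k)) for background level B, window width W points and
anchor size k.  With the default background (a gentle cubic at about
twice the Amide I band height — the level of a photobleached 785-nm
measurement, anchored to the organic matrix because the matrix, not the
mineral, is the main autofluorescence source) and the eight-accumulation
protocol, the weakest cell of the recovery grid (MMR 1, carbonate 0.05)
lands near 4% relative RMSE; backgrounds several times larger make that
cell noise-limited beyond 5% no matter the estimator, which is worth
remembering when judging weak carbonate bands in real data.

**Per-specimen averaging** happens on computed parameters (not on
spectra) across a specimen's periosteal points, one value per parameter
per specimen.  The averaged summary keeps `crystallinity` and `fwhm`
independently averaged, so their product is no longer exactly 1 — the
reciprocal identity is a per-spectrum property.

## Nanoindentation (Oliver–Pharr)

**Forward model (generator).**  Loading is Hertzian spherical contact
`P = (4/3) E_r √R h^{3/2}` in load control up to 1000 μN; the 45-s hold
creeps logarithmically from the elastic Hertz depth to the target
maximum depth; unloading follows `P = α (h − h_f)^m` (default m = 1.5).
Given targets (E_r, H), the generator solves the analysis equations
backwards: `A = P_max/H`, `h_c` from the spherical area relation, `S`
from the reduced-modulus relation, `h_max = h_c + ε P_max/S`, and
anchors the power law through `(h_max, P_max)` with slope `S`.  The
Oliver–Pharr chain therefore recovers the targets exactly (to ~10⁻¹²)
on noiseless curves — a truly closed roundtrip oracle.  Sampling is
100 Hz, the order of a commercial nanoindenter's acquisition rate;
displacement noise is Gaussian with σ = noise·h_max.

**Segmentation.**  The hold is the region where the load sits within a
tolerance (default 1%) of the plateau level.  Robustness: thresholding
runs on a 9-sample running median (a running median of a monotone ramp
returns the center sample, so clean profiles are untouched); the plateau
level is the median of near-peak samples, not the noisy maximum; mask
gaps up to 15 samples are bridged; and both corners are refined to the
intersection of a line fitted to the adjacent ramp (using only samples
clearly below the plateau) with the plateau level — exact for
trapezoidal profiles, within ~2 samples at 1% load noise.

**Stiffness.**  The power law is fitted to unloading samples with
`0.40·P_max ≤ P ≤ 0.95·P_max`, honoring the 95%–40% range convention,
and `S = dP/dh` is evaluated at maximum depth (a secant strategy over
the same range is available as an option).  Two numerical choices
matter:

- the regression is cast as `h(P)`, not `P(h)`: in load control the load
  is the clean programmed variable and measurement noise lives in the
  displacement; regressing the noisy variable on the clean one avoids
  the classic errors-in-variables attenuation of the slope (measured at
  ~7% bias on E_r the other way around);
- the parametrization is `(h_f, h_peak, m)` with
  `h = h_f + (h_peak − h_f)(P/P_max)^{1/m}`, which decouples scale from
  exponent (the raw `(α, m)` pair is so correlated the fit stalls), and
  `h_max` is taken from the fitted curve at `P_max`, removing
  single-sample read noise; on noiseless data it equals the measured
  value.  A fitted exponent outside [1, 3] sets a warning flag.

`H·A = P_max` holds exactly for every result because H is defined as
that quotient.  Unit conventions: load μN, displacement nm, area μm²,
moduli GPa (1 μN/μm² = 1 MPa).  No thermal-drift correction is applied
(none is modelled); creep is excluded from the fit by starting at the
first post-hold sample.

## qBEI and the BMDD

Gray → calcium is affine through two anchors: the carbon standard gray
level ↔ 0 wt% Ca and the aluminum standard gray level ↔ 39.86 wt% Ca
(the calcium mass fraction of stoichiometric hydroxyapatite, the
conventional upper anchor).  Both anchors are conventions, overridable
in configuration; all recovery tests use the same mapping for synthesis
and analysis, so conclusions do not depend on the anchors being
physically exact.  A measurement session is accepted only when both
standards sit within ±1 gray of their targets.

The BMDD histogram has one bin per 8-bit gray step mapped through the
calibration (no re-binning — resolution-faithful and deterministic).
`Ca_Mean` is the frequency-weighted mean of the raw histogram.
`Ca_Peak` and the FWHM (`Ca_Width`, by linear interpolation at half
maximum) are evaluated on a 3-bin moving average so single-bin counting
noise cannot masquerade as the mode; the smoothing widens a Gaussian's
FWHM by a factor `√(1 + (w²−1)Δ²/(12σ²))` ≈ 1.003 at the default image
parameters, far inside the test tolerances.  An ROI collapsed onto one
gray level is flagged degenerate with width reported as one bin.

## Group statistics

Periosteal layer: per-specimen values (≥ 3 per group) pass a
Shapiro–Wilk gate per group at α = 0.05; if all groups pass, one-way
ANOVA with Tukey HSD post hoc (pairwise p-values only when the omnibus
rejects), otherwise Kruskal–Wallis (no post hoc, matching the reference
analysis).  Constant groups route nonparametric with a degeneracy flag.

Perilacunar layer: pooled distributions are compared pairwise with the
two-sample KS test (asymptotic p) and the two-sample Anderson–Darling
test (rank form, midrank ties).  The AD p-value uses the standard
quadratic interpolation of log-significance against the tabulated
critical values, *without* the usual clipping to [0.001, 0.25] — the
extrapolated value is clipped only into (0, 1], so clearly
non-separated samples report a large p instead of an artificial 0.25.
In-range values are identical to the clipped convention.  A seeded
permutation p-value (≥ 2000 resamples) is available as a cross-check.

A shift call at Bonferroni level `α = 0.05/m` (m = 3 group pairs)
requires **both** tests to reject — a conservative conjunction whose
family-wise false-positive rate is below the nominal level by
construction; an either-test rule is available behind a switch.
Direction goes to the sample with the larger median ("right-shifted");
a median tie with significance reports no direction plus a tie flag.

## Synthetic studies

`StudyConfig` defaults reproduce the reference design: 3 groups × 12
animals × 8 periosteal points, and a 6-animal subset per group × 6
lacunae × 4 directions × distances {1, 3, 5, 7} μm = 144 perilacunar
points per group per distance; 8 Raman accumulations per point; 1%
Raman noise and 0.5% displacement noise.

Group ground truths are modelling conventions on realistic hydrated rat
cortical bone values (CTRL: MMR 2.5, carbonate 0.17, crystallinity
1/17 cm, E_r 20 GPa, H 0.7 GPa, Ca_Mean 22.5 wt%), with effect
directions following the qualitative biology being emulated: CKD lowers
carbonate substitution and reduced modulus; calcimimetic treatment keeps
carbonate low, raises crystallinity, restores periosteal modulus and
raises perilacunar MMR/E_r/H toward control with piecewise per-distance
offsets (spatial effects are per-distance constants, not parametric in
distance).  Magnitudes are free configuration parameters of order one
SD.  `truth.csv` labels these as conventions.

Sampled per-measurement targets are truncated to physically measurable
ranges (hardness at the spherical probe's `P_max/(πR²)` floor,
crystallinity inside the spectral model's FWHM domain) — a < 0.1%
tail guard at the default SDs.

Perilacunar points are drawn independently per measurement around the
group/distance mean — the exchangeable pooled-points view that the
distribution-shift layer analyzes.  Real osteocyte data are clustered
within animals and lacunae; pooling clustered data makes rank tests
anticonservative, so passing null-soundness here says nothing about
animal-level clustering in real studies.  That (together with pure
Gaussian band shapes, noise-free load channels, perfectly affine qBEI
response, and absence of drift, charging or registration error) bounds
what green tests demonstrate about real data.

**Two generation levels.**  `generate_study` writes raw signals to disk
(spectra, indent curves, PNG images + masks, manifest, truth tables);
`generate_study_tables` produces the measurement-level parameter tables
directly.  Statistical study-scale checks (null soundness over 50 study
draws, design counts) run on the tables level with the full design;
the raw path — roughly 2000 spectra and 2000 curves per draw — is
exercised end-to-end at reduced counts in the pipeline tests.  This is a
deliberate scaling choice: the tables level *is* the distribution the
raw path estimates, with measurement noise added on top and no group
effect, so the null calibration of the shift layer is the same.

## Determinism

Every generator takes an explicit seed; study generation derives child
seeds from the master seed via `SeedSequence.spawn`, so studies are
bit-reproducible.  The pipeline itself is deterministic: rerunning on
identical inputs produces byte-identical CSVs, and the run log echoes
every decided default for provenance.
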