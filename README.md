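# osteoquant

Colocalized bone-tissue quality analysis: Raman-derived matrix
composition, Oliver-Pharr nanoindentation mechanics, calibrated
backscattered-electron (qBEI) bone mineral density distributions, and
the group/distribution statistics used to compare treatment groups —
plus a synthetic-data generator with known ground truth for every layer.

## Who this is for

Studies of bone material quality (for example in chronic kidney
disease–mineral and bone disorder, where elevated PTH remodels bone at
the tissue level) measure the *same microscopic locations* with Raman
spectroscopy and nanoindentation — on newly formed periosteal bone
between fluorochrome labels, and in the perilacunar matrix at fixed
distances (1, 3, 5, 7 μm) from osteocyte lacunae — and image the same
sections with calibrated backscatter electron microscopy.  `osteoquant`
implements that entire measurement-to-statistics chain as a tested,
scriptable pipeline, and ships generators that synthesize spectra,
load–displacement curves, BSE images and whole three-group studies with
known truth, so every stage can be validated by parameter recovery.

## The quantities it computes

**Raman composition** (after baseline correction with an 11th-order
polynomial fitted with iterative peak exclusion, cosmic-ray removal, and
Savitzky–Golay smoothing):

- mineral-to-matrix ratio `MMR = A(ν1-PO4) / A(Amide I)`
- type B carbonate substitution `A(ν1-CO3) / A(ν1-PO4)`
- crystallinity `1 / FWHM` of a Gaussian fitted to the ν1-PO4 band

where `A(·)` is the band area: the trapezoidal integral inside the band
window minus a linear background chord anchored on the window's endpoint
neighborhoods.

**Nanoindentation** (load-controlled spherical indent, 1000 μN peak,
45 s hold): the Oliver–Pharr power law `P = α (h − h_f)^m` is fitted to
the 95%–40% region of the unloading branch, the stiffness
`S = dP/dh` is evaluated at maximum depth, and

```
E_r = (1/β) (√π / 2) S / √A          H = P_max / A
A(h_c) = π (2 R h_c − h_c²)          h_c = h_max − ε P_max / S
```

with `R = 1.03 μm`, `β = 1`, `ε = 0.75` by default.

**qBEI / BMDD**: 8-bit gray levels calibrated against carbon (gray 25 ±
1 ↔ 0 wt% Ca) and aluminum (gray 225 ± 1 ↔ 39.86 wt% Ca) standards map
each ROI pixel to calcium content; the bone mineral density distribution
is summarized by `Ca_Mean`, `Ca_Peak`, and `Ca_Width` (FWHM).

**Statistics**: periosteal per-specimen values go through a
Shapiro–Wilk normality gate into one-way ANOVA + Tukey HSD (or
Kruskal–Wallis); pooled perilacunar distributions (144 points per group
per distance in the reference design) are compared pairwise with
two-sample Kolmogorov–Smirnov *and* Anderson–Darling tests at the
Bonferroni level `α = 0.05/3 = 0.0167`, a pair being called
"right-shifted" toward the group with the larger median only when both
tests reject.

## Worked example

```python
from osteoquant import (GrayCalibration, ProbeGeometry, analyze_indent,
                        average_accumulations, compute_bmdd, process_spectrum)
from osteoquant.simulate import (generate_bse_image, generate_indent_curve,
                                 generate_spectrum)

# Raman: 8 accumulations at 1% noise, truth (MMR 2.5, carbonate 0.15, fwhm 17)
accs = [generate_spectrum((2.5, 0.15, 17.0), noise=0.01, seed=k) for k in range(8)]
params = process_spectrum(average_accumulations(accs))
print(f"MMR            {params.mmr:.3f}")
print(f"carbonate/PO4  {params.carbonate_substitution:.4f}")
print(f"crystallinity  {params.crystallinity:.5f} cm  (fwhm {params.fwhm_phosphate:.2f} cm^-1)")

# nanoindentation: truth (Er 18 GPa, H 0.65 GPa), 0.5% displacement noise
curve = generate_indent_curve(18.0, 0.65, noise=0.005, seed=0)
res = analyze_indent(curve, ProbeGeometry())
print(f"Er   {res.Er_GPa:.2f} GPa   H {res.H_GPa:.3f} GPa")

# qBEI: Gaussian calcium field (22 ± 2 wt%)
cal = GrayCalibration()
img = generate_bse_image(22.0, 2.0, cal, shape=(400, 400), seed=0)
m = compute_bmdd(img, cal)
print(f"CaMean {m.ca_mean:.2f}  CaPeak {m.ca_peak:.2f}  CaWidth {m.ca_width:.2f} wt%")
```

prints

```
MMR            2.483
carbonate/PO4  0.1498
crystallinity  0.05866 cm  (fwhm 17.05 cm^-1)
Er   19.17 GPa   H 0.647 GPa
CaMean 22.00  CaPeak 21.92  CaWidth 4.68 wt%
```

Each number sits within the expected recovery tolerance of its ground
truth: composition within a few tenths of a percent to a few percent
(noise-limited), mechanics within ~6% at this noise level (median error
~2%), and the BMDD within 0.1 wt% of the 22 wt% mean with the Gaussian
FWHM `2 √(2 ln 2) · 2 ≈ 4.71` wt%.

The same chain runs from the shell on an on-disk study:

```sh
osteoquant simulate --out study --seed 1
osteoquant run-all --manifest study/manifest.csv --out study/results
```

which writes `raman.csv`, `indent.csv`, `bmdd.csv`,
`periosteal_tests.csv`, `perilacunar_shifts.csv` and an auditable
`run.log` of every decided default.

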