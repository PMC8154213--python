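# Methods

This note records the models behind `spotscreen`, the parameter choices
that matter, and what the synthetic test harness does and does not
demonstrate about real instrument data.

## Ion chemistry

Isotope masses and abundances are IUPAC 2021 representative values for the
supported element set (C, H, N, O, P, S, F, Cl, Br), embedded in
`chem.ISOTOPES`. An isotopologue envelope is the convolution of per-element
multinomial distributions, computed by binary-exponentiation convolution of
the single-atom distribution. Peaks closer than **0.01 Da** are merged
(abundance-weighted mass); this is far below the 0.2 Da channel window, so
a merged peak can never straddle a channel edge. Envelopes are truncated at
**1e-6** of total abundance by default and renormalized to sum to 1.

Only singly charged ±H adducts are supported. Ion masses are atom-based:
[M+H]⁺ adds one H atom and subtracts the electron mass. For internal
consistency the package's `PROTON_MASS` is defined as m(¹H) − mₑ (within
1.5e-8 Da of the CODATA proton mass), which makes the identity
mz([M+H]⁺) − mz([M−H]⁻) = 2·PROTON_MASS exact rather than approximate.

Fine isotope structure is deliberately not resolved: a ¹³C₂ and an ¹⁸O
substitution 0.006 Da apart merge into one centroid, which is the correct
granularity for unit-resolution channel extraction. The deoxyfluorinated
hexose-phosphate kinase product computes to [M−H]⁻ = 261.018; screening
reports sometimes quote this channel as "261.1 Da" (nominal-mass rounding);
the computed exact value is what the package uses.

## Grid geometry and channel assignment

Coordinates are millimetres, origin at the membrane top-left, x right / y
down (raster-scan convention); pixels are 0-based row-major, and a pixel
belongs to the cell containing its center (half-open intervals). Channel
assignment sorts species by m/z (per polarity) and merges greedily while
the cluster span stays within one window — the mechanism that lets 88
isomeric-substrate reactions share a single product channel. Predicted
envelope leakage between channels above 0.1% is reported so downstream
correction knows what to subtract.

## Synthetic membranes

The generator emulates the statistical structure the analysis assumes:

* **Spot profile** — isotropic Gaussian, FWHM 2 mm (a dried 0.5 µL spot in
  a 5 mm cell), truncated at the cell edge, centred at the well center.
* **Response** — Langmuir-type I = rf·c/(1 + c/K) per compound, K = 1 mM
  by default, linear through the 5–100 µM calibration range and saturating
  above a millimolar. The default response factor (2e4 intensity·mM⁻¹ at
  the spot peak) sets a convenient dynamic range; per-compound ionization
  efficiencies on real membranes are unknown, so they are exposed as
  parameters rather than guessed.
* **Envelopes** — every species contributes centroids at its full
  isotopologue envelope, so the substrate M+2 interference is present in
  the data exactly as `chem` predicts it (the closed-form identity is
  tested at 1e-6 relative).
* **Noise** — per-centroid Gaussian with SD = noise_scale·√(signal +
  baseline), a Poisson surrogate; negative draws clip to zero. A flat
  per-centroid chemical baseline (default 20) exists wherever a species is
  declared, giving the border frames something to estimate.
* **Drift dimension** — optional; each species' intensity is spread over
  drift bins as a Gaussian at its drift center (default SD 0.5 ms). The
  drift axis is arbitrary "bins with centers"; no CCS calibration.
* **Raster** — 500 µm pixels by default; the raster covers the membrane
  from the scan origin to the far edge of the (possibly translated) grid,
  truncating a final partial pixel row/column.

Identical seeds give bit-identical datasets; every stochastic draw flows
from one `numpy` generator.

Study conditions used by the test harness: screening plates carry 0.1 mM
total substrate+product per well (inside the linear range) for conversion
recovery at ROI SNR ≈ 50; the false-positive/drift-gating harness uses
1 mM spots with noise_scale 1 — quenched biotransformations are spotted at
millimolar concentrations (real calibration spots visibly saturate), which
is what makes a 1.3% isotope leak detectable above the noise floor in
every substrate-containing well. ROI SNR is defined as (noise-free ROI
signal sum)/(SD of the ROI sum), with the SD of a sum of independent
per-centroid noises being noise_scale·√(Σ intensity).

**What passing tests do not show:** the generator has no spray-direction
or raster-lag asymmetry, no membrane-affinity chromatography, no
carry-over between spots, and equal ionization efficiency unless
configured otherwise. Recovery numbers on synthetic plates therefore bound
algorithmic error, not instrument error; detection floors measured here do
not transfer to real matrices.

## imzML dialect

Files are written in processed mode (64-bit m/z, 32-bit intensity) through
pyimzML, SHA-1 checksum embedded and verified on read. imzML has no
standard ion-mobility axis; one spectrum is stored per (pixel, drift bin)
with the bin index carried in the **z coordinate** (z = bin + 1), plus
informational `drift_bin`/`drift_time_ms` userParams. The z coordinate is
authoritative on read (the installed parser does not round-trip
per-spectrum userParams); standard viewers display drift planes as
z-slices. Pixel size and drift-bin centers, which imzML cannot carry here,
go to a JSON sidecar (`<name>.meta.json`) restored on read when present;
third-party files without a sidecar read fine with a pixel-size argument.
Continuous-mode (profile) files are centroided on read by local-maximum
picking. Empty pixel spectra are preserved exactly; grid positions missing
from a file are padded with empty spectra, one warning per gap.

## Quantification

Per channel, a pixel's value is the sum of centroid intensities in the
half-open window [target − w/2, target + w/2). Registration detects bright
connected components (Otsu threshold) in the TIC image, reduces them to
intensity-weighted centroids, scores candidate translations (generated
from centroid/well-center pairs within `max_shift`) by inlier count, and
refines the winner by least squares — robust to translations up to a full
cell because wrong lattice hypotheses strand edge spots without partners.

The ROI is the central square after trimming 10% of the cell size per
side; the trimmed border frame supplies the per-cell background (median)
and noise floor (MAD × ROI pixel count). Corrected sum =
max(raw − background·ROI size, 0); a channel is "empty" when its corrected
sum is ≤ 3 noise floors (the ≤ matters: a noise-free blank has both sides
exactly zero). Per-cell background was preferred over a global blank
because it is robust to slow intensity drift across the membrane.

Calibration fits OLS with saturated points excluded. The linear reference
is built from the low-concentration end upward — the three lowest points
seed the fit and higher points are admitted in ascending order while they
stay within 20% below the prediction — because a single heavily saturated
point dominates an all-point fit and would misclassify the linear points
instead. R² is the squared Pearson correlation of retained points;
LOD = 3.3·σ/slope (ICH convention; the source method states only a
sensitivity floor, so a standard definition was adopted). The 20%
saturation cut is a package choice: saturation in the source data is shown
only graphically.

Conversion c = P/(P + r·S) needs a closed formula even though the
screening readout itself only ranks brightness; r defaults to 1 with the
explicit caveat that cross-compound comparisons at r = 1 are rankings, not
measurements. Wells with both channels at the noise floor return an
undefined conversion and the `empty` flag.

## Mobility gating and interference subtraction

The drift gate is `fitted mode center ± 2 SD` from a single-Gaussian fit
around the mode nearest the expected drift time, shrunk to exclude any
other mode's center. 2 SD keeps ≈95% of the gated species while rejecting
a 6 SD-separated interferent essentially completely; the width is
configurable. When both mobility data and envelopes are available, gate
first, subtract second (the subtraction then removes only residual
leakage). Subtraction reduces the product corrected sum by
interference_fraction × substrate corrected sum, floors at zero, flags
wells whose product signal is fully explained within 3 noise floors, and
marks wells `interference_corrected` so re-application is a no-op
(idempotence by construction).

## Hit calling and throughput

Threshold mode needs declared blank wells (species-table role `other`, or
an explicit cutoff): hits are wells above mean(blanks) + 3·SD(blanks)
without the `isotope_false_positive` flag. Ties break by row-major well
label; ranking is total and permutation-invariant. Raster throughput per
cell is ceil(cell/pixel) lines × (cell width/stage speed + per-line
overhead); the overhead term is instrument-specific and deliberately has
no hidden default — 500 µm pixels at 2000 µm/s give 25 s/sample of pure
scan time, and an overhead of 1.9 s/line reproduces a 44 s/sample
operating point.

A packaged CSV (`data/pal_hplc_conversions.csv`) carries published
HPLC-measured conversion percentages for two ammonia lyases across 21
substituted cinnamic acids, for demonstrating threshold-style calling on
real printed numbers; "<1" entries load as censored NaNs.

## Library statistics

Degenerate codons expand through the standard genetic code (via
Biopython's IUPAC tables). Library size is the product of per-position
*residue* counts (duplicate codons collapse; stops excluded; stop-only
positions rejected); the codon-level count is also available. Clones for
coverage assumes equiprobable variants: n = ln(1−F)/ln(1−1/V), rounded to
nearest (ceiling available). This is the per-variant confidence form — the
probability that *a given* variant is present — not the coupon-collector
"all variants present" requirement, which is stricter and much larger;
the per-variant form is the standard screening-effort estimate and the
default here. It is cross-checked against a Monte-Carlo simulation in the
tests. Codon-usage weighting is deliberately out of scope.

## Test problem sizes

Unit tests run on 4×6 plates (24 cells, 60×40 pixels); the acceptance
harness uses a full 96-well raster (120×80 pixels) for conversion
recovery, 50 random-offset registration trials, 20 seeded drift-gating
plates, and 20 seeded calibration series — sizes chosen so the full suite
completes in about a minute while keeping ≥20 replicates behind every
statistical claim.

## Known limitations

* Translation-only registration (no rotation/shear); one membrane per file.
* Singly charged ±H adducts only; no fine isotope structure.
* Drift axis uncalibrated; no multi-conformer deconvolution.
* Absolute cross-compound quantification is out of scope by design; the
  response ratio r must come from external calibration to make conversions
  quantitative.
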