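# Methods

This note records the models, parameter choices and numerical conventions
behind `enamel_oct`, and what the synthetic validation does and does not
establish about real dental OCT data.

## Coordinate and calibration conventions

Images are arrays with rows indexing depth (z, increasing away from the scan
head) and columns indexing lateral position (one A-scan per column).
Coordinates are 0-based, regions of interest half-open, and physical position
is exactly `index × pitch`. Default calibration mirrors a swept-source
dental system: a 5 mm B-scan of 2000 A-scans (lateral pitch 2.5 µm/px), 1407
samples per A-scan, and C-scans of 500 B-scans over 5 mm. The axial pixel
pitch of such systems is not derivable from the quoted axial *resolution*
(16–18 µm in air, which moreover is reported inconsistently); it is therefore
a required calibration input, with a documented phantom default of
5.0 µm/px. No refractive-index correction is applied by default (factor 1.0,
configurable): thicknesses are optical-path lengths unless the user supplies
the tissue index.

## The tooth phantom

Each column with surface row *s* and enamel thickness *T* px renders, before
noise:

    I(z) = R_surf                      z = s            (1-px specular line)
         = R_en · hs(x) · e^(−µ(z−s))  s < z < s+T      (enamel)
         = R_dej · e^(−µT)             z = s+T          (DEJ line)
         = R_den · e^(−µ(z−s))         z > s+T          (dentin)

with Hunter–Schreger modulation `hs(x) = 1 + A·sq(2πx/P)` (square wave by
default — the bands alternate rather than fade), then axial Gaussian blur
(σ = 1.5 px, the point-spread function), multiplicative gamma speckle and an
additive Gaussian noise floor, clipped at zero.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| enamel thickness | 200 px = 1000 µm | low end of the 1000–1500 µm anatomical range |
| attenuation µ | 0.0025 /px = 0.5 mm⁻¹ | sound enamel is highly transparent at 1310 nm |
| R_surf, R_dej | 5.0 | specular 1-px lines; after PSF blur the surface peak is ~2× the enamel band and the DEJ a clear local maximum, so noise-free A-scans attain their maximum exactly at the surface row and a local maximum exactly at the DEJ row |
| R_en, R_den | 0.5, 0.25 | ~2:1 enamel:dentin backscatter contrast |
| HS period/amplitude | 120 px / 0.15 | bands a few hundred µm wide, moderate contrast |
| speckle shape k | 16 | 25% intensity CV, typical of averaged OCT display data |
| speckle grain | 2 px (axial) × 4 px (lateral) | ~one resolution cell; sampled per-grain and nearest-upsampled, which keeps the exact gamma marginal (CV = 1/√k) while giving speckle its blob size |
| noise floor σ | 0.01 | faint background so "empty" pixels are not exactly zero |

Defects: abrasion notches remove material from the top (the local surface
drops, the DEJ stays), adhesive-remnant patches add a bright band above the
surface and multiply everything deeper in those columns by a shadow factor,
and micro-cracks darken a thin tilted line. Treatment series apply per-stage
thickness reductions (taken from the top) plus stage defects; the optional
stage-2 bonding layer is a full-width remnant band.

The en-face renderer draws the plane `d` µm below the per-column surface
directly from the model instead of materializing a volume. Columns where the
plane glances the 1-px DEJ line are drawn at enamel brightness (the truth
labels them DEJ): a 1-px specular line sampled at glancing incidence is
diluted by the axial point-spread function, and rendering it at the raw line
amplitude would dominate the global intensity histogram.

**What the phantom does not model:** curved 2-D (mesial-distal ×
bucco-lingual) tooth geometry, refraction at the surface, correlated speckle
statistics beyond a rectangular grain, bracket hardware, saturation and
fixed-pattern artifacts. Passing recovery tests on phantoms therefore shows
the pipelines are self-consistent and correctly implemented at realistic
contrast, attenuation and speckle levels — not that they are robust to every
clinical artifact.

## Depth-intensity profiling

Peaks are `scipy.signal.find_peaks` local maxima above a height threshold
(default 20% of the A-scan maximum) with a minimum separation (default 5 px);
the array is padded with −∞ so an endpoint can be a peak — after flattening
the surface must be detectable at index 0. The *first* (surface) peak must
additionally clear a robust noise floor, median + 3·MAD of the A-scan.
A-scans with no detectable peak are excluded from the window average and
reported; missing peaks are never interpolated. Flattening shifts each
A-scan up by its first-peak index and zero-pads the tail (no signal exists
beyond acquisition depth). The DEJ is the highest-amplitude profile peak at
least one minimum-separation deeper than the surface, ties broken shallower;
fewer than two peaks yields a "DEJ not found" record, not an exception, so
batch runs degrade gracefully. Windows tile a region of interest left to
right; a trailing partial window is kept when at least half full.

Thicknesses outside 1000–1500 µm are anatomically unusual; the package
reports them without judgment and leaves range checks to the caller.

## Structural connectivity

The LoG kernel is the classic rotationally symmetric discrete kernel
(default 5×5, σ = 0.5), mean-subtracted so a constant image maps to exactly
zero; filtering uses symmetric border padding. Binarization takes global
Otsu on the min–max rescaled magnitude. One numerical convention matters:
histogram-based Otsu (single and multilevel) assigns the threshold *bin* to
the lower class, so thresholds are reported as the threshold bin's **upper
edge**; `value > t` then reproduces the histogram-optimal partition exactly
(bin centers, the common return convention, misassign values inside the
threshold bin — visible on few-level images).

Components are traced at 8-connectivity, discarded below 20 px, and labeled
in decreasing size order. The opening uses radius-1 square structuring
elements; the closing uses a much larger radius-20 square: its job is to
bridge speckle voids, dark Hunter–Schreger stripes and abraded dents so the
enamel reads as one continuous structure (a radius-r square SE is applied as
r iterations of the 3×3 SE, its exact Minkowski decomposition; the input is
padded by r so closing is extensive at borders). Total enamel is the closed
mask's pixel count and its intensity sum over the source image.

Abrasion detection: a dent lowers the locally detected surface, and the
closing fills the dent from its intact shoulders, so fill pixels appear
*above* the local surface — rows where an intact tooth never produces any.
Fill below the local surface is uninformative (speckle voids fill
everywhere). A column counts as protruding when it holds ≥ 3 fill pixels in
the 15-px band above its surface; protruding columns are grouped into sites
bridging gaps up to 5 px (one lateral speckle grain — protrusion runs
fragment at that scale), and sites under 35 px area are dropped. At these
settings a 20-px-wide, 5-px-deep notch is found in ≥ 94% of speckled
phantoms while an intact phantom yields a spurious site in roughly a quarter
of images; the detector favors sensitivity, and site areas let callers
re-rank. On noise-free piecewise-smooth images the binarized LoG keeps only
boundary ribbons, so the *pixel-count* total is thickness-insensitive there;
thickness sensitivity of the totals is a property of textured (speckled)
data, and the noise-free monotonicity guarantee lives with the en-face
metric below.

## Layer segmentation

Median filtering (5×5, symmetric padding) precedes a multilevel Otsu with 3
thresholds → 4 intensity classes (blue/green/red/magenta palette, lowest to
highest). The class of a pixel is the bin of its *median-filtered* intensity
under the thresholds — the class map partitions the image by construction. A
separate global Otsu pass marks foreground so the lowest class outside it
reads as air. Per class, the class-masked grayscale (not a 0/255 mask) is
processed with exactly the connectivity operations — LoG, binarize,
components, opening, per-class Sobel threshold (default 0.1 each), closing
(radius 1) — so a single-class image reproduces the connectivity pipeline
bit-for-bit; classes never mix. The composite draws closed structures lowest
class first, so the highest class wins overlaps, with configurable alpha.

En-face extraction samples each (slice, column) at
`surface_row + round(depth/Δz)`; columns with no detected surface are zeroed
and flagged, and the extraction errors out when more than half of all
columns fall beyond acquisition.

## Enamel metric and statistics

The per-sample metric is the *total pixel intensity in continuity* of an
en-face plane 500 µm below the surface: Otsu binarization of the en-face
intensities (no LoG here — en-face enamel/dentin contrast is areal, not
edge-like), component tracing, opening, closing with radius 5 (a large SE
would swallow dentin margins narrower than itself on small frames), then the
intensity sum under the closed mask. The µm scale of the published
per-sample table is not derivable from intensity sums without a system
calibration, so `calibration_scale` is an explicit input (default 1.0 with a
warning); consequently the package verifies the published *arithmetic*
(stage-mean differences: 125.40, 69.67, 267.57 µm) rather than image-derived
absolutes. The narrative source also states a 115.40 µm figure for the
baseline→stage-2 loss; the table arithmetic supports 125.40, which is what
the package reproduces.

Statistics: per-stage Kolmogorov–Smirnov tests against a normal with plug-in
(sample) mean and SD — the p-value is the classical KS one, anticonservative
with estimated parameters, matching common practice; sample SD uses n−1;
one-way within-subject ANOVA by explicit sums of squares with no sphericity
correction (a documented limitation — with it, borderline p-values would
grow); degenerate data short-circuit (no stage effect → F = 0, p = 1; zero
error with a stage effect → p = 0). Bonferroni: adjusted p = min(1, 6·p) for
the six stage pairs, significance at α = 0.05.

The simulated cohort (`simulate_cohort_metrics`) gives each of 30 subjects a
laterally tapered enamel cap (base 150 px, parabolic taper 100 px, so the
500 µm plane cuts a finite enamel patch with dentin margins), subject
thickness jitter (SD 8 px, clipped), and stage reductions 0/15/23/29 px
chosen to mirror the published table's relative stage losses (≈16%, 26%,
35% of baseline); every subject-stage cell is rendered as a speckled 48×96
en-face image and measured through the metric pipeline. Problem sizes in the
validation suite (48×96 en-face frames, 300×256 B-scans for abrasion,
full-size 1407×2000 B-scans for thickness recovery) are chosen to exercise
each property at the smallest scale where it is meaningful.

## Known limitations

- Thickness is optical path; supply a refractive index externally for
  geometric thickness.
- The abrasion detector trades specificity for sensitivity (see above).
- Deep enamel (> ~250 px at default attenuation) falls below the global
  binarization threshold, biasing B-scan totals low for very thick enamel.
- KS normality with plug-in parameters is anticonservative; RM-ANOVA assumes
  sphericity.
- The phantom's treatment-series model (thickness reduction + notches +
  bonding band) is an explicit modeling choice, not a physical wear model.
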