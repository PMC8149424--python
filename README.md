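# enamel-oct

Quantitative analysis of dental enamel in optical coherence tomography (OCT)
images across orthodontic treatment stages.

Orthodontic bracket bonding and debonding (pumice prophylaxis, acid etching,
adhesive application, bracket removal, remnant clean-up) can abrade the
enamel — the outer ~1000–1500 µm mineralized cap of a tooth. OCT images a
tooth cross-section non-destructively: each A-scan (depth profile) shows a
bright specular surface reflection, an enamel band with speckle and
Hunter–Schreger banding, a secondary reflectivity peak at the dentinoenamel
junction (DEJ), and dimmer dentin beneath. This package implements three
image-analysis pipelines for such data plus the group statistics used to
compare treatment stages, and — because clinical tooth scans are rarely
shareable — a synthetic tooth-phantom generator with pixel-level ground truth
so every stage of every pipeline is testable.

**Who it is for:** researchers processing dental OCT B-scans/C-scans who need
reproducible enamel thickness, enamel-continuity and abrasion measurements,
and a ground-truthed synthetic testbed for validating such pipelines.

## Methods at a glance

1. **Depth-intensity profiling** (`depth_profile`). Within a lateral window of
   *w* A-scans (default *w* = 10), each A-scan *aᵢ(z)* is shifted so its first
   intensity peak — the surface — sits at flattened index 0; the shifted
   A-scans are averaged and max-normalized,

   ```
   P(z) = mean_i a_i(z + s_i) / max_z mean_i a_i(z + s_i),
   ```

   and the enamel thickness is *T = z_DEJ · Δz*, where *z_DEJ* is the
   highest-amplitude profile peak deeper than the surface and *Δz* the axial
   pixel pitch (µm/px).

2. **Structural connectivity** (`connectivity`). Laplacian-of-Gaussian
   filtering → Otsu binarization of the rescaled magnitude → 8-connected
   component tracing → morphological opening → Sobel edge overlays →
   morphological closing. The *total enamel in continuity* is the sum of
   source intensities under the closed mask. Closing growth immediately above
   the locally detected surface flags **abrasion sites**: a dent is a
   concavity the closing fills from its intact shoulders.

3. **Intensity-based layer segmentation** (`layer_segmentation`). 5×5 median
   filtering → multilevel Otsu thresholds (default 3 thresholds → 4 intensity
   classes) → per-class colorization → per-class LoG/Sobel/component/closing
   structures → composite overlay. Also extracts **en-face** planes a fixed
   physical depth (e.g. 500 µm) below the per-column detected surface.

4. **Quantification and statistics** (`quantify_stats`). The per-sample
   enamel metric is the connected-intensity sum of an en-face plane; a
   subjects × stages table feeds Kolmogorov–Smirnov normality checks, one-way
   within-subject (repeated-measures) ANOVA with
   *F = MS_stage / MS_error*, df = (s−1), (s−1)(n−1), and Bonferroni-adjusted
   paired t-tests (adjusted p = min(1, 6·p) for four stages).

## Worked example

```python
import numpy as np
from enamel_oct import phantom as ph, depth_profile as dp
from enamel_oct import connectivity as conn, quantify_stats as qs
from enamel_oct.io_formats import Roi

# a speckled tooth phantom: 200 px enamel at 5 um/px, one abrasion notch
spec = ph.PhantomSpec(shape=(400, 256), surface=ph.SurfaceModel(base_row=60),
                      enamel_thickness_px=200, seed=42,
                      notches=(ph.AbrasionNotch(x_center=128, width=20, depth_px=5),))
bscan, truth = ph.generate_bscan(spec)

# enamel thickness from one 10-A-scan window
flat, shifts = dp.flatten_window(bscan, Roi(20, 30, 0, 400), window_size=10)
profile = dp.average_profile(flat, shifts, axial_pitch=5.0)
res = dp.measure_enamel_thickness(profile)
print(f"enamel thickness: {res.thickness_um:.0f} um")

# enamel continuity and abrasion sites
result = conn.run_pipeline(bscan, surface_row_per_column=dp.detect_surface(bscan))
print(f"total enamel: {result.total_enamel_px} px")
print(f"abrasion sites: {[(s.x_start, s.x_end) for s in result.abrasion_sites]}")

# a simulated 30-subject, 4-stage treatment cohort measured end-to-end
table = qs.simulate_cohort_metrics(n_subjects=30, seed=1)
report = qs.stats_report(table)
print(table.summary().round(1).to_string(index=False))
print(f"RM-ANOVA F({report.df_treatment},{report.df_error}) = "
      f"{report.f_statistic:.2f}, p = {report.p_value:.2e}")
```

prints

```
enamel thickness: 1005 um
total enamel: 49035 px
abrasion sites: [(108, 138), (160, 172)]
                              stage   mean    sd   min    max
                 Baseline (Control) 1006.3  53.2 903.3 1103.8
After Pumice, Etch, & Bonding Agent  929.2  76.3 813.9 1122.6
              After First Debonding  833.9  95.3 650.5  999.7
             After Second Debonding  766.6 102.3 577.2  907.8
RM-ANOVA F(3,87) = 112.47, p = 7.71e-30
```

The measured thickness (1005 µm) recovers the 1000 µm ground truth to one
pixel; the first abrasion site brackets the true notch (columns 118–138); the
cohort's stage means fall monotonically, and the repeated-measures ANOVA
detects the stage effect decisively. The second, smaller site is a
false-positive speckle artifact — see `docs/methods.md` for the detector's
operating characteristics.

## Command line

Every pipeline is also exposed as a subcommand of `enamel-oct`:

```
enamel-oct simulate --seed 3 --shape 1407,2000 --out phantom/
enamel-oct depth-profile --image b.tif --roi 400,600,0,1407 --window 10 --out profile.csv
enamel-oct connectivity  --image b.tif --out conn/
enamel-oct segment       --image b.tif --out seg/
enamel-oct enface        --volume c.tif --depth-um 500 --out enface.tif
enamel-oct quantify      --enface-dir enfaces/ --out metrics.csv
enamel-oct stats         --metrics metrics.csv --out report.json
```

Inputs are 8/16-bit PNG or TIFF B-scans (rows = depth, columns = lateral) and
multi-page TIFF volumes; outputs are PNG masks/overlays, CSV tables and JSON
reports. Pixel pitches are explicit options — the default phantom calibration
is 5.0 µm/px axial and 2.5 µm/px lateral (a 5 mm B-scan of 2000 A-scans).

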