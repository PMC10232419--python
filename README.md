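# bsscatter

Beam-stopper-based scatter correction for digital planar radiography.

X-ray scatter adds a low-frequency haze to planar radiographs that
compresses contrast, most visibly over the spine and mediastinum.
Antiscatter grids reject it in hardware but cost a 2–4× dose increase and
constrain the acquisition geometry.  `bsscatter` implements a
measurement-based software alternative: a second exposure is acquired with
a perforated tungsten plate (a *beam stopper*) between the X-ray source
and the patient.  The plate's shadow receives no primary radiation, so
shadow pixels sample the scatter field directly — albeit a *reduced*
scatter `S′ < S`, because the plate also blocks part of the fluence that
generates scatter inside the patient.  The pipeline recovers the full
scatter map `I_s` from these samples in five steps and subtracts it:

1. fit the shadow circle-means with 2D LOESS (local quadratic weighted
   least squares, k-NN span) → reduced scatter map `Ŝ′`;
2. `Î_BS^Primary = I_BS − Ŝ′` at the hole sites (primary estimate);
3. `Ŝ = I_ff − Î_BS^Primary` at those sites (full-scatter samples);
4. LOESS-fit `Ŝ` over the grid, upsample → `I_s`;
5. `I_C = I_ff − I_s`.

Both projections are block-mean downsampled (default ×8) before fitting;
scatter is low-frequency, so the estimate is unaffected while the 2D fits
become cheap.  The extra patient dose of the obstructed exposure equals
the plate's open-area fraction `(π/4)(d/p)²` ≈ 19.6% for 5.132 mm holes
on a 10.264 mm pitch — roughly half the total dose of cylinder-mesh
blocker schemes, and far below an antiscatter grid.

The package also ships an analytic cone-beam simulator of a chest-like
phantom (exact ray-traced primary + convolutional, material-weighted
scatter with ideal ground truth), a dehazing-style baseline correction
with its published parameter table, and the ROI evaluation metrics
(percentile-normalised RMSE, SNR, contrast recovery, line profiles).
See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
import numpy as np
from bsscatter import *

geom = default_geometry(scale=8)          # 536x440 detector, 0.8 mm pixels
bs = BeamStopperSpec(hole_diameter_mm=5.132, hole_pitch_mm=10.264)
print(f"open-area fraction: {open_area_fraction(bs):.4f} "
      f"(extra dose of the obstructed exposure: {100*open_area_fraction(bs):.1f}%)")

phantom = default_chest_phantom(geom)
acq = simulate_acquisition(phantom, geom, bs, ScatterModelParams(), seed=0)
res = estimate_scatter(acq.full_field.data, acq.bs_projection.data, geom, bs,
                       CorrectionConfig(downsample_factor=1))

sg = acq.scatter_gt.data
err = res.scatter_estimate - sg
print(f"scatter map rel. RMS error: {np.sqrt((err**2).mean())/np.sqrt((sg**2).mean()):.4f}")

rois = default_rois(acq.full_field.data.shape)
for region in ("lung_rmse", "spine_rmse"):
    r_c = rmse_roi(res.corrected, acq.primary_gt.data, rois[region])
    r_f = rmse_roi(acq.full_field.data, acq.primary_gt.data, rois[region])
    print(f"{region:10s}  RMSE full-field {r_f:.4f} -> corrected {r_c:.4f}")
cr = contrast_recovery(res.corrected, acq.primary_gt.data, rois["lung"], rois["heart"])
cf = contrast_recovery(acq.full_field.data, acq.primary_gt.data, rois["lung"], rois["heart"])
print(f"lung-heart contrast recovery: {cf:.3f} (full-field) -> {cr:.3f} (corrected)")
```

prints

```
open-area fraction: 0.1963 (extra dose of the obstructed exposure: 19.6%)
scatter map rel. RMS error: 0.0006
lung_rmse   RMSE full-field 0.0754 -> corrected 0.0002
spine_rmse  RMSE full-field 0.1015 -> corrected 0.0000
lung-heart contrast recovery: 0.890 (full-field) -> 1.000 (corrected)
```

Reading the numbers: the obstructed exposure adds ~20% dose; on the
noiseless synthetic chest the estimated scatter map matches the
simulator's ground truth to 0.06% RMS, driving the normalised ROI RMSE
against the primary ground truth down by more than two orders of
magnitude in both lung and spine; and the lung–heart contrast that the
haze had compressed to 89% of truth is fully restored.  The intermediate
maps (`Ŝ′`, primary estimate, sample table, Otsu mask) are all available
on the returned `CorrectionResult`.

## Command line

```sh
bsscatter simulate --out sim/                         # paired synthetic acquisition
bsscatter correct --full-field sim/full_field.tif \
    --obstructed sim/bs_projection.tif --out corrected.tif \
    --save-intermediates inter/
bsscatter baseline-meng --full-field sim/full_field.tif --out meng.tif --region lung
bsscatter evaluate --ground-truth sim/primary_gt.tif \
    --image prop corrected.tif --image ff sim/full_field.tif --out metrics.csv
```

Configuration (geometry, plate, correction and simulation parameters) is
a flat YAML/JSON file with all lengths in millimetres; unknown keys are
rejected.  Every run writes a provenance record (config hash, seed,
versions).

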