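# pvsquant

Semi-automatic quantification of perivascular spaces (PVS, also called
Virchow–Robin spaces) in the basal ganglia on conventional T2-weighted
MRI. PVS are fluid-filled spaces around penetrating brain vessels —
small bright dots under 3 mm cross-section on T2W — and their burden is
a marker of cerebral small vessel disease. Clinical visual rating
scales condense them into a few ordinal categories with substantial
observer variability; `pvsquant` instead counts and measures them as
image objects, for researchers who need a quantitative PVS burden from
standard structural MRI.

## Method

On one operator-chosen axial slice at the basal-ganglia level,
restricted to bilateral ovoid BG regions of interest:

1. **Intensity adjustment.** A linear rescale saturating the 1% lowest
   and highest intensities at the new floor/ceiling, mapped to
   `[0, 255]`, followed by the voxelwise self-product of the adjusted
   slice — equivalent to gamma correction
   `i' = (I_max − I_min)·((i − I_min)/(I_max − I_min))^γ + I_min`
   with γ = 2, since the rescaled minimum is 0.
2. **Rule-based thresholding.** One of three thresholds on the adjusted
   slice, chosen from the case's image characteristics: Low (7.5% of
   maximum) for scattered PVS on a uniform background with few lesions,
   High (15% or above) for grouped PVS, high background, many lesions
   or poor quality, Medium (11.25%) otherwise.
3. **Object analysis.** Connected-component labelling (8-connectivity)
   of suprathreshold ROI pixels, removal of objects whose equivalent
   diameter `2·sqrt(area/π)` exceeds the 3 mm PVS criterion (rejecting
   lacunes), then count, per-object area/volume and total volume
   (voxels × 0.47 × 0.47 × 6 mm³ on the reference protocol). Difficult
   cases re-run with another threshold and/or a manual exclusion mask.
4. **Scoring & statistics.** Counts condense to the clinical 0–4 scale
   (0; 1–10; 11–20; 21–39; ≥40, high background ⇒ 4); Bland–Altman
   utilities quantify observer agreement and simple OLS the
   count/volume/score associations.

A seeded synthetic-phantom generator (Gaussian-profile PVS dots with
peaks at 30–90% of the ceiling, ventricular CSF, lacune and WMH
confounds, additive noise) provides ground truth for recovery testing
without patient data. See `docs/methods.md` for assumptions and
limitations.

## Worked example

Simulate a phantom with 14 planted PVS dots and quantify it:

```sh
$ pvsquant simulate --seed 5 --n-pvs 14 --out sim
wrote phantom with 14 PVS dots to sim

$ pvsquant segment --t2w sim/phantom.nii.gz --slice-index 0 \
      --roi-spec roi.yaml --threshold medium --out seg
case phantom: count=14 total_volume_ml=0.137842 score=2 (medium threshold, 0.1125 of max)
```

All 14 planted dots are recovered; their summed slab volume is
0.138 ml, and a count of 14 falls in category 2 (11–20 PVS) of the
clinical scale. `seg/objects.csv` lists each object:

```
label,voxel_count,area_mm2,equivalent_diameter_mm,centroid_row,centroid_col,volume_ml
1,9,1.9880999899148941,1.5910146215692744,97.0,190.0,0.011928599939489365
2,5,1.1044999943971634,1.185872282341667,104.0,50.0,0.00662699996638298
...
```

(a 9-pixel object at 0.47 mm pixels has area 1.99 mm², equivalent
diameter 1.59 mm — comfortably under the 3 mm PVS limit — and volume
9 × 1.3254 mm³ = 0.0119 ml). `seg/summary.json` records the count,
total volume, condensed score and full provenance. The `roi.yaml` file
holds the ovoid ROI parameters (centres, semi-axes, rotation); real
scans would instead pass an operator-drawn mask via `--roi`.

Scoring and statistics from the same toolbox:

```sh
$ pvsquant score --count 21
3
$ pvsquant agree --pairs pairs.csv
n=3 mean_difference=-1.0000 sd=1.0000 limits=(-2.9600, 0.9600)
$ pvsquant assoc --table t.csv --x x --y y
slope=1 (95% CI -0.272979 to 2.27298) intercept=0.2 p=0.0877 n=5
```

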