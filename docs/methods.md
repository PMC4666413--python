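# Methods

## The measurement problem

Perivascular (Virchow–Robin) spaces are fluid-filled sheaths around
penetrating vessels, visible on T2-weighted MRI as small hyperintense
dots or streaks under 3 mm in cross-section. Clinical practice rates
their burden on coarse ordinal scales (0–4), which suffer observer
variability and ceiling/floor effects. `pvsquant` implements a
semi-automatic computational alternative for the basal ganglia (BG): it
counts and measures suprathreshold objects inside bilateral ovoid BG
regions of a single representative axial slice.

The analysis is deliberately 2D. Thick axial slices (here 5 mm with a
1 mm gap, so 6 mm centre-to-centre) make 3D reconstruction of sub-mm
structures meaningless; the method quantifies one operator-chosen slice
that contains characteristic BG anatomy and shows the most PVS.

## Intensity adjustment

PVS peak intensities range from roughly 30% to 90% of the T2W image
maximum, so no single threshold separates them from tissue on the raw
image. Three stages make one threshold workable:

1. **Saturating rescale** (gamma = 1). With `k = floor(f·n)` and
   saturation fraction `f` (default 0.01), the k-th smallest and k-th
   largest intensities in the domain become the new floor `L` and
   ceiling `H`; intensities are clipped to `[L, H]` and mapped affinely
   onto `[0, out_max]` (default `out_max = 255`). Order statistics are
   used rather than interpolated percentiles: they are exact and easy
   to verify against a sort-based oracle. Saturation is what lifts
   faint PVS: on a brain slice the top 1% of intensities lie inside
   ventricular CSF, so `H` sits well below the raw maximum and every
   sub-CSF structure gains relative intensity.
2. **Gamma correction.** The power-law map with fixed points at the
   domain extremes,
   `i' = (I_max − I_min)·((i − I_min)/(I_max − I_min))^γ + I_min`.
   Gamma 1 is the identity; gamma is user-settable.
3. **Self-product combination.** The voxelwise square `i²/out_max` of
   the rescaled slice. Because the rescaled image has minimum 0, this
   is algebraically identical to gamma correction with γ = 2 (asserted
   to 1e-9·out_max in tests). Squaring deepens the tissue/dot
   separation so the fixed threshold fractions below apply cleanly.

All three maps are monotone non-decreasing, so they re-shape the
histogram without reordering structures. By default the statistics are
computed over the chosen slice (the method is single-slice); a domain
mask or whole-volume domain is available via configuration.

## Threshold policy and segmentation

Three thresholds, expressed as fractions of the adjusted maximum
(`out_max`), cover the case mix:

| level  | fraction | indicated when |
|--------|----------|----------------|
| low    | 0.075    | scattered PVS, uniform visually normal background, few focal lesions |
| medium | 0.1125   | neither the low nor the high pattern |
| high   | ≥ 0.15   | grouped PVS, high background signal, many lesions, or poor scan quality |

`select_threshold` encodes exactly this rule from seven operator-set
boolean case characteristics; any "high" criterion wins, the "low"
pattern requires all three of its flags, and everything else is medium.
Pixels inside the ROI with adjusted intensity **at or above**
`fraction · out_max` are candidates (ties included — a deterministic
rule that matters for integer phantoms). Candidates are labelled by
connected components (8-connectivity in-plane by default, since dots at
0.47 mm pixels may touch diagonally; 4-connectivity is available), then
size-filtered:

* components with fewer than `min_voxels` pixels are dropped
  (default 1, i.e. no minimum);
* components whose equivalent diameter `2·sqrt(area/π)` exceeds 3 mm
  are dropped — this enforces the PVS definition and rejects lacunes
  and other large hyperintensities, adapting automatically to pixel
  spacing.

Each kept object is reported with pixel count, area (mm²), equivalent
diameter (mm), centroid and slab volume `n·dx·dy·dz / 1000` ml. The
6 mm centre-to-centre `dz` (slice + gap) is used for volume, matching
the acquisition's printed voxel size; it is configurable for users who
prefer the nominal 5 mm thickness. Difficult cases are re-run with
another threshold and/or an operator-drawn exclusion mask applied
before labelling (this replaces interactive editing; there is no GUI).
Objects clipped by the ROI boundary are kept with their in-ROI area,
and full provenance (saturation, threshold, connectivity, filters,
exclusion-mask use) is recorded in the result.

## ROI

The BG regions are two ovoids, one per hemisphere, anatomically
delineated in the original procedure. Since no coordinates generalise
across scans, the package accepts either an operator-drawn binary mask
(preferred for real data, validated to have exactly two components) or
a parametric rotated-ellipse specification (used for phantoms). Pixel
membership is decided at pixel centres with the exact ellipse
inequality — no anti-aliasing — so masks are reproducible and
oracle-checkable. Slice selection is an operator input.

## Scoring and statistics

Counts are condensed to the ordinal 0–4 categories of the clinical
visual scale: 0 → 0, 1–10 → 1, 11–20 → 2, 21–39 → 3, ≥ 40 → 4, with a
high-background case assigned 4 outright. The printed clinical scales
overlap at the bin edges (10 and 40 each appear in two bins); the
half-open convention above is the unique monotone reconciliation and is
the one implemented. Note the published count↔volume regression
coefficients for this method are mutually inconsistent as printed (a
0.11 ml-per-dot coefficient versus 67.3 for the inverse regression,
against a median total volume of 0.093 ml); no attempt is made to
reproduce either.

Observer agreement uses Bland–Altman statistics: mean and sample
(n−1 denominator) SD of paired differences, limits of agreement at
±1.96 SD. Associations (count vs volume vs visual score, etc.) use
simple ordinary least squares with the t-based 95% CI and two-sided
p-value on the slope; a zero-residual fit is flagged degenerate rather
than reporting meaningless inference.

## Synthetic phantoms

The generator renders a single axial slice containing exactly the
features the pipeline interacts with:

* an elliptical brain (background tissue at 0.10·out_max) on black air
  — the air floor anchors the low 1% tail at 0;
* two paramedian ventricular CSF plateaus at `csf_fraction` (default
  0.80·out_max) covering ~2% of the slice — the high 1% tail lands
  inside this plateau, pinning the rescale ceiling `H` near
  0.80·out_max independently of dot load. This reproduces the
  mechanism by which saturation lifts faint PVS on real scans, and it
  is what makes a 30%-of-max dot exceed the 11.25% threshold after
  squaring ((0.30/0.80)² ≈ 0.14 > 0.1125);
* PVS dots: Gaussian radial profiles (radius = FWHM/2, default
  0.4–0.9 mm, i.e. 0.8–1.8 mm FWHM diameters typical of BG PVS) planted
  at pixel centres inside the ROI with peaks drawn from 30–90% of
  out_max and pairwise centre separation ≥ 4 mm. The radius ceiling
  keeps the suprathreshold footprint of even a 90%-peak dot under the
  3 mm equivalent-diameter filter;
* optional confounds: lacune-like lesions (bright plateaus > 3 mm
  diameter with a narrow partial-volume edge — always rejected by the
  diameter filter) and diffuse WMH-like blobs (large, low-contrast);
* additive zero-mean Gaussian noise (default SD 0.02·out_max), clipped
  to `[0, out_max]`. Gaussian rather than Rician noise: at these
  background levels the difference is immaterial for threshold
  behaviour.

Placement is rejection sampling capped at 1000 attempts per object,
giving a deterministic failure mode on infeasible requests; all
randomness flows from one seeded generator, so phantoms are
bit-reproducible.

What the phantom does **not** emulate: real BG anatomy and its
intensity texture, elongated/linear PVS, bias fields, motion artefact,
partial-volume mixing along the slice axis, and Rician noise floors.
Passing recovery tests therefore demonstrates the internal consistency
of the adjustment–threshold–filter chain under controlled conditions,
not clinical accuracy on patient scans, which the original development
assessed by observer agreement.

## Problem sizes and numerical choices

The recovery suite runs 100 phantoms (256×256 pixels at 0.47 mm, 1–40
dots each, one lacune confound) at the medium threshold and requires
≥ 95% exact-count recovery, a dot-level true-positive rate ≥ 0.98 and
100% lacune rejection; the shipped configuration achieves 98/100,
0.999 and 100/100. Component labelling is cross-checked against an
explicit flood fill on 1000 random masks at both connectivities, the
rescale against a sort-based order-statistic oracle, and the
regression/agreement statistics against closed-form normal equations,
all at the tolerances stated in the tests. Detection-to-truth matching
is greedy nearest-centre within 2 mm (half the minimum planted
separation, so matches are unambiguous).
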