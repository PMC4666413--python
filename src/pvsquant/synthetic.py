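"""Ground-truthed T2W-like phantom slices for pipeline testing.

The generator emulates the features of a basal-ganglia axial T2W slice
that the detection pipeline actually interacts with:

* an elliptical "brain" of mid-intensity tissue surrounded by air, so
  the low-tail saturation of the rescale stage lands in the air floor;
* bright ventricular CSF (a constant plateau, by default at 80% of the
  intensity ceiling) occupying a few percent of the slice, so the
  high-tail saturation lands inside CSF — exactly the mechanism that
  lifts faint PVS relative to the image maximum on real scans;
* PVS dots: small radially decreasing (Gaussian-profile) blobs planted
  at pixel centres inside the bilateral BG ROI, with peak intensities
  drawn from 30-90% of the ceiling and radii below the 3 mm diameter
  criterion;
* optional confounds: lacune-like large hyperintensities (> 3 mm
  diameter, rejected by the size filter) and diffuse WMH-like blobs
  (larger, lower contrast, raising the local background);
* additive zero-mean Gaussian noise, clipped to the valid range.

Every random draw comes from one seeded generator, so a fixed seed
gives bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError
from .image_io import IntensityVolume
from .roi_tools import RoiMask, RoiSpec, make_ovoid_roi
from .segmentation import SegmentationResult

__all__ = [
    "WmhSpec",
    "LacuneSpec",
    "SyntheticSpec",
    "GroundTruth",
    "default_roi_spec",
    "generate_phantom",
    "truth_match",
]

# Gaussian sigma such that the dot "radius" is half the full width at
# half maximum: FWHM = 2*radius = 2*sqrt(2*ln 2)*sigma.
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class WmhSpec:
    """Diffuse white-matter-hyperintensity-like confound blobs."""

    n_blobs: int = 2
    radius_mm: float = 4.0
    peak_fraction: float = 0.35


@dataclass(frozen=True)
class LacuneSpec:
    """Lacune-like confounds: large (> 3 mm) bright lesions."""

    n: int = 1
    diameter_mm: float = 5.0
    peak_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.diameter_mm <= 3.0:
            raise ValueError("lacunes must exceed the 3 mm PVS diameter criterion")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one phantom slice.

    All intensity fractions are relative to ``out_max``.  ``dz`` of the
    spacing only affects reported volumes, not the 2D image.
    """

    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float, float] = (0.47, 0.47, 6.0)
    n_pvs: int = 12
    dot_radius_range_mm: tuple[float, float] = (0.4, 0.9)
    dot_peak_fraction_range: tuple[float, float] = (0.30, 0.90)
    background_fraction: float = 0.10
    csf_fraction: float = 0.80
    noise_sd_fraction: float = 0.02
    min_separation_mm: float = 4.0
    wmh: WmhSpec | None = None
    lacunes: LacuneSpec | None = None
    out_max: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_fraction", "csf_fraction", "noise_sd_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.dot_peak_fraction_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("dot_peak_fraction_range must be ordered and in [0, 1]")
        if self.n_pvs < 0:
            raise ValueError("n_pvs must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-object truth for recovery scoring.

    ``dot_masks`` labels the pixels within each dot's half-maximum
    radius (label i for dot i, 1-based); ``confound_masks`` does the
    same for lacunes and WMH blobs.
    """

    dot_centers: tuple[tuple[int, int], ...]
    dot_masks: np.ndarray
    confound_masks: np.ndarray
    n_pvs_true: int
    lacune_centers: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def default_roi_spec(shape: tuple[int, int] = (256, 256)) -> RoiSpec:
    """Bilateral BG ovoids sized for the default phantom geometry."""
    cr, cc = shape[0] / 2, shape[1] / 2
    return RoiSpec(
        slice_index=0,
        left_center=(cr, cc - 62),
        right_center=(cr, cc + 62),
        semi_axes=(48, 26),
    )


def _place(
    rng: np.random.Generator,
    roi_pixels: np.ndarray,
    existing: list[tuple[float, tuple[int, int]]],
    clearance_mm: float,
    spacing: tuple[float, float],
    what: str,
) -> tuple[int, int]:
    """Rejection-sample one centre among ROI pixels, keeping
    ``clearance_mm`` (plus each neighbour's own clearance) to all
    previously placed centres."""
    dx, dy = spacing
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        r, c = roi_pixels[rng.integers(len(roi_pixels))]
        ok = True
        for other_clearance, (orr, occ) in existing:
            d = np.hypot((r - orr) * dx, (c - occ) * dy)
            if d < clearance_mm + other_clearance:
                ok = False
                break
        if ok:
            return int(r), int(c)
    raise PlacementError(
        f"could not place {what} after {_MAX_PLACEMENT_ATTEMPTS} attempts; "
        "ROI too small for the requested object count/separation"
    )


def generate_phantom(
    spec: SyntheticSpec, roi: RoiMask | None = None
) -> tuple[IntensityVolume, GroundTruth]:
    """Render one phantom slice and its ground truth.

    The returned volume is single-slice 3D (shape ``(*shape, 1)``) so it
    flows through the same I/O and segmentation paths as scanner data.
    """
    if roi is None:
        roi = make_ovoid_roi(spec.shape, default_roi_spec(spec.shape))
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    dx, dy, _ = spec.spacing
    om = spec.out_max

    rows, cols = np.indices(spec.shape)
    cr, cc = (nrows - 1) / 2, (ncols - 1) / 2

    # brain tissue on black air
    brain = ((rows - cr) / (0.92 * nrows / 2)) ** 2 + (
        (cols - cc) / (0.84 * ncols / 2)
    ) ** 2 <= 1.0
    image = np.where(brain, spec.background_fraction * om, 0.0)

    # ventricular CSF: two paramedian plateaus anchoring the bright tail
    for dcol in (-12, 12):
        vent = ((rows - (cr - 8)) / 30.0) ** 2 + ((cols - (cc + dcol)) / 7.0) ** 2 <= 1.0
        image[vent & brain] = spec.csf_fraction * om

    roi_pixels = np.argwhere(roi.mask)
    if spec.n_pvs > 0 and len(roi_pixels) == 0:
        raise PlacementError("ROI is empty")
    placed: list[tuple[float, tuple[int, int]]] = []

    confound_masks = np.zeros(spec.shape, dtype=np.int32)
    next_confound = 1
    lacune_centers: list[tuple[int, int]] = []

    # confounds first so dots keep clear of them
    if spec.lacunes is not None:
        lac_r_mm = spec.lacunes.diameter_mm / 2
        for _ in range(spec.lacunes.n):
            center = _place(rng, roi_pixels, placed, lac_r_mm + 2.0, (dx, dy), "lacune")
            placed.append((lac_r_mm + 2.0, center))
            lacune_centers.append(center)
            d_mm = np.hypot((rows - center[0]) * dx, (cols - center[1]) * dy)
            # bright plateau with a narrow partial-volume edge
            profile = np.exp(-np.maximum(d_mm - lac_r_mm, 0.0) ** 2 / (2 * 0.3**2))
            amp = spec.lacunes.peak_fraction * om - image[center]
            image += amp * profile
            confound_masks[d_mm <= lac_r_mm] = next_confound
            next_confound += 1

    if spec.wmh is not None:
        sigma_mm = spec.wmh.radius_mm / (_FWHM_PER_SIGMA / 2)
        for _ in range(spec.wmh.n_blobs):
            center = _place(rng, roi_pixels, placed, spec.wmh.radius_mm, (dx, dy), "WMH blob")
            placed.append((spec.wmh.radius_mm, center))
            d_mm = np.hypot((rows - center[0]) * dx, (cols - center[1]) * dy)
            profile = np.exp(-(d_mm**2) / (2 * sigma_mm**2))
            amp = spec.wmh.peak_fraction * om - image[center]
            image += amp * profile
            confound_masks[(profile >= 0.5) & (confound_masks == 0)] = next_confound
            next_confound += 1

    # PVS dots
    dot_masks = np.zeros(spec.shape, dtype=np.int32)
    dot_centers: list[tuple[int, int]] = []
    half_sep = spec.min_separation_mm / 2
    for i in range(spec.n_pvs):
        center = _place(rng, roi_pixels, placed, half_sep, (dx, dy), f"PVS dot {i + 1}")
        placed.append((half_sep, center))
        dot_centers.append(center)
        radius_mm = rng.uniform(*spec.dot_radius_range_mm)
        peak = rng.uniform(*spec.dot_peak_fraction_range) * om
        sigma_mm = 2 * radius_mm / _FWHM_PER_SIGMA
        d_mm = np.hypot((rows - center[0]) * dx, (cols - center[1]) * dy)
        profile = np.exp(-(d_mm**2) / (2 * sigma_mm**2))
        image += (peak - image[center]) * profile
        dot_masks[profile >= 0.5] = i + 1

    if spec.noise_sd_fraction > 0:
        image = image + rng.normal(0.0, spec.noise_sd_fraction * om, spec.shape)
    image = np.clip(image, 0.0, om)

    volume = IntensityVolume(
        image[:, :, np.newaxis], spec.spacing, id=f"phantom-seed{spec.seed}"
    )
    truth = GroundTruth(
        dot_centers=tuple(dot_centers),
        dot_masks=dot_masks,
        confound_masks=confound_masks,
        n_pvs_true=len(dot_centers),
        lacune_centers=tuple(lacune_centers),
    )
    return volume, truth


def truth_match(
    result: SegmentationResult,
    truth: GroundTruth,
    tolerance_mm: float = 2.0,
    spacing: tuple[float, float] = (0.47, 0.47),
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to planted dots.

    Each detected centroid claims the nearest unmatched true centre
    within ``tolerance_mm``.  Returns ``(true_positives,
    false_positives, false_negatives)``; TP + FN always equals
    ``truth.n_pvs_true`` and TP + FP equals the detection count.
    """
    dx, dy = spacing
    remaining = {i: c for i, c in enumerate(truth.dot_centers)}
    tp = fp = 0
    for obj in result.objects:
        best, best_d = None, np.inf
        for i, (tr, tc) in remaining.items():
            d = np.hypot((obj.centroid[0] - tr) * dx, (obj.centroid[1] - tc) * dy)
            if d < best_d:
                best, best_d = i, d
        if best is not None and best_d <= tolerance_mm:
            del remaining[best]
            tp += 1
        else:
            fp += 1
    fn = len(remaining)
    return tp, fp, fn
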