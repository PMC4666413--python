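"""Rule-based PVS detection on a single basal-ganglia slice.

The detection procedure is strictly 2D (thick slices with an inter-slice
gap rule out 3D analysis):

1. choose the standard BG axial slice;
2. saturating rescale of the slice intensities to ``[0, out_max]``;
3. self-product combination (equivalently gamma = 2);
4. restrict to the bilateral ovoid BG ROI;
5. apply one of three thresholds — Low (7.5%), Medium (11.25%) or High
   (15% or above of maximum signal intensity) — chosen from the image
   characteristics of the individual case;
6. connected-component labelling of the suprathreshold pixels;
7. size filtering: discard components larger than the 3 mm cross-section
   diameter criterion for PVS (lacunes and other large lesions), and
   optionally those below a minimum pixel count.

Difficult cases are re-run with another threshold and/or a manual
exclusion mask covering lesions mistaken for PVS; the exclusion mask is
applied before labelling.  The output is the object count, per-object
areas/volumes and the total PVS volume inside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ShapeMismatchError
from .image_io import IntensityVolume
from .intensity_adjust import (
    AdjustmentParams,
    combine_self_product_array,
    saturate_rescale_array,
)
from .roi_tools import RoiMask

__all__ = [
    "CaseCharacteristics",
    "ThresholdPolicy",
    "SizeFilter",
    "PvsObjectRecord",
    "SegmentationResult",
    "LOW_FRACTION",
    "MEDIUM_FRACTION",
    "HIGH_FRACTION",
    "select_threshold",
    "apply_threshold",
    "label_objects",
    "filter_objects",
    "quantify",
    "segment_case",
]

# Threshold fractions of maximum signal intensity on the adjusted scale.
LOW_FRACTION = 0.075
MEDIUM_FRACTION = 0.1125
HIGH_FRACTION = 0.15


@dataclass(frozen=True)
class CaseCharacteristics:
    """Operator-rated T2W image characteristics that drive threshold choice.

    The first three flags describe the benign pattern that tolerates the
    Low threshold; the last four each force the High threshold.
    """

    scattered_pvs: bool = False
    uniform_background: bool = False
    few_focal_lesions: bool = False
    grouped_pvs: bool = False
    high_background: bool = False
    many_lesions: bool = False
    poor_quality: bool = False


@dataclass(frozen=True)
class ThresholdPolicy:
    """A named threshold level and its fraction of maximum intensity."""

    level: str
    fraction_of_max: float

    _FRACTIONS = {
        "low": LOW_FRACTION,
        "medium": MEDIUM_FRACTION,
        "high": HIGH_FRACTION,
    }

    def __post_init__(self) -> None:
        if self.level not in ("low", "medium", "high", "custom"):
            raise ValueError(f"unknown threshold level {self.level!r}")
        if not 0 < self.fraction_of_max <= 1:
            raise ValueError("fraction_of_max must be in (0, 1]")
        if self.level in ("low", "medium"):
            expected = self._FRACTIONS[self.level]
            if self.fraction_of_max != expected:
                raise ValueError(
                    f"{self.level} threshold is fixed at {expected}"
                )
        elif self.level == "high" and self.fraction_of_max < HIGH_FRACTION:
            raise ValueError(f"high threshold must be >= {HIGH_FRACTION}")

    @classmethod
    def named(cls, level: str, fraction: float | None = None) -> "ThresholdPolicy":
        """Build a policy from a level name; ``fraction`` only applies to
        ``high`` (>= 0.15) and ``custom``."""
        if level == "custom":
            if fraction is None:
                raise ValueError("custom threshold needs a fraction")
            return cls("custom", fraction)
        if level == "high":
            return cls("high", HIGH_FRACTION if fraction is None else fraction)
        return cls(level, cls._FRACTIONS[level])


@dataclass(frozen=True)
class SizeFilter:
    """Object size limits.

    ``min_voxels`` removes speckle below a pixel count (default 1, i.e.
    keep everything); ``max_equivalent_diameter_mm`` enforces the PVS
    definition — cross-sections under 3 mm diameter — and so rejects
    lacunes and other large hyperintensities regardless of pixel spacing.
    """

    min_voxels: int = 1
    max_equivalent_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.max_equivalent_diameter_mm <= 0:
            raise ValueError("max_equivalent_diameter_mm must be positive")


@dataclass(frozen=True)
class PvsObjectRecord:
    """One detected PVS: in-plane geometry plus its slab volume.

    ``area_mm2 = voxel_count * dx * dy``;
    ``equivalent_diameter_mm = 2 * sqrt(area_mm2 / pi)`` (diameter of the
    circle of equal area); ``volume_ml = voxel_count * dx * dy * dz / 1000``.
    """

    label: int
    voxel_count: int
    area_mm2: float
    equivalent_diameter_mm: float
    centroid: tuple[float, float]
    volume_ml: float


@dataclass(frozen=True)
class SegmentationResult:
    """Finalised detection result for one case/slice."""

    objects: tuple[PvsObjectRecord, ...]
    policy: ThresholdPolicy
    slice_index: int
    case_id: str = ""
    score: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.objects)

    @property
    def total_volume_ml(self) -> float:
        return float(sum(o.volume_ml for o in self.objects))


def select_threshold(chars: CaseCharacteristics) -> ThresholdPolicy:
    """Pick the threshold level from the case characteristics.

    High if the case has grouped PVS, a high background signal, many
    other lesions, or poor scan quality; Low if it has scattered PVS on
    a uniform, visually normal background with few focal lesions; Medium
    otherwise.
    """
    if chars.grouped_pvs or chars.high_background or chars.many_lesions or chars.poor_quality:
        return ThresholdPolicy.named("high")
    if chars.scattered_pvs and chars.uniform_background and chars.few_focal_lesions:
        return ThresholdPolicy.named("low")
    return ThresholdPolicy.named("medium")


def apply_threshold(
    adjusted_slice: np.ndarray,
    roi: RoiMask | np.ndarray,
    policy: ThresholdPolicy,
    exclusion_mask: np.ndarray | None = None,
    out_max: float = 255.0,
) -> np.ndarray:
    """Binary candidate mask: ROI pixels at or above the threshold.

    A pixel is a candidate iff it lies inside the ROI, is not excluded,
    and its adjusted intensity is ``>= fraction_of_max * out_max`` (ties
    at the threshold are included).
    """
    adjusted_slice = np.asarray(adjusted_slice, dtype=float)
    roi_mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    if roi_mask.shape != adjusted_slice.shape:
        raise ShapeMismatchError(
            f"ROI shape {roi_mask.shape} != slice shape {adjusted_slice.shape}"
        )
    if not roi_mask.any():
        raise EmptyMaskError("ROI contains no pixels")
    candidate = roi_mask & (adjusted_slice >= policy.fraction_of_max * out_max)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != adjusted_slice.shape:
            raise ShapeMismatchError(
                f"exclusion mask shape {exclusion_mask.shape} != slice shape "
                f"{adjusted_slice.shape}"
            )
        candidate &= ~exclusion_mask
    return candidate


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int),
    8: np.ones((3, 3), dtype=int),
}


def label_objects(candidate_mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Maximal connected components of a binary mask.

    Returns one ``(n_pixels, 2)`` array of (row, col) indices per
    component, ordered by first pixel in raster order.  ``connectivity``
    is 4 (edge neighbours) or 8 (edge + diagonal, the default: PVS dots
    at sub-mm pixels may touch diagonally).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    labels, n = ndimage.label(candidate_mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    order = np.argsort(labels[candidate_mask], kind="stable")
    coords = np.argwhere(candidate_mask)[order]
    sizes = np.bincount(labels[candidate_mask])[1:]
    splits = np.cumsum(sizes)[:-1]
    return [np.array(c) for c in np.split(coords, splits)]


def filter_objects(
    components: Sequence[np.ndarray],
    size_filter: SizeFilter,
    spacing: Sequence[float],
) -> list[PvsObjectRecord]:
    """Apply the size limits and convert surviving components to records.

    A component is kept iff ``voxel_count >= min_voxels`` and its
    equivalent diameter ``2*sqrt(voxel_count*dx*dy/pi)`` does not exceed
    ``max_equivalent_diameter_mm``.
    """
    dx, dy, dz = spacing
    records: list[PvsObjectRecord] = []
    for component in components:
        component = np.asarray(component)
        n = component.shape[0]
        area = n * dx * dy
        diameter = 2.0 * np.sqrt(area / np.pi)
        if n < size_filter.min_voxels or diameter > size_filter.max_equivalent_diameter_mm:
            continue
        centroid = component.mean(axis=0)
        records.append(
            PvsObjectRecord(
                label=len(records) + 1,
                voxel_count=int(n),
                area_mm2=float(area),
                equivalent_diameter_mm=float(diameter),
                centroid=(float(centroid[0]), float(centroid[1])),
                volume_ml=float(n * dx * dy * dz / 1000.0),
            )
        )
    return records


def quantify(
    objects: Sequence[PvsObjectRecord], spacing: Sequence[float] | None = None
) -> tuple[int, float, list[float]]:
    """Count and total volume (ml) of the detected objects.

    Returns ``(count, total_volume_ml, per_object_volumes_ml)``.
    ``spacing`` is accepted for interface symmetry; volumes are already
    fixed on the records.
    """
    volumes = [o.volume_ml for o in objects]
    return len(objects), float(sum(volumes)), volumes


def segment_case(
    volume: IntensityVolume,
    slice_index: int,
    roi: RoiMask | np.ndarray,
    characteristics: CaseCharacteristics | None = None,
    policy: ThresholdPolicy | None = None,
    size_filter: SizeFilter = SizeFilter(),
    exclusion_mask: np.ndarray | None = None,
    connectivity: int = 8,
    adjustment: AdjustmentParams = AdjustmentParams(),
) -> SegmentationResult:
    """Run the full single-slice detection pipeline on one case.

    The chosen axial slice is rescaled with tail saturation, combined
    with itself (gamma = 2), thresholded inside the ROI at the given or
    characteristic-selected policy, labelled, size-filtered and
    quantified.  Re-running with a different policy or an edited
    exclusion mask is the intended path for difficult cases.

    Exactly one of ``characteristics`` / ``policy`` decides the
    threshold; an explicit ``policy`` wins.
    """
    if policy is None:
        if characteristics is None:
            raise ValueError("provide either characteristics or an explicit policy")
        policy = select_threshold(characteristics)
    if not 0 <= slice_index < volume.shape[2]:
        raise IndexError(
            f"slice_index {slice_index} out of range for volume depth {volume.shape[2]}"
        )

    raw_slice = volume.get_slice(slice_index)
    rescaled = saturate_rescale_array(raw_slice, adjustment)
    adjusted = combine_self_product_array(rescaled, adjustment.out_max)
    candidate = apply_threshold(adjusted, roi, policy, exclusion_mask, adjustment.out_max)
    components = label_objects(candidate, connectivity)
    objects = filter_objects(components, size_filter, volume.spacing)

    from .scoring_stats import condense_score  # local import avoids a cycle

    high_background = characteristics.high_background if characteristics else False
    score = condense_score(len(objects), high_background=high_background).value

    provenance = {
        "saturation_fraction": adjustment.saturation_fraction,
        "gamma_stage": 1.0,
        "combination": "self_product (gamma=2)",
        "out_max": adjustment.out_max,
        "adjust_domain": "slice",
        "connectivity": connectivity,
        "min_voxels": size_filter.min_voxels,
        "max_equivalent_diameter_mm": size_filter.max_equivalent_diameter_mm,
        "exclusion_mask": exclusion_mask is not None,
        "roi_clipped_objects_kept": True,
        "spacing_mm": list(volume.spacing),
    }
    return SegmentationResult(
        objects=tuple(objects),
        policy=policy,
        slice_index=slice_index,
        case_id=volume.id,
        score=score,
        provenance=provenance,
    )
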