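"""Bilateral ovoid basal-ganglia regions of interest.

The assessment is restricted to two ovoid regions on a single axial
slice at the level of the basal ganglia, one per hemisphere, because
PVS identification in the centrum semiovale and the outer parts of the
BG slice is unreliable (elongated spaces, WMH contamination).  On real
data the ROI is drawn by an operator following anatomical boundaries and
supplied as a mask file; for phantoms and scripted analyses an explicit
rotated-ellipse parameterisation is provided here.

Pixel membership is decided at pixel centres (no anti-aliasing): pixel
(r, c) belongs to an ovoid iff, after translating to the centre and
rotating by the ellipse angle, (u/a)^2 + (v/b)^2 <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, RoiBoundsError, RoiOverlapError

__all__ = ["RoiSpec", "RoiMask", "make_ovoid_roi", "validate_roi"]


@dataclass(frozen=True)
class RoiSpec:
    """Parametric description of the two BG ovoids on one axial slice.

    Coordinates are (row, col) in 0-based voxel index space; semi-axes
    ``(a, b)`` are in voxels along the (rotated) row and column
    directions; ``rotation`` is in degrees, counter-clockwise in index
    space.
    """

    slice_index: int
    left_center: tuple[float, float]
    right_center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")


@dataclass(frozen=True)
class RoiMask:
    """Binary ROI mask on one slice, with its component count."""

    mask: np.ndarray
    n_components: int = field(default=0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if self.n_components == 0:
            _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
            object.__setattr__(self, "n_components", int(n))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    rows, cols = np.indices(shape)
    dr = rows - center[0]
    dc = cols - center[1]
    theta = np.deg2rad(rotation_deg)
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_ovoid_roi(slice_shape: tuple[int, int], spec: RoiSpec) -> RoiMask:
    """Rasterise the bilateral ovoid ROI onto a slice.

    Raises
    ------
    RoiBoundsError
        If either ellipse's bounding circle exceeds the slice bounds or
        a centre lies outside the slice.
    RoiOverlapError
        If the two rasterised ovoids overlap or touch (they must form
        exactly two 8-connected components).
    """
    nrows, ncols = slice_shape
    a, b = spec.semi_axes
    theta = np.deg2rad(spec.rotation)
    # tight bounding box of the rotated ellipse
    half_r = np.hypot(a * np.cos(theta), b * np.sin(theta))
    half_c = np.hypot(a * np.sin(theta), b * np.cos(theta))
    for name, (cr, cc) in (("left", spec.left_center), ("right", spec.right_center)):
        if not (0 <= cr < nrows and 0 <= cc < ncols):
            raise RoiBoundsError(f"{name} centre {cr, cc} outside slice {slice_shape}")
        if cr - half_r < -0.5 or cr + half_r > nrows - 0.5 or cc - half_c < -0.5 or cc + half_c > ncols - 0.5:
            raise RoiBoundsError(
                f"{name} ovoid (semi-axes {spec.semi_axes}) exceeds slice bounds"
            )
    left = _ellipse_mask(slice_shape, spec.left_center, spec.semi_axes, spec.rotation)
    right = _ellipse_mask(slice_shape, spec.right_center, spec.semi_axes, spec.rotation)
    if np.any(left & right):
        raise RoiOverlapError("left and right ovoids overlap")
    mask = left | right
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n != 2:
        raise RoiOverlapError(
            f"ovoids must form exactly 2 connected components, got {n}"
        )
    return RoiMask(mask=mask, n_components=2)


def validate_roi(
    mask: np.ndarray, brain_mask: np.ndarray | None = None
) -> dict:
    """Check a user-supplied ROI mask and report its structure.

    Returns a dict with ``n_components``, per-component pixel areas,
    ``valid`` (True iff exactly two components), and — when a brain mask
    is given — the fraction of ROI pixels inside it.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("ROI mask is empty")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    areas = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
    report = {
        "n_components": int(n),
        "component_areas": [int(a) for a in areas],
        "total_area": int(mask.sum()),
        "valid": n == 2,
    }
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        report["fraction_in_brain"] = float((mask & brain_mask).sum() / mask.sum())
    return report
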