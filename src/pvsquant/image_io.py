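"""Reading and writing volumes, masks and result tables.

Volumes are handled through :mod:`nibabel` in NIfTI-1 (``.nii``/``.nii.gz``)
or Analyze 7.5 (``.hdr``/``.img``) format.  All geometry downstream is
computed in 0-based voxel index space, with axial slices indexed along the
third axis; the only use of the header is the voxel spacing, taken from
``pixdim``.  No affine resampling or reorientation is performed, and
intensities are used exactly as stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ImageReadError, InvalidSpacingError, NonVolumeImageError

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import SegmentationResult

__all__ = [
    "IntensityVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar image with its voxel spacing.

    Parameters
    ----------
    data
        Non-negative, finite 3D intensity grid.
    spacing
        ``(dx, dy, dz)`` in mm.  ``dz`` is the centre-to-centre slice
        spacing, i.e. slice thickness plus any inter-slice gap (a 5 mm
        slice with a 1 mm gap has ``dz = 6``).
    id
        Free-text case identifier carried through to reports.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise NonVolumeImageError(
                f"expected a 3D grid, got shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("intensities must be finite")
        if data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidSpacingError(f"spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel, ``dx * dy * dz`` in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def get_slice(self, index: int) -> np.ndarray:
        """Axial slice ``data[:, :, index]`` (0-based)."""
        return self.data[:, :, index]


def read_volume(path: str | Path, id: str | None = None) -> IntensityVolume:
    """Load a 3D volume from a NIfTI-1 or Analyze 7.5 file.

    Intensities are returned exactly as stored (scale slope/intercept
    mandated by the format are applied by nibabel; nothing else is).

    Raises
    ------
    ImageReadError
        If the file is missing or unreadable.
    NonVolumeImageError
        If the image does not have exactly 3 axes (trailing singleton
        axes are squeezed first).
    InvalidSpacingError
        If any voxel dimension is absent, zero or negative.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types here
        raise ImageReadError(f"could not read {path}: {exc}") from exc

    data = np.asanyarray(img.dataobj)
    # 4D files with a singleton last axis are common exports of 2D/3D data
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NonVolumeImageError(
            f"{path} has {data.ndim} axes after squeezing; expected 3"
        )
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise InvalidSpacingError(f"{path} header has voxel dimensions {zooms}")
    return IntensityVolume(
        data=np.ascontiguousarray(data),
        spacing=tuple(float(z) for z in zooms),
        id=id if id is not None else path.name.split(".")[0],
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask (2D slice or single-slice 3D file) as bool."""
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    data = np.asanyarray(nib.load(str(path)).dataobj)
    data = np.squeeze(data)
    if data.ndim not in (2, 3):
        raise NonVolumeImageError(f"mask {path} has {data.ndim} axes")
    return data > 0


def write_volume(volume: IntensityVolume, path: str | Path) -> None:
    """Save a volume as NIfTI-1 with spacing recorded in the header."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


_OBJECT_COLUMNS = [
    "label",
    "voxel_count",
    "area_mm2",
    "equivalent_diameter_mm",
    "centroid_row",
    "centroid_col",
    "volume_ml",
]


def write_results(
    result: "SegmentationResult",
    table_path: str | Path,
    summary_path: str | Path,
) -> None:
    """Write the per-object CSV table and the JSON case summary.

    The CSV has one row per detected object with the fixed column set
    (label, voxel_count, area_mm2, equivalent_diameter_mm, centroid_row,
    centroid_col, volume_ml); an empty result produces a header-only file.
    The summary records case id, slice index, threshold policy, count,
    total volume and condensed score alongside full provenance.
    """
    rows = [
        {
            "label": o.label,
            "voxel_count": o.voxel_count,
            "area_mm2": o.area_mm2,
            "equivalent_diameter_mm": o.equivalent_diameter_mm,
            "centroid_row": o.centroid[0],
            "centroid_col": o.centroid[1],
            "volume_ml": o.volume_ml,
        }
        for o in result.objects
    ]
    pd.DataFrame(rows, columns=_OBJECT_COLUMNS).to_csv(table_path, index=False)

    summary = {
        "case_id": result.case_id,
        "slice_index": result.slice_index,
        "threshold_level": result.policy.level,
        "threshold_fraction_of_max": result.policy.fraction_of_max,
        "count": result.count,
        "total_volume_ml": result.total_volume_ml,
        "score": result.score,
        "provenance": result.provenance,
    }
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(table_path: str | Path, summary_path: str | Path):
    """Load a previously written object table and summary.

    Returns ``(DataFrame, dict)``; the inverse of :func:`write_results`
    for inspection and round-trip tests.
    """
    table = pd.read_csv(table_path)
    with open(summary_path) as fh:
        summary = json.load(fh)
    return table, summary
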