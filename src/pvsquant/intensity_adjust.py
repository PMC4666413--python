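"""Three-stage intensity adjustment for T2-weighted slices.

Perivascular spaces appear on T2W at anywhere from 30% to 90% of the
image maximum, so no single threshold separates them from tissue on the
raw image.  The adjustment makes one threshold workable:

1. ``saturate_rescale`` — a linear map (gamma = 1) that saturates the 1%
   lowest and highest intensities at the output minimum and maximum and
   rescales to ``[0, out_max]``.  Saturation pulls the effective maximum
   below bright CSF, lifting faint spaces relative to the ceiling.
2. ``gamma_correct`` — power-law remapping

       i' = I_max * ((i - I_min) / (I_max - I_min))**gamma + I_min

   with fixed points at ``I_min`` and ``I_max``.
3. ``combine_self_product`` — the voxelwise product of the rescaled image
   with itself, divided by ``out_max``.  Because the rescaled image has
   minimum 0, this is identical to gamma correction with gamma = 2; it
   deepens the separation between background tissue and the bright dots.

All three maps are monotone non-decreasing in input intensity, so they
never reorder structures, only reshape the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyDomainError, NegativeIntensityError, ZeroDynamicRangeError
from .image_io import IntensityVolume

__all__ = [
    "AdjustmentParams",
    "saturate_rescale",
    "saturate_rescale_array",
    "gamma_correct",
    "gamma_correct_array",
    "combine_self_product",
    "combine_self_product_array",
]


@dataclass(frozen=True)
class AdjustmentParams:
    """Parameters of the saturating rescale stage.

    saturation_fraction: fraction of voxels saturated at each tail
    (default 0.01, i.e. the lowest and highest 1%); gamma: exponent of
    the power-law stage (1 = plain rescale); out_max: output ceiling of
    the normalised scale (default 255) against which all threshold
    fractions are later taken.
    """

    saturation_fraction: float = 0.01
    gamma: float = 1.0
    out_max: float = 255.0

    def __post_init__(self) -> None:
        if not 0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.out_max <= 0:
            raise ValueError("out_max must be positive")


def _saturation_bounds(values: np.ndarray, fraction: float) -> tuple[float, float]:
    """Order-statistic saturation limits: with ``k = floor(fraction * n)``,
    the k-th smallest and k-th largest value (0-based)."""
    values = np.sort(values, axis=None)
    n = values.size
    k = int(np.floor(fraction * n))
    low, high = float(values[k]), float(values[n - 1 - k])
    if high == low:
        raise ZeroDynamicRangeError(
            "all intensities equal after saturation; cannot rescale"
        )
    return low, high


def saturate_rescale_array(
    data: np.ndarray,
    params: AdjustmentParams = AdjustmentParams(),
    domain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Saturating linear rescale of an array to ``[0, out_max]``.

    Saturation limits ``L`` and ``H`` are the order statistics of the
    intensities inside ``domain_mask`` (whole array if None); values are
    clipped to ``[L, H]`` and mapped affinely so that ``L -> 0`` and
    ``H -> out_max``.
    """
    data = np.asarray(data, dtype=float)
    if domain_mask is not None:
        domain_mask = np.asarray(domain_mask, dtype=bool)
        if domain_mask.shape != data.shape:
            raise EmptyDomainError(
                f"domain mask shape {domain_mask.shape} != data shape {data.shape}"
            )
        sample = data[domain_mask]
        if sample.size < 2:
            raise EmptyDomainError("domain mask selects fewer than 2 voxels")
    else:
        sample = data
    low, high = _saturation_bounds(sample, params.saturation_fraction)
    out = np.clip(data, low, high)
    return (out - low) / (high - low) * params.out_max


def saturate_rescale(
    volume: IntensityVolume,
    params: AdjustmentParams = AdjustmentParams(),
    domain_mask: np.ndarray | None = None,
) -> IntensityVolume:
    """Volume wrapper for :func:`saturate_rescale_array`."""
    out = saturate_rescale_array(volume.data, params, domain_mask)
    return IntensityVolume(out, volume.spacing, volume.id)


def gamma_correct_array(data: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law remap with fixed points at the data minimum and maximum."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    data = np.asarray(data, dtype=float)
    i_min, i_max = float(data.min()), float(data.max())
    if i_max == i_min:
        raise ZeroDynamicRangeError("gamma correction needs I_max > I_min")
    # endpoint-preserving form; identical to scaling by I_max alone when
    # I_min = 0, which is the case after the saturating rescale
    return (i_max - i_min) * ((data - i_min) / (i_max - i_min)) ** gamma + i_min


def gamma_correct(volume: IntensityVolume, gamma: float) -> IntensityVolume:
    """Volume wrapper for :func:`gamma_correct_array`."""
    return IntensityVolume(gamma_correct_array(volume.data, gamma), volume.spacing, volume.id)


def combine_self_product_array(data: np.ndarray, out_max: float = 255.0) -> np.ndarray:
    """Voxelwise self-product ``i**2 / out_max`` of a rescaled image.

    On an image spanning ``[0, out_max]`` this equals gamma correction
    with gamma = 2 (the minimum being zero makes the two forms identical),
    and the output range stays ``[0, out_max]``.
    """
    data = np.asarray(data, dtype=float)
    if data.size and data.min() < 0:
        raise NegativeIntensityError(
            "self-product combination requires non-negative intensities "
            "(apply saturate_rescale first)"
        )
    return data * data / out_max


def combine_self_product(volume: IntensityVolume, out_max: float = 255.0) -> IntensityVolume:
    """Volume wrapper for :func:`combine_self_product_array`."""
    return IntensityVolume(
        combine_self_product_array(volume.data, out_max), volume.spacing, volume.id
    )
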