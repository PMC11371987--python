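"""Voxel-associated normal strain (field of strain) between two inflation states.

Lung strain is the relative volume change from the resting state,
(V1 - V_FRC)/V_FRC. Assuming deformation is homogeneous inside each voxel
and purely normal (perpendicular to voxel faces), the per-axis share of
the voxel volumetric strain is

    VoStrain_i = (1/3) * (V_i,1 - V_i,FRC) / V_i,FRC

computed from the CT-derived gas content of voxel i at the inflated (V1)
and reference (FRC/ZEEP) states. Voxels that are completely gasless at
reference (atelectasis) would yield infinite strain; they receive an
arbitrary gas-content floor — by default 0.01% of the voxel volume — in
the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .aeration import AerationMap

__all__ = ["StrainField", "vostrain_map", "whole_slice_strain_summary", "SliceSummary"]

logger = logging.getLogger(__name__)

DEFAULT_FLOOR_FRACTION = 1e-4  # 0.01% of voxel volume


@dataclass
class StrainField:
    """Per-voxel VoStrain map (dimensionless) over a lung mask."""

    vostrain: np.ndarray
    mask: np.ndarray
    floor_fraction: float
    n_floored: int


@dataclass
class SliceSummary:
    """Descriptive statistics of a map over the masked voxels of one slice."""

    mean: float
    sd: float
    median: float
    iqr: float
    n_voxels: int


def vostrain_map(
    ref: AerationMap,
    inflated: AerationMap,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> StrainField:
    """Compute the voxel-associated normal strain field between two states.

    Parameters
    ----------
    ref, inflated : AerationMap
        Gas-content maps at the reference (ZEEP/FRC) and inflated states.
        Must share grid shape, voxel volume and mask, and be voxel-wise
        co-registered.
    floor_fraction : float
        Gas floor for empty reference voxels, as a fraction of voxel
        volume. Default 1e-4 (0.01%).

    Returns
    -------
    StrainField
        vostrain = (1/3) (gas_inflated - gas_ref') / gas_ref' with
        gas_ref' = max(gas_ref, floor_fraction * voxel_volume);
        ``n_floored`` counts reference voxels inside the mask that
        received the floor.
    """
    if floor_fraction <= 0:
        raise ValueError(f"floor_fraction must be > 0, got {floor_fraction}")
    if ref.gas_volume.shape != inflated.gas_volume.shape:
        raise ValueError("reference and inflated grids differ in shape")
    if not np.isclose(ref.voxel_volume, inflated.voxel_volume):
        raise ValueError("reference and inflated voxel volumes differ")
    if not np.array_equal(ref.mask, inflated.mask):
        raise ValueError("reference and inflated masks differ")

    floor = floor_fraction * ref.voxel_volume
    gas_ref = np.maximum(ref.gas_volume, floor)
    n_floored = int(np.count_nonzero(ref.gas_volume[ref.mask] < floor))
    if n_floored:
        logger.warning(
            "vostrain_map: %d masked reference voxels below the %.4g%% gas floor",
            n_floored,
            100 * floor_fraction,
        )
    vostrain = (inflated.gas_volume - gas_ref) / (3.0 * gas_ref)
    return StrainField(
        vostrain=vostrain,
        mask=ref.mask.copy(),
        floor_fraction=floor_fraction,
        n_floored=n_floored,
    )


def whole_slice_strain_summary(
    field: StrainField, slice_index: int, slice_axis: int = 0
) -> SliceSummary:
    """Mean, SD, median and IQR of VoStrain over one transverse slice.

    SD is the population (n-denominator) standard deviation; IQR is the
    75th minus the 25th percentile (linear interpolation). Raises if the
    slice carries no masked voxels.
    """
    return summarize_slice(field.vostrain, field.mask, slice_index, slice_axis)


def summarize_slice(
    values: np.ndarray, mask: np.ndarray, slice_index: int, slice_axis: int = 0
) -> SliceSummary:
    """Descriptive statistics of any voxel map over one masked slice."""
    if not 0 <= slice_index < values.shape[slice_axis]:
        raise IndexError(f"slice {slice_index} outside axis of length {values.shape[slice_axis]}")
    sl = np.take(values, slice_index, axis=slice_axis)
    m = np.take(mask, slice_index, axis=slice_axis).astype(bool)
    if not m.any():
        raise ValueError(f"no masked voxels on slice {slice_index}")
    v = sl[m]
    sd = float(np.std(v)) if v.size > 1 else 0.0
    q25, q75 = np.percentile(v, [25, 75])
    return SliceSummary(
        mean=float(np.mean(v)),
        sd=sd,
        median=float(np.median(v)),
        iqr=float(q75 - q25),
        n_voxels=int(v.size),
    )
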