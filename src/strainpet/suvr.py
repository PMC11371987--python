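"""Standardized uptake value ratio (SUVR) maps from PET activity volumes.

The SUVR of a lung voxel is its radioactivity concentration divided by the
average concentration inside a blood-pool reference region (the left
ventricle), both taken from the same image:

    SUVR(x, y, z) = c_voxel(x, y, z) / c_ref

A dynamic series is reduced to the single late frame whose mid-time is
nearest the analysis time (default 3596 s ~ 1 h post-injection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUVRMap",
    "reference_concentration",
    "suvr_map",
    "select_frame",
    "DEFAULT_FRAME_TIME_S",
]

DEFAULT_FRAME_TIME_S = 3596.0


@dataclass
class SUVRMap:
    """Voxel-wise SUVR map with its reference concentration.

    Attributes
    ----------
    suvr : ndarray
        Dimensionless per-voxel ratio.
    c_ref : float
        Blood-pool reference concentration, MBq/mL. Always positive.
    frame_time_s : float
        Acquisition time of the analyzed frame, seconds post-injection.
    mask : ndarray of bool
        Lung voxels.
    """

    suvr: np.ndarray
    c_ref: float
    frame_time_s: float
    mask: np.ndarray


def reference_concentration(pet: np.ndarray, ref_roi_mask: np.ndarray) -> float:
    """Arithmetic mean activity (MBq/mL) over the blood-pool reference ROI.

    Raises
    ------
    ValueError
        If the ROI is empty or its mean activity is not positive.
    """
    pet = np.asarray(pet, dtype=float)
    roi = np.asarray(ref_roi_mask, dtype=bool)
    if roi.shape != pet.shape:
        raise ValueError(f"ROI shape {roi.shape} != PET shape {pet.shape}")
    if not roi.any():
        raise ValueError("reference ROI is empty")
    c_ref = float(np.mean(pet[roi]))
    if not c_ref > 0:
        raise ValueError(f"reference concentration must be > 0, got {c_ref}")
    return c_ref


def select_frame(
    series: np.ndarray,
    frame_mid_times_s: np.ndarray,
    target_time_s: float = DEFAULT_FRAME_TIME_S,
) -> tuple[np.ndarray, float]:
    """Pick from a 4-D dynamic series the frame whose mid-time is nearest
    ``target_time_s``; returns (3-D volume, selected mid-time)."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(frame_mid_times_s, dtype=float)
    if series.ndim != 4:
        raise ValueError(f"dynamic series must be 4-D, got ndim={series.ndim}")
    if times.shape != (series.shape[-1],):
        raise ValueError("frame_mid_times_s length must match the last series axis")
    i = int(np.argmin(np.abs(times - target_time_s)))
    return series[..., i], float(times[i])


def suvr_map(
    pet: np.ndarray,
    c_ref: float,
    mask: np.ndarray,
    frame_time_s: float = DEFAULT_FRAME_TIME_S,
) -> SUVRMap:
    """Divide a (static) PET activity volume by the reference concentration.

    Scaling the whole PET image (lung and reference together) by any
    positive constant leaves the resulting map unchanged.
    """
    pet = np.asarray(pet, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pet.shape:
        raise ValueError(f"mask shape {mask.shape} != PET shape {pet.shape}")
    if not c_ref > 0:
        raise ValueError(f"c_ref must be > 0, got {c_ref}")
    return SUVRMap(suvr=pet / c_ref, c_ref=float(c_ref), frame_time_s=float(frame_time_s), mask=mask)
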